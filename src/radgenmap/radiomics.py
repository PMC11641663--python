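"""3D radiomic feature extraction on segmented tumour volumes.

The engine computes first-order intensity statistics and four
gray-level texture families (GLCM, GLRLM, GLSZM, GLDM) on a discretized
region of interest, optionally after applying an image filter
(Laplacian of Gaussian, separable Haar wavelet subbands, logarithm
rescaling, or a simplified 3D local binary pattern). Feature formulas
follow the IBSI / PyRadiomics conventions; texture matrices are built
from 26-connected 3D neighbourhoods at distance 1 and direction-dependent
families aggregate by averaging the per-direction feature values.

Also provides the Dice similarity coefficient for comparing two binary
segmentations of the same volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "FilterSpec",
    "DiscretizedROI",
    "DEFAULT_FILTERS",
    "dice",
    "apply_filter",
    "discretize",
    "firstorder_features",
    "texture_features",
    "extract_feature_vector",
]

# The 13 unique direction vectors of the 26-connected 3D neighbourhood
# (one representative per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass(frozen=True)
class ImageVolume:
    """A 3D intensity grid with physical voxel spacing in mm."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 3:
            raise ValueError("image grid must be 3D")
        if not np.all(np.isfinite(grid)):
            raise ValueError("image contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} voxel mask aligned with an :class:`ImageVolume`."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must contain only 0/1 values")
        object.__setattr__(self, "grid", grid.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class FilterSpec:
    """Image filter specification.

    kind
        One of ``original``, ``log_sigma`` (Laplacian of Gaussian),
        ``wavelet`` (single-level 3D Haar subband), ``logarithm``,
        ``lbp3d``.
    sigma_mm
        LoG scale in millimetres (``log_sigma`` only).
    subband
        Three-letter code over {L, H}, e.g. ``"LLH"`` (``wavelet`` only).
    """

    kind: str
    sigma_mm: float | None = None
    subband: str | None = None

    VALID_KINDS = ("original", "log_sigma", "wavelet", "logarithm", "lbp3d")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        if self.kind == "log_sigma":
            if self.sigma_mm is None or self.sigma_mm <= 0:
                raise ValueError("log_sigma requires a positive sigma_mm")
        elif self.sigma_mm is not None:
            raise ValueError("sigma_mm is only valid for log_sigma")
        if self.kind == "wavelet":
            if self.subband is None or len(self.subband) != 3 or set(self.subband) - {"L", "H"}:
                raise ValueError("wavelet requires a 3-letter subband over {L,H}")
        elif self.subband is not None:
            raise ValueError("subband is only valid for wavelet")

    @property
    def name(self) -> str:
        if self.kind == "log_sigma":
            s = ("%g" % self.sigma_mm).replace(".", "-")
            return f"log-sigma-{s}mm"
        if self.kind == "wavelet":
            return f"wavelet-{self.subband}"
        return self.kind


DEFAULT_FILTERS: tuple[FilterSpec, ...] = (
    FilterSpec("original"),
    FilterSpec("log_sigma", sigma_mm=2.0),
    FilterSpec("log_sigma", sigma_mm=3.0),
    FilterSpec("wavelet", subband="LLL"),
    FilterSpec("wavelet", subband="LLH"),
    FilterSpec("wavelet", subband="LHL"),
    FilterSpec("logarithm"),
    FilterSpec("lbp3d"),
)


@dataclass(frozen=True)
class DiscretizedROI:
    """Masked voxels mapped to integer gray levels 1..Ng.

    Keeps the level values on the full 3D grid (0 outside the mask) so
    spatial texture matrices can be built; ``levels_flat`` gives the
    masked values only.
    """

    level_grid: np.ndarray
    mask: np.ndarray
    bin_width: float

    @property
    def ng(self) -> int:
        return int(self.level_grid.max())

    @property
    def levels_flat(self) -> np.ndarray:
        return self.level_grid[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient DSC = 2|A n B| / (|A| + |B|)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks have different shapes")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.logical_and(a.grid, b.grid).sum())
    return 2.0 * inter / (na + nb)


def _wavelet_subband(grid: np.ndarray, subband: str) -> np.ndarray:
    """Single-level 3D Haar decomposition; reconstruct one subband to
    the original grid shape (other subbands zeroed)."""
    coeffs = pywt.dwtn(grid, "haar", axes=(0, 1, 2))
    # pywt keys use 'a'/'d' per axis; map L->a, H->d
    key = subband.replace("L", "a").replace("H", "d")
    kept = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
    rec = pywt.idwtn(kept, "haar", axes=(0, 1, 2))
    return rec[tuple(slice(0, s) for s in grid.shape)]


def _lbp3d(grid: np.ndarray) -> np.ndarray:
    """Simplified 3D local binary pattern: for each voxel, the count of
    26-neighbours with intensity >= the centre voxel. The count is
    invariant to rotations of the neighbourhood, which stands in for
    rotation normalisation of the full spherical pattern."""
    out = np.zeros(grid.shape, dtype=float)
    padded = np.pad(grid, 1, mode="edge")
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                shifted = padded[
                    1 + dz : 1 + dz + grid.shape[0],
                    1 + dy : 1 + dy + grid.shape[1],
                    1 + dx : 1 + dx + grid.shape[2],
                ]
                out += (shifted >= grid).astype(float)
    return out


def apply_filter(v: ImageVolume, spec: FilterSpec) -> ImageVolume:
    """Apply an image filter; shape and spacing are preserved."""
    grid = v.grid
    if spec.kind == "original":
        out = grid.copy()
    elif spec.kind == "log_sigma":
        sigma_vox = [spec.sigma_mm / s for s in v.spacing_mm]
        out = ndimage.gaussian_laplace(grid, sigma=sigma_vox)
        # the truncated discrete kernel does not sum exactly to zero;
        # subtract the response to the DC level so constants map to 0
        dc = ndimage.gaussian_laplace(np.ones_like(grid), sigma=sigma_vox)
        out = out - grid.mean() * dc
    elif spec.kind == "wavelet":
        out = _wavelet_subband(grid, spec.subband)
    elif spec.kind == "logarithm":
        out = np.sign(grid) * np.log1p(np.abs(grid))
    elif spec.kind == "lbp3d":
        out = _lbp3d(grid)
    else:  # pragma: no cover - guarded by FilterSpec
        raise ValueError(spec.kind)
    return ImageVolume(out, v.spacing_mm)


def discretize(v: ImageVolume, m: BinaryMask, bin_width: float = 20.0) -> DiscretizedROI:
    """Fixed-bin-width discretization anchored at the ROI minimum.

    level(x) = floor((x - min_ROI) / bin_width) + 1
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if v.grid.shape != m.grid.shape:
        raise ValueError("volume and mask shapes differ")
    if m.n_voxels == 0:
        raise ValueError("mask is empty")
    vals = v.grid[m.grid]
    levels = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    level_grid = np.zeros(v.grid.shape, dtype=np.int64)
    level_grid[m.grid] = levels
    return DiscretizedROI(level_grid, m.grid.copy(), float(bin_width))


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


def firstorder_features(roi_values: np.ndarray) -> dict[str, float]:
    """First-order intensity statistics of the masked voxels.

    Skewness is the Fisher population skewness (third standardized
    moment); it is defined as 0 for zero-variance input.
    """
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mu = x.mean()
    var = x.var()  # population
    if var > 0:
        skew = float(np.mean((x - mu) ** 3) / var**1.5)
    else:
        skew = 0.0
    return {
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Mean": float(mu),
        "Median": float(np.median(x)),
        "Variance": float(var),
        "Skewness": skew,
        "Range": float(x.max() - x.min()),
        "Energy": float(np.sum(x**2)),
    }


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------


def glcm_matrices(d: DiscretizedROI) -> list[np.ndarray]:
    """Symmetric gray-level co-occurrence matrix per direction
    (counts, Ng x Ng, level i at row i-1)."""
    ng = d.ng
    lev = d.level_grid
    mask = d.mask
    out = []
    for (dz, dy, dx) in DIRECTIONS_3D:
        m = np.zeros((ng, ng), dtype=float)
        src = _shift_view(lev, mask, dz, dy, dx)
        if src is not None:
            a, b = src
            np.add.at(m, (a - 1, b - 1), 1.0)
        m = m + m.T
        out.append(m)
    return out


def _shift_view(lev, mask, dz, dy, dx):
    """Pairs (level_at_voxel, level_at_voxel+offset) for voxels where
    both ends are inside the mask."""
    nz, ny, nx = lev.shape
    sz0, sz1 = max(0, -dz), min(nz, nz - dz)
    sy0, sy1 = max(0, -dy), min(ny, ny - dy)
    sx0, sx1 = max(0, -dx), min(nx, nx - dx)
    if sz0 >= sz1 or sy0 >= sy1 or sx0 >= sx1:
        return None
    a_lev = lev[sz0:sz1, sy0:sy1, sx0:sx1]
    a_msk = mask[sz0:sz1, sy0:sy1, sx0:sx1]
    b_lev = lev[sz0 + dz : sz1 + dz, sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx]
    b_msk = mask[sz0 + dz : sz1 + dz, sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx]
    both = a_msk & b_msk
    if not both.any():
        return None
    return a_lev[both], b_lev[both]


def glrlm_matrices(d: DiscretizedROI) -> list[np.ndarray]:
    """Gray-level run-length matrix per direction (Ng x Nr_max)."""
    ng = d.ng
    lev = d.level_grid.astype(np.int64)
    mask = d.mask
    max_run = max(lev.shape)
    out = []
    for (dz, dy, dx) in DIRECTIONS_3D:
        m = np.zeros((ng, max_run), dtype=float)
        # run starts: masked voxels whose predecessor along -d is not the
        # same level inside the mask
        starts = mask.copy()
        prev = _neighbour_same(lev, mask, -dz, -dy, -dx)
        starts &= ~prev
        # walk forward from each start counting run length
        coords = np.argwhere(starts)
        if coords.size:
            levels_at = lev[starts]
            lengths = np.ones(len(coords), dtype=np.int64)
            cur = coords.copy()
            active = np.ones(len(coords), dtype=bool)
            step = np.array([dz, dy, dx])
            while active.any():
                nxt = cur[active] + step
                ok = np.all((nxt >= 0) & (nxt < lev.shape), axis=1)
                idx_active = np.flatnonzero(active)
                cont = np.zeros(len(idx_active), dtype=bool)
                if ok.any():
                    n_ok = nxt[ok]
                    same = mask[n_ok[:, 0], n_ok[:, 1], n_ok[:, 2]] & (
                        lev[n_ok[:, 0], n_ok[:, 1], n_ok[:, 2]]
                        == levels_at[idx_active[ok]]
                    )
                    cont[ok] = same
                lengths[idx_active[cont]] += 1
                cur[idx_active[cont]] += step
                active[idx_active[~cont]] = False
            np.add.at(m, (levels_at - 1, lengths - 1), 1.0)
        out.append(m)
    return out


def _neighbour_same(lev, mask, dz, dy, dx):
    """Boolean grid: the voxel at +offset is inside the grid, masked and
    has the same level."""
    res = np.zeros(lev.shape, dtype=bool)
    nz, ny, nx = lev.shape
    sz0, sz1 = max(0, -dz), min(nz, nz - dz)
    sy0, sy1 = max(0, -dy), min(ny, ny - dy)
    sx0, sx1 = max(0, -dx), min(nx, nx - dx)
    if sz0 >= sz1 or sy0 >= sy1 or sx0 >= sx1:
        return res
    a = lev[sz0:sz1, sy0:sy1, sx0:sx1]
    b = lev[sz0 + dz : sz1 + dz, sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx]
    bm = mask[sz0 + dz : sz1 + dz, sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx]
    res[sz0:sz1, sy0:sy1, sx0:sx1] = bm & (a == b)
    return res


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Gray-level size-zone matrix (Ng x Nz_max): 26-connected zones of
    equal gray level."""
    ng = d.ng
    lev = d.level_grid
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        lab, n = ndimage.label(lev == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    if not zones:
        raise ValueError("empty ROI")
    max_size = max(s for _, s in zones)
    m = np.zeros((ng, max_size), dtype=float)
    for g, s in zones:
        m[g - 1, s - 1] += 1.0
    return m


def gldm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Gray-level dependence matrix (Ng x (1+26)): dependence of a voxel
    = number of 26-neighbours inside the mask with equal gray level
    (tolerance 0); column index j = dependence + 1."""
    lev = d.level_grid
    mask = d.mask
    dep = np.zeros(lev.shape, dtype=np.int64)
    for (dz, dy, dx) in DIRECTIONS_3D:
        dep += _neighbour_same(lev, mask, dz, dy, dx)
        dep += _neighbour_same(lev, mask, -dz, -dy, -dx)
    ng = d.ng
    m = np.zeros((ng, 27), dtype=float)
    np.add.at(m, (lev[mask] - 1, dep[mask]), 1.0)
    # trim trailing all-zero dependence columns
    last = int(np.max(np.nonzero(m.sum(axis=0))[0])) if m.any() else 0
    return m[:, : last + 1]


# ---------------------------------------------------------------------------
# texture features from matrices
# ---------------------------------------------------------------------------

_EPS = np.finfo(float).eps


def glcm_features_from_matrix(m: np.ndarray) -> dict[str, float]:
    """GLCM features of one symmetric co-occurrence count matrix."""
    total = m.sum()
    if total == 0:
        # degenerate direction (e.g. single voxel); all features 0
        return {"Imc2": 0.0, "JointEntropy": 0.0, "Contrast": 0.0, "JointEnergy": 0.0}
    p = m / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -np.sum(px * np.log2(px + _EPS))
    hxy = -np.sum(p * np.log2(p + _EPS))
    hxy2 = -np.sum(np.outer(px, py) * np.log2(np.outer(px, py) + _EPS))
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy) * np.log(2))
    imc2 = float(np.sqrt(max(arg, 0.0)))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    return {
        "Imc2": imc2,
        "JointEntropy": float(hxy),
        "Contrast": contrast,
        "JointEnergy": float(np.sum(p**2)),
    }


def glrlm_features_from_matrix(m: np.ndarray) -> dict[str, float]:
    nr = m.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    ng, lmax = m.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, lmax + 1)[None, :].astype(float)
    return {
        "ShortRunEmphasis": float(np.sum(m / j**2) / nr),
        "LongRunEmphasis": float(np.sum(m * j**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(m / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(m * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(m / (i**2 * j**2)) / nr),
        "RunPercentage": float(nr / np.sum(m * j)),
    }


def glszm_features_from_matrix(m: np.ndarray) -> dict[str, float]:
    nz = m.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    ng, smax = m.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, smax + 1)[None, :].astype(float)
    return {
        "SmallAreaEmphasis": float(np.sum(m / j**2) / nz),
        "LargeAreaEmphasis": float(np.sum(m * j**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(m / (i**2 * j**2)) / nz),
        "GrayLevelNonUniformity": float(np.sum(m.sum(axis=1) ** 2) / nz),
        "ZonePercentage": float(nz / np.sum(m * j)),
    }


def gldm_features_from_matrix(m: np.ndarray) -> dict[str, float]:
    nd = m.sum()
    if nd == 0:
        raise ValueError("empty dependence matrix")
    ng, dmax = m.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, dmax + 1)[None, :].astype(float)
    return {
        "SmallDependenceEmphasis": float(np.sum(m / j**2) / nd),
        "LargeDependenceEmphasis": float(np.sum(m * j**2) / nd),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(m * j**2 / i**2) / nd),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(m * j**2 * i**2) / nd),
        "DependenceNonUniformity": float(np.sum(m.sum(axis=0) ** 2) / nd),
    }


def texture_features(d: DiscretizedROI, family: str) -> dict[str, float]:
    """Features of one texture family on a discretized ROI.

    Direction-dependent families (GLCM, GLRLM) average the feature
    values over the 13 unique 3D directions.
    """
    if d.n_voxels == 0 or d.ng == 0:
        raise ValueError("empty ROI")
    if family == "GLCM":
        per_dir = [glcm_features_from_matrix(m) for m in glcm_matrices(d)]
        return _average_dicts(per_dir)
    if family == "GLRLM":
        per_dir = [glrlm_features_from_matrix(m) for m in glrlm_matrices(d)]
        return _average_dicts(per_dir)
    if family == "GLSZM":
        return glszm_features_from_matrix(glszm_matrix(d))
    if family == "GLDM":
        return gldm_features_from_matrix(gldm_matrix(d))
    raise ValueError(f"unknown texture family: {family!r}")


def _average_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "GLDM")


def extract_feature_vector(
    v: ImageVolume,
    m: BinaryMask,
    filters: tuple[FilterSpec, ...] = DEFAULT_FILTERS,
    bin_width: float = 20.0,
) -> dict[str, float]:
    """Full radiomic feature vector over a filter bank.

    Feature names follow "<filter>_<class>_<feature>", e.g.
    ``wavelet-LHL_glszm_SmallAreaLowGrayLevelEmphasis``.
    """
    if v.grid.shape != m.grid.shape:
        raise ValueError("volume and mask shapes differ")
    if m.n_voxels == 0:
        raise ValueError("mask is empty")
    out: dict[str, float] = {}
    for spec in filters:
        filtered = apply_filter(v, spec)
        prefix = spec.name
        fo = firstorder_features(filtered.grid[m.grid])
        for k, val in fo.items():
            out[f"{prefix}_firstorder_{k}"] = val
        d = discretize(filtered, m, bin_width)
        for family in TEXTURE_FAMILIES:
            feats = texture_features(d, family)
            for k, val in feats.items():
                out[f"{prefix}_{family.lower()}_{k}"] = val
    return out
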