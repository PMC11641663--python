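"""Independent brute-force oracles for texture features and exact tests.

Everything here is written with plain Python loops and explicit
enumeration (all voxel pairs, all maximal runs, flood-filled zones,
neighbour counting, full hypergeometric sums) so it shares no code
path with the vectorised implementations it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
DIRECTIONS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def _masked_level(level_grid, mask, v):
    if _inside(level_grid.shape, v) and mask[v]:
        return int(level_grid[v])
    return None


# ---------------------------------------------------------------------------
# matrix construction by exhaustive enumeration
# ---------------------------------------------------------------------------


def glcm_oracle_matrices(level_grid, mask, ng):
    """One symmetric co-occurrence matrix per direction, counting every
    ordered voxel pair in both orientations."""
    out = []
    shape = level_grid.shape
    for d in DIRECTIONS_13:
        m = [[0.0] * ng for _ in range(ng)]
        for v in product(*(range(s) for s in shape)):
            a = _masked_level(level_grid, mask, v)
            if a is None:
                continue
            w = tuple(v[i] + d[i] for i in range(3))
            b = _masked_level(level_grid, mask, w)
            if b is None:
                continue
            m[a - 1][b - 1] += 1
            m[b - 1][a - 1] += 1
        out.append(np.array(m))
    return out


def glrlm_oracle_matrices(level_grid, mask, ng):
    """Run-length matrices: explicitly list every maximal run per
    direction."""
    shape = level_grid.shape
    max_run = max(shape)
    out = []
    for d in DIRECTIONS_13:
        m = [[0.0] * max_run for _ in range(ng)]
        for v in product(*(range(s) for s in shape)):
            lev = _masked_level(level_grid, mask, v)
            if lev is None:
                continue
            prev = tuple(v[i] - d[i] for i in range(3))
            if _masked_level(level_grid, mask, prev) == lev:
                continue  # not a run start
            length = 1
            w = tuple(v[i] + d[i] for i in range(3))
            while _masked_level(level_grid, mask, w) == lev:
                length += 1
                w = tuple(w[i] + d[i] for i in range(3))
            m[lev - 1][length - 1] += 1
        out.append(np.array(m))
    return out


def glszm_oracle_matrix(level_grid, mask, ng):
    """Size-zone matrix via explicit flood fill over 26-connectivity."""
    shape = level_grid.shape
    seen = set()
    zones = []
    for v in product(*(range(s) for s in shape)):
        lev = _masked_level(level_grid, mask, v)
        if lev is None or v in seen:
            continue
        stack = [v]
        seen.add(v)
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in OFFSETS_26:
                w = tuple(u[i] + d[i] for i in range(3))
                if w not in seen and _masked_level(level_grid, mask, w) == lev:
                    seen.add(w)
                    stack.append(w)
        zones.append((lev, size))
    max_size = max(s for _, s in zones)
    m = [[0.0] * max_size for _ in range(ng)]
    for lev, size in zones:
        m[lev - 1][size - 1] += 1
    return np.array(m)


def gldm_oracle_matrix(level_grid, mask, ng):
    """Dependence matrix: per masked voxel, count equal-level masked
    26-neighbours; column j = dependence + 1."""
    shape = level_grid.shape
    counts = {}
    max_dep = 0
    for v in product(*(range(s) for s in shape)):
        lev = _masked_level(level_grid, mask, v)
        if lev is None:
            continue
        dep = 0
        for d in OFFSETS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _masked_level(level_grid, mask, w) == lev:
                dep += 1
        counts[(lev, dep)] = counts.get((lev, dep), 0) + 1
        max_dep = max(max_dep, dep)
    m = [[0.0] * (max_dep + 1) for _ in range(ng)]
    for (lev, dep), c in counts.items():
        m[lev - 1][dep] += c
    return np.array(m)


# ---------------------------------------------------------------------------
# feature formulas with explicit loops
# ---------------------------------------------------------------------------


def glcm_oracle_features(m):
    total = m.sum()
    if total == 0:
        return {"Imc2": 0.0, "JointEntropy": 0.0, "Contrast": 0.0, "JointEnergy": 0.0}
    ng = m.shape[0]
    p = m / total
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    eps = np.finfo(float).eps
    hxy = -sum(
        p[i][j] * math.log2(p[i][j] + eps) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + eps)
        for i in range(ng)
        for j in range(ng)
    )
    arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy) * math.log(2))
    contrast = sum(
        p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
    )
    energy = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    return {
        "Imc2": math.sqrt(max(arg, 0.0)),
        "JointEntropy": hxy,
        "Contrast": contrast,
        "JointEnergy": energy,
    }


def glrlm_oracle_features(m):
    nr = m.sum()
    ng, lmax = m.shape
    def s(f):
        return sum(f(i + 1, j + 1) * m[i][j] for i in range(ng) for j in range(lmax))
    return {
        "ShortRunEmphasis": s(lambda i, j: 1 / j**2) / nr,
        "LongRunEmphasis": s(lambda i, j: j**2) / nr,
        "LowGrayLevelRunEmphasis": s(lambda i, j: 1 / i**2) / nr,
        "HighGrayLevelRunEmphasis": s(lambda i, j: i**2) / nr,
        "ShortRunLowGrayLevelEmphasis": s(lambda i, j: 1 / (i**2 * j**2)) / nr,
        "RunPercentage": nr / s(lambda i, j: j),
    }


def glszm_oracle_features(m):
    nz = m.sum()
    ng, smax = m.shape
    def s(f):
        return sum(f(i + 1, j + 1) * m[i][j] for i in range(ng) for j in range(smax))
    gln = sum(sum(m[i]) ** 2 for i in range(ng))
    return {
        "SmallAreaEmphasis": s(lambda i, j: 1 / j**2) / nz,
        "LargeAreaEmphasis": s(lambda i, j: j**2) / nz,
        "SmallAreaLowGrayLevelEmphasis": s(lambda i, j: 1 / (i**2 * j**2)) / nz,
        "GrayLevelNonUniformity": gln / nz,
        "ZonePercentage": nz / s(lambda i, j: j),
    }


def gldm_oracle_features(m):
    nd = m.sum()
    ng, dmax = m.shape
    def s(f):
        return sum(f(i + 1, j + 1) * m[i][j] for i in range(ng) for j in range(dmax))
    dnu = sum(sum(m[i][j] for i in range(ng)) ** 2 for j in range(dmax))
    return {
        "SmallDependenceEmphasis": s(lambda i, j: 1 / j**2) / nd,
        "LargeDependenceEmphasis": s(lambda i, j: j**2) / nd,
        "LargeDependenceLowGrayLevelEmphasis": s(lambda i, j: j**2 / i**2) / nd,
        "LargeDependenceHighGrayLevelEmphasis": s(lambda i, j: j**2 * i**2) / nd,
        "DependenceNonUniformity": dnu / nd,
    }


def texture_oracle(level_grid, mask, family):
    """Direction-averaged (where applicable) oracle features."""
    ng = int(level_grid.max())
    if family == "GLCM":
        mats = glcm_oracle_matrices(level_grid, mask, ng)
        feats = [glcm_oracle_features(m) for m in mats]
        return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}
    if family == "GLRLM":
        mats = glrlm_oracle_matrices(level_grid, mask, ng)
        feats = [glrlm_oracle_features(m) for m in mats]
        return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}
    if family == "GLSZM":
        return glszm_oracle_features(glszm_oracle_matrix(level_grid, mask, ng))
    if family == "GLDM":
        return gldm_oracle_features(gldm_oracle_matrix(level_grid, mask, ng))
    raise ValueError(family)


# ---------------------------------------------------------------------------
# exact 2x2 test by full hypergeometric enumeration
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))
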