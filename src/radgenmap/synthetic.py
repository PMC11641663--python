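"""Synthetic paired imaging + SNP-array cohorts with known ground truth.

Generates two-class cohorts (benign oncocytoma-like class 0 vs
chromophobe-carcinoma-like class 1) in which each patient carries:

* a 3D tumour image and binary mask whose texture statistics depend on
  class (mean intensity, noise amplitude and granularity of a smoothed
  Gaussian random field),
* a per-probe SNP-array track (chromosome, position, B-allele frequency,
  log R ratio) with deletion / duplication / copy-neutral-LOH segments
  implanted at named cytobands with class-conditional frequencies,
* the implanted segments as ground truth for caller benchmarking.

The genome model is deliberately small: two autosomes plus X, 50 Mb
each, partitioned into named cytobands. LRR shifts use canonical
Illumina-like values (copy number 1: -0.45, copy number 3: +0.30) and
the default LRR noise SD (0.15) is below the 0.28 QC cut-off so
generated tracks pass quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .radiomics import BinaryMask, ImageVolume

__all__ = [
    "ClassTextureParams",
    "CnvProfileEntry",
    "CohortConfig",
    "CytobandDef",
    "SyntheticPatient",
    "default_chrom_sizes",
    "default_cytobands",
    "generate_cohort",
    "simulate_probe_track",
    "simulate_tumour_image",
]

LRR_SHIFT = {"DEL": -0.45, "DUP": 0.30, "LOH": 0.0}
CN_VALUE = {"DEL": 1, "DUP": 3, "LOH": 2}


def default_chrom_sizes() -> dict[str, int]:
    """Two autosomes + X, 50 Mb each."""
    return {"chr1": 50_000_000, "chr2": 50_000_000, "chrX": 50_000_000}


@dataclass(frozen=True)
class CytobandDef:
    """A named chromosomal band (half-open interval)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"band {self.name}: start must be < end")


def default_cytobands(
    chrom_sizes: dict[str, int] | None = None, bands_per_arm: int = 5
) -> list[CytobandDef]:
    """Partition each chromosome into p/q arms of equal-width bands,
    named like real cytobands (e.g. ``1p3``, ``Xq2``)."""
    sizes = chrom_sizes or default_chrom_sizes()
    bands = []
    for chrom, size in sizes.items():
        label = chrom.removeprefix("chr")
        half = size // 2
        for arm, lo, hi in (("p", 0, half), ("q", half, size)):
            edges = np.linspace(lo, hi, bands_per_arm + 1).astype(int)
            for i in range(bands_per_arm):
                bands.append(
                    CytobandDef(f"{label}{arm}{i + 1}", chrom, int(edges[i]), int(edges[i + 1]))
                )
    return bands


@dataclass(frozen=True)
class ClassTextureParams:
    """Texture settings for one class: tumour intensity field mean, SD
    and granularity (Gaussian smoothing length in voxels)."""

    mean: float
    sd: float
    granularity: float


@dataclass(frozen=True)
class CnvProfileEntry:
    """One aberration in the cohort profile: where, what type and with
    what per-class implantation probability."""

    cytoband: str
    type: str
    prob_class0: float
    prob_class1: float

    def __post_init__(self) -> None:
        if self.type not in ("DEL", "DUP", "LOH"):
            raise ValueError(f"unknown aberration type: {self.type!r}")
        for p in (self.prob_class0, self.prob_class1):
            if not 0.0 <= p <= 1.0:
                raise ValueError("implantation probabilities must be in [0, 1]")


def _default_texture() -> dict[int, ClassTextureParams]:
    # class 1 (malignant-like) tumours are slightly denser and
    # coarser-textured; the overlap is deliberate - the two renal
    # tumour types are hard to tell apart on CT
    return {
        0: ClassTextureParams(mean=40.0, sd=20.0, granularity=1.0),
        1: ClassTextureParams(mean=52.0, sd=24.0, granularity=1.8),
    }


def _default_cnv_profile() -> tuple[CnvProfileEntry, ...]:
    # one strongly class-linked deletion plus background aberrations
    return (
        CnvProfileEntry("1p2", "DEL", 0.10, 0.85),
        CnvProfileEntry("2q3", "DUP", 0.20, 0.25),
        CnvProfileEntry("Xp3", "LOH", 0.15, 0.15),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate the pilot study scale: 14 patients, 6 benign
    (class 0) and ~8 malignant (class 1), with class-conditional tumour
    texture and one class-linked deletion.
    """

    n_patients: int = 14
    class_probability: float = 8 / 14  # P(class 1)
    image_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_texture_params: dict[int, ClassTextureParams] = field(
        default_factory=_default_texture
    )
    cnv_profile: tuple[CnvProfileEntry, ...] = field(default_factory=_default_cnv_profile)
    chrom_sizes: dict[str, int] = field(default_factory=default_chrom_sizes)
    probe_spacing_bp: int = 25_000
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    het_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.class_probability <= 1.0:
            raise ValueError("class_probability must be in [0, 1]")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must be in [0, 1]")
        if any(s < 8 for s in self.image_shape):
            raise ValueError("image_shape must be >= 8 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        if self.lrr_noise_sd <= 0 or self.baf_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")

    def cytobands(self) -> list[CytobandDef]:
        return default_cytobands(self.chrom_sizes)


@dataclass(frozen=True)
class TruthSegment:
    """An implanted aberration (ground truth for the CNV caller)."""

    chrom: str
    start: int
    end: int
    type: str
    cn_value: int


@dataclass
class SyntheticPatient:
    patient_id: str
    label: int
    age: float
    sex: str
    tumour_size_cm: float
    volume: ImageVolume
    mask: BinaryMask
    track: pd.DataFrame
    truth_segments: list[TruthSegment]


# Table-style demographics per class: age mean/sd, size mean/sd, P(male)
_DEMOGRAPHICS = {
    0: {"age": (63.5, 8.67), "size": (3.60, 1.47), "p_male": 6 / 14},
    1: {"age": (61.40, 7.13), "size": (3.80, 1.09), "p_male": 0.5},
}


def simulate_tumour_image(
    class_params: ClassTextureParams,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int | np.random.Generator,
) -> tuple[ImageVolume, BinaryMask]:
    """One tumour volume: an ellipsoidal ROI filled with a smoothed
    Gaussian random field on a dark background.

    The field is white noise blurred with a Gaussian of width
    ``granularity`` voxels and rescaled to unit variance, so the ROI
    mean and SD match the class parameters while the autocorrelation
    length grows with granularity.
    """
    rng = np.random.default_rng(seed)
    if any(s < 8 for s in shape):
        raise ValueError("shape must be >= 8 voxels per axis")
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centre = [(s - 1) / 2 for s in shape]
    semi = [0.35 * s for s in shape]
    mask = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    ) <= 1.0
    if not mask.any():
        raise ValueError("generated mask is empty")
    noise = rng.standard_normal(shape)
    if class_params.granularity > 0:
        field_ = ndimage.gaussian_filter(noise, class_params.granularity)
        field_ = (field_ - field_.mean()) / field_.std()
    else:
        field_ = noise
    grid = np.zeros(shape)
    grid[mask] = class_params.mean + class_params.sd * field_[mask]
    return ImageVolume(grid, spacing), BinaryMask(mask.astype(np.uint8))


def simulate_probe_track(
    chrom_sizes: dict[str, int],
    config: CohortConfig,
    truth: list[TruthSegment],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-probe BAF/LRR signal for one sample.

    Outside aberrations the LRR is N(0, lrr_noise_sd) and the BAF
    clusters at {0, 0.5, 1} according to het_fraction. Deletions shift
    the LRR down and remove the heterozygous band; duplications shift
    it up and split heterozygotes to {1/3, 2/3}; copy-neutral LOH keeps
    LRR at 0 but removes heterozygotes. BAF noise is truncated to [0,1].
    """
    for seg in truth:
        size = chrom_sizes.get(seg.chrom)
        if size is None or seg.start < 0 or seg.end > size:
            raise ValueError(f"truth segment outside chromosome bounds: {seg}")
    # conflicting-type overlap check
    by_chrom: dict[str, list[TruthSegment]] = {}
    for seg in truth:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end and a.type != b.type:
                raise ValueError(f"overlapping truth segments of conflicting type: {a} / {b}")

    frames = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = np.arange(1, size + 1, config.probe_spacing_bp, dtype=np.int64)
        n = len(pos)
        state = np.array(["NORMAL"] * n, dtype=object)
        for seg in by_chrom.get(chrom, []):
            state[(pos >= seg.start) & (pos <= seg.end)] = seg.type

        lrr = rng.normal(0.0, config.lrr_noise_sd, n)
        for t, shift in LRR_SHIFT.items():
            lrr[state == t] += shift

        het = rng.random(n) < config.het_fraction
        b_allele = rng.random(n) < 0.5  # which homozygote for hom probes
        baf = np.where(b_allele, 1.0, 0.0)
        baf[het] = 0.5
        # genotype-band adjustments inside aberrations
        for t in ("DEL", "LOH"):
            sel = (state == t) & het
            baf[sel] = np.where(rng.random(sel.sum()) < 0.5, 0.0, 1.0)
        dup_het = (state == "DUP") & het
        baf[dup_het] = np.where(rng.random(dup_het.sum()) < 0.5, 1 / 3, 2 / 3)
        baf = np.clip(baf + rng.normal(0.0, config.baf_noise_sd, n), 0.0, 1.0)

        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{chrom}_{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "baf": baf,
                    "lrr": lrr,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Draw a full cohort: labels, demographics, tumour images and probe
    tracks with implanted aberrations, all deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    bands = {b.name: b for b in config.cytobands()}
    for entry in config.cnv_profile:
        if entry.cytoband not in bands:
            raise ValueError(f"cnv_profile names unknown cytoband: {entry.cytoband!r}")

    patients = []
    for i in range(config.n_patients):
        label = int(rng.random() < config.class_probability)
        demo = _DEMOGRAPHICS[label]
        age = float(rng.normal(*demo["age"]))
        size_cm = max(0.5, float(rng.normal(*demo["size"])))
        sex = "M" if rng.random() < demo["p_male"] else "F"

        # per-patient biological variability around the class texture means
        base = config.class_texture_params[label]
        params = ClassTextureParams(
            mean=float(rng.normal(base.mean, 8.0)),
            sd=float(max(5.0, rng.normal(base.sd, 5.0))),
            granularity=float(max(0.3, rng.normal(base.granularity, 0.4))),
        )

        truth = []
        for entry in config.cnv_profile:
            p = entry.prob_class1 if label == 1 else entry.prob_class0
            if rng.random() < p:
                band = bands[entry.cytoband]
                truth.append(
                    TruthSegment(band.chrom, band.start, band.end, entry.type, CN_VALUE[entry.type])
                )

        volume, mask = simulate_tumour_image(
            params,
            config.image_shape,
            config.spacing_mm,
            rng,
        )
        track = simulate_probe_track(config.chrom_sizes, config, truth, rng)
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i + 1:03d}",
                label=label,
                age=age,
                sex=sex,
                tumour_size_cm=size_cm,
                volume=volume,
                mask=mask,
                track=track,
                truth_segments=truth,
            )
        )
    return patients


def demographics_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Tabular demographics of a cohort (one row per patient)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "label": [p.label for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "tumour_size_cm": [p.tumour_size_cm for p in patients],
        }
    )
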