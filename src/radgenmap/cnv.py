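"""Copy-number and LOH calling from SNP-array BAF/LRR probe tracks.

Each probe emits a (LRR, BAF) pair modelled as an independent Gaussian
LRR term and a BAF mixture over the genotype bands of the copy-number
state (e.g. {0, 1/2, 1} for a normal diploid locus, {0, 1} for a
single-copy deletion or copy-neutral LOH, {0, 1/3, 2/3, 1} for a
three-copy gain). Homozygous-band Gaussians are truncated to [0, 1].
Segmentation is a Viterbi pass over the per-probe state log-likelihoods
with a uniform per-transition penalty; contiguous same-state runs are
merged into segments. A segment is emitted only when it covers at least
``min_probes`` probes and its confidence - the summed 10*log10
likelihood ratio against the diploid state - reaches the confidence
threshold. Default thresholds: minimum probe count 3, confidence 35,
and a sample-level QC cut excluding tracks whose LRR standard deviation
exceeds 0.28.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CNVSegment",
    "StateModel",
    "QCReport",
    "default_state_model",
    "qc_track",
    "call_segments",
    "detect_loh",
    "summarize_cnv",
    "per_chromosome_percent",
    "read_track_tsv",
    "write_track_tsv",
    "segments_to_bed",
    "standard_report",
]

LRR_SD_MAX = 0.28
SEGMENT_TYPES = ("loss", "gain", "LOH")


@dataclass(frozen=True)
class State:
    name: str
    cn_value: int
    type: str  # loss / normal / gain / LOH
    lrr_mean: float
    lrr_sd: float
    baf_means: tuple[float, ...]
    baf_weights: tuple[float, ...]
    baf_sd: float


@dataclass(frozen=True)
class StateModel:
    """Emission model: one entry per copy-number scenario."""

    states: tuple[State, ...]

    def __post_init__(self) -> None:
        if not any(
            s.type == "normal" and s.cn_value == 2 and s.lrr_mean == 0 for s in self.states
        ):
            raise ValueError("state model must contain a diploid normal state")

    @property
    def normal_index(self) -> int:
        for i, s in enumerate(self.states):
            if s.type == "normal":
                return i
        raise AssertionError


def default_state_model(
    het_fraction: float = 0.30,
    lrr_sd: float = 0.15,
    baf_sd: float = 0.03,
) -> StateModel:
    """Six-state model spanning loss / normal / copy-neutral-LOH / gain.

    LRR means use canonical Illumina-like shifts (CN1 -0.45, CN3 +0.30);
    BAF band weights reflect the expected heterozygous-probe fraction.
    """
    h = het_fraction
    hom = (1 - h) / 2
    return StateModel(
        states=(
            State("CN0", 0, "loss", -2.0, 3 * lrr_sd, (0.5,), (1.0,), 0.3),
            State("CN1", 1, "loss", -0.45, lrr_sd, (0.0, 1.0), (0.5, 0.5), baf_sd),
            State("CN2", 2, "normal", 0.0, lrr_sd, (0.0, 0.5, 1.0), (hom, h, hom), baf_sd),
            State("CN2-LOH", 2, "LOH", 0.0, lrr_sd, (0.0, 1.0), (0.5, 0.5), baf_sd),
            State("CN3", 3, "gain", 0.30, lrr_sd, (0.0, 1 / 3, 2 / 3, 1.0),
                  (hom, h / 2, h / 2, hom), baf_sd),
            State("CN4", 4, "gain", 0.60, lrr_sd, (0.0, 0.25, 0.5, 0.75, 1.0),
                  (hom, h / 2, 0.0, h / 2, hom), baf_sd),
        )
    )


@dataclass(frozen=True)
class CNVSegment:
    """A called aberration on one chromosome (positions 1-based,
    inclusive of the first and last supporting probe)."""

    chrom: str
    start: int
    end: int
    n_probes: int
    cn_value: int
    type: str
    confidence: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.type not in SEGMENT_TYPES:
            raise ValueError(f"unknown segment type: {self.type!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QCReport:
    lrr_sd: float
    passed: bool


def qc_track(track: pd.DataFrame) -> QCReport:
    """Sample-level QC: pass iff the LRR standard deviation (sample SD)
    does not exceed 0.28."""
    if len(track) < 2:
        raise ValueError("QC requires at least 2 probes")
    sd = float(track["lrr"].std(ddof=1))
    return QCReport(lrr_sd=sd, passed=sd <= LRR_SD_MAX)


def _band_loglik(baf: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Log-density of one BAF genotype band, truncated to [0, 1] for
    bands at the boundaries."""
    if mean in (0.0, 1.0):
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        return stats.truncnorm.logpdf(baf, a, b, loc=mean, scale=sd)
    return stats.norm.logpdf(baf, loc=mean, scale=sd)


def _emission_loglik(track: pd.DataFrame, model: StateModel) -> np.ndarray:
    """(n_probes, n_states) log-likelihood matrix."""
    lrr = track["lrr"].to_numpy(float)
    baf = track["baf"].to_numpy(float)
    n = len(track)
    out = np.empty((n, len(model.states)))
    for j, s in enumerate(model.states):
        ll = stats.norm.logpdf(lrr, loc=s.lrr_mean, scale=s.lrr_sd)
        band_ll = np.full((len(s.baf_means), n), -np.inf)
        for k, (m, w) in enumerate(zip(s.baf_means, s.baf_weights)):
            if w > 0:
                band_ll[k] = np.log(w) + _band_loglik(baf, m, s.baf_sd)
        ll = ll + np.logaddexp.reduce(band_ll, axis=0)
        out[:, j] = ll
    return out


def _viterbi(emissions: np.ndarray, penalty: float) -> np.ndarray:
    """Maximum a-posteriori state path with a uniform per-transition
    penalty (log-likelihood units, natural log)."""
    n, k = emissions.shape
    v = emissions[0].copy()
    back = np.zeros((n, k), dtype=np.int8)
    idx = np.arange(k)
    for t in range(1, n):
        best_prev = int(np.argmax(v))
        stay = v
        switch = v[best_prev] - penalty
        choose_switch = switch > stay
        back[t] = np.where(choose_switch, best_prev, idx)
        v = np.where(choose_switch, switch, stay) + emissions[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(v))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def call_segments(
    track: pd.DataFrame,
    model: StateModel | None = None,
    min_probes: int = 3,
    conf_threshold: float = 35.0,
    transition_penalty: float = 10.0,
) -> list[CNVSegment]:
    """Call copy-number and LOH segments from a sorted probe track.

    Per-probe states come from a Viterbi pass over the bivariate
    Gaussian emissions; contiguous non-normal runs become candidate
    segments, emitted when n_probes >= min_probes and confidence
    (summed 10*log10 likelihood ratio vs the diploid state) >=
    conf_threshold.
    """
    if model is None:
        model = default_state_model()
    segments: list[CNVSegment] = []
    for chrom, sub in track.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"track not sorted by position on {chrom}")
        em = _emission_loglik(sub, model)
        path = _viterbi(em, transition_penalty)
        normal = model.normal_index
        llr10 = (em - em[:, [normal]]) * (10.0 / np.log(10.0))
        # contiguous same-state runs
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(path)]))
        for s0, s1 in zip(starts, ends):
            st = model.states[path[s0]]
            if st.type == "normal":
                continue
            n_probes = s1 - s0
            conf = float(llr10[s0:s1, path[s0]].sum())
            if n_probes >= min_probes and conf >= conf_threshold:
                segments.append(
                    CNVSegment(
                        chrom=str(chrom),
                        start=int(pos[s0]),
                        end=int(pos[s1 - 1]),
                        n_probes=int(n_probes),
                        cn_value=st.cn_value,
                        type=st.type,
                        confidence=conf,
                    )
                )
    return segments


def detect_loh(
    track: pd.DataFrame,
    model: StateModel | None = None,
    min_probes: int = 3,
    conf_threshold: float = 35.0,
    transition_penalty: float = 10.0,
) -> list[CNVSegment]:
    """Copy-neutral LOH calls: runs with LRR near 0 but no heterozygous
    BAF band, reported with cn_value 2."""
    segs = call_segments(track, model, min_probes, conf_threshold, transition_penalty)
    return [s for s in segs if s.type == "LOH"]


TYPE_ALIASES = {"loss": "DEL", "gain": "DUP", "LOH": "LOH"}


def summarize_cnv(cohort_segments: dict[str, list[CNVSegment]]) -> pd.DataFrame:
    """Per-patient, per-type summary with the cohort-share percentage.

    CNV% of a type for a patient = (patient's segment count of that
    type / total count of that type across all patients) * 100. Mean
    segment sizes are in bp.
    """
    if not cohort_segments:
        raise ValueError("at least one patient required")
    rows = []
    totals = {t: 0 for t in SEGMENT_TYPES}
    for segs in cohort_segments.values():
        for s in segs:
            totals[s.type] += 1
    for patient, segs in cohort_segments.items():
        for t in SEGMENT_TYPES:
            mine = [s for s in segs if s.type == t]
            pct = 100.0 * len(mine) / totals[t] if totals[t] else 0.0
            rows.append(
                {
                    "patient_id": patient,
                    "type": TYPE_ALIASES[t],
                    "segment_count": len(mine),
                    "cnv_percent": pct,
                    "mean_segment_size_bp": float(np.mean([s.length_bp for s in mine]))
                    if mine
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def per_chromosome_percent(
    cohort_segments: dict[str, list[CNVSegment]], labels: dict[str, int]
) -> pd.DataFrame:
    """Percentage of segments per (class, chromosome, type)."""
    for patient in cohort_segments:
        if patient not in labels:
            raise ValueError(f"unknown label for patient {patient!r}")
    chroms = sorted({s.chrom for segs in cohort_segments.values() for s in segs})
    classes = sorted(set(labels.values()))
    rows = []
    for cls in classes:
        segs_cls = [
            s
            for patient, segs in cohort_segments.items()
            if labels[patient] == cls
            for s in segs
        ]
        for t in SEGMENT_TYPES:
            of_type = [s for s in segs_cls if s.type == t]
            for chrom in chroms:
                count = sum(1 for s in of_type if s.chrom == chrom)
                pct = 100.0 * count / len(of_type) if of_type else 0.0
                rows.append(
                    {
                        "class": cls,
                        "chrom": chrom,
                        "type": TYPE_ALIASES[t],
                        "count": count,
                        "percent": pct,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["probe_id", "chrom", "pos", "baf", "lrr"]


def read_track_tsv(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(track.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    return track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_track_tsv(track: pd.DataFrame, path) -> None:
    track[TRACK_COLUMNS].to_csv(path, sep="\t", index=False)


def segments_to_bed(segments: list[CNVSegment], type_filter: str | None = None) -> pd.DataFrame:
    """Segments as a BED-like frame (0-based half-open coordinates),
    optionally restricted to one type (DEL/DUP/LOH)."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start - 1,
            "end": s.end,
            "name": TYPE_ALIASES[s.type],
            "score": s.confidence,
            "cn_value": s.cn_value,
        }
        for s in segments
        if type_filter is None or TYPE_ALIASES[s.type] == type_filter
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "cn_value"])


def standard_report(cohort_segments: dict[str, list[CNVSegment]]) -> pd.DataFrame:
    """Flat per-segment report (sample, chrom, start, end, cn_value,
    confidence, type)."""
    rows = [
        {
            "sample": patient,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "n_probes": s.n_probes,
            "cn_value": s.cn_value,
            "confidence": s.confidence,
            "type": TYPE_ALIASES[s.type],
        }
        for patient, segs in cohort_segments.items()
        for s in segs
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "n_probes", "cn_value", "confidence", "type"],
    )
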