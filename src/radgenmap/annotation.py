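"""Cytoband-level annotation of CNV segments and pathogenicity classes.

Maps called segments onto named cytobands by interval intersection,
builds the patients x cytobands copy-number matrix used for
histology correlation (diploid baseline 2, copy-neutral LOH carried as
separate 0/1 indicator columns), and converts numeric pathogenicity
scores into the five ACMG-style classes by fixed cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import math

import numpy as np
import pandas as pd

from .synthetic import CytobandDef

__all__ = [
    "PathogenicityClass",
    "CytobandCall",
    "classify_score",
    "map_to_cytobands",
    "build_cytoband_matrix",
]


class PathogenicityClass(Enum):
    BENIGN = "Benign"
    LIKELY_BENIGN = "Likely Benign"
    VUS = "Variant of Uncertain Significance"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    PATHOGENIC = "Pathogenic"


def classify_score(score: float) -> PathogenicityClass:
    """Map a numeric CNV pathogenicity score to its class.

    Cut-offs (intervals completed continuously so the map is total):
    Benign <= -0.99 < Likely Benign <= -0.89 < VUS < 0.90 <=
    Likely Pathogenic < 0.99 <= Pathogenic.
    """
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if score <= -0.99:
        return PathogenicityClass.BENIGN
    if score <= -0.89:
        return PathogenicityClass.LIKELY_BENIGN
    if score < 0.90:
        return PathogenicityClass.VUS
    if score < 0.99:
        return PathogenicityClass.LIKELY_PATHOGENIC
    return PathogenicityClass.PATHOGENIC


@dataclass(frozen=True)
class CytobandCall:
    """One (segment, cytoband) intersection for one patient."""

    patient_id: str
    cytoband_name: str
    cn_value: int
    type: str  # DEL / DUP / LOH
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("overlap must be positive")


def map_to_cytobands(segments, bands: list[CytobandDef], patient_id: str) -> list[CytobandCall]:
    """Intersect segments with cytobands (half-open interval
    arithmetic); one call per pair with positive overlap."""
    by_chrom: dict[str, list[CytobandDef]] = {}
    for b in bands:
        if b.start >= b.end:
            raise ValueError(f"malformed band {b.name}")
        by_chrom.setdefault(b.chrom, []).append(b)
    calls = []
    from .cnv import TYPE_ALIASES

    for seg in segments:
        seg_start = seg.start - 1  # to 0-based half-open
        seg_end = seg.end
        for b in by_chrom.get(seg.chrom, []):
            lo = max(seg_start, b.start)
            hi = min(seg_end, b.end)
            if hi > lo:
                calls.append(
                    CytobandCall(
                        patient_id=patient_id,
                        cytoband_name=b.name,
                        cn_value=seg.cn_value,
                        type=TYPE_ALIASES.get(seg.type, seg.type),
                        overlap_bp=hi - lo,
                    )
                )
    return calls


def build_cytoband_matrix(
    calls: list[CytobandCall], patients: list[str], bands: list[CytobandDef]
) -> pd.DataFrame:
    """Patients x cytobands copy-number matrix.

    Entries default to the diploid value 2; where calls cover a band
    the largest-overlap call wins. Copy-neutral LOH does not change the
    copy-number entry but sets the auxiliary "<band>_LOH" indicator.
    """
    if len(set(patients)) != len(patients):
        raise ValueError("duplicate patient ids")
    band_names = [b.name for b in bands]
    cn = pd.DataFrame(2, index=patients, columns=band_names, dtype=int)
    loh = pd.DataFrame(0, index=patients, columns=[f"{n}_LOH" for n in band_names], dtype=int)
    best: dict[tuple[str, str], CytobandCall] = {}
    for c in calls:
        if c.patient_id not in cn.index or c.cytoband_name not in cn.columns:
            raise ValueError(f"call references unknown patient or band: {c}")
        if c.type == "LOH":
            loh.loc[c.patient_id, f"{c.cytoband_name}_LOH"] = 1
            continue
        key = (c.patient_id, c.cytoband_name)
        if key not in best or c.overlap_bp > best[key].overlap_bp:
            best[key] = c
    for (patient, band), c in best.items():
        cn.loc[patient, band] = c.cn_value
    out = pd.concat([cn, loh], axis=1)
    out.index.name = "patient_id"
    return out
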