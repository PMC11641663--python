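"""End-to-end radiogenomics pipeline.

Orchestrates cohort generation (or file ingestion), LRR-based sample
QC, radiomic feature extraction, CNV/LOH calling, the cytoband
copy-number matrix, redundancy filtering and consensus feature
selection, histology-correlated cytoband selection, the radiomic x
genomic association map, and cross-validated random-forest evaluation.
All thresholds live in one configuration object with defaults matching
the analysis settings (bin width 20, redundancy cut 0.8, two selector
votes, top-14 per selector, cytoband |r| > 0.1, association cut-offs
0.4 / 0.55, minimum 3 probes, confidence 35, LRR SD <= 0.28, 201
trees).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, association, cnv, modeling
from .biostats import demographic_report
from .radiomics import DEFAULT_FILTERS, FilterSpec, extract_feature_vector
from .synthetic import CohortConfig, demographics_frame, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_reports"]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dumps(payload) -> bytes:
    return json.dumps(payload, indent=2, default=_json_default).encode()


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: tuple[FilterSpec, ...] = DEFAULT_FILTERS
    bin_width: float = 20.0
    redundancy_r_max: float = 0.8
    consensus_k: int = 14
    consensus_min_votes: int = 2
    cytoband_r_min: float = 0.1
    association_cutoffs: tuple[float, ...] = (0.4, 0.55)
    min_probes: int = 3
    conf_threshold: float = 35.0
    lrr_sd_max: float = 0.28
    n_estimators: int = 201
    cv: str = "loo"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width", "redundancy_r_max", "cytoband_r_min",
                     "conf_threshold", "lrr_sd_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_probes < 1 or self.n_estimators < 1:
            raise ValueError("counts must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "cohort": {k: str(v) for k, v in asdict(self.cohort).items()},
                "filters": [f.name for f in self.filters],
                "bin_width": self.bin_width,
                "redundancy_r_max": self.redundancy_r_max,
                "consensus_k": self.consensus_k,
                "consensus_min_votes": self.consensus_min_votes,
                "cytoband_r_min": self.cytoband_r_min,
                "association_cutoffs": list(self.association_cutoffs),
                "min_probes": self.min_probes,
                "conf_threshold": self.conf_threshold,
                "lrr_sd_max": self.lrr_sd_max,
                "n_estimators": self.n_estimators,
                "cv": self.cv,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_digest: str
    seed: int
    n_patients: int
    qc_excluded: list[str]
    feature_table: pd.DataFrame
    selected_features: list[str]
    selector_rankings: dict[str, list[str]]
    cytoband_matrix: pd.DataFrame
    selected_cytobands: list[tuple[str, float]]
    association_map: association.AssociationMap
    model_report: modeling.ModelReport
    demographics: dict
    cnv_summary: pd.DataFrame
    stage_seconds: dict[str, float]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on a synthetic cohort; deterministic in the seed."""
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    _stage("simulate")
    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.seed:
        cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.seed})
    patients = generate_cohort(cohort_cfg)
    _done("simulate")

    _stage("qc")
    kept, excluded = [], []
    for p in patients:
        if cnv.qc_track(p.track).passed:
            kept.append(p)
        else:
            excluded.append(p.patient_id)
    if not kept:
        raise RuntimeError(
            "all samples failed LRR-SD quality control; check the noise settings"
        )
    if excluded:
        logger.warning("QC excluded %d samples: %s", len(excluded), excluded)
    _done("qc")

    _stage("radiomics")
    rows = {
        p.patient_id: extract_feature_vector(p.volume, p.mask, config.filters, config.bin_width)
        for p in kept
    }
    feature_table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    feature_table.index.name = "patient_id"
    _done("radiomics")

    _stage("cnv")
    model = cnv.default_state_model(
        het_fraction=cohort_cfg.het_fraction,
        lrr_sd=cohort_cfg.lrr_noise_sd,
        baf_sd=cohort_cfg.baf_noise_sd,
    )
    cohort_segments = {
        p.patient_id: cnv.call_segments(
            p.track, model, config.min_probes, config.conf_threshold
        )
        for p in kept
    }
    cnv_summary = cnv.summarize_cnv(cohort_segments)
    _done("cnv")

    _stage("cytobands")
    bands = cohort_cfg.cytobands()
    calls = [
        c
        for p in kept
        for c in annotation.map_to_cytobands(cohort_segments[p.patient_id], bands, p.patient_id)
    ]
    cytoband_matrix = annotation.build_cytoband_matrix(
        calls, [p.patient_id for p in kept], bands
    )
    _done("cytobands")

    labels = np.array([p.label for p in sorted(kept, key=lambda p: p.patient_id)])
    feature_table = feature_table.loc[sorted(p.patient_id for p in kept)]
    cytoband_matrix = cytoband_matrix.loc[feature_table.index]

    _stage("selection")
    standardized = association.standardize(feature_table)
    reduced = association.redundancy_filter(standardized, config.redundancy_r_max)
    if reduced.shape[1] >= 2:
        k = min(config.consensus_k, reduced.shape[1])
        selected, rankings = association.consensus_select(
            reduced, labels, k=k, min_votes=config.consensus_min_votes, seed=config.seed
        )
    else:
        # redundancy filtering can collapse tiny cohorts to a single
        # representative feature; keep it rather than aborting
        selected, rankings = list(reduced.columns), {}
        logger.warning("only %d features after redundancy filter; consensus skipped",
                       reduced.shape[1])
    selected_bands = association.select_cytobands(
        cytoband_matrix, labels, config.cytoband_r_min
    )
    _done("selection")

    _stage("association")
    radiomic_sel = standardized[selected] if selected else reduced
    band_cols = [b for b, _ in selected_bands] or list(cytoband_matrix.columns)
    amap = association.cross_correlate(
        radiomic_sel, cytoband_matrix[band_cols], config.association_cutoffs
    )
    _done("association")

    _stage("model")
    combined = pd.concat([radiomic_sel, cytoband_matrix[band_cols]], axis=1)
    model_report = modeling.evaluate_rf(
        combined,
        labels,
        n_estimators=config.n_estimators,
        cv=config.cv,
        seed=config.seed,
    )
    _done("model")

    _stage("demographics")
    demo = demographic_report(
        demographics_frame(kept).set_index("patient_id").loc[feature_table.index].reset_index()
    )
    _done("demographics")

    return RunReport(
        config_digest=config.digest(),
        seed=config.seed,
        n_patients=len(kept),
        qc_excluded=excluded,
        feature_table=feature_table,
        selected_features=selected,
        selector_rankings=rankings,
        cytoband_matrix=cytoband_matrix,
        selected_cytobands=selected_bands,
        association_map=amap,
        model_report=model_report,
        demographics=demo,
        cnv_summary=cnv_summary,
        stage_seconds=timings,
    )


def write_reports(report: RunReport, outdir: str | Path, overwrite: bool = False) -> dict[str, str]:
    """Write all artefacts to ``outdir``; returns a manifest mapping
    relative file names to SHA-256 checksums. Refuses to overwrite an
    existing artefact unless ``overwrite`` is set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    artefacts: dict[str, bytes] = {}
    artefacts["feature_table.tsv"] = report.feature_table.to_csv(sep="\t").encode()
    artefacts["cytoband_matrix.tsv"] = report.cytoband_matrix.to_csv(sep="\t").encode()
    artefacts["association_map.tsv"] = report.association_map.matrix.to_csv(sep="\t").encode()
    artefacts["cnv_summary.tsv"] = report.cnv_summary.to_csv(sep="\t", index=False).encode()
    artefacts["association_pairs.json"] = _dumps(
        {str(c): p for c, p in report.association_map.pairs.items()}
    )
    artefacts["selected_features.json"] = _dumps(
        {
            "selected": report.selected_features,
            "rankings": report.selector_rankings,
            "cytobands": report.selected_cytobands,
        }
    )
    artefacts["model_report.json"] = _dumps(
        {
            **report.model_report.as_percent(),
            "mcc": report.model_report.mcc,
            "f1": report.model_report.f1,
            "n_estimators": report.model_report.n_estimators,
            "cv_scheme": report.model_report.cv_scheme,
            "seed": report.model_report.seed,
        }
    )
    artefacts["run_summary.json"] = _dumps(
        {
            "config_digest": report.config_digest,
            "seed": report.seed,
            "n_patients": report.n_patients,
            "qc_excluded": report.qc_excluded,
            "n_features": int(report.feature_table.shape[1]),
            "n_selected_features": len(report.selected_features),
            "n_selected_cytobands": len(report.selected_cytobands),
            "demographics": report.demographics,
        }
    )

    manifest: dict[str, str] = {}
    for name, payload in artefacts.items():
        path = outdir / name
        if path.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite {path}; pass overwrite=True")
        path.write_bytes(payload)
        manifest[name] = hashlib.sha256(payload).hexdigest()
    # stage timings are run-specific provenance, kept out of the
    # checksummed artefact set
    (outdir / "timings.json").write_text(
        json.dumps(report.stage_seconds, indent=2, default=_json_default)
    )
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return manifest
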