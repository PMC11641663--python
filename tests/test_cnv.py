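"""CNV caller: QC, segmentation, LOH detection, cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from radgenmap.cnv import (
    CNVSegment,
    call_segments,
    default_state_model,
    detect_loh,
    per_chromosome_percent,
    qc_track,
    read_track_tsv,
    segments_to_bed,
    summarize_cnv,
    write_track_tsv,
)
from radgenmap.synthetic import (
    CohortConfig,
    TruthSegment,
    default_chrom_sizes,
    simulate_probe_track,
)


def make_track(lrr, baf=None, chrom="chr1"):
    n = len(lrr)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * 1000,
            "baf": baf if baf is not None else np.tile([0.0, 0.5, 1.0], n)[:n],
            "lrr": lrr,
        }
    )


class TestQC:
    def test_quiet_track_passes(self, rng):
        t = make_track(rng.normal(0, 0.10, 500))
        assert qc_track(t).passed

    def test_noisy_track_fails(self, rng):
        # LRR SD 0.30 exceeds the 0.28 cut
        lrr = rng.normal(0, 0.30, 5000)
        lrr = (lrr - lrr.mean()) / lrr.std(ddof=1) * 0.30
        assert not qc_track(make_track(lrr)).passed

    def test_single_probe_errors(self):
        with pytest.raises(ValueError):
            qc_track(make_track([0.1]))


@pytest.fixture(scope="module")
def cohort_tracks():
    """Tracks with known implants across 12 samples (forced draws)."""
    from radgenmap.synthetic import CnvProfileEntry, generate_cohort

    cfg = CohortConfig(
        n_patients=12,
        seed=17,
        image_shape=(8, 8, 8),
        cnv_profile=(
            CnvProfileEntry("1p2", "DEL", 1.0, 1.0),
            CnvProfileEntry("2q3", "DUP", 1.0, 1.0),
            CnvProfileEntry("Xp3", "LOH", 1.0, 1.0),
        ),
    )
    return generate_cohort(cfg)


def reciprocal_overlap(a, b) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0 or a.chrom != b.chrom:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


class TestCallSegments:
    def test_diploid_track_yields_no_calls(self, rng):
        cfg = CohortConfig(seed=2)
        track = simulate_probe_track(default_chrom_sizes(), cfg, [], rng)
        assert call_segments(track) == []

    def test_implanted_deletion_recovered(self, rng):
        cfg = CohortConfig(seed=2)
        truth = TruthSegment("chr1", 5_000_000, 7_000_000, "DEL", 1)  # ~80 probes
        track = simulate_probe_track(default_chrom_sizes(), cfg, [truth], rng)
        segs = call_segments(track)
        losses = [s for s in segs if s.type == "loss"]
        assert len(losses) == 1
        assert reciprocal_overlap(losses[0], truth) >= 0.5
        assert losses[0].cn_value == 1

    def test_two_probe_aberration_not_emitted(self, rng):
        """The minimum-probe rule: a 2-probe deletion yields no call."""
        cfg = CohortConfig(seed=4)
        truth = TruthSegment("chr1", 1_000_001, 1_030_000, "DEL", 1)  # 2 probes
        track = simulate_probe_track(default_chrom_sizes(), cfg, [truth], rng)
        inside = track[(track.chrom == "chr1") & track.pos.between(truth.start, truth.end)]
        assert len(inside) == 2
        assert [s for s in call_segments(track) if s.type == "loss"] == []

    def test_unsorted_track_rejected(self, rng):
        t = make_track(rng.normal(0, 0.1, 100))
        t.loc[5, "pos"] = t.loc[4, "pos"]
        with pytest.raises(ValueError):
            call_segments(t)

    def test_emitted_segments_disjoint_and_thresholded(self, cohort_tracks):
        for p in cohort_tracks:
            segs = call_segments(p.track)
            for s in segs:
                assert s.n_probes >= 3
                assert s.confidence >= 35
            by_chrom: dict[str, list[CNVSegment]] = {}
            for s in segs:
                by_chrom.setdefault(s.chrom, []).append(s)
            for group in by_chrom.values():
                group.sort(key=lambda s: s.start)
                for a, b in zip(group, group[1:]):
                    assert a.end < b.start

    def test_confidence_threshold_monotone(self, cohort_tracks):
        track = cohort_tracks[0].track
        counts = [len(call_segments(track, conf_threshold=c)) for c in (35, 300, 5000)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_recovery_sensitivity_and_precision(self, cohort_tracks):
        """Segment-level sensitivity and precision >= 0.9 at 50%%
        reciprocal overlap under generator defaults."""
        tp = fp = fn = 0
        type_map = {"DEL": "loss", "DUP": "gain", "LOH": "LOH"}
        for p in cohort_tracks:
            calls = call_segments(p.track)
            matched_calls = set()
            for t in p.truth_segments:
                hit = [
                    i
                    for i, c in enumerate(calls)
                    if c.type == type_map[t.type] and reciprocal_overlap(c, t) >= 0.5
                ]
                if hit:
                    tp += 1
                    matched_calls.update(hit)
                else:
                    fn += 1
            fp += len(calls) - len(matched_calls)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9


class TestLOH:
    def test_implanted_loh_recovered_with_cn2(self, rng):
        cfg = CohortConfig(seed=6)
        truth = TruthSegment("chr2", 20_000_000, 21_500_000, "LOH", 2)  # 60 probes
        track = simulate_probe_track(default_chrom_sizes(), cfg, [truth], rng)
        calls = detect_loh(track)
        assert len(calls) == 1
        assert calls[0].cn_value == 2
        assert reciprocal_overlap(calls[0], truth) >= 0.5

    def test_normal_track_no_loh(self, rng):
        cfg = CohortConfig(seed=12, het_fraction=0.3)
        track = simulate_probe_track(default_chrom_sizes(), cfg, [], rng)
        assert detect_loh(track) == []

    def test_all_homozygous_track_is_loh_everywhere(self):
        n = 400
        rng = np.random.default_rng(0)
        baf = np.where(rng.random(n) < 0.5, 0.0, 1.0)
        baf = np.clip(baf + rng.normal(0, 0.02, n), 0, 1)
        t = make_track(rng.normal(0, 0.12, n), baf=baf)
        calls = detect_loh(t)
        assert len(calls) == 1
        assert calls[0].n_probes == n


class TestSummaries:
    def seg(self, chrom="chr1", start=1, end=1000, typ="gain"):
        return CNVSegment(chrom, start, end, 10, 3 if typ == "gain" else 1, typ, 100.0)

    def test_cnv_percent_is_cohort_share(self):
        cohort = {
            "A": [self.seg() for _ in range(2)],
            "B": [self.seg() for _ in range(8)],
        }
        s = summarize_cnv(cohort)
        dup = s[(s.type == "DUP")].set_index("patient_id")
        assert dup.loc["A", "cnv_percent"] == pytest.approx(20.0)
        assert dup.loc["B", "cnv_percent"] == pytest.approx(80.0)

    def test_patient_without_segments_zero(self):
        s = summarize_cnv({"A": [self.seg()], "B": []})
        b = s[s.patient_id == "B"]
        assert (b.cnv_percent == 0).all()

    def test_percent_sums_to_100_per_type(self, cohort_tracks):
        cohort = {p.patient_id: call_segments(p.track) for p in cohort_tracks[:6]}
        s = summarize_cnv(cohort)
        for typ, grp in s.groupby("type"):
            if grp.segment_count.sum() > 0:
                assert grp.cnv_percent.sum() == pytest.approx(100.0)

    def test_per_chromosome_percent(self):
        cohort = {
            "A": [self.seg("chr1"), self.seg("chr2")],
            "B": [self.seg("chr1")],
        }
        out = per_chromosome_percent(cohort, {"A": 0, "B": 1})
        a_dup = out[(out["class"] == 0) & (out.type == "DUP")]
        assert sorted(a_dup.percent) == [50.0, 50.0]
        b_dup = out[(out["class"] == 1) & (out.type == "DUP")]
        assert b_dup[b_dup.chrom == "chr1"].percent.iloc[0] == 100.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            per_chromosome_percent({"A": []}, {"B": 0})


class TestIO:
    def test_track_roundtrip(self, tmp_path, rng):
        t = make_track(rng.normal(0, 0.1, 50))
        path = tmp_path / "track.tsv"
        write_track_tsv(t, path)
        back = read_track_tsv(path)
        pd.testing.assert_frame_equal(back, t)

    def test_bed_export_is_zero_based_half_open(self):
        s = CNVSegment("chr1", 1001, 2000, 10, 1, "loss", 50.0)
        bed = segments_to_bed([s])
        assert bed.iloc[0].start == 1000
        assert bed.iloc[0].end == 2000
        assert bed.iloc[0]["name"] == "DEL"
        assert segments_to_bed([s], "DUP").empty
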