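"""Coverage summarization, log2 M:F ratios, chromosome classification and
windowed ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wzgenefate.coverage import (
    classify_chromosomes,
    log2_mf,
    summarize_coverage,
    windowed_ratio,
)
from wzgenefate.models import CoverageTrack


def _const_track(chrom, depth, n, sample, sex):
    return CoverageTrack(chrom=chrom, depths=np.full(n, depth, dtype=int), sample_id=sample, sex=sex)


def _toy_tracks(female_medians={"A": 30, "Z": 15, "W": 15}, male_medians={"A": 30, "Z": 30, "W": 0}, n=200):
    tracks = []
    for chrom, d in female_medians.items():
        tracks.append(_const_track(chrom, d, n, "f1", "female"))
    for chrom, d in male_medians.items():
        tracks.append(_const_track(chrom, d, n, "m1", "male"))
    return tracks, {"f1": "female", "m1": "male"}


class TestSummarize:
    def test_normalization_divides_by_mean_of_medians(self):
        tracks, manifest = _toy_tracks()
        summary = summarize_coverage(tracks, manifest)
        # female medians 30/15/15 -> mean 20 -> normalized 1.5/0.75/0.75
        assert summary.loc["A", "norm:f1"] == pytest.approx(1.5)
        assert summary.loc["Z", "norm:f1"] == pytest.approx(0.75)
        assert summary.loc["W", "norm:f1"] == pytest.approx(0.75)

    def test_equal_constant_depths_normalize_to_one(self):
        tracks, manifest = _toy_tracks({"A": 12, "B": 12}, {"A": 12, "B": 12})
        summary = summarize_coverage(tracks, manifest)
        assert np.allclose(summary.filter(like="norm:"), 1.0)

    def test_per_sample_normalized_mean_is_one(self, small_coverage):
        tracks, manifest = small_coverage
        summary = summarize_coverage(tracks, manifest)
        for col in summary.filter(like="norm:"):
            assert summary[col].mean() == pytest.approx(1.0)

    def test_sex_means_agree_on_autosome(self, small_coverage):
        tracks, manifest = small_coverage
        summary = summarize_coverage(tracks, manifest)
        assert summary.loc["chr1", "male_mean"] == pytest.approx(
            summary.loc["chr1", "female_mean"], rel=0.05
        )

    def test_library_size_invariance(self, small_coverage):
        tracks, manifest = small_coverage
        base = summarize_coverage(tracks, manifest)
        scaled = [
            CoverageTrack(t.chrom, t.depths * (3 if t.sample_id == "male_1" else 1), t.sample_id, t.sex)
            for t in tracks
        ]
        rescaled = summarize_coverage(scaled, manifest)
        pd.testing.assert_frame_equal(
            base.filter(like="norm:"), rescaled.filter(like="norm:"), rtol=1e-12
        )

    def test_missing_chromosome_is_an_error(self):
        tracks, manifest = _toy_tracks()
        with pytest.raises(ValueError, match="no coverage track"):
            summarize_coverage(tracks[:-1], manifest)

    def test_sample_absent_from_manifest(self):
        tracks, manifest = _toy_tracks()
        with pytest.raises(ValueError, match="missing from the manifest"):
            summarize_coverage(tracks, {"f1": "female"})

    def test_single_sex_rejected(self):
        tracks, _ = _toy_tracks()
        female_only = [t for t in tracks if t.sex == "female"]
        with pytest.raises(ValueError, match="no male sample"):
            summarize_coverage(female_only, {"f1": "female"})


class TestLog2MF:
    def test_equal_means_give_zero(self):
        assert log2_mf(1.0, 1.0) == 0.0

    def test_twofold_male_excess_near_one(self):
        assert log2_mf(1.2, 0.6, pseudocount=0.0) == pytest.approx(1.0)
        assert log2_mf(1.2, 0.6) == pytest.approx(1.0, abs=0.02)

    def test_absent_male_coverage_with_pseudocount(self):
        assert log2_mf(0.0, 1.0, pseudocount=0.01) == pytest.approx(np.log2(0.01 / 1.01))
        assert log2_mf(0.0, 1.0) == pytest.approx(-6.658, abs=0.01)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_mf(-0.1, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_antisymmetry(self, m, f):
        assert log2_mf(m, f) == pytest.approx(-log2_mf(f, m), abs=1e-9)


class TestClassify:
    @staticmethod
    def _summary(rows):
        return pd.DataFrame(rows, index=pd.Index([r["chrom"] for r in rows], name="chrom"))

    def test_bands(self):
        summary = self._summary(
            [
                {"chrom": "a", "log2_mf": 0.02, "male_mean": 1.0, "female_mean": 1.0},
                {"chrom": "z", "log2_mf": 0.97, "male_mean": 1.3, "female_mean": 0.65},
                {"chrom": "w", "log2_mf": -4.4, "male_mean": 0.03, "female_mean": 0.7},
                {"chrom": "odd", "log2_mf": 0.5, "male_mean": 1.0, "female_mean": 0.7},
            ]
        )
        labels = classify_chromosomes(summary)
        assert list(labels) == ["autosome", "Z", "W", "ambiguous"]

    def test_full_recovery_on_simulation(self, small_sim, small_coverage):
        tracks, manifest = small_coverage
        summary = summarize_coverage(tracks, manifest)
        labels = classify_chromosomes(summary)
        truth = {c.name: c.true_class for c in small_sim["genome"]}
        assert {c: labels[c] for c in labels.index} == truth


class TestWindowed:
    def test_tiling_with_partial_tail(self):
        tracks, manifest = _toy_tracks(n=2500)
        win = windowed_ratio(tracks, manifest, window_bp=1000)
        a = win[win["chrom"] == "A"].reset_index(drop=True)
        assert list(a["start"]) == [0, 1000, 2000]
        assert list(a["end"]) == [1000, 2000, 2500]
        assert list(a["partial"]) == [False, False, True]

    def test_constant_equal_depths_give_zero_everywhere(self):
        tracks, manifest = _toy_tracks({"A": 10, "B": 10}, {"A": 10, "B": 10}, n=3000)
        win = windowed_ratio(tracks, manifest, window_bp=500)
        assert np.allclose(win["log2_mf"], 0.0)

    def test_window_longer_than_chromosome(self):
        tracks, manifest = _toy_tracks(n=300)
        win = windowed_ratio(tracks, manifest, window_bp=1000)
        a = win[win["chrom"] == "A"]
        assert len(a) == 1 and bool(a["partial"].iloc[0])

    def test_window_mean_matches_chromosome_log2(self, small_coverage):
        # constant-copy-number chromosomes: window ratios average to the
        # chromosome-wide value
        tracks, manifest = small_coverage
        summary = summarize_coverage(tracks, manifest)
        win = windowed_ratio(tracks, manifest, window_bp=1000)
        for chrom in ("chr1", "chr2", "Z"):
            w = win[(win["chrom"] == chrom) & ~win["partial"]]
            assert w["log2_mf"].mean() == pytest.approx(
                summary.loc[chrom, "log2_mf"], abs=0.05
            )

    def test_z_window_variance_shrinks_with_window_size(self, small_coverage):
        tracks, manifest = small_coverage
        v = {}
        for wbp in (500, 2000):
            win = windowed_ratio(tracks, manifest, window_bp=wbp)
            z = win[(win["chrom"] == "Z") & ~win["partial"]]
            v[wbp] = z["log2_mf"].var()
            assert z["log2_mf"].mean() == pytest.approx(1.0, abs=0.1)
        assert v[2000] < v[500]

    def test_bad_window_rejected(self, small_coverage):
        tracks, manifest = small_coverage
        with pytest.raises(ValueError):
            windowed_ratio(tracks, manifest, window_bp=0)
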