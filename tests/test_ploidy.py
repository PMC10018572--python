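"""Ploidy inference: analytic ratio expectations, depth binning, baseline
estimation, the mixture classifier (with an independent likelihood oracle),
segmentation and depth-anomaly detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyoscope import karyosim as ks, ploidy as pl
from karyoscope.formats_io import AlleleBalanceRecord, DepthTrack, GenomeLayout


class TestExpectedRatios:
    @pytest.mark.parametrize(
        "c,k,expected",
        [
            (2, 1, {0.5}),
            (3, 1, {1 / 3, 2 / 3}),
            (4, 1, {0.25, 0.75}),
            (4, 2, {0.5}),
            (2, 2, set()),
            (1, 0, set()),
            (0, 0, set()),
        ],
    )
    def test_analytic_values(self, c, k, expected):
        assert pl.expected_allele_ratios(c, k) == expected

    def test_k_above_c_is_error(self):
        with pytest.raises(ValueError):
            pl.expected_allele_ratios(2, 3)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12))
    def test_symmetry_in_allele_exchange(self, c, k):
        if k > c:
            with pytest.raises(ValueError):
                pl.expected_allele_ratios(c, k)
        else:
            assert pl.expected_allele_ratios(c, k) == pl.expected_allele_ratios(c, c - k)


class TestBinDepth:
    def test_constant_track(self):
        t = DepthTrack.from_intervals("c", [(0, 100_000, 30.0)])
        binned = pl.bin_depth(t, 50_000)
        assert len(binned) == 2
        np.testing.assert_allclose(binned.depths, [30.0, 30.0])

    def test_weighted_mean_within_bin(self):
        t = DepthTrack.from_intervals("c", [(0, 25_000, 20.0), (25_000, 50_000, 40.0)])
        binned = pl.bin_depth(t, 50_000)
        assert binned.depths[0] == pytest.approx(30.0)

    def test_hand_computed_seven_interval_fixture(self):
        # intervals crossing 10-kb bin boundaries; expectations worked by hand
        t = DepthTrack.from_intervals(
            "c",
            [
                (0, 4_000, 10.0),
                (4_000, 12_000, 20.0),
                (12_000, 15_000, 30.0),
                (15_000, 22_000, 40.0),
                (26_000, 30_000, 50.0),
                (30_000, 33_000, 10.0),
                (38_000, 41_000, 60.0),
            ],
        )
        binned = pl.bin_depth(t, 10_000, chrom_length=50_000)
        # bin0: 4k@10 + 6k@20 -> 16;  bin1: 2k@20 + 3k@30 + 5k@40 -> 33
        # bin2: 2k@40 + 4k@50 over 6k covered -> 140/3
        # bin3: 3k@10 + 2k@60 over 5k covered -> 30;  bin4: 1k@60 -> 60
        np.testing.assert_allclose(binned.depths, [16.0, 33.0, 140 / 3, 30.0, 60.0])

    def test_uncovered_bin_is_missing(self):
        t = DepthTrack.from_intervals("c", [(0, 10_000, 5.0)])
        binned = pl.bin_depth(t, 10_000, chrom_length=30_000)
        assert np.isnan(binned.depths[1]) and np.isnan(binned.depths[2])

    def test_bad_bin_size(self):
        t = DepthTrack.from_intervals("c", [(0, 10, 1.0)])
        with pytest.raises(ValueError):
            pl.bin_depth(t, 0)


class TestDiploidBaseline:
    def _tracks(self, medians):
        return {
            f"c{i}": DepthTrack.from_intervals(f"c{i}", [(0, 1000, m)])
            for i, m in enumerate(medians)
        }

    def test_majority_mode(self):
        assert pl.diploid_baseline(self._tracks([30, 30, 30, 45])) == pytest.approx(30, abs=1.0)

    def test_prior_list_overrides(self):
        tracks = self._tracks([30, 30, 45, 45])
        assert pl.diploid_baseline(tracks, prior_diploid=["c2", "c3"]) == pytest.approx(45)

    def test_all_missing_is_error(self):
        tracks = {"c": DepthTrack.from_intervals("c", [(0, 10, np.nan)])}
        with pytest.raises(ValueError):
            pl.diploid_baseline(tracks)

    def test_preset_genome_recovers_simulated_baseline(self, ipecj2_sim):
        spec, sim = ipecj2_sim
        est = pl.diploid_baseline(sim.depth)
        assert est == pytest.approx(spec.baseline_depth, rel=0.05)


def _betabinom_logpmf_oracle(k, n, p, rho):
    """Independent beta-binomial log-pmf via the lgamma form."""
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho

    def lbeta(x, y):
        return math.lgamma(x) + math.lgamma(y) - math.lgamma(x + y)

    lchoose = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return lchoose + lbeta(k + a, n - k + b) - lbeta(a, b)


class TestClassifier:
    def test_site_likelihood_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        total = rng.integers(10, 60, size=50)
        alt = rng.binomial(total, 0.33)
        rho = 0.01
        for state in pl.DEFAULT_CANDIDATES:
            if not state.is_het_capable:
                continue
            expected = 0.0
            for k, n in zip(alt, total):
                comps = [
                    math.log(0.5) + _betabinom_logpmf_oracle(int(k), int(n), p, rho)
                    for p in {state.expected_ratios[0], state.expected_ratios[-1]}
                ]
                if len(comps) == 1:
                    expected += comps[0] - math.log(0.5)
                else:
                    m = max(comps)
                    expected += m + math.log(sum(math.exp(c - m) for c in comps))
            got = pl.site_log_likelihood(alt, total, state, rho=rho)
            assert got == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "c,k,label", [(2, 1, "2:AB"), (3, 1, "3:AAB"), (4, 1, "4:AAAB"), (4, 2, "4:AABB")]
    )
    def test_recovers_simulated_state(self, c, k, label):
        spec = ks.KaryotypeSpec(
            GenomeLayout({"x": 2_000_000}),
            [ks.SegmentState("x", 0, 2_000_000, c, k)],
            baseline_depth=30.0,
        )
        sim = ks.simulate_wgs(spec, seed=100 + 10 * c + k)
        call = pl.classify_chromosome_ploidy(
            sim.records["x"], sim.depth["x"].median_depth(), 30.0, chromosome="x"
        )
        assert call.best_state == label
        assert call.confidence > 10

    def test_balanced_tetraploid_needs_depth(self):
        """AABB and AB share the 0.5 ratio mode; only depth separates them."""
        spec = ks.KaryotypeSpec(
            GenomeLayout({"x": 2_000_000}),
            [ks.SegmentState("x", 0, 2_000_000, 4, 2)],
            baseline_depth=30.0,
        )
        sim = ks.simulate_wgs(spec, seed=11)
        with_depth = pl.classify_chromosome_ploidy(sim.records["x"], 60.0, 30.0)
        assert with_depth.best_state == "4:AABB"
        without_depth = pl.classify_chromosome_ploidy(sim.records["x"], None, None)
        # ties break toward smaller copy number when depth is unavailable
        assert without_depth.best_state == "2:AB"

    def test_monosomy_from_depth_and_absent_hets(self):
        call = pl.classify_chromosome_ploidy([], 15.0, 30.0)
        assert call.best_state == "1"

    def test_no_evidence_is_unknown(self):
        call = pl.classify_chromosome_ploidy([], None, None)
        assert call.best_state == "unknown"

    def test_confidence_grows_with_site_count(self):
        confidences = []
        for n_mb, _ in ((1, None), (4, None)):
            vals = []
            for seed in range(20):
                spec = ks.KaryotypeSpec(
                    GenomeLayout({"x": n_mb * 1_000_000}),
                    [ks.SegmentState("x", 0, n_mb * 1_000_000, 3, 1)],
                    het_rate=2e-4,
                )
                sim = ks.simulate_wgs(spec, seed=seed)
                call = pl.classify_chromosome_ploidy(sim.records["x"], None, None)
                vals.append(call.confidence)
            confidences.append(np.mean(vals))
        assert confidences[1] > confidences[0]


class TestSegmentation:
    def test_homogeneous_diploid_is_single_segment(self):
        spec = ks.KaryotypeSpec(GenomeLayout({"x": 10_000_000}), [], het_rate=5e-4)
        sim = ks.simulate_wgs(spec, seed=3)
        segs = pl.segment_allele_ratio(
            sim.records["x"], depth_track=sim.depth["x"], baseline=30.0, chrom_length=10_000_000
        )
        assert len(segs) == 1
        assert segs[0].state == "2:AB"

    def test_distal_higher_ploidy_breakpoint_located(self):
        spec = ks.KaryotypeSpec(
            GenomeLayout({"x": 20_000_000}),
            [ks.SegmentState("x", 12_000_000, 20_000_000, 4, 1)],
            het_rate=2e-4,
        )
        sim = ks.simulate_wgs(spec, seed=21)
        segs = pl.segment_allele_ratio(
            sim.records["x"], depth_track=sim.depth["x"], baseline=30.0, chrom_length=20_000_000
        )
        assert [s.state for s in segs] == ["2:AB", "4:AAAB"]
        assert segs[0].end == pytest.approx(12_000_000, abs=500_000)

    def test_het_desert_called_monosomic(self):
        spec = ks.KaryotypeSpec(
            GenomeLayout({"x": 16_000_000}),
            [
                ks.SegmentState("x", 0, 8_000_000, 1),
                ks.SegmentState("x", 8_000_000, 16_000_000, 4, 1),
            ],
            het_rate=2e-4,
        )
        sim = ks.simulate_wgs(spec, seed=22)
        segs = pl.segment_allele_ratio(
            sim.records["x"], depth_track=sim.depth["x"], baseline=30.0, chrom_length=16_000_000
        )
        assert segs[0].state == "1"
        assert segs[0].start == 0 and segs[0].end == pytest.approx(8_000_000, abs=1_000_000)
        assert segs[-1].state == "4:AAAB"

    def test_too_few_sites_flagged_low_confidence(self):
        recs = [AlleleBalanceRecord("x", p * 1000, 15, 15) for p in range(30)]
        segs = pl.segment_allele_ratio(recs, chrom_length=100_000)
        assert len(segs) == 1
        assert segs[0].low_confidence


class TestDepthAnomalies:
    def test_constant_track_is_clean(self):
        t = DepthTrack(
            "c",
            np.arange(0, 100) * 50_000,
            (np.arange(0, 100) + 1) * 50_000,
            np.full(100, 30.0),
        )
        assert pl.detect_depth_anomalies(t) == []

    def test_simulated_deletion_recovered(self, ipecj2_sim):
        _, sim = ipecj2_sim
        anomalies = pl.detect_depth_anomalies(sim.depth["chr16"])
        losses = [a for a in anomalies if a.kind == "loss"]
        assert len(losses) == 1
        a = losses[0]
        truth = (9_000_000, 17_000_000)
        inter = min(a.end, truth[1]) - max(a.start, truth[0])
        assert inter / (truth[1] - truth[0]) >= 0.9
        assert inter / (a.end - a.start) >= 0.9

    def test_short_dip_gated_by_min_length(self):
        depths = np.full(100, 30.0)
        depths[40:58] = 10.0  # 0.9 Mb at 50-kb bins
        t = DepthTrack("c", np.arange(100) * 50_000, (np.arange(100) + 1) * 50_000, depths)
        assert pl.detect_depth_anomalies(t, min_length=1_000_000) == []
        found = pl.detect_depth_anomalies(t, min_length=500_000)
        assert len(found) == 1 and found[0].kind == "loss"
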