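import numpy as np
import pytest

from radiascan.io import MISSING, MarkerMatrix
from radiascan.qc import (
    QcConfig,
    assess_repeatability,
    genotyping_error_rate,
    score_profiles,
    select_markers,
)
from radiascan.simulate import (
    IntensityParams,
    SimParams,
    corrupt_and_replicate,
    simulate_metapopulation,
    simulate_peak_profiles,
)


def _pair_matrix(pairs_per_marker: dict[str, list[tuple[int, int]]]) -> MarkerMatrix:
    """Build a matrix whose replicate pairs realize the given call pairs."""
    loci = list(pairs_per_marker)
    n_pairs = len(next(iter(pairs_per_marker.values())))
    sample_ids, reps, rows_a, rows_b = [], {}, [], []
    for p in range(n_pairs):
        sample_ids.append(f"s{p}")
        rows_a.append([pairs_per_marker[l][p][0] for l in loci])
    for p in range(n_pairs):
        rid = f"s{p}_rep1"
        sample_ids.append(rid)
        reps[rid] = f"s{p}"
        rows_b.append([pairs_per_marker[l][p][1] for l in loci])
    return MarkerMatrix(sample_ids, loci, np.array(rows_a + rows_b, np.int8), reps)


class TestScoreProfiles:
    def test_below_detection_threshold_absent(self):
        profiles = {
            "s1": [(100.0, 10_000.0), (200.0, 5_000.0), (300.0, 40.0)],
            "s2": [(100.0, 9_000.0), (200.0, 4_000.0), (300.0, 2_000.0)],
        }
        mm = score_profiles(profiles)
        j = mm.locus_ids.index("300.00")
        assert mm.calls[0, j] == 0          # 40 < 50 detection threshold
        assert mm.calls[1, j] == 1

    def test_boundary_peak_at_one_percent_retained(self):
        # 1% of second-largest (5000) = 50 exactly -> kept (>= rule), and
        # height 50 >= detection threshold 50 -> present
        profiles = {
            "s1": [(100.0, 10_000.0), (200.0, 5_000.0), (300.0, 50.0)],
            "s2": [(100.0, 9_000.0), (200.0, 4_000.0)],
        }
        mm = score_profiles(profiles)
        assert mm.calls[0, mm.locus_ids.index("300.00")] == 1

    def test_out_of_range_peaks_excluded(self):
        profiles = {
            "s1": [(55.0, 9_000.0), (100.0, 8_000.0), (600.0, 7_000.0), (200.0, 6_000.0)],
            "s2": [(100.0, 8_000.0), (200.0, 6_000.0)],
        }
        mm = score_profiles(profiles)
        assert set(mm.locus_ids) == {"100.00", "200.00"}

    def test_single_peak_profile_all_absent_with_warning(self):
        profiles = {
            "s1": [(100.0, 8_000.0)],
            "s2": [(100.0, 8_000.0), (200.0, 6_000.0)],
        }
        with pytest.warns(UserWarning, match="fewer than 2 peaks"):
            mm = score_profiles(profiles)
        assert mm.calls[mm.sample_index("s1")].sum() == 0

    def test_round_trip_from_synthetic(self):
        mm, _, _ = simulate_metapopulation(
            SimParams(n_pops=2, n_ind=8, n_loci=60, fst=0.15, seed=1)
        )
        profiles = simulate_peak_profiles(mm, IntensityParams(), seed=2)
        scored = score_profiles(profiles)
        keep = np.flatnonzero(mm.calls.sum(axis=0) > 0)
        assert np.array_equal(scored.calls, mm.calls[:, keep])

    def test_bin_width_cap(self):
        # peaks 0.5b apart chain into one bin; >0.75b from the first opens a new one
        profiles = {
            "s1": [(100.0, 8_000.0), (100.5, 7_000.0), (101.0, 6_000.0)],
            "s2": [(100.0, 8_000.0), (101.0, 6_000.0)],
        }
        mm = score_profiles(profiles)
        assert mm.n_loci == 2   # [100.0, 100.5] and [101.0]


class TestRepeatability:
    def test_nine_of_ten_concordant(self):
        pairs = {"A": [(1, 1)] * 9 + [(1, 0)]}
        rep = assess_repeatability(_pair_matrix(pairs))
        assert rep.repeatability["A"] == pytest.approx(0.9)

    def test_all_absent_pairs_null_only(self):
        rep = assess_repeatability(_pair_matrix({"A": [(0, 0)] * 5}))
        assert rep.repeatability["A"] == pytest.approx(1.0)
        assert "A" in rep.null_only
        assert "A" not in rep.confirmed_present

    def test_mixed_pairs(self):
        rep = assess_repeatability(_pair_matrix({"A": [(1, 1), (1, 0)]}))
        assert rep.repeatability["A"] == pytest.approx(0.5)
        assert "A" in rep.confirmed_present

    def test_missing_pairs_excluded_from_denominator(self):
        rep = assess_repeatability(
            _pair_matrix({"A": [(1, 1), (MISSING, 1), (1, 0)]})
        )
        assert rep.repeatability["A"] == pytest.approx(0.5)

    def test_no_replicates_raises(self, tiny_matrix):
        with pytest.raises(ValueError, match="replicate"):
            assess_repeatability(tiny_matrix)


class TestSelectMarkers:
    def _matrix(self):
        pairs = {
            "keep": [(1, 1)] * 5 + [(0, 0)] * 5,                # rep 1.0, confirmed
            "low": [(1, 0)] * 5 + [(0, 1)] * 5,                 # rep 0.0
            "null": [(0, 0)] * 10,                              # never present
            "unconfirmed": [(0, 0)] * 9 + [(1, 0)],             # rep 0.9, no (1,1)
        }
        return _pair_matrix(pairs)

    def test_rules_fire_in_order(self):
        mm = self._matrix()
        rep = assess_repeatability(mm)
        out, ledger = select_markers(mm, rep, QcConfig())
        assert ledger.dropped["low_repeatability"] == ["low"]
        assert ledger.dropped["null_allele_only"] == ["null"]
        assert ledger.dropped["unconfirmed"] == ["unconfirmed"]
        assert ledger.retained == ["keep"]

    def test_exact_threshold_kept(self):
        # 0.81 survives the strict "< 0.81" rule; just below is dropped
        good = [(1, 1)] * 81 + [(0, 1)] * 19       # 0.81, polymorphic in mains
        bad = [(1, 1)] * 80 + [(0, 1)] * 20        # 0.80
        mm = _pair_matrix({"at081": good, "at080": bad})
        rep = assess_repeatability(mm)
        out, ledger = select_markers(mm, rep, QcConfig())
        assert "at081" in ledger.retained
        assert "at080" in ledger.dropped["low_repeatability"]

    def test_monomorphic_dropped(self):
        pairs = {"poly": [(1, 1), (0, 0)], "mono1": [(1, 1), (1, 1)]}
        mm = _pair_matrix(pairs)
        rep = assess_repeatability(mm)
        out, ledger = select_markers(mm, rep, QcConfig())
        assert "mono1" in ledger.dropped["monomorphic"]
        assert ledger.retained == ["poly"]

    def test_ledger_conserves_loci(self):
        mm = self._matrix()
        rep = assess_repeatability(mm)
        _, ledger = select_markers(mm, rep, QcConfig())
        assert ledger.n_dropped() + len(ledger.retained) == mm.n_loci

    def test_idempotent(self):
        mm = self._matrix()
        rep = assess_repeatability(mm)
        out1, _ = select_markers(mm, rep, QcConfig())
        rep2 = assess_repeatability(out1)
        out2, ledger2 = select_markers(out1, rep2, QcConfig())
        assert out2.locus_ids == out1.locus_ids
        assert ledger2.n_dropped() == 0

    def test_all_removed_raises(self):
        mm = _pair_matrix({"null": [(0, 0)] * 3})
        rep = assess_repeatability(mm)
        with pytest.raises(ValueError, match="all loci removed"):
            select_markers(mm, rep, QcConfig())


class TestErrorRate:
    def test_perfect_concordance_zero(self):
        mm = _pair_matrix({"A": [(1, 1), (0, 0)], "B": [(0, 0), (1, 1)]})
        assert genotyping_error_rate(mm) == 0.0

    def test_recovery_against_closed_form(self):
        # truth bands at frequency ~0.3; analytic per-pair discordance
        # probability = 2 e (1-e) for either true state when e01=e10=e
        rng = np.random.default_rng(3)
        calls = (rng.random((100, 50)) < 0.3).astype(np.int8)
        mm = MarkerMatrix([f"s{i}" for i in range(100)],
                          [f"L{j}" for j in range(50)], calls)
        e = 0.04
        out = corrupt_and_replicate(mm, e, e, 1.0, seed=4)
        est = genotyping_error_rate(out) / 100.0
        p_exp = 2 * e * (1 - e)
        n_calls = 100 * 50
        half_ci = 2.576 * np.sqrt(p_exp * (1 - p_exp) / n_calls)
        assert abs(est - p_exp) < half_ci + 1e-12

    def test_pooled_vs_per_marker_agree_on_balanced_data(self):
        mm = _pair_matrix({"A": [(1, 1), (1, 0)], "B": [(0, 0), (0, 1)]})
        assert genotyping_error_rate(mm) == pytest.approx(
            genotyping_error_rate(mm, method="pooled")
        )

    def test_order_invariance(self):
        pairs = {"A": [(1, 0), (1, 1), (0, 0)], "B": [(0, 1), (0, 0), (1, 1)]}
        mm = _pair_matrix(pairs)
        perm = ["s2", "s0_rep1", "s1", "s2_rep1", "s0", "s1_rep1"]
        shuffled = mm.subset_samples(perm)
        assert genotyping_error_rate(mm) == pytest.approx(
            genotyping_error_rate(shuffled)
        )

    def test_unbiasedness_over_seeds(self):
        # estimator mean within 2 s.e. of the analytic discordance probability
        e = 0.05
        p_exp = 2 * e * (1 - e)
        rng = np.random.default_rng(5)
        ests = []
        for seed in range(50):
            calls = (rng.random((40, 40)) < 0.4).astype(np.int8)
            mm = MarkerMatrix([f"s{i}" for i in range(40)],
                              [f"L{j}" for j in range(40)], calls)
            out = corrupt_and_replicate(mm, e, e, 1.0, seed=seed)
            ests.append(genotyping_error_rate(out) / 100.0)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - p_exp) < 2 * se + 1e-9
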