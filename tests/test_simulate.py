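import numpy as np
import pytest

from radiascan.io import MISSING
from radiascan.phylo import motu_cluster, p_distance
from radiascan.simulate import (
    IntensityParams,
    SimParams,
    corrupt_and_replicate,
    simulate_landmarks,
    simulate_metapopulation,
    simulate_peak_profiles,
    simulate_sequences,
)


class TestMetapopulation:
    def test_fst_recovery_against_truth_moment_estimator(self):
        # oracle: Weir-Cockerham-style moment estimate on the realized p_ij
        params = SimParams(n_pops=2, n_ind=50, n_loci=500, fst=0.1, seed=42)
        _, _, truth = simulate_metapopulation(params)
        assert abs(truth.wc_fst() - 0.1) < 0.03

    def test_low_f_limit_shrinks_between_pop_variance(self):
        var = {}
        for f in (0.005, 0.1, 0.4):
            _, _, truth = simulate_metapopulation(
                SimParams(n_pops=4, n_ind=5, n_loci=400, fst=f, seed=7)
            )
            q = truth.band_freq()
            var[f] = q.var(axis=0).mean()
        assert var[0.005] < 0.002
        assert var[0.005] < var[0.1] < var[0.4]

    def test_selected_locus_exceeds_median_f(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            alpha = np.zeros(100)
            alpha[17] = 3.0
            # enough populations that a high-F locus rarely fixes the same
            # way everywhere (which would erase its realized variance)
            _, _, truth = simulate_metapopulation(
                SimParams(n_pops=12, n_ind=5, n_loci=100, fst=0.1,
                          alpha=alpha, seed=seed)
            )
            pbar = truth.p_pop.mean(axis=0)
            den = pbar * (1 - pbar)
            with np.errstate(invalid="ignore", divide="ignore"):
                f_loc = truth.p_pop.var(axis=0, ddof=1) / den
            if f_loc[17] > np.nanmedian(f_loc):
                hits += 1
        assert hits >= 95

    def test_determinism(self):
        params = SimParams(n_pops=3, n_ind=10, n_loci=50, fst=0.2,
                           replicate_fraction=0.2, e01=0.02, e10=0.02, seed=5)
        a, _, _ = simulate_metapopulation(params)
        b, _, _ = simulate_metapopulation(params)
        assert np.array_equal(a.calls, b.calls)
        assert a.sample_ids == b.sample_ids

    def test_variance_monotone_in_f(self):
        grid = [0.02, 0.05, 0.1, 0.2, 0.4]
        vs = []
        for f in grid:
            _, _, truth = simulate_metapopulation(
                SimParams(n_pops=6, n_ind=5, n_loci=600, fst=f, seed=123)
            )
            vs.append(truth.p_pop.var(axis=0).mean())
        assert all(a < b for a, b in zip(vs, vs[1:]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimParams(fst=1.5)
        with pytest.raises(ValueError):
            SimParams(e01=-0.1)
        with pytest.raises(ValueError):
            SimParams(prior_lo=0.5, prior_hi=0.5)

    def test_spatial_mode_produces_ibd(self):
        # truth-frequency Fst must correlate positively with km distance
        from radiascan.ibd import mantel_test
        from radiascan.phylo import DistanceMatrix
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            params = SimParams(n_pops=8, n_ind=5, n_loci=150, spatial=True,
                               drift_per_km=0.002, seed=seed)
            _, st, truth = simulate_metapopulation(params)
            p = truth.p_pop
            J = p.shape[0]
            fst = np.zeros((J, J))
            for i in range(J):
                for j in range(i + 1, J):
                    pb = (p[i] + p[j]) / 2
                    den = (pb * (1 - pb)).sum()
                    fst[i, j] = fst[j, i] = ((p[i] - p[j]) ** 2 / 2).sum() / den
            pos = np.arange(J) * 25.0
            km = np.abs(pos[:, None] - pos[None, :])
            ids = [f"P{k + 1}" for k in range(J)]
            res = mantel_test(DistanceMatrix(ids, km, "km"),
                              DistanceMatrix(ids, fst, "fst"),
                              n_perm=99, seed=seed, exact_max_n=0)
            wins += res.r > 0
        assert wins >= int(0.95 * n_seeds)


class TestCorruptAndReplicate:
    def test_no_error_appends_identical_replicates(self, tiny_matrix):
        out = corrupt_and_replicate(tiny_matrix, 0.0, 0.0, 0.5, seed=1)
        assert out.n_samples == 6
        for rep, orig in out.replicate_of.items():
            i, j = out.sample_index(orig), out.sample_index(rep)
            assert np.array_equal(out.calls[i], out.calls[j])
        assert np.array_equal(out.calls[:4], tiny_matrix.calls)

    def test_e10_one_kills_all_presences(self, tiny_matrix):
        out = corrupt_and_replicate(tiny_matrix, 0.0, 0.999999, 0.0, seed=1)
        assert (out.calls[tiny_matrix.calls == 1] == 0).all()

    def test_discordance_matches_closed_form(self):
        # both members of a pair are independent corruptions of the truth:
        # P(discordant | true=1) = 2*e10*(1-e10); | true=0) = 2*e01*(1-e01)
        rng = np.random.default_rng(0)
        from radiascan.io import MarkerMatrix
        calls = (rng.random((100, 100)) < 0.3).astype(np.int8)
        mm = MarkerMatrix([f"s{i}" for i in range(100)],
                          [f"L{j}" for j in range(100)], calls)
        e = 0.04
        out = corrupt_and_replicate(mm, e, e, 1.0, seed=2)
        pairs = out.replicate_pairs()
        a = out.calls[[i for i, _ in pairs]]
        b = out.calls[[j for _, j in pairs]]
        rate = (a != b).mean()
        p_exp = 2 * e * (1 - e)
        n = a.size
        half_ci = 2.576 * np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(rate - p_exp) < half_ci + 1e-12

    def test_bad_fraction(self, tiny_matrix):
        with pytest.raises(ValueError):
            corrupt_and_replicate(tiny_matrix, 0, 0, 1.5, seed=0)


class TestPeakProfiles:
    def test_zero_noise_round_trip(self):
        from radiascan.qc import score_profiles
        params = SimParams(n_pops=2, n_ind=10, n_loci=40, fst=0.2, seed=3)
        mm, _, _ = simulate_metapopulation(params)
        profiles = simulate_peak_profiles(mm, IntensityParams(), seed=4)
        scored = score_profiles(profiles)
        present_loci = np.flatnonzero(mm.calls.sum(axis=0) > 0)
        assert scored.n_loci == present_loci.size
        assert np.array_equal(scored.calls, mm.calls[:, present_loci])

    def test_noise_only_band_frequency_bounded(self):
        from radiascan.io import MarkerMatrix
        from radiascan.qc import QcConfig, score_profiles
        mm = MarkerMatrix([f"s{i}" for i in range(20)], ["L1", "L2"],
                          np.zeros((20, 2), dtype=np.int8))
        # noise peaks below the 50-unit detection threshold never score
        profiles = simulate_peak_profiles(
            mm, IntensityParams(noise_rate=5.0, noise_height_max=45.0), seed=5
        )
        profiles = {k: v for k, v in profiles.items() if len(v) >= 2}
        scored = score_profiles(profiles, QcConfig())
        assert scored.calls.sum() == 0

    def test_jitter_within_bin(self):
        # sd=0.2b against 0.75b bins: P(|N(0,0.2)| < 0.375) > 0.93 per side;
        # adjacent loci are >1b apart so collisions are negligible
        from scipy.stats import norm
        assert norm.cdf(0.375, scale=0.2) - norm.cdf(-0.375, scale=0.2) > 0.93
        params = SimParams(n_pops=2, n_ind=20, n_loci=30, fst=0.2, seed=6)
        mm, _, _ = simulate_metapopulation(params)
        from radiascan.qc import score_profiles
        profiles = simulate_peak_profiles(mm, IntensityParams(jitter_sd=0.2), seed=7)
        scored = score_profiles(profiles)
        # at least 99% of true presences recovered in some bin
        assert scored.calls.sum() >= 0.99 * mm.calls.sum()

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            IntensityParams(jitter_sd=-1)


class TestSequences:
    def test_four_clusters_recovered_at_3pct(self):
        ss = simulate_sequences(4, 5, 600, 0.005, 0.10, seed=8)
        part = motu_cluster(p_distance(ss), 0.03)
        assert part.n_clusters() == 4

    def test_zero_within_divergence(self):
        ss = simulate_sequences(3, 4, 300, 0.0, 0.2, seed=9)
        dm = p_distance(ss)
        for c in range(3):
            ids = [i for i, s in enumerate(ss.ids) if s.startswith(f"C{c + 1}_")]
            sub = dm.values[np.ix_(ids, ids)]
            assert sub.max() == 0.0

    def test_single_cluster_within_bound(self):
        within = 0.02
        ss = simulate_sequences(1, 8, 1000, within, 0.5, seed=10)
        dm = p_distance(ss)
        iu = np.triu_indices(8, 1)
        # pairwise expectation ~ within; binomial 99.9% upper bound
        ub = within + 4 * np.sqrt(within * (1 - within) / 1000)
        assert dm.values[iu].max() <= ub

    def test_bad_ordering(self):
        with pytest.raises(ValueError):
            simulate_sequences(2, 2, 100, 0.2, 0.1, seed=0)


class TestLandmarks:
    def test_zero_offset_goodall_f_near_one(self):
        from radiascan.morpho import goodall_f, gpa
        fs = []
        for seed in range(40):
            configs, labels = simulate_landmarks(2, 10, 10, 0.0, 0.02, True, seed)
            space = gpa(configs)
            res = goodall_f(space, labels.astype(str), "0", "1", n_perm=0)
            fs.append(res.f)
        assert 0.8 < np.mean(fs) < 1.35   # E[F] = df2/(df2-2) ~ 1.007

    def test_nuisance_removed_by_gpa(self):
        from radiascan.morpho import procrustes_distance
        configs, _ = simulate_landmarks(1, 1, 8, 0.0, 0.0, False, seed=11)
        base = configs[0]
        rng = np.random.default_rng(12)
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 3.1 * base @ rot.T + np.array([2.0, -5.0])
        assert procrustes_distance(base, moved) < 1e-8

    def test_separable_groups_assignable(self):
        from radiascan.morpho import cva_assign, gpa
        configs, labels = simulate_landmarks(2, 15, 10, 0.3, 0.01, True, seed=13)
        res = cva_assign(gpa(configs), labels.astype(str))
        assert res.overall_success >= 0.95

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_landmarks(2, 5, 5, 0.1, -0.1, False, seed=0)
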