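import numpy as np
import pandas as pd
import pytest

from chronospace import (
    bgpca,
    consensus_age_ranges,
    factor_impact,
    node_shifts,
    permutation_baseline,
    simulate_chronospace,
)
from chronospace.simulate import SimulationConfig

from brute import brute_bgpca
from conftest import make_matrix, random_matrix


class TestBgPCA:
    def test_two_group_hand_oracle(self):
        # group means (11,21) and (21,21): the only informative direction is
        # the first node; scores are first-column deviations from 16
        m = make_matrix([[10, 20], [12, 22], [20, 20], [22, 22]], ["G1"] * 2 + ["G2"] * 2)
        res = bgpca(m, "g")
        assert res.n_axes == 1
        assert np.allclose(res.axes[:, 0], [1.0, 0.0])
        assert np.allclose(res.scores[:, 0], [-6, -4, 4, 6])
        assert res.total_variance_explained == pytest.approx((104 / 3) / 36.0)

    def test_identical_group_means_give_zero_axes(self):
        X = [[10, 20], [12, 22], [10, 21], [12, 21]]
        m = make_matrix(X, ["G1", "G1", "G2", "G2"])
        res = bgpca(m, "g")
        assert res.n_axes == 0
        assert res.total_variance_explained == 0.0

    def test_five_levels_give_four_axes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(100, 10, size=(50, 8))
        labels = [f"L{i % 5}" for i in range(50)]
        res = bgpca(make_matrix(X, labels), "g")
        assert res.n_axes == 4

    def test_level_with_single_sample_errors(self):
        m = make_matrix([[1, 2], [2, 3], [3, 4]], ["a", "a", "b"])
        with pytest.raises(ValueError, match="< 2 samples"):
            bgpca(m, "g")

    def test_constant_matrix_errors(self):
        m = make_matrix(np.full((6, 3), 7.0), ["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="constant"):
            bgpca(m, "g")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_eigen_implementation(self, seed):
        rng = np.random.default_rng(seed)
        X, labels = random_matrix(rng)
        res = bgpca(make_matrix(X, labels), "g")
        axes, scores, ve = brute_bgpca(X, labels)
        assert res.axes.shape == axes.shape
        assert np.max(np.abs(res.axes - axes)) < 1e-8
        assert np.max(np.abs(res.scores - scores)) < 1e-8
        assert np.max(np.abs(res.variance_explained - ve)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_axes_orthonormal_and_centroids_are_projected_means(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, labels = random_matrix(rng)
        res = bgpca(make_matrix(X, labels), "g")
        k = res.n_axes
        assert np.allclose(res.axes.T @ res.axes, np.eye(k), atol=1e-10)
        for a, lv in enumerate(res.levels):
            rows = [i for i, l in enumerate(labels) if l == lv]
            proj = (X[rows].mean(axis=0) - res.grand_mean) @ res.axes
            assert np.allclose(res.group_centroids.loc[lv].to_numpy(), proj)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(42)
        X, labels = random_matrix(rng, n=30, p=6, g=3)
        base = bgpca(make_matrix(X, labels), "g")
        shifted = X.copy()
        shifted[:, 2] += 123.4  # constant added to one node column
        res_shift = bgpca(make_matrix(shifted, labels), "g")
        assert np.allclose(
            res_shift.variance_explained, base.variance_explained, atol=1e-12
        )
        res_scale = bgpca(make_matrix(X * 3.5, labels), "g")
        assert np.allclose(
            res_scale.variance_explained, base.variance_explained, atol=1e-12
        )
        assert np.allclose(res_scale.scores, base.scores * 3.5, atol=1e-8)

    def test_variance_explained_monotone_in_effect_size(self):
        cfg = SimulationConfig(n_tips=30, n_samples_per_set=40, runs_per_setting=1)
        ve = []
        for delta in [0.0, 10.0, 30.0, 100.0]:
            sim = simulate_chronospace(cfg, effect_shift=delta, seed=5)
            ve.append(bgpca(sim.matrix, "clock").total_variance_explained)
        assert all(a <= b + 1e-9 for a, b in zip(ve, ve[1:]))


class TestFactorImpact:
    def test_single_factor_duplicates_bgpca(self):
        rng = np.random.default_rng(7)
        X, labels = random_matrix(rng, n=24, p=5, g=2)
        m = make_matrix(X, labels)
        table, results = factor_impact(m, factors=["g"])
        assert table.loc[0, "factor"] == "g"
        direct = bgpca(m, "g")
        assert table.loc[0, "variance_explained"] == pytest.approx(
            direct.total_variance_explained
        )
        assert np.allclose(results["g"].scores, direct.scores)

    def test_injected_factor_ranked_first(self):
        sim = simulate_chronospace(
            SimulationConfig(n_tips=40, n_samples_per_set=60, runs_per_setting=1, seed=2)
        )
        table, _ = factor_impact(sim.matrix)
        assert table.loc[0, "factor"] == "clock"


class TestNodeShifts:
    def test_simple_shift_flagging(self):
        X = np.array([[120.0, 50], [120, 50], [95, 50], [95, 50]])
        m = make_matrix(X, ["a", "a", "b", "b"])
        table = node_shifts(m, "g", threshold=20.0)
        assert table.loc[0, "max_shift"] == pytest.approx(25.0)
        assert bool(table.loc[0, "flagged"])
        assert table.loc[1, "max_shift"] == pytest.approx(0.0)
        assert not bool(table.loc[1, "flagged"])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_pairwise_recomputation(self, seed):
        rng = np.random.default_rng(200 + seed)
        X, labels = random_matrix(rng, n=30, p=6, g=3)
        m = make_matrix(X, labels)
        table = node_shifts(m, "g", threshold=5.0).set_index("node")
        levels = sorted(set(labels))
        for j, key in enumerate(m.node_keys):
            means = [
                np.mean([X[i, j] for i in range(len(labels)) if labels[i] == lv])
                for lv in levels
            ]
            expected = max(
                abs(a - b) for a in means for b in means
            )
            label = "|".join(sorted(key))
            assert table.loc[label, "max_shift"] == pytest.approx(expected)


class TestConsensusRanges:
    def test_min_max_of_run_medians(self):
        df = pd.DataFrame({"nodeA": [100.0, 110.0, 90.0], "nodeB": [5.0, 5.0, 5.0]})
        out = consensus_age_ranges(df).set_index("node")
        assert out.loc["nodeA", "min_age"] == 90.0
        assert out.loc["nodeA", "max_age"] == 110.0
        assert out.loc["nodeB", "width"] == 0.0

    def test_single_run_gives_degenerate_ranges(self):
        df = pd.DataFrame({"nodeA": [100.0], "nodeB": [42.0]})
        out = consensus_age_ranges(df).set_index("node")
        assert (out["min_age"] == out["max_age"]).all()

    def test_many_runs_against_direct_scan(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(100, 20, size=(80, 7)),
                          columns=[f"n{i}" for i in range(7)])
        out = consensus_age_ranges(df, top=3)
        assert len(out) == 3
        full = consensus_age_ranges(df).set_index("node")
        for c in df.columns:
            assert full.loc[c, "min_age"] == df[c].min()
            assert full.loc[c, "max_age"] == df[c].max()


class TestPermutationBaseline:
    def test_single_permutation_gives_single_null_value(self):
        rng = np.random.default_rng(0)
        X, labels = random_matrix(rng, n=20, p=4, g=2)
        pb = permutation_baseline(make_matrix(X, labels), "g", n_perm=1, seed=0)
        assert pb.null_values.shape == (1,)

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(0)
        X, labels = random_matrix(rng, n=20, p=4, g=2)
        with pytest.raises(ValueError):
            permutation_baseline(make_matrix(X, labels), "g", n_perm=0)

    def test_injected_effect_exceeds_null_quantiles(self):
        sim = simulate_chronospace(
            SimulationConfig(n_tips=40, n_samples_per_set=60, runs_per_setting=1, seed=4)
        )
        pb = permutation_baseline(sim.matrix, "clock", n_perm=60, seed=4)
        assert pb.observed > pb.quantile(0.99)
        assert pb.percentile == 100.0
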