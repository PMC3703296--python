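"""The four signal statistics against brute-force and enumeration oracles."""

import itertools

import numpy as np
import pytest

from tests.conftest import (
    blomberg_oracle,
    geary_oracle,
    mantel_oracle,
    moran_oracle,
)

from phyloacoustics.matrices import SquareTaxonMatrix
from phyloacoustics.phylo import bm_vcv, tree_from_newick
from phyloacoustics.signal_tests import (
    BlombergKTest,
    GearyTest,
    MantelTest,
    MoranTest,
    UndefinedStatisticError,
    blombergs_k,
    gearys_c,
    mantel,
    mantel_bootstrap,
    mantel_mc,
    morans_i,
    morans_i_mc,
)
from phyloacoustics.simulate import simulate_bm, simulate_yule


def chain_weights(n):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W / W.sum(axis=1, keepdims=True)


def random_weights(rng, n):
    W = rng.random((n, n))
    np.fill_diagonal(W, 0)
    return W / W.sum(axis=1, keepdims=True)


class TestMoran:
    def test_three_point_chain_matches_enumeration(self):
        """n=3 chain: statistic equals the quadratic form; permutation mean
        over all 6 relabelings equals -1/(n-1)."""
        W = chain_weights(3)
        z = np.array([1.0, 0.0, -1.0])
        got = morans_i(z, W).statistic
        assert got == pytest.approx(moran_oracle(z, W))
        perms = [
            moran_oracle(z[list(p)], W) for p in itertools.permutations(range(3))
        ]
        assert np.mean(perms) == pytest.approx(-0.5)

    def test_permutation_mean_is_null_expectation(self, rng):
        for n in (4, 5, 6):
            W = random_weights(rng, n)
            z = rng.standard_normal(n)
            perms = [
                moran_oracle(z[list(p)], W) for p in itertools.permutations(range(n))
            ]
            assert np.mean(perms) == pytest.approx(-1.0 / (n - 1))

    def test_ordered_chain_positive_autocorrelation(self):
        n = 12
        z = np.arange(n, dtype=float)
        res = morans_i_mc(z, chain_weights(n), n_perm=999, seed=0)
        assert res.statistic > 0
        assert res.p_mc < 0.01

    def test_statistic_matches_bruteforce_on_random_data(self, rng):
        for _ in range(5):
            n = rng.integers(5, 15)
            W = random_weights(rng, n)
            z = rng.standard_normal(n)
            assert morans_i(z, W).statistic == pytest.approx(moran_oracle(z, W))

    def test_constant_trait_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            morans_i(np.ones(5), chain_weights(5))


class TestGeary:
    def test_statistic_matches_bruteforce(self, rng):
        for _ in range(5):
            n = rng.integers(5, 15)
            W = random_weights(rng, n)
            z = rng.standard_normal(n)
            assert gearys_c(z, W).statistic == pytest.approx(geary_oracle(z, W))

    def test_permutation_mean_is_one(self, rng):
        for n in (4, 5, 6):
            W = random_weights(rng, n)
            z = rng.standard_normal(n)
            perms = [
                geary_oracle(z[list(p)], W) for p in itertools.permutations(range(n))
            ]
            assert np.mean(perms) == pytest.approx(1.0)

    def test_clustered_values_give_c_below_one(self):
        # neighbors nearly identical along a chain -> strong similarity
        n = 10
        z = np.repeat([0.0, 10.0], 5) + np.linspace(0, 0.1, n)
        res = GearyTest(n_perm=499, seed=1).fit(z, chain_weights(n))
        assert res.statistic_ < 1.0
        assert res.p_value_ < 0.05
        assert res.std_deviate_ > 0  # deviate oriented so signal is positive


class TestBlombergK:
    def test_star_phylogeny_identity(self, star_tree, rng):
        C = bm_vcv(star_tree)
        for _ in range(20):
            y = rng.standard_normal(8) * rng.uniform(0.5, 5)
            assert abs(blombergs_k(y, C).statistic - 1.0) < 1e-10

    def test_matches_bruteforce_oracle(self, rng):
        for seed in range(4):
            tree = simulate_yule(12, 1.0, seed=seed)
            C = bm_vcv(tree)
            y = rng.standard_normal(12)
            assert blombergs_k(y, C).statistic == pytest.approx(
                blomberg_oracle(y, C.values)
            )

    def test_iid_trait_on_deep_balanced_tree_low_k(self, rng):
        # perfectly balanced depth-7 tree (128 tips), long shared history
        newick = "A:1"
        for _ in range(7):
            newick = f"({newick},{newick}):1"
        # deduplicate labels
        count = itertools.count()
        newick = "".join(
            f"t{next(count)}" if ch == "A" else ch for ch in newick
        ) + ";"
        tree = tree_from_newick(newick)
        y = rng.standard_normal(128)
        assert blombergs_k(y, bm_vcv(tree)).statistic < 0.5

    def test_bm_trait_detected_with_high_power(self):
        hits = 0
        for seed in range(20):
            tree = simulate_yule(64, 1.0, seed=seed)
            y = simulate_bm(tree, 1.0, 0.0, 1.0, seed=seed)["trait0"].to_numpy()
            res = BlombergKTest(n_perm=199, seed=seed).fit(y, bm_vcv(tree))
            hits += res.p_value_ <= 0.01
        assert hits >= 19  # >=95% of replicates significant at 0.01


class TestMantel:
    @staticmethod
    def _rand_dist(rng, n):
        M = rng.random((n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        return M

    def test_self_correlation_is_one(self, rng):
        D = self._rand_dist(rng, 8)
        assert mantel(D, D).statistic == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        D = self._rand_dist(rng, 8)
        assert mantel(D, 3.0 * D + 2.0).statistic == pytest.approx(1.0)

    def test_four_taxon_hand_computation(self, rng):
        DX = self._rand_dist(rng, 4)
        DY = self._rand_dist(rng, 4)
        assert mantel(DX, DY).statistic == pytest.approx(mantel_oracle(DX, DY))

    def test_taxon_order_mismatch_rejected(self, rng):
        D = self._rand_dist(rng, 4)
        A = SquareTaxonMatrix(list("abcd"), D, "distance")
        B = SquareTaxonMatrix(list("abdc"), D, "distance")
        with pytest.raises(ValueError, match="mismatch"):
            mantel(A, B)

    def test_constant_offdiagonal_rejected(self):
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(UndefinedStatisticError):
            mantel(D, D)


class TestDeterminismAndInvariance:
    """Shared contracts: seed determinism and location-scale invariance."""

    def test_same_seed_identical_p(self, rng):
        tree = simulate_yule(20, 1.0, seed=7)
        C = bm_vcv(tree)
        y = simulate_bm(tree, 1.0, 0.0, 0.5, seed=7)["trait0"].to_numpy()
        W = random_weights(rng, 20)
        DX = np.abs(y[:, None] - y[None, :])
        DY = C.values.max() - C.values
        np.fill_diagonal(DY, 0)
        for fn in (
            lambda s: morans_i_mc(y, W, 499, s).p_mc,
            lambda s: GearyTest(499, s).fit(y, W).p_value_,
            lambda s: BlombergKTest(499, s).fit(y, C).p_value_,
            lambda s: mantel_mc(DX, DY, 499, s).p_mc,
        ):
            assert fn(42) == fn(42)

    def test_location_scale_invariance(self, rng):
        tree = simulate_yule(15, 1.0, seed=2)
        C = bm_vcv(tree)
        W = random_weights(rng, 15)
        y = rng.standard_normal(15)
        y2 = 3.5 * y + 11.0
        assert abs(morans_i(y, W).statistic - morans_i(y2, W).statistic) < 1e-10
        assert abs(gearys_c(y, W).statistic - gearys_c(y2, W).statistic) < 1e-10
        assert abs(blombergs_k(y, C).statistic - blombergs_k(y2, C).statistic) < 1e-10
        DX1 = np.abs(y[:, None] - y[None, :])
        DX2 = np.abs(y2[:, None] - y2[None, :])
        DY = self_dist = np.abs(rng.standard_normal(15)[:, None] - rng.standard_normal(15)[None, :])
        assert abs(mantel(DX1, DY).statistic - mantel(DX2, DY).statistic) < 1e-10


def test_power_increases_with_signal_strength():
    """Rejection rate of K rises monotonically along the lambda grid
    {0, 0.5, 1} (independence -> diluted BM -> pure BM)."""
    rates = []
    for lam in (0.0, 0.5, 1.0):
        hits = 0
        for seed in range(40):
            tree = simulate_yule(25, 1.0, seed=800 + seed)
            y = simulate_bm(tree, 1.0, 0.0, lam, seed=900 + seed)["trait0"]
            res = BlombergKTest(99, seed).fit(y.to_numpy(), bm_vcv(tree))
            hits += res.p_value_ <= 0.05
        rates.append(hits / 40)
    assert rates[0] < rates[1] <= rates[2]
    assert rates[2] > 0.8


class TestMantelBootstrap:
    def test_identical_matrices_bootstrap_r_is_one(self, rng):
        M = rng.random((12, 12))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        boot = mantel_bootstrap(M, M, n_iter=200, seed=0)
        np.testing.assert_allclose(boot.r, 1.0)

    def test_seed_determinism(self, rng):
        X = rng.random((10, 10)); X = (X + X.T) / 2; np.fill_diagonal(X, 0)
        Y = rng.random((10, 10)); Y = (Y + Y.T) / 2; np.fill_diagonal(Y, 0)
        b1 = mantel_bootstrap(X, Y, 300, seed=5)
        b2 = mantel_bootstrap(X, Y, 300, seed=5)
        np.testing.assert_array_equal(b1.r, b2.r)

    def test_small_bias_at_moderate_n(self):
        """Bootstrap mean r tracks the full-sample r (bias < 0.05 at n=60)."""
        tree = simulate_yule(60, 1.0, seed=3)
        C = bm_vcv(tree)
        y = simulate_bm(tree, 1.0, 0.0, 1.0, seed=3)["trait0"].to_numpy()
        DX = np.abs(y[:, None] - y[None, :])
        DY = C.values.max() - C.values
        np.fill_diagonal(DY, 0)
        full_r = mantel(DX, DY).statistic
        boot = mantel_bootstrap(DX, DY, n_iter=2000, seed=1)
        assert abs(boot.r.mean() - full_r) < 0.05

    def test_too_small_subsample_rejected(self, rng):
        M = rng.random((4, 4)); M = (M + M.T) / 2; np.fill_diagonal(M, 0)
        with pytest.raises(ValueError, match="too small"):
            mantel_bootstrap(M, M, 10, frac=0.5)
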