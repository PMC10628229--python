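import numpy as np
import pytest

from siagmm import (
    Dataset,
    GMMParams,
    PenaltyWeights,
    kl_gaussian,
    klf_klb,
    mpkl,
    penalized_objective,
)
from siagmm.kl import pairwise_kl_matrix

from conftest import random_gmm


def mc_kl(mean1, cov1, mean2, cov2, n=100_000, seed=0):
    """Monte-Carlo E_{x~N1}[log f1(x) - log f2(x)] with a standard error."""
    from scipy.stats import multivariate_normal as mvn

    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.atleast_1d(mean1), np.atleast_2d(cov1), size=n)
    lr = mvn.logpdf(X, np.atleast_1d(mean1), np.atleast_2d(cov1)) - mvn.logpdf(
        X, np.atleast_1d(mean2), np.atleast_2d(cov2)
    )
    return lr.mean(), lr.std(ddof=1) / np.sqrt(n)


class TestKLGaussian:
    def test_identical_components_zero(self, rng):
        P = random_gmm(rng, 1, 3)
        b = kl_gaussian(P.means[0], P.covariances[0], P.means[0], P.covariances[0])
        assert b.total == pytest.approx(0.0, abs=1e-10)
        assert b.term_a == pytest.approx(0.0, abs=1e-10)
        assert b.term_b == pytest.approx(0.0, abs=1e-10)
        assert b.term_c == pytest.approx(0.0, abs=1e-10)

    def test_univariate_values_and_asymmetry(self):
        # frozen from the Monte-Carlo oracle (1e5 samples, agreement << 3 SE)
        fwd = kl_gaussian([0.0], [[1.0]], [0.0], [[4.0]]).total
        bwd = kl_gaussian([0.0], [[4.0]], [0.0], [[1.0]]).total
        assert fwd == pytest.approx(0.318147, abs=1e-5)
        assert bwd == pytest.approx(0.806853, abs=1e-5)
        assert fwd != pytest.approx(bwd, abs=0.1)

    @pytest.mark.parametrize("p", [1, 2, 5])
    def test_matches_monte_carlo(self, rng, p):
        P = random_gmm(rng, 2, p)
        closed = kl_gaussian(
            P.means[0], P.covariances[0], P.means[1], P.covariances[1]
        ).total
        est, se = mc_kl(P.means[0], P.covariances[0], P.means[1], P.covariances[1], seed=p)
        assert abs(closed - est) < 3 * se

    def test_term_signs(self, rng):
        # C >= 0 always; A + B is the LogDet divergence, non-negative
        for _ in range(20):
            P = random_gmm(rng, 2, 3)
            b = kl_gaussian(P.means[0], P.covariances[0], P.means[1], P.covariances[1])
            assert b.term_c >= 0
            assert b.term_a + b.term_b >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kl_gaussian([0.0], [[1.0]], [0.0, 0.0], np.eye(2))


class TestKlfKlb:
    def test_identical_pair_zero(self):
        P = GMMParams([0.5, 0.5], np.zeros((2, 2)), np.stack([np.eye(2)] * 2))
        out = klf_klb(P)
        assert out["KLF"] == pytest.approx(0.0, abs=1e-12)
        assert out["KLB"] == pytest.approx(0.0, abs=1e-12)

    def test_two_component_directed_sums(self):
        P = GMMParams([0.5, 0.5], np.zeros((2, 1)), [[[1.0]], [[4.0]]])
        out = klf_klb(P)
        assert out["KLF"] == pytest.approx(0.318147, abs=1e-5)
        assert out["KLB"] == pytest.approx(0.806853, abs=1e-5)
        swapped = klf_klb(P.permuted([1, 0]))
        assert swapped["KLF"] == pytest.approx(out["KLB"])
        assert swapped["KLB"] == pytest.approx(out["KLF"])

    def test_sum_is_jeffreys_and_permutation_invariant(self, rng):
        P = random_gmm(rng, 3, 2)
        out = klf_klb(P)
        D = pairwise_kl_matrix(P)
        jeffreys = sum(
            D[a, b] + D[b, a] for a in range(3) for b in range(3) if a < b
        )
        assert out["KLF"] + out["KLB"] == pytest.approx(jeffreys)
        perm = klf_klb(P.permuted([2, 0, 1]))
        assert perm["KLF"] + perm["KLB"] == pytest.approx(jeffreys)

    def test_single_component_signalled(self):
        with pytest.raises(ValueError):
            klf_klb(GMMParams([1.0], [[0.0]], [[[1.0]]]))


class TestPenalizedObjective:
    def test_zero_weights_give_likelihood(self, rng):
        P = random_gmm(rng, 2, 2)
        data = Dataset(rng.normal(size=(30, 2)))
        out = penalized_objective(data, P, PenaltyWeights(0.0, 0.0))
        assert out["M"] == out["L"]

    def test_recomposition(self, rng):
        P = random_gmm(rng, 3, 2)
        data = Dataset(rng.normal(size=(30, 2)))
        out = penalized_objective(data, P, PenaltyWeights(1.0, 1.0))
        pieces = klf_klb(P)
        from siagmm import log_likelihood

        assert out["M"] == pytest.approx(
            log_likelihood(data, P)["total"] - pieces["KLF"] - pieces["KLB"]
        )

    def test_identical_components_no_penalty(self, rng):
        P = GMMParams([0.5, 0.5], np.zeros((2, 2)), np.stack([np.eye(2)] * 2))
        data = Dataset(rng.normal(size=(20, 2)))
        out = penalized_objective(data, P, PenaltyWeights(3.0, 7.0))
        assert out["M"] == pytest.approx(out["L"])

    def test_permutation_invariance_equal_weights(self, rng):
        P = random_gmm(rng, 3, 2)
        data = Dataset(rng.normal(size=(30, 2)))
        a = penalized_objective(data, P, PenaltyWeights(1.0, 1.0))["M"]
        b = penalized_objective(data, P.permuted([1, 2, 0]), PenaltyWeights(1.0, 1.0))["M"]
        assert a == pytest.approx(b)


class TestMPKL:
    def test_equal_covariances_zero(self, rng):
        means = rng.normal(size=(2, 3))
        P = GMMParams([0.4, 0.6], means, np.stack([np.eye(3)] * 2))
        assert mpkl(P) == pytest.approx(0.0, abs=1e-10)

    def test_two_component_value(self):
        P = GMMParams([0.5, 0.5], np.zeros((2, 1)), [[[1.0]], [[4.0]]])
        assert mpkl(P) == pytest.approx(abs(0.318147 - 0.806853), abs=1e-5)

    def test_matches_brute_force_and_permutation_invariant(self, rng):
        P = random_gmm(rng, 3, 2)
        D = pairwise_kl_matrix(P)
        brute = max(
            abs(D[a, b] - D[b, a]) for a in range(3) for b in range(3) if a < b
        )
        assert mpkl(P) == pytest.approx(brute)
        assert mpkl(P.permuted([2, 1, 0])) == pytest.approx(brute)


class TestBoundedness:
    def test_penalty_bounds_collapsing_component(self):
        """Collapse one covariance onto a data point: the raw likelihood
        grows without bound while the penalized objective turns over."""
        rng = np.random.default_rng(7)
        p, n = 20, 40
        X = rng.normal(0.0, 0.1, (n, p))
        data = Dataset(X)
        sig2 = float(np.var(X))
        Ls, Ms = [], []
        for eps in 10.0 ** -np.arange(1, 13):
            P = GMMParams(
                [0.5, 0.5],
                [X[0], X.mean(axis=0)],
                [eps * np.eye(p), sig2 * np.eye(p)],
            )
            out = penalized_objective(data, P, PenaltyWeights(1.0, 1.0))
            Ls.append(out["L"])
            Ms.append(out["M"])
        assert Ls[-1] - Ls[0] > 100  # unbounded growth of the raw likelihood
        k = int(np.argmax(Ms))
        assert 0 < k < len(Ms) - 1  # interior maximum of the penalized objective
        assert np.all(np.diff(Ms[k:]) < 0)
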