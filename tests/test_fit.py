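import numpy as np
import pytest

from siagmm import (
    Dataset,
    GMMParams,
    PenaltyWeights,
    adgd_fit,
    ari,
    em_fit,
    kmeans_init,
    penalized_objective,
    sia_fit,
)

from conftest import random_gmm


def sample_gmm(rng, P, n):
    counts = np.round(P.weights * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    parts, labs = [], []
    for k in range(P.K):
        C = np.linalg.cholesky(P.covariances[k])
        parts.append(rng.standard_normal((counts[k], P.p)) @ C.T + P.means[k])
        labs.append(np.full(counts[k], k))
    return Dataset(np.vstack(parts), np.concatenate(labs))


class TestKMeansInit:
    def test_single_cluster_moments(self, rng):
        X = rng.normal(size=(200, 3))
        P = kmeans_init(Dataset(X), 1, seed=0)
        assert np.allclose(P.weights, [1.0])
        assert np.allclose(P.means[0], X.mean(axis=0), atol=1e-8)
        assert np.allclose(P.covariances[0], np.cov(X, rowvar=False), atol=1e-6)

    def test_two_separated_clouds(self, two_blob_data):
        P = kmeans_init(two_blob_data, 2, seed=0)
        cloud_means = np.array(
            [two_blob_data.X[:200].mean(axis=0), two_blob_data.X[200:].mean(axis=0)]
        )
        order = np.argsort(P.means[:, 0])
        assert np.allclose(P.means[order], cloud_means[np.argsort(cloud_means[:, 0])], atol=1e-6)
        assert np.allclose(np.sort(P.weights), [0.5, 0.5])

    def test_deterministic_given_seed(self, two_blob_data):
        a = kmeans_init(two_blob_data, 2, seed=3)
        b = kmeans_init(two_blob_data, 2, seed=3)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)

    def test_n_less_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_init(Dataset(rng.normal(size=(2, 2))), 3)


class TestEM:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(2.0, 1.5, size=(300, 2))
        data = Dataset(X)
        fit = em_fit(data, kmeans_init(data, 1, seed=0))
        assert np.allclose(fit.params.means[0], X.mean(axis=0), atol=1e-8)
        # M-step MLE covariance divides by n, not n-1
        assert np.allclose(
            fit.params.covariances[0], np.cov(X, rowvar=False, ddof=0), atol=1e-6
        )

    def test_far_separated_recovery(self, rng):
        P = GMMParams(
            [0.5, 0.5], [[0.0, 0.0], [20.0, 0.0]], np.stack([np.eye(2)] * 2)
        )
        data = sample_gmm(rng, P, 400)
        fit = em_fit(data, kmeans_init(data, 2, seed=0))
        assert ari(data.labels, fit.labels) == 1.0
        assert fit.converged

    def test_monotone_ascent_random_instances(self):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            P = random_gmm(rng, 2, 2)
            data = Dataset(rng.normal(scale=2.0, size=(80, 2)))
            fit = em_fit(data, kmeans_init(data, 2, seed=seed), max_iter=150)
            assert np.all(np.diff(fit.objective_trace) >= -1e-8)

    def test_degenerate_run_signalled(self):
        # five coincident points + one component pinned on them with a tiny
        # covariance: the M-step covariance collapses to zero
        X = np.vstack([np.zeros((5, 2)), np.random.default_rng(1).normal(5, 1, (20, 2))])
        init = GMMParams(
            [0.2, 0.8],
            [[0.0, 0.0], [5.0, 5.0]],
            [1e-6 * np.eye(2), np.eye(2)],
        )
        fit = em_fit(Dataset(X), init)
        assert fit.degenerate
        assert not fit.converged
        assert fit.message  # diagnostics name the failing component
        fit.params.validate()  # last valid parameters are returned


class TestADGD:
    def test_near_stationary_at_em_solution(self, two_blob_data):
        em = em_fit(two_blob_data, kmeans_init(two_blob_data, 2, seed=0))
        gd = adgd_fit(two_blob_data, em.params, PenaltyWeights(0.0, 0.0))
        assert gd.objective_trace[-1] - gd.objective_trace[0] < 1e-4 * (
            1 + abs(gd.objective_trace[0])
        )

    def test_deterministic_trace(self, two_blob_data):
        init = kmeans_init(two_blob_data, 2, seed=1)
        a = adgd_fit(two_blob_data, init, PenaltyWeights(0.5, 0.5), max_iter=300)
        b = adgd_fit(two_blob_data, init, PenaltyWeights(0.5, 0.5), max_iter=300)
        assert np.array_equal(a.objective_trace, b.objective_trace)
        assert np.array_equal(a.params.means, b.params.means)

    def test_final_objective_not_below_init(self, rng, two_blob_data):
        init = kmeans_init(two_blob_data, 2, seed=2)
        w = PenaltyWeights(1.0, 1.0)
        fit = adgd_fit(two_blob_data, init, w, max_iter=500)
        M0 = penalized_objective(two_blob_data, init, w)["M"]
        M1 = penalized_objective(two_blob_data, fit.params, w)["M"]
        assert M1 >= M0 - 1e-6

    def test_improves_maximum_likelihood_from_kmeans(self, two_blob_data):
        init = kmeans_init(two_blob_data, 2, seed=0)
        fit = adgd_fit(two_blob_data, init, PenaltyWeights(0.0, 0.0))
        em = em_fit(two_blob_data, init)
        assert fit.loglik_total == pytest.approx(em.loglik_total, abs=1.0)
        assert ari(two_blob_data.labels, fit.labels) == 1.0


class TestSIA:
    def test_zero_weight_grid_is_unpenalized_refinement(self, two_blob_data):
        res = sia_fit(two_blob_data, 2, weight_grid=(0.0,), seed=0)
        assert res.selected is res.step2_by_weight[0.0]
        assert res.selected.weights_used == PenaltyWeights(0.0, 0.0)
        assert res.selected.loglik_total == pytest.approx(res.step1.loglik_total, abs=1.0)

    def test_selected_minimizes_mpkl_with_zero_in_grid(self, two_blob_data):
        res = sia_fit(two_blob_data, 2, seed=0)
        mpkls = {
            w: f.mpkl for w, f in res.step2_by_weight.items() if f is not None
        }
        assert res.selected.mpkl == min(mpkls.values())
        assert res.selected.mpkl <= res.step1.mpkl + 1e-8

    def test_pinwheel_step2_trades_likelihood_for_symmetry(self):
        # warped-arm data: penalized refinement reduces both directed KL
        # sums and their asymmetry while total likelihood decreases and
        # label agreement improves
        from siagmm import PinwheelConfig, pinwheel

        ds = pinwheel(PinwheelConfig(n_per_class=100, r=0.3, t=0.05, s=0.4, seed=1))
        res = sia_fit(ds, 3, seed=1)
        s1 = res.step1
        for w, f in res.step2_by_weight.items():
            if w == 0 or f is None:
                continue
            assert f.klf < s1.klf
            assert f.klb < s1.klb
            assert abs(f.klf - f.klb) < abs(s1.klf - s1.klb)
            assert f.loglik_total < s1.loglik_total
        assert ari(ds.labels, res.selected.labels) >= ari(ds.labels, s1.labels)

    def test_well_specified_truth_unchanged(self, rng):
        # equal-covariance well-separated truth: penalty ~ 0 at the optimum,
        # so the selected solution stays at the Step-I fit
        P = GMMParams([0.5, 0.5], [[0.0, 0.0], [6.0, 0.0]], np.stack([np.eye(2)] * 2))
        data = sample_gmm(rng, P, 1000)
        res = sia_fit(data, 2, seed=0)
        assert ari(res.step1.labels, res.selected.labels) == 1.0
        assert abs(res.selected.loglik_total - res.step1.loglik_total) < 0.01 * abs(
            res.step1.loglik_total
        )


class TestParameterRecovery:
    @pytest.mark.parametrize("method", ["em", "adgd", "sia"])
    def test_well_specified_two_component(self, method):
        rng = np.random.default_rng(6)
        truth = GMMParams(
            [0.5, 0.5], [[0.0, 0.0], [6.0, 0.0]], np.stack([np.eye(2)] * 2)
        )
        data = sample_gmm(rng, truth, 2000)
        if method == "em":
            fit = em_fit(data, kmeans_init(data, 2, seed=0))
        elif method == "adgd":
            fit = adgd_fit(data, kmeans_init(data, 2, seed=0))
        else:
            fit = sia_fit(data, 2, seed=0).selected
        order = np.argsort(fit.params.means[:, 0])
        assert np.allclose(fit.params.weights[order], truth.weights, atol=0.05)
        assert np.allclose(fit.params.means[order], truth.means, atol=0.05)
        for k in range(2):
            diff = fit.params.covariances[order][k] - truth.covariances[k]
            assert np.linalg.norm(diff, "fro") < 0.1
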