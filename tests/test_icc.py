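import math

import numpy as np
import pytest

from iccmix.icc import (
    ClusterCollapseError,
    MixtureModel,
    average_model,
    complete_data_bic,
    impute_memberships,
    posterior_membership,
    run_icc,
    update_component,
)
from iccmix.screening import SparseFit, sis_mcp_fit
from iccmix.simulate import SimulationConfig, generate_dataset


def make_model(pi, intercepts, slopes, sigmas):
    """Build a MixtureModel from per-component (index -> slope) maps."""
    betas = [
        SparseFit(intercept=b0, coefficients=dict(sl),
                  screened_set=np.asarray([], dtype=np.intp))
        for b0, sl in zip(intercepts, slopes)
    ]
    return MixtureModel(pi=np.asarray(pi), betas=betas,
                        sigmas=np.asarray(sigmas))


class TestPosteriorMembership:
    def test_identical_components_give_uniform_rows(self):
        model = make_model([0.5, 0.5], [1.0, 1.0], [{0: 2.0}, {0: 2.0}],
                           [1.5, 1.5])
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        probs = posterior_membership(model, X, y)
        np.testing.assert_allclose(probs, 0.5)

    def test_single_component_probability_one(self):
        model = make_model([1.0], [0.0], [{0: 1.0}], [1.0])
        X = np.random.default_rng(1).standard_normal((5, 2))
        probs = posterior_membership(model, X, X[:, 0])
        np.testing.assert_array_equal(probs, 1.0)

    def test_matches_scalar_gaussian_arithmetic_on_toy(self):
        """Two samples, two components: compare to the membership formula
        evaluated coordinate by coordinate with math.exp/sqrt."""
        pi = (0.3, 0.7)
        model = make_model(pi, [0.5, -1.0], [{0: 2.0}, {0: -1.0, 1: 0.5}],
                           [0.8, 1.7])
        X = np.array([[0.4, -1.2], [2.0, 0.3]])
        y = np.array([1.1, -0.6])
        means = [
            [0.5 + 2.0 * 0.4, -1.0 - 1.0 * 0.4 + 0.5 * -1.2],
            [0.5 + 2.0 * 2.0, -1.0 - 1.0 * 2.0 + 0.5 * 0.3],
        ]
        expected = np.empty((2, 2))
        for i in range(2):
            dens = [
                pi[k]
                * math.exp(-0.5 * ((y[i] - means[i][k]) / s) ** 2)
                / (s * math.sqrt(2 * math.pi))
                for k, s in enumerate((0.8, 1.7))
            ]
            expected[i] = np.array(dens) / sum(dens)
        got = posterior_membership(model, X, y)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_extreme_outlier_falls_back_to_uniform(self, caplog):
        model = make_model([0.5, 0.5], [0.0, 0.0], [{}, {}], [1e-3, 1e-3])
        X = np.zeros((1, 1))
        y = np.array([1e6])  # underflows both components
        probs = posterior_membership(model, X, y)
        np.testing.assert_allclose(probs, 0.5)


class TestImputeMemberships:
    def test_degenerate_row_is_certain(self):
        probs = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        labels = impute_memberships(probs, np.random.default_rng(0))
        assert labels.tolist() == [0, 2]

    def test_fair_row_frequency_within_three_standard_errors(self):
        n = 100_000
        probs = np.full((n, 2), 0.5)
        labels = impute_memberships(probs, np.random.default_rng(1))
        freq = np.mean(labels == 0)
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_seeded_draws_are_reproducible(self):
        probs = np.random.default_rng(2).dirichlet([1, 1, 1], size=50)
        a = impute_memberships(probs, np.random.default_rng(3))
        b = impute_memberships(probs, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestUpdateComponent:
    def test_perfect_fit_sigma_hits_floor(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = 2.0 * X[:, 1]  # exact linear model, zero residuals
        _, fit, sigma = update_component(X, y, np.arange(40))
        assert fit.support.tolist() == [1]
        # zero residuals: sigma equals the applied floor
        assert sigma <= max(1e-4, 0.05 * y.std()) + 1e-12

    def test_single_cluster_reduces_to_plain_fit(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = X @ ([3.0] + [0.0] * 9) + 0.3 * rng.standard_normal(80)
        pi, fit, _ = update_component(X, y, np.arange(80))
        ref = sis_mcp_fit(X, y)
        assert pi == 1.0
        assert fit.support.tolist() == ref.support.tolist()
        assert fit.intercept == pytest.approx(ref.intercept)

    def test_undersized_cluster_gets_intercept_only(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        _, fit, _ = update_component(X, y, np.arange(4))
        assert fit.card == 0
        assert fit.intercept == pytest.approx(y[:4].mean())

    def test_sigma_estimate_at_benchmark_component_scale(self):
        """One true component (n=200, sigma=1): residual s.d. lands within
        0.15 of the truth."""
        ds = generate_dataset(SimulationConfig(), seed=9)
        members = np.flatnonzero(ds.truth.memberships == 0)
        _, _, sigma = update_component(ds.X, ds.y, members)
        assert sigma == pytest.approx(1.0, abs=0.15)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            update_component(np.zeros((5, 2)), np.zeros(5),
                             np.asarray([], dtype=int))


class TestRunIcc:
    def test_single_component_short_circuits(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 20))
        y = X @ ([3.0] * 2 + [0.0] * 18) + 0.3 * rng.standard_normal(80)
        trace = run_icc(X, y, K=1, T=500, t0=100, seed=0)
        assert trace.T == 1
        ref = sis_mcp_fit(X, y)
        assert trace.models[0].betas[0].support.tolist() == ref.support.tolist()
        assert trace.models[0].pi.tolist() == [1.0]

    def test_equal_seeds_give_identical_traces(self, small_dataset):
        a = run_icc(small_dataset.X, small_dataset.y, K=3, T=25, t0=5, seed=11)
        b = run_icc(small_dataset.X, small_dataset.y, K=3, T=25, t0=5, seed=11)
        assert np.array_equal(a.memberships, b.memberships)
        np.testing.assert_array_equal(a.bics, b.bics)

    def test_mixing_proportions_are_count_fractions(self, small_trace):
        n = small_trace.memberships.shape[1]
        for t in range(0, small_trace.T, 10):
            model = small_trace.models[t]
            counts = np.bincount(small_trace.memberships[t], minlength=3)
            np.testing.assert_allclose(model.pi, counts / n)
            assert model.pi.sum() == pytest.approx(1.0, abs=1e-15)

    def test_bic_path_stabilizes_after_burn_in(self, small_trace):
        """The chain equilibrates: late BIC variation is small compared to
        the burn-in excursion."""
        bics = small_trace.bics
        excursion = bics[:20].max() - bics.min()
        late = bics[-50:]
        assert late.std() < 0.05 * excursion

    def test_persistent_collapse_raises(self):
        # 7 samples cannot keep 3 components populated for long
        rng = np.random.default_rng(8)
        X = rng.standard_normal((7, 3))
        y = rng.standard_normal(7)
        with pytest.raises(ClusterCollapseError):
            run_icc(X, y, K=3, T=100, t0=10, seed=1,
                    max_rescues=1, max_restarts=1)

    def test_invalid_iteration_budget(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            run_icc(X, np.zeros(10), K=2, T=10, t0=10, seed=0)


class TestAverageModel:
    def test_relabeled_chain_average_recovers_coefficients(self, small_trace,
                                                           small_dataset):
        """Averaging the relabeled post-burn-in models stays close to the
        generating coefficients (per-component l2 error below 1)."""
        avg = average_model(small_trace, small_dataset.p)
        from iccmix.experiments import truth_model
        from iccmix.metrics import match_components

        tm = truth_model(small_dataset.truth)
        perm = match_components(avg, tm, small_dataset.p)
        for k in range(3):
            err = np.linalg.norm(
                avg.betas[perm[k]].coef_array(small_dataset.p)
                - small_dataset.truth.betas[k]
            )
            assert err < 1.0


class TestCompleteDataBic:
    def test_more_parameters_cost_log_n_each(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        labels = np.zeros(50, dtype=int)
        lean = make_model([1.0], [0.0], [{}], [1.0])
        rich = make_model([1.0], [0.0], [{0: 0.0, 1: 0.0}], [1.0])
        # identical likelihood, two extra slopes => BIC differs by 2 log n
        diff = complete_data_bic(rich, X, y, labels) - complete_data_bic(
            lean, X, y, labels
        )
        assert diff == pytest.approx(2 * np.log(50))


class TestModelSerialization:
    def test_json_round_trip(self):
        model = make_model([0.4, 0.6], [1.0, -2.0],
                           [{3: 1.5}, {0: -0.5, 7: 2.0}], [0.9, 1.1])
        back = MixtureModel.from_json(model.to_json())
        np.testing.assert_allclose(back.pi, model.pi)
        np.testing.assert_allclose(back.sigmas, model.sigmas)
        for a, b in zip(back.betas, model.betas):
            assert a.intercept == b.intercept
            assert a.coefficients == b.coefficients
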