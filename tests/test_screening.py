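import numpy as np
import pytest

from iccmix.screening import (
    default_screen_budget,
    fit_mcp_path,
    mcp_univariate,
    model_free_screen,
    sis_mcp_fit,
    sure_independence_screen,
)
from iccmix.simulate import SimulationConfig, generate_dataset

from conftest import orthonormal_design


def mcp_penalty(b, lam, gamma):
    b = abs(b)
    return np.where(
        b <= gamma * lam, lam * b - b ** 2 / (2 * gamma), 0.5 * gamma * lam ** 2
    )


def mcp_grid_argmin(z, lam, gamma):
    """Dense two-stage grid search of the univariate MCP objective
    0.5 (z-b)^2 + P(|b|) — the independent oracle for the threshold rule."""
    lo, hi = -abs(z) - 1.0, abs(z) + 1.0
    grid = np.linspace(lo, hi, 20_001)
    obj = 0.5 * (z - grid) ** 2 + mcp_penalty(grid, lam, gamma)
    b0 = grid[np.argmin(obj)]
    step = grid[1] - grid[0]
    fine = np.linspace(b0 - step, b0 + step, 20_001)
    obj = 0.5 * (z - fine) ** 2 + mcp_penalty(fine, lam, gamma)
    return fine[np.argmin(obj)]


class TestSureIndependenceScreen:
    def test_perfect_marginal_correlation_wins(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        y = X[:, 3].copy()
        assert sure_independence_screen(X, y, 1).tolist() == [3]

    def test_tie_broken_by_ascending_index(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30)
        X = np.column_stack([y, -y, rng.standard_normal(30)])
        assert sure_independence_screen(X, y, 2).tolist() == [0, 1]

    def test_budget_beyond_dimension_returns_all_ranked(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 4))
        y = X @ [0.0, 2.0, 0.0, 0.5] + 0.01 * rng.standard_normal(25)
        idx = sure_independence_screen(X, y, 10)
        assert len(idx) == 4 and idx[0] == 1

    def test_constant_column_scores_zero_not_nan(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = X[:, 1] + 0.1 * rng.standard_normal(20)
        assert sure_independence_screen(X, y, 2).tolist() == [1, 0]

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sure_independence_screen(np.eye(4), np.ones(4), 1)

    def test_affine_column_rescaling_is_irrelevant(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 8))
        y = X @ rng.standard_normal(8)
        scaled = X * np.array([2.0, -5.0, 0.1, 1.0, 3.0, -0.2, 7.0, 1.5]) + 11.0
        a = sure_independence_screen(X, y, 4)
        b = sure_independence_screen(scaled, y, 4)
        assert a.tolist() == b.tolist()

    def test_rank_based_screen_finds_monotone_signal(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = np.exp(X[:, 2])  # monotone but nonlinear
        assert model_free_screen(X, y, 1).tolist() == [2]

    def test_budget_rule(self):
        assert default_screen_budget(200) == int(200 / np.log(200))
        with pytest.raises(ValueError):
            default_screen_budget(1)


class TestMcpUnivariate:
    def test_zero_input_stays_zero(self):
        assert mcp_univariate(0.0, 1.0, 3.0) == 0.0

    def test_large_inputs_unshrunk(self):
        # beyond gamma*lam the penalty is flat: no bias
        assert mcp_univariate(10.0, 1.0, 3.0) == 10.0
        assert mcp_univariate(-7.5, 2.0, 3.0) == -7.5

    def test_matches_grid_search_oracle(self):
        zs = np.linspace(-4, 4, 20)
        cases = [(z, lam, gamma) for z in zs for lam in (0.5, 1.5)
                 for gamma in (2.0, 3.0)]
        for z, lam, gamma in cases:
            assert mcp_univariate(z, lam, gamma) == pytest.approx(
                mcp_grid_argmin(z, lam, gamma), abs=1e-6
            )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            mcp_univariate(1.0, 1.0, gamma=1.0)
        with pytest.raises(ValueError):
            mcp_univariate(1.0, -0.5, gamma=3.0)


class TestMcpPath:
    def test_lambda_max_endpoint_is_null_model(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 5))
        y = X @ [1.0, 0, 0, 0, 0.5] + 0.1 * rng.standard_normal(60)
        fits = fit_mcp_path(X, y)
        assert fits[0].card == 0
        assert fits[0].intercept == pytest.approx(y.mean())

    def test_orthonormal_design_matches_coordinatewise_rule(self):
        n, d = 64, 6
        X = orthonormal_design(n, d, seed=7)
        rng = np.random.default_rng(8)
        y = X @ [2.0, -1.0, 0.4, 0.0, 0.0, 0.05] + 0.3 * rng.standard_normal(n)
        yc = y - y.mean()
        z = X.T @ yc / n
        fits = fit_mcp_path(X, y, gamma=3.0)
        for f in fits:
            expected = np.array(
                [mcp_univariate(zj, f.lambda_selected, 3.0) for zj in z]
            )
            got = np.zeros(d)
            for j, v in f.coefficients.items():
                got[j] = v
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_support_size_monotone_in_lambda_on_orthogonal_design(self):
        n, d = 80, 8
        X = orthonormal_design(n, d, seed=9)
        rng = np.random.default_rng(10)
        y = X @ [3, 2, 1.5, 1, 0.7, 0.4, 0.1, 0] + 0.2 * rng.standard_normal(n)
        fits = fit_mcp_path(X, y)
        cards = [f.card for f in fits]  # path runs lambda_max -> small
        assert all(a <= b for a, b in zip(cards, cards[1:]))

    def test_recovery_on_small_noisy_instance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 3))
        y = 3.0 * X[:, 0] + 0.1 * rng.standard_normal(50)
        fit = sis_mcp_fit(X, y, d=3)
        assert fit.support.tolist() == [0]
        assert fit.coefficients[0] == pytest.approx(3.0, abs=0.2)
        # consistent with least squares on the true support
        ls = np.linalg.lstsq(np.column_stack([np.ones(50), X[:, 0]]), y,
                             rcond=None)[0]
        assert fit.coefficients[0] == pytest.approx(ls[1], abs=0.05)

    def test_ascending_lambda_grid_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError):
            fit_mcp_path(X, X[:, 0], lambdas=np.array([0.1, 0.5]))

    def test_invalid_gamma_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError):
            fit_mcp_path(X, X[:, 0], gamma=0.9)


class TestSisMcpFit:
    def test_screening_noop_when_budget_covers_dimension(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 4))
        y = X @ [2.0, 0, -1.0, 0] + 0.1 * rng.standard_normal(60)
        a = sis_mcp_fit(X, y, d=4)
        b = sis_mcp_fit(X, y, d=100)
        assert a.support.tolist() == b.support.tolist()
        assert a.intercept == pytest.approx(b.intercept)
        for j in a.coefficients:
            assert a.coefficients[j] == pytest.approx(b.coefficients[j])

    def test_recovers_sparse_truth_at_benchmark_component_scale(self):
        """Single-component design at the per-component scale of the
        benchmark (n=200, p=2000, three slopes of 3): perfect selection in
        at least 90% of 50 replicates."""
        cfg = SimulationConfig.homogeneous(n=200, p=2000, support=(0, 1, 2))
        perfect = 0
        for s in range(50):
            ds = generate_dataset(cfg, seed=1000 + s)
            fit = sis_mcp_fit(ds.X, ds.y)
            if fit.support.tolist() == [0, 1, 2]:
                perfect += 1
        assert perfect >= 45

    def test_pure_noise_selects_almost_nothing(self):
        lean = 0
        for s in range(50):
            rng = np.random.default_rng(2000 + s)
            X = rng.standard_normal((100, 300))
            y = rng.standard_normal(100)
            if sis_mcp_fit(X, y).card <= 2:
                lean += 1
        assert lean >= 45

    def test_screened_set_contains_support(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((100, 50))
        y = X @ ([3.0] * 2 + [0.0] * 48) + 0.2 * rng.standard_normal(100)
        fit = sis_mcp_fit(X, y, d=10)
        assert set(fit.support) <= set(fit.screened_set)
        assert len(fit.screened_set) <= 10
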