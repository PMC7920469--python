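"""Path-entry statistics and the signed-max comparison of originals/knockoffs."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.linear_model import Lasso

from akoselect.knockoffs import build_knockoff_model, compute_s_vector, sample_knockoffs
from akoselect.statistics import (
    compute_statistics,
    lasso_entry_times,
    logistic_entry_times,
    signed_max_statistic,
)


def grid_lasso_entry_oracle(aug, y, n_alpha=2000):
    """Independent oracle: entry penalties from a fine-grid coordinate-descent
    lasso sweep (no least-angle path involved)."""
    n = aug.shape[0]
    yc = y - y.mean()
    alpha_max = np.max(np.abs(aug.T @ yc)) / n
    alphas = np.geomspace(alpha_max * 1.001, alpha_max * 1e-3, n_alpha)
    entry = np.zeros(aug.shape[1])
    model = Lasso(fit_intercept=False, warm_start=True, max_iter=50_000, tol=1e-10)
    for alpha in alphas:
        model.set_params(alpha=alpha)
        model.fit(aug, yc)
        newly = (np.abs(model.coef_) > 1e-8) & (entry == 0)
        entry[newly] = n * alpha
    return entry


class TestSignedMax:
    def test_worked_example(self):
        W = signed_max_statistic([3, 0, 1], [1, 2, 1])
        assert W == pytest.approx([3, -2, 0])

    def test_tied_entries_give_zero(self):
        Z = np.array([2.0, 0.0, 5.0])
        assert signed_max_statistic(Z, Z) == pytest.approx(np.zeros(3))

    def test_swapping_arguments_flips_sign_and_keeps_magnitude(self):
        rng = np.random.default_rng(0)
        Z, Zt = rng.random(20), rng.random(20)
        assert signed_max_statistic(Zt, Z) == pytest.approx(-signed_max_statistic(Z, Zt))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            signed_max_statistic([-1.0], [0.0])


class TestLassoEntries:
    def test_zero_outcome_has_empty_path(self):
        rng = np.random.default_rng(1)
        X, Xt = rng.standard_normal((30, 4)), rng.standard_normal((30, 4))
        Z, Zt, _ = lasso_entry_times(X, Xt, np.zeros(30))
        assert not Z.any() and not Zt.any()

    def test_first_entry_equals_max_inner_product(self):
        # closed form: the path starts at max_j |x_j' y|
        rng = np.random.default_rng(2)
        n = 100
        u = rng.standard_normal(n)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(n)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        y = 5 * u
        Z, Zt, _ = lasso_entry_times(u[:, None], v[:, None], y)
        yc = y - y.mean()
        assert Z[0] == pytest.approx(abs(u @ yc), rel=1e-8)
        assert Zt[0] < Z[0]

    def test_entries_match_fine_grid_coordinate_descent_oracle(self):
        rng = np.random.default_rng(3)
        n, p = 60, 5
        X, Xt = rng.standard_normal((n, p)), rng.standard_normal((n, p))
        beta = np.array([2.0, -1.5, 0.0, 0.0, 1.0])
        y = X @ beta + 0.3 * rng.standard_normal(n)
        Z, Zt, _ = lasso_entry_times(X, Xt, y)
        oracle = grid_lasso_entry_oracle(np.hstack([X, Xt]), y)
        exact = np.concatenate([Z, Zt])
        # agree within the oracle's own grid resolution (multiplicative step)
        step = (1e3) ** (1 / 1999)
        active = oracle > 0
        assert np.all(exact[active] <= oracle[active] * step * 1.01)
        assert np.all(exact[active] >= oracle[active] / step / 1.01)
        # variables the oracle's bounded grid never saw must have entered, if
        # at all, below the bottom of that grid
        yc = y - y.mean()
        grid_bottom = np.max(np.abs(np.hstack([X, Xt]).T @ yc)) * 1e-3
        assert np.all(exact[~active] <= grid_bottom * 1.01)

    def test_variable_order_permutation_permutes_entries(self):
        rng = np.random.default_rng(4)
        n, p = 40, 6
        X, Xt = rng.standard_normal((n, p)), rng.standard_normal((n, p))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.standard_normal(n)
        Z, Zt, _ = lasso_entry_times(X, Xt, y)
        perm = rng.permutation(p)
        Zp, Ztp, _ = lasso_entry_times(X[:, perm], Xt[:, perm], y)
        assert Zp == pytest.approx(Z[perm], rel=1e-9)
        assert Ztp == pytest.approx(Zt[perm], rel=1e-9)

    def test_constant_column_rejected_with_standardization_hint(self):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            lasso_entry_times(X, X, np.arange(20.0))


class TestLogisticEntries:
    def _toy(self, seed=0, n=120, p=3, effect=2.0):
        rng = np.random.default_rng(seed)
        X, Xt = rng.standard_normal((n, p)), rng.standard_normal((n, p))
        logits = effect * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        return X, Xt, y

    def test_all_coefficients_zero_at_path_start(self):
        X, Xt, y = self._toy()
        Z, Zt, grid = logistic_entry_times(X, Xt, y, n_grid=30)
        assert np.all(np.maximum(Z, Zt) < grid[0])

    def test_single_class_outcome_rejected(self):
        X, Xt, _ = self._toy()
        with pytest.raises(ValueError, match="single class"):
            logistic_entry_times(X, Xt, np.ones(X.shape[0]))

    def test_nonbinary_outcome_rejected(self):
        X, Xt, _ = self._toy()
        with pytest.raises(ValueError, match="binary"):
            logistic_entry_times(X, Xt, np.linspace(0, 2, X.shape[0]))

    def test_strong_effect_enters_before_its_knockoff_in_most_replicates(self):
        # a unit logistic effect at n = 400 should beat its knockoff's entry
        # in the clear majority of seeds (W_1 > 0)
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n, p = 400, 5
            X = rng.standard_normal((n, p))
            model = build_knockoff_model(np.eye(p), compute_s_vector(np.eye(p)))
            Xt = sample_knockoffs(X, model, 2000 + seed)
            y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
            Z, Zt, _ = logistic_entry_times(X, Xt, y, n_grid=40)
            wins += Z[0] > Zt[0]
        assert wins > n_seeds / 2

    def test_null_entry_values_exchangeable_between_originals_and_knockoffs(self):
        # pure-noise outcome: pooled Z and Z_tilde indistinguishable
        pooled_Z, pooled_Zt = [], []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            n, p = 200, 10
            X = rng.standard_normal((n, p))
            model = build_knockoff_model(np.eye(p), compute_s_vector(np.eye(p)))
            Xt = sample_knockoffs(X, model, 600 + seed)
            y = (rng.random(n) < 0.5).astype(float)
            Z, Zt, _ = logistic_entry_times(X, Xt, y, n_grid=30)
            pooled_Z.append(Z)
            pooled_Zt.append(Zt)
        stat = mannwhitneyu(np.concatenate(pooled_Z), np.concatenate(pooled_Zt))
        assert stat.pvalue > 0.01

    def test_grid_refinement_changes_entries_by_less_than_one_step(self):
        X, Xt, y = self._toy(seed=9)
        Z1, Zt1, grid1 = logistic_entry_times(X, Xt, y, n_grid=40)
        Z2, Zt2, _ = logistic_entry_times(X, Xt, y, n_grid=80)
        step = grid1[0] / grid1[1]  # multiplicative spacing of the coarse grid
        for coarse, fine in ((Z1, Z2), (Zt1, Zt2)):
            both = (coarse > 0) & (fine > 0)
            ratio = coarse[both] / fine[both]
            assert np.all((ratio <= step * 1.01) & (ratio >= 1 / (step * 1.01)))


class TestNullSignSymmetry:
    def test_null_variables_have_fair_coin_signs(self):
        # with a pure-noise outcome every variable is null, so among nonzero
        # W the positive fraction must be 1/2 up to binomial error
        signs = []
        for seed in range(40):
            rng = np.random.default_rng(3000 + seed)
            n, p = 100, 10
            X = rng.standard_normal((n, p))
            model = build_knockoff_model(np.eye(p), compute_s_vector(np.eye(p)))
            Xt = sample_knockoffs(X, model, 4000 + seed)
            y = rng.standard_normal(n)
            W = compute_statistics(X, Xt, y, loss="linear").W
            signs.extend(np.sign(W[W != 0]))
        signs = np.array(signs)
        frac_pos = (signs > 0).mean()
        se = 0.5 / np.sqrt(signs.size)
        assert abs(frac_pos - 0.5) < 4 * se


class TestComputeStatistics:
    def test_invariant_w_is_signed_max_of_entries(self):
        rng = np.random.default_rng(11)
        n, p = 50, 4
        X, Xt = rng.standard_normal((n, p)), rng.standard_normal((n, p))
        y = X[:, 1] + 0.2 * rng.standard_normal(n)
        stats = compute_statistics(X, Xt, y, loss="linear")
        assert np.abs(stats.W) == pytest.approx(np.maximum(stats.Z, stats.Z_tilde))
        assert np.sign(stats.W) == pytest.approx(np.sign(stats.Z - stats.Z_tilde))

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError, match="unknown loss"):
            compute_statistics(np.eye(3), np.eye(3) * 0.5, np.arange(3.0), loss="poisson")
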