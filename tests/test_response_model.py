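import numpy as np
import pytest
import statsmodels.api as sm

from tgmo import (
    TermSpace,
    build_model_matrix,
    compute_tw,
    cooks_distances,
    cooks_filter,
    model_diagnostics,
    stepwise_fit,
)
from tgmo.response_model import RegressionModel


def _fit_all_terms(X, y, space, **kwargs):
    return stepwise_fit(X, y, space, forced=space.terms[1:], **kwargs)


class TestComputeTw:
    @pytest.mark.parametrize(
        "normal, cancer, expected",
        [(79.1, 73.2, 5.9), (77.2, 63.7, 13.5), (64.2, 64.2, 0.0)],
    )
    def test_window_arithmetic(self, normal, cancer, expected):
        assert compute_tw(normal, cancer) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetric(self, rng):
        a, b = rng.uniform(0, 120, size=(2, 50))
        assert np.allclose(compute_tw(a, b), -compute_tw(b, a))


class TestBuildModelMatrix:
    @pytest.mark.parametrize("k, p", [(4, 15), (10, 66)])
    def test_column_count(self, k, p):
        from tgmo import generate_oacd

        X, space = build_model_matrix(generate_oacd(k, seed=0), replicates=1)
        assert X.shape[1] == p
        assert len(space.terms) == p

    def test_replicates_repeat_rows(self, k3_design):
        X1, _ = build_model_matrix(k3_design, replicates=1)
        X3, _ = build_model_matrix(k3_design, replicates=3)
        assert X3.shape[0] == 3 * X1.shape[0]
        assert np.allclose(X3[0::3], X1)

    def test_all_zero_run_has_zero_raw_terms(self):
        space = TermSpace(drug_order=("a", "b"), means=(0.0, 0.0))
        row = space.expand(np.zeros((1, 2)))
        assert row[0, 0] == 1.0
        assert np.allclose(row[0, 1:], 0.0)


class TestStepwiseFit:
    def test_noiseless_truth_recovered_exactly(self, k3_design):
        X, space = build_model_matrix(k3_design, replicates=2)
        beta_true = {("intercept", ()): 100.0, ("linear", (0,)): -10.0,
                     ("interaction", (0, 1)): -8.0}
        all_terms = space.terms
        beta = np.zeros(len(all_terms))
        for key, val in beta_true.items():
            beta[all_terms.index(key)] = val
        y = X @ beta
        model = stepwise_fit(X, y, space)
        assert set(model.term_keys) == set(beta_true)
        for term in model.terms:
            assert term.beta == pytest.approx(beta_true[term.key], abs=1e-8)

    def test_constant_response_gives_intercept_only(self, k3_design):
        X, space = build_model_matrix(k3_design, replicates=2)
        model = stepwise_fit(X, np.full(X.shape[0], 100.0), space)
        assert model.term_keys == [("intercept", ())]
        assert model.terms[0].beta == pytest.approx(100.0)

    def test_forced_full_model_equals_normal_equations(self, k3_design, rng):
        X, space = build_model_matrix(k3_design, replicates=2)
        y = rng.normal(80, 10, size=X.shape[0])
        model = _fit_all_terms(X, y, space)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        all_terms = space.terms
        fitted = np.zeros(len(all_terms))
        for t in model.terms:
            fitted[all_terms.index(t.key)] = t.beta
        assert np.max(np.abs(fitted - beta_ne)) < 1e-8

    def test_matches_independent_statsmodels_stepwise(self, rng):
        """Dual route: the fast QR-update selection must walk the same path
        as a naive statsmodels-based reimplementation on a small instance."""
        n = 40
        Z = rng.normal(size=(n, 5))
        X = np.column_stack([np.ones(n), Z])
        space = None  # bypass TermSpace: drive the low-level scan directly
        y = 5.0 + 2.0 * Z[:, 1] - 1.5 * Z[:, 3] + rng.normal(0, 1.0, n)

        # independent oracle
        p_enter, p_remove = 0.05, 0.10
        included = [0]
        while True:
            changed = False
            cands = [j for j in range(6) if j not in included]
            best, best_p = None, np.inf
            for j in cands:
                res = sm.OLS(y, X[:, included + [j]]).fit()
                pv = res.pvalues[-1]
                if pv < best_p:
                    best, best_p = j, pv
            if best is not None and best_p < p_enter:
                included.append(best)
                changed = True
            res = sm.OLS(y, X[:, included]).fit()
            worst_i, worst_p = None, -np.inf
            for pos, j in enumerate(included):
                if j == 0:
                    continue
                if res.pvalues[pos] > worst_p:
                    worst_i, worst_p = j, res.pvalues[pos]
            if worst_i is not None and worst_p > p_remove:
                included.remove(worst_i)
                changed = True
            if not changed:
                break
        oracle_set = set(included)

        # implementation under test, via a synthetic 5-drug linear-only space
        space = TermSpace(drug_order=tuple("abcde"), means=(0,) * 5)
        cols = {("intercept", ()): X[:, 0]}
        for i in range(5):
            cols[("linear", (i,))] = Z[:, i]
        Xfull = np.column_stack(
            [cols.get(t, np.zeros(n)) for t in space.terms]
        )
        model = stepwise_fit(Xfull, y, space, p_enter=p_enter, p_remove=p_remove)
        got = {0 if t.key[0] == "intercept" else t.key[1][0] + 1
               for t in model.terms}
        assert got == oracle_set

    def test_collinear_candidate_skipped(self, rng):
        space = TermSpace(drug_order=("a", "b"), means=(0.0, 0.0))
        n = 30
        x = rng.normal(size=n)
        # quadratic column duplicates the linear one: perfectly collinear
        X = np.column_stack([np.ones(n), x, 2 * x, np.zeros(n), np.zeros(n), np.zeros(n)])
        y = 3 * x + rng.normal(0, 0.5, n)
        model = stepwise_fit(X, y, space)
        assert len(model.terms) == 2  # intercept + one of the aliased pair


class TestCooksDistance:
    @pytest.fixture()
    def toy(self, rng):
        n, p = 12, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ np.array([10.0, 2.0, -1.0]) + rng.normal(0, 1, n)
        return X, y

    def test_matches_leave_one_out_brute_force(self, toy):
        X, y = toy
        D = cooks_distances(X, y)
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = float((y - X @ beta) @ (y - X @ beta)) / (n - p)
        xtx = X.T @ X
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            diff = beta - beta_i
            d_loo = float(diff @ xtx @ diff) / (p * s2)
            assert abs(D[i] - d_loo) < 1e-10

    def test_clean_data_flags_only_a_small_fraction_of_rows(self):
        """Cook's distances are right-skewed, so the 3x-mean rule usually
        flags a handful of rows even on clean data — but never many."""
        fractions = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(60), rng.normal(size=(60, 4))])
            y = X @ np.array([5.0, 1.0, 1.0, -2.0, 0.5]) + rng.normal(0, 1, 60)
            D = cooks_distances(X, y)
            fractions.append((D > 3 * D.mean()).mean())
        assert float(np.mean(fractions)) < 0.10
        assert max(fractions) < 0.25

    def test_planted_outlier_removed_and_refit(self, k3_design, rng):
        X, space = build_model_matrix(k3_design, replicates=2)
        all_terms = space.terms
        beta = np.zeros(len(all_terms))
        beta[all_terms.index(("intercept", ()))] = 90.0
        beta[all_terms.index(("linear", (0,)))] = -8.0
        y = X @ beta + rng.normal(0, 1.0, X.shape[0])
        y_bad = y.copy()
        y_bad[7] += 50.0
        model = stepwise_fit(X, y_bad, space)
        refit = cooks_filter(model, X, y_bad)
        assert 7 in [i for i, _ in refit.removed_points]
        lin = refit.get("linear", (0,))
        assert lin is not None and lin.beta == pytest.approx(-8.0, abs=1.0)

    def test_removal_aborts_when_too_few_rows_remain(self, rng):
        n = 6
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        space = TermSpace(drug_order=tuple("abcd"), means=(0,) * 4)
        Xfull = np.zeros((n, len(space.terms)))
        Xfull[:, :5] = X
        y = rng.normal(size=n)
        model = stepwise_fit(Xfull, y, space, forced=space.terms[1:5])
        result = cooks_filter(model, Xfull, y)
        assert result.removed_points == []


class TestModelDiagnostics:
    def test_noiseless_fit_is_exact(self, k3_design):
        X, space = build_model_matrix(k3_design, replicates=2)
        beta = np.zeros(len(space.terms))
        beta[0] = 100.0
        beta[1] = -5.0
        y = X @ beta
        model = stepwise_fit(X, y, space)
        d = model.diagnostics
        assert d.r2 == pytest.approx(1.0, abs=1e-10)
        assert d.rmse == pytest.approx(0.0, abs=1e-6)

    def test_fitted_observed_correlation_squares_to_r2(self, k3_design, rng):
        X, space = build_model_matrix(k3_design, replicates=2)
        beta = np.zeros(len(space.terms))
        beta[0], beta[1], beta[4] = 90.0, -6.0, 2.0
        y = X @ beta + rng.normal(0, 4, X.shape[0])
        model = stepwise_fit(X, y, space)
        d = model.diagnostics
        assert d.fitted_observed_r**2 == pytest.approx(d.r2, abs=1e-10)

    def test_agrees_with_statsmodels_on_the_full_fit(self, k3_design, rng):
        X, space = build_model_matrix(k3_design, replicates=2)
        y = rng.normal(75, 8, X.shape[0])
        model = _fit_all_terms(X, y, space)
        res = sm.OLS(y, X).fit()
        d = model.diagnostics
        assert d.r2 == pytest.approx(res.rsquared, abs=1e-10)
        assert d.adj_r2 == pytest.approx(res.rsquared_adj, abs=1e-10)
        assert d.anova_p == pytest.approx(res.f_pvalue, abs=1e-10)

    def test_zero_residual_df_flagged_unavailable(self, rng):
        space = TermSpace(drug_order=("a",), means=(0.0,))
        X = np.column_stack([np.ones(3), rng.normal(size=3), rng.normal(size=3)])
        y = rng.normal(size=3)
        model = stepwise_fit(X, y, space, forced=space.terms[1:])
        assert model.diagnostics.available is False


class TestParameterRecovery:
    def test_interaction_bias_shrinks_with_noise(self, k4_design):
        """Coefficient error decreases monotonically as plate noise drops."""
        X, space = build_model_matrix(k4_design, replicates=3)
        key = ("interaction", (0, 1))
        beta = np.zeros(len(space.terms))
        beta[0] = 100.0
        beta[space.terms.index(key)] = -10.0
        truth = X @ beta
        errors = []
        for sigma in (5.0, 2.0, 0.5, 0.0):
            errs = []
            for seed in range(40):
                rng = np.random.default_rng(1000 + seed)
                y = truth + (rng.normal(0, sigma, len(truth)) if sigma else 0.0)
                model = stepwise_fit(X, y, space)
                term = model.get(*key)
                errs.append(abs((term.beta if term else 0.0) - (-10.0)))
            errors.append(float(np.mean(errs)))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-8
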