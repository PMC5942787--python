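"""OLS fits, collinearity diagnostics and stepwise selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tpcorpus.corpus import load_beethoven_matrix
from tpcorpus.regression import (
    ProbabilityTrendModel,
    ScreenedOutError,
    SingularDesignError,
    StepwiseSettings,
    adj_r2_from_f,
    condition_indices,
    fit_ols,
    select_final,
    stepwise,
    vif,
)


class TestFitOLS:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        m = fit_ols(x.reshape(-1, 1), x)
        assert m.B[0] == pytest.approx(1.0)
        assert m.beta[0] == pytest.approx(1.0)
        assert m.R2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = fit_ols(X, y)
        design = np.column_stack([np.ones(10), X])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        assert m.intercept == pytest.approx(coef[0], abs=1e-8)
        assert m.B == pytest.approx(list(coef[1:]), abs=1e-8)

    def test_identities_hold(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25) + X[:, 0]
        m = fit_ols(X, y)
        n, k = m.n_obs, m.k
        assert m.adj_R2 == pytest.approx(
            1 - (1 - m.R2) * (n - 1) / (n - k - 1), abs=1e-10
        )
        assert m.F == pytest.approx(
            (m.R2 / k) / ((1 - m.R2) / (n - k - 1)), abs=1e-10
        )
        assert all(v >= 1 for v in m.VIF)
        assert m.CI == sorted(m.CI) and m.CI[0] >= 1

    def test_exact_collinearity_raises(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError):
            fit_ols(X, x)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_ols(np.ones((3, 2)), np.arange(3.0))

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20) + X @ np.array([1.0, -0.5, 0.2])
        base = fit_ols(X, y)
        c = 7.5
        X2 = X.copy()
        X2[:, 1] *= c
        scaled = fit_ols(X2, y)
        assert scaled.B[1] == pytest.approx(base.B[1] / c)
        assert scaled.beta == pytest.approx(base.beta)
        assert scaled.R2 == pytest.approx(base.R2)
        assert scaled.F == pytest.approx(base.F)
        assert scaled.VIF == pytest.approx(base.VIF)


class TestVIF:
    def test_orthogonal_columns(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        assert vif(X) == pytest.approx([1.0, 1.0])

    def test_closed_form_for_correlated_pair(self, rng):
        # build two columns with an exact sample correlation of 0.6
        r = 0.6
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        x2 = r * a + np.sqrt(1 - r**2) * b
        X = np.column_stack([a, x2])
        assert np.corrcoef(X.T)[0, 1] == pytest.approx(r, abs=1e-12)
        assert vif(X) == pytest.approx([1 / (1 - r**2)] * 2)  # 1.5625

    def test_single_column_is_exactly_one(self, rng):
        assert vif(rng.normal(size=(10, 1))) == pytest.approx([1.0])

    def test_exact_collinearity_gives_inf(self):
        x = np.arange(10.0)
        out = vif(np.column_stack([x, 2 * x]))
        assert np.isinf(out).all()


class TestConditionIndices:
    def test_duplicated_column_blows_up(self):
        x = np.arange(1, 11, dtype=float)
        ci = condition_indices(np.column_stack([x, x]))
        assert ci[-1] >= 1e6

    def test_smallest_index_is_one(self, rng):
        ci = condition_indices(rng.normal(size=(15, 2)))
        assert ci[0] == pytest.approx(1.0)
        assert len(ci) == 3

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        A = np.column_stack([np.ones(20), X])
        A = A / np.linalg.norm(A, axis=0)
        s = np.linalg.svd(A, compute_uv=False)
        expected = np.sort(s.max() / s)
        assert condition_indices(X) == pytest.approx(list(expected), abs=1e-8)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            condition_indices(np.zeros((10, 1)))


class TestStepwise:
    def test_single_strong_predictor_selected(self, rng):
        n = 32
        signal = rng.normal(size=n)
        noise = rng.normal(size=(n, 3))
        y = 2 * signal + rng.normal(scale=0.5, size=n)
        X = pd.DataFrame(
            np.column_stack([signal, noise]), columns=["sig", "n1", "n2", "n3"]
        )
        res = stepwise(X, y)
        assert "sig" in res.final.predictors

    def test_no_entry_gives_intercept_only(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.zeros(20)
        y[:10] = 1e-12  # essentially constant: nothing can enter
        res = stepwise(X, y)
        assert res.path == []
        assert res.final.predictors == []
        assert res.final.intercept == pytest.approx(y.mean())

    def test_path_models_grow_or_shrink_by_one(self):
        m = load_beethoven_matrix(2)
        res = stepwise(m.to_frame(), np.array(m.piece_index))
        sizes = [len(p.predictors) for p in res.path]
        assert all(abs(b - a) == 1 for a, b in zip([0] + sizes, sizes))

    def test_backward_removal_happens(self, rng):
        # x1 weakly proxies the signal; once x2 (the true signal) enters,
        # x1 should fall back out
        n = 40
        true = rng.normal(size=n)
        x1 = true + rng.normal(scale=1.5, size=n)
        y = true + rng.normal(scale=0.1, size=n)
        X = pd.DataFrame({"proxy": x1, "true": true})
        res = stepwise(X, y, StepwiseSettings(p_enter=0.05, p_remove=0.10))
        assert res.final.predictors == ["true"]

    def test_false_entry_rate_matches_permutation_oracle(self, rng):
        # with k independent noise candidates the chance stepwise admits
        # anything should match the permutation distribution of the
        # minimum partial p-value
        n, k, reps = 32, 5, 250
        hits = 0
        oracle_hits = 0
        import statsmodels.api as sm

        for _ in range(reps):
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            res = stepwise(X, y)
            hits += bool(res.final.predictors)
            yp = rng.permutation(y)
            pmin = min(
                sm.OLS(yp, sm.add_constant(X[:, [j]])).fit().pvalues[1]
                for j in range(k)
            )
            oracle_hits += pmin < 0.05
        assert abs(hits / reps - oracle_hits / reps) < 0.10


class TestSelectFinal:
    def test_largest_passing_model_adopted(self):
        m = load_beethoven_matrix(2)
        res = stepwise(m.to_frame(), np.array(m.piece_index))
        final = select_final(res, vif_limit=2.0, ci_limit=20.0)
        assert final.k == max(p.k for p in res.path)

    def test_ci_screen_falls_back_to_smaller_model(self):
        m = load_beethoven_matrix(2)
        res = stepwise(m.to_frame(), np.array(m.piece_index))
        largest_ci = max(max(p.CI) for p in res.path if p.k == 4)
        final = select_final(res, vif_limit=2.0, ci_limit=largest_ci - 0.01)
        assert final.k < 4

    def test_all_models_screened_out(self):
        m = load_beethoven_matrix(1)
        res = stepwise(m.to_frame(), np.array(m.piece_index))
        with pytest.raises(ScreenedOutError, match="CI"):
            select_final(res, vif_limit=2.0, ci_limit=1.0)

    def test_empty_path_rejected(self):
        m = load_beethoven_matrix(5)
        res = stepwise(m.to_frame(), np.array(m.piece_index))
        with pytest.raises(ValueError):
            select_final(res)


class TestImpliedAdjustedR2:
    @pytest.mark.parametrize(
        "F, k, df, expected",
        [
            (5.96, 2, 29, 0.24),
            (10.10, 4, 27, 0.54),
            (9.25, 2, 29, 0.35),
            (6.65, 1, 30, 0.15),
        ],
    )
    def test_f_implies_adjusted_r2(self, F, k, df, expected):
        assert adj_r2_from_f(F, k, df) == pytest.approx(expected, abs=0.005)


class TestModelResultsAPI:
    def test_summary_and_reports(self, tmp_path):
        res = ProbabilityTrendModel(load_beethoven_matrix(1)).fit()
        text = res.summary()
        assert "0,1" in text and "adj R2" in text
        res.to_report_csv(tmp_path / "m.csv")
        payload = res.to_json(tmp_path / "m.json")
        assert (tmp_path / "m.csv").exists()
        import json

        report = json.loads(payload)
        assert report["final"]["predictors"] == res.selected

    def test_from_dataframe_constructor(self):
        df = load_beethoven_matrix(3).to_frame()
        res = ProbabilityTrendModel.from_dataframe(df).fit()
        assert set(res.selected) == {"0,2,0,-1", "0,2,4,5"}
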