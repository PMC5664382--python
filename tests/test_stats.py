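"""Questionnaire scoring, OLS association, partial correlations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facecolor as fc


def _response(items, subject="s1", sex="female", age=40):
    return fc.QuestionnaireResponse(subject, tuple(items), sex, age)


class TestCps:
    @pytest.mark.parametrize("items, score", [
        ([4] * 8, 32),
        ([1] * 8, 8),
        ([1, 2, 3, 4, 1, 2, 3, 4], 20),
    ])
    def test_score_is_item_sum(self, items, score):
        assert fc.compute_cps(_response(items)).score == score

    def test_items_outside_scale_rejected(self):
        with pytest.raises(fc.DataError):
            _response([0, 2, 3, 4, 1, 2, 3, 4])
        with pytest.raises(fc.DataError):
            _response([5] * 8)

    def test_wrong_item_count_rejected(self):
        with pytest.raises(fc.DataError):
            _response([2] * 7)


class TestOlsFit:
    def test_exact_linear_relation_recovered(self):
        x = np.arange(20.0)
        res = fc.ols_fit(2.0 + 3.0 * x, pd.DataFrame({"x": x}))
        assert res.coefficients["x"] == pytest.approx(3.0)
        assert res.coefficients["intercept"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_null_coefficients_small_on_average(self):
        rng = np.random.default_rng(0)
        n, reps = 200, 200
        betas, r2 = [], []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = fc.ols_fit(y, pd.DataFrame({"x": x}))
            betas.append(res.coefficients["x"])
            r2.append(res.r_squared)
        assert abs(np.mean(betas)) < 0.02
        # E[R^2] under the null is p/(n-1)
        assert np.mean(r2) == pytest.approx(1.0 / (n - 1), abs=2e-3)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        res = fc.ols_fit(y, X)
        pred = (res.coefficients["intercept"]
                + X.to_numpy() @ np.array([res.coefficients[c] for c in "abc"]))
        resid = y - pred
        for c in "abc":
            assert abs(resid @ X[c].to_numpy()) < 1e-8

    def test_adjusted_r_squared_definition(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        y = X["u"].to_numpy() + rng.normal(size=40)
        res = fc.ols_fit(y, X)
        n, p = 40, 2
        expected = 1 - (1 - res.r_squared) * (n - 1) / (n - p - 1)
        assert res.adjusted_r_squared == pytest.approx(expected, abs=1e-12)

    def test_collinear_design_names_offenders(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.raises(fc.CollinearityError) as exc:
            fc.ols_fit(rng.normal(size=30), X)
        assert set(exc.value.columns) & {"x", "x2"}

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 1.0, 0.5]})
        with pytest.raises(fc.DataError):
            fc.ols_fit(np.array([1.0, 2.0, 3.0]), X)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = fc.partial_correlation(x, y)
        assert rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_perfect_dependence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        rho, p = fc.partial_correlation(x, x, z)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_two_step_residualization_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 6
            x, y = rng.normal(size=n), rng.normal(size=n)
            z = rng.normal(size=(n, 1))
            rho, _ = fc.partial_correlation(x, y, z)
            # independent oracle: explicit projection residuals
            Z1 = np.column_stack([np.ones(n), z])
            P = Z1 @ np.linalg.inv(Z1.T @ Z1) @ Z1.T
            rx, ry = x - P @ x, y - P @ y
            oracle = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
            assert rho == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=50), rng.normal(size=50)
        Z = rng.normal(size=(50, 2))
        rho, p = fc.partial_correlation(x, y, Z)
        df = pd.DataFrame({"x": x, "y": y, "z1": Z[:, 0], "z2": Z[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-12)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_symmetry_in_x_and_y(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        z = rng.normal(size=(15, 2))
        assert fc.partial_correlation(x, y, z) == fc.partial_correlation(y, x, z)

    def test_zero_residual_variance_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(fc.DataError):
            fc.partial_correlation(2.0 * z, np.random.default_rng(0).normal(size=10), z)


class TestRunAssociation:
    def test_planted_effect_detected(self):
        feats, q = fc.simulate_cohort(fc.CohortSpec(seed=12))
        reg, pc = fc.run_association(feats, q)
        row = reg[(reg.region == "whole_face") & (reg.term == "a_star")]
        assert float(row["B"].iloc[0]) < 0
        assert len(reg) == 7 * 6
        assert len(pc) == 7 * 3 * 8

    def test_planted_effect_power_over_seeds(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            feats, q = fc.simulate_cohort(fc.CohortSpec(seed=seed))
            reg, _ = fc.run_association(feats, q)
            row = reg[(reg.region == "whole_face") & (reg.term == "a_star")]
            if float(row["B"].iloc[0]) < 0 and bool(row["significant_05"].iloc[0]):
                hits += 1
        assert hits / reps >= 0.9

    def test_permuted_scores_rarely_significant(self):
        rng = np.random.default_rng(99)
        rates = []
        for seed in range(8):
            feats, q = fc.simulate_cohort(fc.CohortSpec(seed=seed + 500))
            q = q.copy()
            perm = rng.permutation(len(q))
            for col in [f"item{i}" for i in range(1, 9)]:
                q[col] = q[col].to_numpy()[perm]
            _, pc = fc.run_association(feats, q)
            rates.append(pc["significant_05"].mean())
        assert 0.0 <= np.mean(rates) < 0.12  # near the nominal 5% level

    def test_mismatched_subjects_reported(self):
        feats, q = fc.simulate_cohort(fc.CohortSpec(seed=1))
        with pytest.raises(fc.DataError, match="S001"):
            fc.run_association(feats, q[q.subject_id != "S001"])

    def test_single_subject_rejected(self):
        feats, q = fc.simulate_cohort(fc.CohortSpec(seed=1))
        one = feats[feats.subject_id == "S001"]
        with pytest.raises(fc.DataError):
            fc.run_association(one, q[q.subject_id == "S001"])

    def test_bh_adjustment_is_monotone_and_optional(self):
        feats, q = fc.simulate_cohort(fc.CohortSpec(seed=2))
        _, raw = fc.run_association(feats, q)
        _, adj = fc.run_association(feats, q, bh_adjust=True)
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-12).all()
        assert adj["significant_05"].sum() <= raw["significant_05"].sum()
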