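import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semload import (
    CorrelationResult,
    bicor,
    bicor_test,
    cohort_association,
    qc_batch_anova,
    qc_conversion_pearson,
    residualize,
    stouffer_meta,
)
from semload.assoc import pearson_p_from_r


def bicor_reference(x, y):
    """Independent literal transcription of the biweight midcorrelation
    formula: med/raw-MAD standardization, Tukey biweights zeroed at
    |u| >= 1, normalized cross-product."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2
        w[np.abs(u) >= 1] = 0
        return (v - med) * w

    xt, yt = transform(x), transform(y)
    return np.sum(xt * yt) / np.sqrt(np.sum(xt**2) * np.sum(yt**2))


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = pd.Series(rng.normal(10, 2, 50))
        cov = pd.DataFrame(index=y.index)
        resid = residualize(y, cov)
        assert np.allclose(resid, y - y.mean())

    def test_orthogonal_values_just_centered(self, rng):
        x = pd.Series(rng.normal(size=200))
        y = pd.Series(rng.normal(size=200))
        y_orth = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonal to x
        resid = residualize(pd.Series(y_orth), pd.DataFrame({"x": x}))
        assert np.allclose(resid, y_orth - y_orth.mean(), atol=1e-10)

    def test_removes_linear_age_effect(self, rng):
        age = pd.Series(rng.uniform(40, 90, 300))
        y = 2 * age + pd.Series(rng.normal(0, 1, 300))
        resid = residualize(y, pd.DataFrame({"age": age}))
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-12

    def test_categorical_expansion_orthogonality(self, rng):
        sex = pd.Series(rng.choice(["F", "M"], 200))
        y = pd.Series(rng.normal(size=200)) + (sex == "M") * 3
        resid = residualize(y, pd.DataFrame({"sex": sex}))
        assert abs(resid[sex == "M"].mean()) < 1e-10
        assert abs(resid[sex == "F"].mean()) < 1e-10

    def test_rank_deficiency_names_columns(self, rng):
        x = pd.Series(rng.normal(size=50))
        cov = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear.*x"):
            residualize(pd.Series(rng.normal(size=50)), cov)

    def test_single_level_categorical_dropped_with_warning(self, rng):
        cov = pd.DataFrame({"cohort": ["A"] * 30})
        y = pd.Series(rng.normal(size=30))
        with pytest.warns(UserWarning, match="single level"):
            resid = residualize(y, cov)
        assert np.allclose(resid, y - y.mean())

    def test_listwise_deletion_marks_nan(self, rng):
        y = pd.Series(rng.normal(size=20))
        cov = pd.DataFrame({"x": rng.normal(size=20)})
        cov.iloc[3, 0] = np.nan
        resid = residualize(y, cov)
        assert np.isnan(resid.iloc[3])
        assert resid.drop(resid.index[3]).notna().all()


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=40)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_positive_affine_equivariance(self, rng):
        x = rng.normal(size=40)
        assert bicor(x, 3.5 * x + 2.0) == pytest.approx(1.0)
        assert bicor(x, -2.0 * x + 1.0) == pytest.approx(-1.0)

    def test_matches_reference_formula_with_outlier(self):
        x = np.arange(1.0, 11.0)
        y = x.copy()
        y[9] = 100.0
        r = bicor(x, y)
        assert r == pytest.approx(bicor_reference(x, y), abs=1e-12)
        # Robustness: the outlier drags Pearson down much further.
        pearson = np.corrcoef(x, y)[0, 1]
        assert r > pearson

    def test_matches_reference_on_random_pairs(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = 0.4 * x + rng.normal(size=30)
            assert bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_zero_mad_falls_back_to_pearson_with_warning(self, rng):
        x = np.zeros(10)
        x[0] = 1.0  # median and MAD both 0
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="mean-centering"):
            r = bicor(x, y)
        assert np.isfinite(r)

    def test_pairwise_complete_filtering(self, rng):
        x = rng.normal(size=30)
        y = 0.9 * x + rng.normal(0, 0.1, 30)
        x_nan = x.copy()
        x_nan[5] = np.nan
        assert bicor(x_nan, y) == pytest.approx(
            bicor(np.delete(x, 5), np.delete(y, 5))
        )


class TestBicorTest:
    def test_zero_correlation_p_one(self):
        # A perfectly symmetric configuration: r is exactly 0.
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])
        res = bicor_test(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_t_transform_example(self, rng):
        # Construct any pair, then verify p equals the t-tail mapping of
        # the returned r at df = n - 2 (the stated oracle).
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        res = bicor_test(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=res.n - 2))

    def test_reference_t_value_for_half_correlation(self):
        # r = 0.5 at n = 12 gives t = 0.5*sqrt(10/0.75) = 1.8257
        t = 0.5 * np.sqrt((12 - 2) / (1 - 0.25))
        assert t == pytest.approx(1.8257, abs=1e-4)
        assert pearson_p_from_r(0.5, 12) == pytest.approx(
            2 * stats.t.sf(t, df=10), abs=1e-12
        )

    def test_larger_n_decreases_p_at_fixed_r(self):
        assert pearson_p_from_r(0.3, 100) < pearson_p_from_r(0.3, 20)

    def test_perfect_correlation_flagged(self, rng):
        x = rng.normal(size=10)
        res = bicor_test(x, 2 * x)
        assert res.p == 0.0
        assert res.flag == "perfect-correlation"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            bicor_test([1.0, 2, 3], [1.0, 2, 3])


class TestStoufferMeta:
    def test_all_zero_correlations(self):
        rows = [
            CorrelationResult("x", "y", 0.0, 1.0, 100, cohort=c) for c in "abcd"
        ]
        m = stouffer_meta(rows)
        assert m.meta_r == 0.0
        assert m.meta_p == pytest.approx(1.0)
        assert m.total_n == 400

    def test_single_cohort_p_preserved(self):
        p = pearson_p_from_r(0.3, 200)
        row = CorrelationResult("x", "y", 0.3, p, 200)
        # p-value deviates reproduce the cohort p exactly for one cohort;
        # the Fisher-z deviate (normal approximation of the correlation
        # test) agrees to within rounding.
        exact = stouffer_meta([row], deviates="p-value")
        assert exact.meta_p == pytest.approx(p, rel=1e-9)
        approx = stouffer_meta([row])
        assert approx.meta_p == pytest.approx(p, rel=0.25)
        assert approx.total_n == 200

    def test_order_invariance(self):
        rows = [
            CorrelationResult("x", "y", 0.2, 0.01, 150),
            CorrelationResult("x", "y", 0.1, 0.30, 80),
            CorrelationResult("x", "y", -0.05, 0.60, 40),
        ]
        a = stouffer_meta(rows)
        b = stouffer_meta(rows[::-1])
        assert a.meta_r == pytest.approx(b.meta_r)
        assert a.meta_p == pytest.approx(b.meta_p)

    def test_null_cohort_shrinks_z(self):
        rows = [CorrelationResult("x", "y", 0.25, 1e-4, 300)]
        with_null = rows + [CorrelationResult("x", "y", 0.0, 1.0, 300)]
        assert stouffer_meta(with_null).meta_p > stouffer_meta(rows).meta_p

    def test_back_transform_applies_tanh(self):
        rows = [CorrelationResult("x", "y", 0.9, 1e-10, 50)]
        a = stouffer_meta(rows)
        b = stouffer_meta(rows, back_transform=True)
        assert a.meta_r == pytest.approx(np.arctanh(0.9))
        assert b.meta_r == pytest.approx(0.9)

    def test_missing_n_rejected(self):
        df = pd.DataFrame({"r": [0.1], "p": [0.5], "n": [np.nan]})
        with pytest.raises(ValueError, match="sample size"):
            stouffer_meta(df)

    def test_accepts_dataframe_rows(self):
        df = pd.DataFrame(
            {"r": [0.2, 0.1], "p": [0.01, 0.2], "n": [100, 50], "cohort": ["a", "b"]}
        )
        m = stouffer_meta(df)
        assert m.total_n == 150


class TestCohortAssociation:
    def _cohort(self, rng, n=300, sex_effect=0.0):
        age = rng.uniform(40, 90, n)
        sex = rng.choice(["F", "M"], n)
        log_eml = 0.02 * age + sex_effect * (sex == "M") + rng.normal(0, 0.3, n)
        idx = pd.Index([f"s{i}" for i in range(n)])
        return (
            pd.Series(log_eml, index=idx, name="log_eml"),
            pd.DataFrame({"age": age}, index=idx),
            pd.DataFrame({"sex": pd.Series(sex, index=idx)}, index=idx),
            pd.Series(sex, index=idx),
        )

    def test_sex_strata_both_recover_positive_age_effect(self, rng):
        outcome, targets, cov, sex = self._cohort(rng)
        rows = cohort_association(outcome, targets, group_by=sex, cohort="sim")
        assert set(rows["stratum"]) == {"F", "M"}
        assert (rows["r"] > 0).all()
        assert (rows["p"] < 0.01).all()

    def test_sign_split_empty_stratum_flagged(self, rng):
        outcome, targets, _cov, _sex = self._cohort(rng, n=50)
        accel = pd.Series(1.0, index=outcome.index)  # all positive
        rows = cohort_association(outcome, targets, sign_split=accel)
        dec = rows[rows["stratum"] == "deceleration"]
        assert (dec["flag"] == "too-few-samples").all()
        assert dec["r"].isna().all()

    def test_sign_split_partitions_on_sign(self, rng):
        outcome, targets, _cov, _sex = self._cohort(rng)
        accel = pd.Series(rng.normal(size=len(outcome)), index=outcome.index)
        rows = cohort_association(outcome, targets, sign_split=accel)
        n_acc = rows.loc[rows["stratum"] == "acceleration", "n"].iloc[0]
        n_dec = rows.loc[rows["stratum"] == "deceleration", "n"].iloc[0]
        assert n_acc + n_dec == (accel != 0).sum()

    def test_quadratic_age_covariate_keeps_direction(self, rng):
        # Sensitivity parity: adding age^2 to the confounder set must not
        # flip the recovered direction of an acceleration effect.
        n = 400
        age = rng.uniform(40, 90, n)
        acc = rng.normal(0, 5, n)
        log_eml = 0.01 * age + 0.03 * acc + rng.normal(0, 0.2, n)
        idx = pd.Index([f"s{i}" for i in range(n)])
        outcome = pd.Series(log_eml, index=idx)
        targets = pd.DataFrame({"accel": acc}, index=idx)
        cov1 = pd.DataFrame({"age": age}, index=idx)
        cov2 = cov1.assign(age2=age**2)
        r1 = cohort_association(outcome, targets, covariates=cov1)["r"].iloc[0]
        r2 = cohort_association(outcome, targets, covariates=cov2)["r"].iloc[0]
        assert r1 > 0 and r2 > 0
        assert r1 == pytest.approx(r2, abs=0.05)


class TestQc:
    def test_batch_anova_power(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(5, 1, 60)  # 5 SD apart
        eml = pd.Series(np.concatenate([a, b]))
        batch = pd.Series(["x"] * 60 + ["y"] * 60)
        f, p = qc_batch_anova(eml, batch)
        assert p < 1e-6

    def test_batch_anova_null_matches_scipy(self, rng):
        eml = pd.Series(rng.normal(size=90))
        batch = pd.Series(rng.choice(["a", "b", "c"], 90))
        f, p = qc_batch_anova(eml, batch)
        groups = [eml[batch == g].to_numpy() for g in ["a", "b", "c"]]
        f2, p2 = stats.f_oneway(*groups)
        assert f == pytest.approx(f2) and p == pytest.approx(p2)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            qc_batch_anova(pd.Series([1.0, 2, 3]), pd.Series(["a", "a", "a"]))

    def test_one_observation_per_group_errors(self):
        with pytest.raises(ValueError, match="at least 2 observations"):
            qc_batch_anova(pd.Series([1.0, 2.0]), pd.Series(["a", "b"]))

    def test_conversion_pearson_self(self, rng):
        x = pd.Series(rng.normal(size=50))
        r, p = qc_conversion_pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_conversion_pearson_independent_near_zero(self, rng):
        x = pd.Series(rng.normal(size=1000))
        y = pd.Series(rng.normal(size=1000))
        r, _p = qc_conversion_pearson(x, y)
        assert abs(r) < 0.1

    def test_printed_r_to_p_consistency(self):
        # r = -0.085 at n = 237 maps to p ~ 0.19 through the t transform.
        assert pearson_p_from_r(-0.085, 237) == pytest.approx(0.19, abs=0.01)

    def test_constant_input_warns_nan(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            r, p = qc_conversion_pearson(
                pd.Series([1.0] * 10), pd.Series(rng.normal(size=10))
            )
        assert np.isnan(r)
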