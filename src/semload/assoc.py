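"""Covariate residualization, biweight midcorrelation, stratified
association scans, QC checks, and Stouffer/Fisher-z meta-analysis.

The association pattern is residualize-then-correlate: the outcome
(log EML or entropy) is regressed on the confounders (age, sex,
race/ethnicity, estimated cell fractions) and only its residuals are
correlated — robustly, by biweight midcorrelation — with the targets
(age, accelerations, cell fractions), which enter untouched.  Cohorts
are analyzed separately and combined with Stouffer's method: meta r is
the sample-size-weighted mean of Fisher-z transformed per-cohort
correlations, and meta p combines signed per-cohort normal deviates with
sqrt(n) weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    p: float
    n: int
    cohort: str = ""
    stratum: str = ""
    flag: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


@dataclass
class MetaResult:
    rows: list[CorrelationResult]
    meta_r: float
    meta_p: float
    total_n: int
    back_transformed: bool = False


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric columns + treatment-coded categoricals.

    Single-level categoricals are dropped with a warning; a
    rank-deficient design raises with the names of collinear columns.
    """
    cols: list[pd.Series] = []
    names: list[str] = ["intercept"]
    cols.append(pd.Series(1.0, index=covariates.index))
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
            names.append(name)
        else:
            levels = pd.unique(col.astype(str))
            if len(levels) < 2:
                warnings.warn(
                    f"covariate {name!r} has a single level; dropped", stacklevel=3
                )
                continue
            ref, *rest = sorted(levels)
            for lev in rest:
                cols.append((col.astype(str) == lev).astype(float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack([c.to_numpy() for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Name the columns whose removal restores full rank.
        collinear = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return X, names


def residualize(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of ``values`` on the covariate design (intercept
    included; categoricals expanded to indicators).  Rows with any
    missing field are dropped (listwise deletion) and returned as NaN.
    Residuals are orthogonal to every design column."""
    values, covariates = values.align(covariates, join="inner", axis=0)
    ok = values.notna() & covariates.notna().all(axis=1)
    X, _ = _design_matrix(covariates[ok])
    y = values[ok].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = pd.Series(np.nan, index=values.index, name=values.name)
    out[ok] = y - X @ coef
    return out


def _biweight_transform(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight centered values x~ = (x - med) * w, with
    w = (1 - u^2)^2 for |u| < 1, u = (x - med) / (9 * mad); raw MAD, no
    consistency factor.  Falls back to plain mean-centering when the MAD
    is zero."""
    m = np.median(x)
    d = np.median(np.abs(x - m))
    if d == 0:
        warnings.warn(
            "median absolute deviation is zero; falling back to "
            "mean-centering with unit weights for this vector",
            stacklevel=3,
        )
        return x - np.mean(x)
    u = (x - m) / (9.0 * d)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - m) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors
    (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    xt = _biweight_transform(x)
    yt = _biweight_transform(y)
    denom = np.sqrt(np.sum(xt**2)) * np.sqrt(np.sum(yt**2))
    if denom == 0:
        warnings.warn("zero denominator after weighting; r undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(xt * yt) / denom)


def bicor_test(
    x,
    y,
    variable_x: str = "x",
    variable_y: str = "y",
    cohort: str = "",
) -> CorrelationResult:
    """bicor with a two-sided p-value from the Student-t transform
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 4:
        raise ValueError("need at least 4 complete pairs for a p-value")
    r = bicor(x[ok], y[ok])
    flag = ""
    if not np.isfinite(r):
        return CorrelationResult(variable_x, variable_y, np.nan, np.nan, n, cohort, flag="degenerate")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p, flag = 0.0, "perfect-correlation"
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(variable_x, variable_y, r, p, n, cohort, flag=flag)


def cohort_association(
    outcome: pd.Series,
    targets: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    group_by: pd.Series | None = None,
    sign_split: pd.Series | None = None,
    cohort: str = "",
    outcome_name: str | None = None,
) -> pd.DataFrame:
    """Residualize the outcome on the covariates, then bicor it against
    every target column, optionally within strata.

    ``group_by`` yields one stratum per level (e.g. sex).  ``sign_split``
    splits on the sign of an acceleration column: the "acceleration"
    stratum keeps samples with positive values, "deceleration" negative;
    zeros are excluded.  Strata with fewer than 4 complete pairs produce
    rows with missing r/p and a size flag.  Returns one row per
    (target, stratum).
    """
    outcome_name = outcome_name or (outcome.name or "outcome")
    strata: list[tuple[str, pd.Index]] = []
    if group_by is not None:
        for level in pd.unique(group_by.dropna()):
            strata.append((str(level), group_by.index[group_by == level]))
    elif sign_split is not None:
        strata.append(("acceleration", sign_split.index[sign_split > 0]))
        strata.append(("deceleration", sign_split.index[sign_split < 0]))
    else:
        strata.append(("", outcome.index))

    rows = []
    for label, idx in strata:
        idx = outcome.index.intersection(idx)
        y = outcome.loc[idx]
        if covariates is not None:
            cov = covariates.loc[idx]
            if len(idx) >= cov.shape[1] + 2 and len(idx) >= 4:
                y = residualize(y, cov)
        for target in targets.columns:
            x = targets[target].reindex(idx)
            ok = x.notna() & y.notna()
            if ok.sum() < 4:
                rows.append(
                    {
                        "cohort": cohort,
                        "variable_x": target,
                        "variable_y": outcome_name,
                        "stratum": label,
                        "r": np.nan,
                        "p": np.nan,
                        "n": int(ok.sum()),
                        "flag": "too-few-samples",
                    }
                )
                continue
            res = bicor_test(x[ok], y[ok], target, outcome_name, cohort)
            rows.append(
                {
                    "cohort": cohort,
                    "variable_x": target,
                    "variable_y": outcome_name,
                    "stratum": label,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)


def stouffer_meta(
    rows: list[CorrelationResult] | pd.DataFrame,
    back_transform: bool = False,
    deviates: str = "fisher-z",
) -> MetaResult:
    """Combine per-cohort correlations with Stouffer's method.

    meta r = sum(n_i * atanh(r_i)) / sum(n_i), reported on the Fisher-z
    scale by default (``back_transform=True`` applies tanh).  meta p
    comes from Z = sum(sqrt(n_i) * s_i) / sqrt(sum(n_i)) mapped back to
    a two-sided probability, where s_i is the cohort's standard-normal
    deviate: with ``deviates="fisher-z"`` (default) it is the normal
    score of the correlation itself, atanh(r_i) * sqrt(n_i - 3); with
    ``deviates="p-value"`` it is the signed normal quantile of the
    cohort's two-sided p with the sign of r_i.
    """
    if isinstance(rows, pd.DataFrame):
        if rows["n"].isna().any():
            raise ValueError("every cohort row needs a positive sample size n")
        rows = [
            CorrelationResult(
                variable_x=str(r.get("variable_x", "x")),
                variable_y=str(r.get("variable_y", "y")),
                r=float(r["r"]),
                p=float(r["p"]),
                n=int(r["n"]),
                cohort=str(r.get("cohort", "")),
            )
            for _, r in rows.iterrows()
        ]
    if not rows:
        raise ValueError("no cohort rows to combine")
    n = np.array([row.n for row in rows], dtype=float)
    if np.any(~np.isfinite(n)) or np.any(n <= 0):
        raise ValueError("every cohort row needs a positive sample size n")
    r = np.array([row.r for row in rows], dtype=float)
    p = np.array([row.p for row in rows], dtype=float)
    z = np.arctanh(r)
    meta_r = float(np.sum(n * z) / np.sum(n))
    if back_transform:
        meta_r = float(np.tanh(meta_r))
    if deviates == "fisher-z":
        with np.errstate(divide="ignore"):
            s = z * np.sqrt(np.maximum(n - 3.0, 0.0))
    elif deviates == "p-value":
        s = np.sign(r) * stats.norm.isf(np.clip(p, 0.0, 1.0) / 2.0)
    else:
        raise ValueError(f"unknown deviates option {deviates!r}")
    Z = np.sum(np.sqrt(n) * s) / np.sqrt(np.sum(n))
    meta_p = float(2.0 * stats.norm.sf(abs(Z)))
    return MetaResult(
        rows=list(rows),
        meta_r=meta_r,
        meta_p=meta_p,
        total_n=int(np.sum(n)),
        back_transformed=back_transform,
    )


def qc_batch_anova(log_eml: pd.Series, batch: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of log EML across batch labels
    (microarray slide or array position); returns (F, p)."""
    log_eml, batch = log_eml.align(batch, join="inner")
    ok = log_eml.notna() & batch.notna()
    groups = [
        g.to_numpy(dtype=float)
        for _, g in log_eml[ok].groupby(batch[ok].astype(str))
    ]
    if len(groups) < 2:
        raise ValueError("batch ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every batch group needs at least 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def qc_conversion_pearson(
    log_eml: pd.Series, control_intensity: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (with t-based two-sided p) between log EML and
    the average bisulfite-conversion control intensity."""
    log_eml, control_intensity = log_eml.align(control_intensity, join="inner")
    ok = log_eml.notna() & control_intensity.notna()
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete pairs")
    x = log_eml[ok].to_numpy(dtype=float)
    y = control_intensity[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Pearson r undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson/bicor coefficient via the Student-t
    transform; used to sanity-check printed (r, n, p) triples."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
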