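"""Linear epigenetic clocks and residual age acceleration.

A clock is a linear model: DNAm age = intercept + sum_j w_j * beta_j over
a fixed CpG set, optionally followed by a user-supplied post-transform.
Epigenetic age acceleration is the residual of the ordinary
least-squares regression of DNAm age on chronological age, fit within
the cohort being analyzed; by construction the residuals have mean zero
and zero correlation with chronological age.  Published clock
coefficient sets are not bundled — the module reads user-supplied
coefficient files or accepts precomputed DNAm-age columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass
class ClockModel:
    name: str
    intercept: float
    coefficients: pd.Series  # indexed by probe id
    post_transform: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise ValueError(f"clock {self.name!r} has duplicate probe ids")


def read_clock(path, name: str | None = None) -> ClockModel:
    """Read a two-column clock CSV (probe_id, weight) with a leading
    ``#intercept=<float>`` header line."""
    intercept = 0.0
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#intercept="):
            intercept = float(first.split("=", 1)[1])
            coef = pd.read_csv(fh)
        else:
            fh.seek(0)
            coef = pd.read_csv(fh)
    if coef.shape[1] < 2:
        raise ValueError("clock file needs probe_id and weight columns")
    s = pd.Series(
        coef.iloc[:, 1].astype(float).to_numpy(),
        index=coef.iloc[:, 0].astype(str),
    )
    return ClockModel(
        name=name or str(path), intercept=intercept, coefficients=s
    )


def write_clock(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept={clock.intercept!r}\n")
        fh.write("probe_id,weight\n")
        for pid, w in clock.coefficients.items():
            fh.write(f"{pid},{w!r}\n")


def apply_linear_clock(
    beta, clock: ClockModel, missing_policy: str = "error"
) -> pd.Series:
    """Evaluate a linear clock on every sample.

    ``missing_policy`` controls clock CpGs absent from the matrix:
    ``"error"`` refuses, ``"mean-impute"`` fills an absent probe with the
    mean of the present clock probes per sample.  More than 20% of clock
    probes absent is always an error.
    """
    present = clock.coefficients.index.intersection(beta.probe_ids)
    absent = clock.coefficients.index.difference(beta.probe_ids)
    frac_absent = len(absent) / len(clock.coefficients)
    if frac_absent > 0.20:
        raise ValueError(
            f"clock {clock.name!r}: {len(absent)} of {len(clock.coefficients)} "
            f"probes absent from the matrix, e.g. {absent[:5].tolist()}"
        )
    if len(absent) and missing_policy == "error":
        raise ValueError(
            f"clock {clock.name!r}: missing probes {absent[:5].tolist()} "
            "(set missing_policy='mean-impute' to proceed)"
        )
    sub = beta.values.loc[present]
    w = clock.coefficients.loc[present]
    ages = clock.intercept + sub.mul(w, axis=0).sum(axis=0, skipna=True)
    if len(absent) and missing_policy == "mean-impute":
        ages = ages + sub.mean(axis=0) * clock.coefficients.loc[absent].sum()
    if clock.post_transform is not None:
        ages = pd.Series(clock.post_transform(ages.to_numpy()), index=ages.index)
    ages.name = clock.name
    return ages


def age_acceleration(dnam_age: pd.Series, chrono_age: pd.Series) -> pd.Series:
    """Residuals of OLS of DNAm age on chronological age (with intercept).

    Residuals have mean zero and exactly zero sample correlation with
    chronological age; samples missing either value get NaN.
    """
    dnam_age, chrono_age = dnam_age.align(chrono_age, join="inner")
    ok = dnam_age.notna() & chrono_age.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete samples")
    x = chrono_age[ok].to_numpy(dtype=float)
    y = dnam_age[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; residuals undefined")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    out = pd.Series(np.nan, index=dnam_age.index, name="accel")
    out[ok] = resid
    return out


def accel_table(
    chrono_age: pd.Series, dnam_ages: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample chronological age, DNAm ages, and one acceleration
    column (``accel_<measure>``) per DNAm-age column."""
    out = pd.DataFrame({"age": chrono_age})
    for col in dnam_ages.columns:
        out[col] = dnam_ages[col]
        out[f"accel_{col}"] = age_acceleration(dnam_ages[col], chrono_age)
    out.index.name = "sample_id"
    return out


def measure_correlation_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations (pairwise-complete); symmetric with
    unit diagonal.  Constant columns yield missing entries."""
    corr = measures.corr(method="pearson", min_periods=3)
    for col in measures.columns:
        x = measures[col].dropna()
        if len(x) and np.ptp(x.to_numpy(dtype=float)) == 0:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
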