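"""SEM calling by interquartile-range fences and epigenetic mutation load.

A stochastic epigenetic mutation (SEM) is a sample whose beta value at a
CpG lies strictly beyond Q1 - k*IQR or Q3 + k*IQR of the cohort
distribution at that CpG (default k = 3; k = 2 "loose", k = 4
"stringent").  The epigenetic mutation load (EML) of a person is their
total SEM count, analyzed on the natural-log scale.  Fences are
cohort-specific: quantiles are estimated across all non-missing samples
of the matrix being processed, including the evaluated sample itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

DIRECTIONS = ("hypo", "hyper")

MIN_NONMISSING = 4  # fewer values than this and a probe's fences are unusable


@dataclass
class FenceTable:
    """Per-probe quartiles and outlier fences.

    ``table`` is indexed by probe id with columns q1, q3, iqr,
    lower_fence, upper_fence, n_used, usable.
    """

    table: pd.DataFrame
    k: float
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        t = self.table
        ok = t["usable"]
        if (t.loc[ok, "iqr"] < 0).any():
            raise ValueError("negative IQR in fence table")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class SemCallSet:
    """Sparse set of SEM calls plus the fences that produced them.

    ``calls`` has one row per (sample_id, probe_id) with columns
    direction, beta, lower_fence, upper_fence.  ``sample_ids`` and
    ``probe_ids`` record the full universe so zero-count samples and
    never-mutated probes are representable.
    """

    calls: pd.DataFrame
    fences: FenceTable
    k: float
    sample_ids: pd.Index
    probe_ids: pd.Index

    def __post_init__(self) -> None:
        pairs = self.calls[["sample_id", "probe_id"]]
        if pairs.duplicated().any():
            raise ValueError("a (sample, probe) pair carries more than one call")

    def __len__(self) -> int:
        return len(self.calls)


def compute_fences(
    beta,
    k: float = 3.0,
    quantile_method: str = "linear",
) -> FenceTable:
    """Per-probe Q1/Q3/IQR and fences at multiplier ``k``.

    Quantiles are computed across non-missing samples with linear
    interpolation between order statistics by default (numpy's
    ``method`` vocabulary is accepted for sensitivity analyses, since
    call counts depend on the quantile rule).  Probes with fewer than
    four non-missing values are flagged unusable and excluded from
    calling, with a warning.
    """
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")
    values = beta.values.to_numpy(dtype=float)
    nan_mask = np.isnan(values)
    n_used = np.sum(~nan_mask, axis=1)
    if nan_mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            q1, q3 = np.nanquantile(
                values, [0.25, 0.75], axis=1, method=quantile_method
            )
    else:
        q1, q3 = np.quantile(values, [0.25, 0.75], axis=1, method=quantile_method)
    iqr = q3 - q1
    usable = n_used >= MIN_NONMISSING
    n_bad = int((~usable).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} probes have < {MIN_NONMISSING} non-missing values; "
            "their fences are unusable and they are excluded from calling",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower_fence": q1 - k * iqr,
            "upper_fence": q3 + k * iqr,
            "n_used": n_used,
            "usable": usable,
        },
        index=beta.values.index,
    )
    return FenceTable(table=table, k=k, quantile_method=quantile_method)


def call_sems(beta, fences: FenceTable) -> SemCallSet:
    """Call SEMs: strictly below the lower fence (hypo) or strictly above
    the upper fence (hyper).  Values exactly on a fence are not called;
    missing values are never called."""
    missing = beta.probe_ids.difference(fences.probe_ids)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes in the beta matrix have no fences, "
            f"e.g. {missing[:5].tolist()}"
        )
    ft = fences.table.loc[beta.probe_ids]
    values = beta.values.to_numpy(dtype=float)
    usable = ft["usable"].to_numpy()
    lower = ft["lower_fence"].to_numpy()[:, None]
    upper = ft["upper_fence"].to_numpy()[:, None]
    with np.errstate(invalid="ignore"):
        hypo = (values < lower) & usable[:, None]
        hyper = (values > upper) & usable[:, None]
    pi, si = np.nonzero(hypo | hyper)
    direction = np.where(hyper[pi, si], "hyper", "hypo")
    calls = pd.DataFrame(
        {
            "sample_id": beta.sample_ids[si],
            "probe_id": beta.probe_ids[pi],
            "direction": direction,
            "beta": values[pi, si],
            "lower_fence": ft["lower_fence"].to_numpy()[pi],
            "upper_fence": ft["upper_fence"].to_numpy()[pi],
        }
    )
    return SemCallSet(
        calls=calls,
        fences=fences,
        k=fences.k,
        sample_ids=beta.sample_ids,
        probe_ids=beta.probe_ids,
    )


def compute_eml(
    calls: SemCallSet,
    subset: Iterable[str] | None = None,
    direction: str | None = None,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-sample SEM counts and their natural logs.

    ``subset`` restricts counting to a probe set; ``direction`` to hypo or
    hyper calls.  ``log_eml`` is ln(count) for positive counts.  For zero
    counts it is NaN unless ``pseudocount`` is given, in which case
    ln(count + pseudocount) is used for the zero-count samples as well.
    """
    df = calls.calls
    if direction is not None:
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        df = df[df["direction"] == direction]
    if subset is not None:
        subset = set(map(str, subset))
        extra = subset - set(calls.probe_ids)
        if extra:
            raise ValueError(f"subset contains {len(extra)} probes outside the universe")
        df = df[df["probe_id"].isin(subset)]
    counts = (
        df.groupby("sample_id").size().reindex(calls.sample_ids, fill_value=0)
    )
    eml = counts.astype(int)
    if pseudocount is None:
        log_eml = np.where(eml > 0, np.log(np.maximum(eml, 1)), np.nan)
    else:
        log_eml = np.log(eml + pseudocount * (eml == 0))
    out = pd.DataFrame({"eml": eml, "log_eml": log_eml}, index=calls.sample_ids)
    out.index.name = "sample_id"
    return out


def _membership_columns(annot: pd.DataFrame) -> dict[str, pd.Index]:
    """Expand set-valued annotation columns into named probe subsets."""
    subsets: dict[str, set] = {}
    for probe, row in annot.iterrows():
        for g in row.get("gene_region_groups", frozenset()):
            subsets.setdefault(f"region:{g}", set()).add(probe)
        for f in row.get("regulatory_features", frozenset()):
            subsets.setdefault(f"regulatory:{f}", set()).add(probe)
        ic = row.get("island_context")
        if isinstance(ic, str) and ic:
            subsets.setdefault(f"island:{ic}", set()).add(probe)
        for c in row.get("clock_memberships", frozenset()):
            subsets.setdefault(f"clock:{c}", set()).add(probe)
    return {k: pd.Index(sorted(v)) for k, v in subsets.items()}


def region_emls(calls: SemCallSet, annot: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SEM counts within each gene-region group, regulatory
    feature, island context, and clock membership, plus per-direction
    totals.

    A call on a probe annotated to several region groups increments each
    group once.  Columns are ``region:TSS200``-style names; ``total``,
    ``hyper`` and ``hypo`` columns are always present.
    """
    df = calls.calls
    out = pd.DataFrame(index=calls.sample_ids)
    out.index.name = "sample_id"
    out["total"] = df.groupby("sample_id").size().reindex(calls.sample_ids, fill_value=0)
    for d in DIRECTIONS:
        out[d] = (
            df[df["direction"] == d]
            .groupby("sample_id")
            .size()
            .reindex(calls.sample_ids, fill_value=0)
        )
    for name, probes in _membership_columns(annot).items():
        sub = df[df["probe_id"].isin(set(probes))]
        out[name] = sub.groupby("sample_id").size().reindex(calls.sample_ids, fill_value=0)
    return out.astype(int)


def recurrent_sems(calls: SemCallSet, min_participants: int = 10) -> pd.DataFrame:
    """Consistently-mutated CpGs: (probe, direction) pairs mutated in the
    same direction in strictly more than ``min_participants`` people."""
    counts = (
        calls.calls.groupby(["probe_id", "direction"], observed=True)
        .size()
        .rename("n_carriers")
        .reset_index()
    )
    out = counts[counts["n_carriers"] > min_participants].reset_index(drop=True)
    return out.sort_values(["n_carriers", "probe_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def island_direction_crosstab(calls: SemCallSet, annot: pd.DataFrame) -> pd.DataFrame:
    """Counts of hypo/hyper calls by island context (Island/Shore/Shelf/
    OpenSea), for checking where each direction concentrates."""
    ctx = annot["island_context"].reindex(calls.probe_ids)
    df = calls.calls.copy()
    df["island_context"] = ctx.loc[df["probe_id"]].to_numpy()
    return pd.crosstab(df["direction"], df["island_context"])
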