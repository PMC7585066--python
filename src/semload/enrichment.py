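"""Per-participant hypergeometric enrichment of SEMs in probe sets.

For each participant and each probe set (genomic region, regulatory
feature, clock-CpG set, or gene-expanded pathway) the test asks: of the
participant's n SEM probes drawn from the N-probe universe, are the k
landing in the K-probe set more than chance allows?  p = P(X >= k) for X
hypergeometric(N, K, n), upper tail only (over-representation).  A
pathway's per-person significance indicator then feeds a linear model of
age acceleration on the indicator, adjusted for total log EML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProbeSetCollection:
    """Named probe sets over a common universe; every set is clipped to
    the universe."""

    sets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.universe = frozenset(map(str, self.universe))
        clipped = {}
        for name, probes in self.sets.items():
            probes = frozenset(map(str, probes)) & self.universe
            if not probes:
                warnings.warn(f"probe set {name!r} is empty after clipping to "
                              "the universe; dropped", stacklevel=2)
                continue
            clipped[name] = probes
        self.sets = clipped

    def __len__(self) -> int:
        return len(self.sets)


def sample_enrichment(
    calls, sets: ProbeSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation test per (sample, set).

    Returns rows with k (SEMs in set), n (sample's SEMs in the
    universe), K (set size), N (universe size), the upper-tail p, and a
    significance indicator at ``alpha``.  SEM probes outside the
    universe are dropped (count logged in the ``n_dropped`` column).
    """
    N = len(sets.universe)
    by_sample = {
        sid: set(g["probe_id"])
        for sid, g in calls.calls.groupby("sample_id", observed=True)
    }
    rows = []
    for sid in calls.sample_ids:
        probes = by_sample.get(sid, set())
        in_universe = probes & sets.universe
        n_dropped = len(probes) - len(in_universe)
        n = len(in_universe)
        for name, members in sets.sets.items():
            K = len(members)
            k = len(in_universe & members)
            if n == 0:
                p, flag = 1.0, "no-draws"
            else:
                p = float(stats.hypergeom.sf(k - 1, N, K, n))
                flag = ""
            rows.append(
                {
                    "sample_id": sid,
                    "set_name": name,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": p,
                    "significant": bool(p < alpha),
                    "n_dropped": n_dropped,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def enrichment_prevalence(results: pd.DataFrame) -> pd.DataFrame:
    """Per-set count and fraction of participants whose enrichment test
    is significant."""
    grouped = results.groupby("set_name", observed=True)
    n_sig = grouped["significant"].sum().astype(int)
    n_tested = grouped.size()
    out = pd.DataFrame(
        {
            "n_significant": n_sig,
            "n_tested": n_tested,
            "fraction_significant": n_sig / n_tested,
        }
    )
    return out.sort_values("n_significant", ascending=False)


def indicator_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot enrichment rows into a samples x sets 0/1 indicator."""
    return (
        results.pivot(index="sample_id", columns="set_name", values="significant")
        .fillna(False)
        .astype(int)
    )


def pathway_association(
    accel: pd.Series,
    enrich_indicator: pd.DataFrame,
    log_total_eml: pd.Series,
    accel_name: str | None = None,
) -> pd.DataFrame:
    """Per pathway: OLS of acceleration on the enrichment indicator,
    adjusted for total log EML.

    Model: AgeAccel = b0 + b1*Enrich + b2*log(EML) + e; reports b1, its
    two-sided p, b2, and n.  A constant indicator is inestimable and
    flagged.
    """
    accel_name = accel_name or (accel.name or "accel")
    rows = []
    for pathway in enrich_indicator.columns:
        ind = enrich_indicator[pathway]
        df = pd.DataFrame(
            {"accel": accel, "ind": ind, "log_eml": log_total_eml}
        ).dropna()
        n = len(df)
        if n < 4 or df["ind"].nunique() < 2:
            rows.append(
                {
                    "pathway": pathway,
                    "measure": accel_name,
                    "beta1": np.nan,
                    "p_beta1": np.nan,
                    "beta2": np.nan,
                    "n": n,
                    "flag": "inestimable",
                }
            )
            continue
        X = np.column_stack(
            [np.ones(n), df["ind"].to_numpy(float), df["log_eml"].to_numpy(float)]
        )
        y = df["accel"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se1 = np.sqrt(cov[1, 1])
        t1 = coef[1] / se1
        p1 = float(2.0 * stats.t.sf(abs(t1), df=dof))
        rows.append(
            {
                "pathway": pathway,
                "measure": accel_name,
                "beta1": float(coef[1]),
                "p_beta1": p1,
                "beta2": float(coef[2]),
                "n": n,
                "flag": "",
            }
        )
    return pd.DataFrame(rows)


def gene_sets_to_probe_sets(
    gene_sets: Mapping[str, list],
    annot: pd.DataFrame,
    universe: frozenset | set,
) -> ProbeSetCollection:
    """Expand gene-level sets to probe-level sets.

    ``annot`` must carry a ``genes`` column of per-probe gene-symbol
    sets (as produced by :func:`semload.ingest.read_annotation`); a
    probe joins every set containing any of its annotated genes.
    """
    gene_to_probes: dict[str, set] = {}
    for probe, genes in annot["genes"].items():
        for g in genes:
            gene_to_probes.setdefault(g, set()).add(str(probe))
    sets = {}
    for name, genes in gene_sets.items():
        probes: set = set()
        for g in genes:
            probes |= gene_to_probes.get(g, set())
        sets[name] = frozenset(probes)
    return ProbeSetCollection(sets=sets, universe=frozenset(universe))


def read_gmt(path) -> dict[str, list]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
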