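"""Reading and validation of beta matrices, sample metadata, and probe
annotation, plus standard probe-level quality filters.

The beta matrix is the central container: a probes x samples table of
methylation fractions in [0, 1].  Missing values are permitted (NaN) and
are carried through; downstream operations decide per-probe how to handle
them.  Probe filtering removes the union of probes failing a detection
p-value rule, a bead-count rule, or appearing on user-supplied exclusion
lists (sex chromosomes, SNP overlap, cross-reactive probes), and reports
per-rule counts so that the arithmetic retained + unique-removed = input
always closes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CELL_TYPES = ("cd8_naive", "cd8pcd28ncd45ran", "plasmablast", "cd4t", "gran")

ISLAND_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")

GENE_REGION_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

REGULATORY_FEATURES = ("Enhancer", "DHS", "OpenChromatin", "TFBS", "Promoter")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions.

    ``values`` is a DataFrame indexed by probe id with sample ids as
    columns.  Every non-missing value lies in [0, 1]; identifiers are
    unique on both axes.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        keep = self.values.index.intersection(pd.Index(probes))
        return BetaMatrix(self.values.loc[keep])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id")


@dataclass
class FilterReport:
    """Bookkeeping of probe removals; removal categories may overlap."""

    n_input: int
    n_retained: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_removed_unique: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed_unique": self.n_removed_unique,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")


def read_beta_matrix(path, orientation: str = "probes-in-rows") -> BetaMatrix:
    """Read a delimited beta matrix (TSV/CSV, gzip accepted).

    ``orientation`` is ``"probes-in-rows"`` (default: header row holds
    sample ids) or ``"samples-in-rows"`` (transposed on read).
    """
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(d) for d in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValueError(f"non-numeric cell in column {col!r} at row {where!r}")
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "probes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return BetaMatrix(df)


def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample metadata table (sample_id, age, sex, ethnicity, cohort,
    cell fractions, optional batch/bisulfite-control/BMI columns)."""
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata must contain a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(pd.Index(df["sample_id"]), "sample")
    if "age" in df.columns and (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    for ct in CELL_TYPES:
        if ct in df.columns and (df[ct] < 0).any():
            raise ValueError(f"cell fraction {ct!r} must be non-negative")
    return df.set_index("sample_id")


def _split_region_groups(s) -> frozenset:
    if pd.isna(s) or not str(s).strip():
        return frozenset()
    return frozenset(part for part in str(s).split(";") if part)


_ISLAND_MAP = {
    "island": "Island",
    "shore": "Shore",
    "shelf": "Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "sea": "OpenSea",
    "": "OpenSea",
}


def _island_context(s) -> str:
    raw = "" if pd.isna(s) else str(s).strip()
    # Collapse directional N_/S_ prefixes (N_Shore -> Shore).
    if raw[:2] in ("N_", "S_"):
        raw = raw[2:]
    key = raw.lower()
    if key not in _ISLAND_MAP:
        raise ValueError(f"unrecognized island relation {s!r}")
    return _ISLAND_MAP[key]


def read_annotation(path) -> pd.DataFrame:
    """Parse an Illumina-manifest-style probe annotation CSV.

    Expects columns ``Name`` (probe id), and optionally ``CHR``,
    ``UCSC_RefGene_Group`` (semicolon-delimited), ``UCSC_RefGene_Name``,
    ``Relation_to_UCSC_CpG_Island``, ``Enhancer``, ``DHS``,
    ``Regulatory_Feature_Group``; extra columns are ignored.  Returns a
    DataFrame indexed by probe id with columns ``chromosome``,
    ``gene_region_groups`` (frozenset), ``genes`` (frozenset),
    ``regulatory_features`` (frozenset), ``island_context``.
    """
    df = pd.read_csv(path, dtype=str)
    if "Name" not in df.columns:
        raise ValueError("annotation is missing the probe-id column 'Name'")
    _check_unique(pd.Index(df["Name"]), "probe")
    out = pd.DataFrame(index=pd.Index(df["Name"].astype(str), name="probe_id"))
    out["chromosome"] = (
        df["CHR"].fillna("").to_numpy() if "CHR" in df.columns else ""
    )
    groups_src = df.get("UCSC_RefGene_Group", pd.Series([""] * len(df)))
    out["gene_region_groups"] = [_split_region_groups(s) for s in groups_src]
    genes_src = df.get("UCSC_RefGene_Name", pd.Series([""] * len(df)))
    out["genes"] = [_split_region_groups(s) for s in genes_src]
    island_src = df.get("Relation_to_UCSC_CpG_Island", pd.Series([""] * len(df)))
    out["island_context"] = [_island_context(s) for s in island_src]

    feats = []
    reg_group = df.get("Regulatory_Feature_Group", pd.Series([""] * len(df)))
    enh = df.get("Enhancer", pd.Series([""] * len(df)))
    dhs = df.get("DHS", pd.Series([""] * len(df)))
    for e, d, g in zip(enh, dhs, reg_group):
        f = set()
        if str(e).upper() in ("TRUE", "1", "YES"):
            f.add("Enhancer")
        if str(d).upper() in ("TRUE", "1", "YES"):
            f.add("DHS")
        g = "" if pd.isna(g) else str(g)
        if "Promoter" in g:
            f.add("Promoter")
        if "Open_Chromatin" in g or "OpenChromatin" in g:
            f.add("OpenChromatin")
        if "TFBS" in g or "Transcription_Factor" in g:
            f.add("TFBS")
        feats.append(frozenset(f))
    out["regulatory_features"] = feats
    return out


def filter_probes(
    beta: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    bead_counts: pd.DataFrame | None = None,
    exclusion_lists: Mapping[str, Iterable[str]] | None = None,
    p_threshold: float = 0.05,
    frac_threshold: float = 0.05,
    min_beads: int = 3,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove low-quality and excluded probes.

    A probe is removed when (a) its detection p-value exceeds
    ``p_threshold`` in at least ``frac_threshold`` of samples, (b) its bead
    count is below ``min_beads`` in at least ``frac_threshold`` of samples,
    or (c) it appears on any exclusion list.  Rules overlap; the report
    records per-rule counts and the count of unique removals.
    """
    n_input = len(beta.probe_ids)
    removed_by_rule: dict[str, int] = {}
    removed: set[str] = set()

    if detection_p is not None:
        dp = detection_p.reindex(index=beta.probe_ids, columns=beta.sample_ids)
        frac_fail = (dp.to_numpy(dtype=float) > p_threshold).mean(axis=1)
        hit = set(beta.probe_ids[frac_fail >= frac_threshold])
        removed_by_rule["detection_p"] = len(hit)
        removed |= hit
    if bead_counts is not None:
        bc = bead_counts.reindex(index=beta.probe_ids, columns=beta.sample_ids)
        frac_fail = (bc.to_numpy(dtype=float) < min_beads).mean(axis=1)
        hit = set(beta.probe_ids[frac_fail >= frac_threshold])
        removed_by_rule["bead_count"] = len(hit)
        removed |= hit
    for name, probes in (exclusion_lists or {}).items():
        probes = set(map(str, probes))
        unknown = probes - set(beta.probe_ids)
        if unknown:
            warnings.warn(
                f"exclusion list {name!r}: {len(unknown)} probe ids not in matrix",
                stacklevel=2,
            )
        hit = probes & set(beta.probe_ids)
        removed_by_rule[name] = len(hit)
        removed |= hit

    keep = beta.probe_ids[~beta.probe_ids.isin(removed)]
    out = BetaMatrix(beta.values.loc[keep])
    report = FilterReport(
        n_input=n_input,
        n_retained=len(keep),
        removed_by_rule=removed_by_rule,
        n_removed_unique=len(removed),
    )
    return out, report
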