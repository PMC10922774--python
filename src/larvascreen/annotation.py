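"""Target and pathway composition of a compound set.

Given a flat annotation table (compound -> target gene -> pathway, with
a primary/secondary tier and the source database), rank target genes by
how many compounds of a set hit them, and rank pathways by the
percentage of set compounds hitting them versus the rest of the library.
The annotation table is consumed as a file; no live database queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

TIERS = ("primary", "secondary")
COLUMNS = ("compound_id", "gene_symbol", "tier", "pathway_id",
           "pathway_name", "source_db")


@dataclass
class AnnotationTable:
    """Records of (compound, gene, tier, pathway, source)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"annotation table lacks columns {sorted(missing)}")
        key = ["compound_id", "gene_symbol", "pathway_id", "source_db"]
        if self.records.duplicated(subset=key).any():
            raise ValueError("duplicate (compound, gene, pathway, source) records")
        bad = set(self.records["tier"].dropna()) - set(TIERS)
        if bad:
            raise ValueError(f"unknown tiers {sorted(bad)}")

    @property
    def library(self) -> set[str]:
        return set(self.records["compound_id"])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnnotationTable":
        return cls(pd.read_csv(path))


def _subset(table: AnnotationTable, tiers) -> pd.DataFrame:
    df = table.records
    if tiers is not None:
        df = df[df["tier"].isin(set(tiers))]
    return df


def target_frequency(
    compound_set,
    table: AnnotationTable,
    top_n: int = 10,
    tiers=None,
) -> pd.DataFrame:
    """Rank target genes by the number of distinct set compounds
    annotated to them (multi-source records deduplicated on
    (compound, gene)); ties broken alphabetically.
    """
    cset = set(compound_set)
    extra = cset - table.library
    if extra:
        raise KeyError(f"compounds not in annotation library: {sorted(extra)[:5]}")
    df = _subset(table, tiers).drop_duplicates(subset=["compound_id", "gene_symbol"])
    if df.empty:
        warnings.warn("empty annotation table after tier filtering", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_symbol", "count_in_set", "count_in_library",
                     "pct_in_set", "pct_in_rest"]
        )
    in_set = df[df["compound_id"].isin(cset)]
    counts = in_set.groupby("gene_symbol")["compound_id"].nunique()
    lib_counts = df.groupby("gene_symbol")["compound_id"].nunique()
    n_set = len(cset)
    n_rest = len(table.library - cset)
    out = pd.DataFrame({
        "gene_symbol": counts.index,
        "count_in_set": counts.values,
        "count_in_library": lib_counts.reindex(counts.index).values,
    })
    out["pct_in_set"] = 100.0 * out["count_in_set"] / n_set if n_set else 0.0
    rest = out["count_in_library"] - out["count_in_set"]
    out["pct_in_rest"] = 100.0 * rest / n_rest if n_rest else 0.0
    out = out.sort_values(
        ["count_in_set", "gene_symbol"], ascending=[False, True]
    ).head(top_n).reset_index(drop=True)
    return out


def pathway_percentage(
    compound_set,
    table: AnnotationTable,
    top_n: int = 25,
    tiers=None,
) -> pd.DataFrame:
    """Rank pathways by the percentage of set compounds hitting them
    minus the percentage among the rest of the library; the ratio is
    reported alongside."""
    cset = set(compound_set)
    extra = cset - table.library
    if extra:
        raise KeyError(f"compounds not in annotation library: {sorted(extra)[:5]}")
    df = _subset(table, tiers).dropna(subset=["pathway_id"])
    df = df.drop_duplicates(subset=["compound_id", "pathway_id"])
    if df.empty:
        warnings.warn("no pathway annotations available", stacklevel=2)
        return pd.DataFrame(
            columns=["pathway_id", "pathway_name", "pct_in_set",
                     "pct_in_rest", "difference", "ratio"]
        )
    n_set = len(cset)
    rest = table.library - cset
    n_rest = len(rest)
    rows = []
    for (pid, pname), grp in df.groupby(["pathway_id", "pathway_name"], dropna=False):
        hits = set(grp["compound_id"])
        pct_set = 100.0 * len(hits & cset) / n_set if n_set else 0.0
        pct_rest = 100.0 * len(hits & rest) / n_rest if n_rest else 0.0
        rows.append({
            "pathway_id": pid,
            "pathway_name": pname,
            "pct_in_set": pct_set,
            "pct_in_rest": pct_rest,
            "difference": pct_set - pct_rest,
            "ratio": pct_set / pct_rest if pct_rest > 0 else float("inf"),
        })
    out = pd.DataFrame(rows).sort_values(
        ["difference", "pathway_id"], ascending=[False, True]
    ).head(top_n).reset_index(drop=True)
    return out
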