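"""Core-versus-total evaluation: retention table, origin counts, PCA overlay.

The retention report compares the whole collection and the core subset
on the same nine statistics as the per-population report, computed under
the all-loci policy (every locus, polymorphic or not), and expresses the
core value as a percentage of the total value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .diversity_stats import (
    REPORT_COLUMNS,
    round_half_up,
    whole_collection_summary,
)
from .core_selection import CoreSelection
from . import distance_phylo


@dataclass
class RetentionReport:
    """Total-vs-core diversity values and retention percentages."""

    table: pd.DataFrame  # rows: total, core, percentage; columns: Number + stats

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for c in out.columns:
            decimals = 0 if c in ("Number", "Np") else 3
            out[c] = [
                round_half_up(v, 2) if r == "Percentage of core (%)"
                else round_half_up(v, decimals)
                for r, v in zip(out.index, out[c])
            ]
        out.to_csv(path)


def compare_core(G: GenotypeMatrix, core: CoreSelection | Sequence[str]) -> RetentionReport:
    """Compute the retention report (all-loci policy on both sets).

    Percentages are ``100 * core / total`` per statistic, plus the core
    size as a percentage of the collection size; rounded to 2 decimals
    half-up on output.
    """
    selected = list(core.selected if isinstance(core, CoreSelection) else core)
    if not selected:
        raise ValueError("empty core set")
    unknown = set(selected) - set(G.accession_ids)
    if unknown:
        raise ValueError(f"core accessions not in collection: {sorted(unknown)}")
    total = whole_collection_summary(G, "all", label="total", policy="all")
    sub = whole_collection_summary(G, selected, label="core", policy="all")
    rows = {
        "Total sample": {"Number": float(G.n_accessions), **total.as_row()},
        "Core germplasm": {"Number": float(len(selected)), **sub.as_row()},
    }
    df = pd.DataFrame.from_dict(rows, orient="index")[["Number"] + REPORT_COLUMNS]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * df.loc["Core germplasm"] / df.loc["Total sample"]
    df.loc["Percentage of core (%)"] = pct
    df.index.name = "Type"
    return RetentionReport(df)


def counts_by_region(
    core: CoreSelection | Sequence[str],
    populations: Mapping[str, str],
) -> pd.DataFrame:
    """Per-region accession and core counts with a totals row.

    Rows follow first appearance order of regions in the map; regions
    with no core member still get a row (zero core count).
    """
    selected = set(core.selected if isinstance(core, CoreSelection) else core)
    regions = list(dict.fromkeys(populations.values()))
    rows = []
    for region in regions:
        members = [a for a, r in populations.items() if r == region]
        n_core = sum(1 for a in members if a in selected)
        rows.append((region, len(members), n_core))
    df = pd.DataFrame(rows, columns=["Collection region", "Number of accessions",
                                     "Number of core germplasms"])
    df.index = pd.RangeIndex(1, len(df) + 1, name="Number")
    return add_totals(df)


def add_totals(df: pd.DataFrame, label: str = "Total") -> pd.DataFrame:
    """Append a totals row summing every numeric column."""
    out = df.copy()
    totals = {c: (df[c].sum() if pd.api.types.is_numeric_dtype(df[c]) else "")
              for c in df.columns}
    first_text = next((c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])), None)
    if first_text is not None:
        totals[first_text] = label
    out.loc[label] = pd.Series(totals)
    return out


def region_proportions(counts: pd.DataFrame, decimals: int = 1) -> pd.Series:
    """Each region's share of the core, in percent (totals row excluded)."""
    body = counts.drop(index="Total", errors="ignore")
    total = body["Number of core germplasms"].sum()
    pct = 100.0 * body["Number of core germplasms"] / total
    return pct.map(lambda v: round_half_up(v, decimals))


def pca_overlay(
    G: GenotypeMatrix, core: CoreSelection | Sequence[str], k: int = 2
) -> pd.DataFrame:
    """PCA scores of every accession labelled in-core / out-of-core.

    Scores are exactly those of :func:`wildcore.distance_phylo.pca` on
    the full collection; the core is an annotation, not a re-projection.
    """
    selected = set(core.selected if isinstance(core, CoreSelection) else core)
    scores, _, _ = distance_phylo.pca(G, k)
    out = scores.copy()
    out["in_core"] = [a in selected for a in out.index]
    return out
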