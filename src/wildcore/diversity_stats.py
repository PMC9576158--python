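"""Per-locus and per-population genetic diversity statistics.

For a biallelic locus with alternate-allele frequency ``p`` (``q = 1-p``)
estimated from non-missing calls:

======================  =======================================
expected heterozygosity  ``He = 1 - p^2 - q^2``  (Nei gene diversity, biased)
unbiased gene diversity  ``Nei = 2n/(2n-1) * He``  (n = called accessions)
effective allele number  ``Ne = 1 / (p^2 + q^2)``
polymorphism information ``PIC = 1 - (p^2 + q^2) - 2 p^2 q^2``
Shannon-Wiener index     ``I = -p ln p - q ln q``  (0 at a fixed locus)
observed heterozygosity  ``Ho`` = heterozygote fraction among called
======================  =======================================

Population summaries average per-locus values.  Two locus-inclusion
policies exist: ``"polymorphic"`` averages over loci segregating within
the population (the per-region report), while ``"all"`` averages over
every locus (the whole-collection report); see the methods note for why
both are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

#: Column order of the per-population report.
REPORT_COLUMNS = ["MAF", "Np", "Na", "Ne", "Nei", "I", "PIC", "Ho", "He"]


def allele_frequencies(
    G: GenotypeMatrix, subset: Sequence[str] | str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and called-sample count per locus.

    Returns ``(p, n_called)``; ``p`` is NaN where no accession in the
    subset has a call (undefined frequency).
    """
    idx = G.accession_indices(subset)
    if idx.size == 0:
        raise ValueError("empty accession subset")
    calls = G.calls[idx]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    return p, n_called


def locus_stats(G: GenotypeMatrix, subset: Sequence[str] | str = "all") -> pd.DataFrame:
    """All per-locus statistics as a DataFrame indexed by locus name.

    Loci with undefined frequency (no calls in the subset) carry NaN
    statistics and are excluded from downstream summaries.
    """
    idx = G.accession_indices(subset)
    p, n_called = allele_frequencies(G, subset)
    q = 1.0 - p
    sq = p * p + q * q
    he = 1.0 - sq
    with np.errstate(divide="ignore", invalid="ignore"):
        nei = np.where(n_called > 0, 2.0 * n_called / np.maximum(2.0 * n_called - 1.0, 1.0), np.nan) * he
        ne = 1.0 / sq
    pic = 1.0 - sq - 2.0 * (p * q) ** 2
    shannon = -_xlogx(p) - _xlogx(q)
    calls = G.calls[idx]
    called = calls != MISSING
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    poly = (p > 0) & (p < 1)
    na = np.where(np.isnan(p), np.nan, np.where(poly, 2.0, 1.0))
    return pd.DataFrame(
        {
            "p": p, "maf": np.minimum(p, q), "n_called": n_called,
            "ho": ho, "he": he, "nei": nei, "ne": ne, "pic": pic,
            "shannon_i": shannon, "na": na, "is_polymorphic": poly,
        },
        index=pd.Index(G.locus_names, name="locus"),
    )


def _xlogx(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.log(x)
    return np.where(x == 0, 0.0, out)


@dataclass(frozen=True)
class PopulationSummary:
    """Mean diversity statistics of one population (one report row)."""

    population: str
    n_accessions: int
    mean_maf: float
    np_: int  # polymorphic marker count
    na_mean: float
    ne_mean: float
    nei_mean: float
    shannon_mean: float
    pic_mean: float
    ho_mean: float
    he_mean: float

    def as_row(self) -> dict[str, float]:
        return {
            "MAF": self.mean_maf, "Np": self.np_, "Na": self.na_mean,
            "Ne": self.ne_mean, "Nei": self.nei_mean, "I": self.shannon_mean,
            "PIC": self.pic_mean, "Ho": self.ho_mean, "He": self.he_mean,
        }


def population_summary(
    G: GenotypeMatrix, population: str, policy: str = "polymorphic"
) -> PopulationSummary:
    """Summarise one population under a locus-inclusion policy.

    ``policy="polymorphic"`` averages over loci with both alleles present
    within the population; ``policy="all"`` averages over every locus with
    a defined frequency.
    """
    pops = G.population_series()
    members = list(pops.index[pops == population])
    if not members:
        raise ValueError(f"unknown or empty population {population!r}")
    return _summarise(G, members, population, policy)


def _summarise(
    G: GenotypeMatrix, members: list[str], label: str, policy: str
) -> PopulationSummary:
    if policy not in ("polymorphic", "all"):
        raise ValueError(f"policy must be 'polymorphic' or 'all', got {policy!r}")
    st = locus_stats(G, members)
    defined = st["p"].notna()
    n_poly = int(st["is_polymorphic"].sum())
    inc = (st["is_polymorphic"] if policy == "polymorphic" else defined) & defined
    if inc.sum() == 0:
        # e.g. a population of identical homozygotes under the polymorphic
        # policy: report zero diversity rather than NaN
        return PopulationSummary(label, len(members), 0.0, 0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    sub = st[inc]
    return PopulationSummary(
        population=label,
        n_accessions=len(members),
        mean_maf=float(sub["maf"].mean()),
        np_=n_poly,
        na_mean=float(sub["na"].mean()),
        ne_mean=float(sub["ne"].mean()),
        nei_mean=float(sub["nei"].mean()),
        shannon_mean=float(sub["shannon_i"].mean()),
        pic_mean=float(sub["pic"].mean()),
        ho_mean=float(sub["ho"].mean()),
        he_mean=float(sub["he"].mean()),
    )


def whole_collection_summary(
    G: GenotypeMatrix, subset: Sequence[str] | str = "all", label: str = "all", policy: str = "all"
) -> PopulationSummary:
    """Summary over an arbitrary accession set (default: everything, all loci)."""
    members = list(G.accession_ids) if isinstance(subset, str) else list(subset)
    return _summarise(G, members, label, policy)


def summary_table(G: GenotypeMatrix, policy: str = "polymorphic") -> pd.DataFrame:
    """One row per population plus an unweighted ``Mean`` row.

    The mean row is the arithmetic mean of the population rows (not an
    accession-weighted pool), matching how multi-region diversity tables
    are conventionally reported.
    """
    rows = {}
    n_acc = {}
    for pop in G.population_labels():
        s = population_summary(G, pop, policy)
        rows[pop] = s.as_row()
        n_acc[pop] = s.n_accessions
    df = pd.DataFrame.from_dict(rows, orient="index")[REPORT_COLUMNS]
    df.loc["Mean"] = mean_row(df.iloc[: len(rows)])
    df.insert(0, "N", pd.Series(n_acc))
    df.index.name = "Group"
    return df


def mean_row(df: pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic mean across population rows (Np to nearest int)."""
    m = df[REPORT_COLUMNS].mean(axis=0)
    m["Np"] = round_half_up(m["Np"], 0)
    return m


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal half-up rounding for report output (0.00005 -> 0.0001)."""
    if isinstance(x, float) and np.isnan(x):
        return x
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(exp, rounding=ROUND_HALF_UP))


def write_summary_table(df: pd.DataFrame, path: str | Path, decimals: int = 4) -> None:
    """Write the per-population report as TSV, values rounded half-up."""
    out = df.copy()
    for c in REPORT_COLUMNS:
        if c == "Np":
            out[c] = out[c].map(lambda v: int(round_half_up(v, 0)))
        else:
            out[c] = out[c].map(lambda v: round_half_up(v, decimals))
    out.to_csv(path, sep="\t")
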