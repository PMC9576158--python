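"""Genotype matrix container, readers/writers and the SNP filter.

Genotypes are diploid biallelic dosages of the alternate allele
(0, 1, 2), with a dedicated sentinel for missing calls.  This is the
entry point of every pipeline run: everything downstream (diversity
statistics, distances, core selection) consumes a :class:`GenotypeMatrix`.

Supported formats:

* VCF 4.x (uncompressed or bgzipped), GT field only; biallelic SNP
  records are kept, anything else is skipped with a logged count.
* A TSV dosage dialect: header row ``accession<TAB>locus1<TAB>...``,
  cells ``0/1/2/NA``, locus metadata in a side file
  ``locus<TAB>chrom<TAB>pos<TAB>ref<TAB>alt``.
* Population map: two-column TSV (accession, population), no header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call.  Never 0 (0 = homozygous reference).
MISSING: int = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a GenotypeMatrix invariant."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one biallelic SNP locus."""

    name: str
    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"locus {self.name}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"locus {self.name}: ref == alt ({self.ref_allele})")


@dataclass
class GenotypeMatrix:
    """Accessions x loci diploid dosage matrix with optional population labels.

    Parameters
    ----------
    accession_ids
        Ordered, unique accession identifiers (rows).
    loci
        Ordered locus metadata (columns).
    calls
        ``(N, L)`` int8 array of alternate-allele dosages in {0, 1, 2},
        with :data:`MISSING` (-1) for no-calls.
    populations
        Optional map accession id -> population label.  When attached,
        every accession must be labelled.
    """

    accession_ids: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray
    populations: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        n, l = len(self.accession_ids), len(self.loci)
        if self.calls.shape != (n, l):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n} accessions, {l} loci)"
            )
        if len(set(self.accession_ids)) != n:
            dupes = pd.Index(self.accession_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate accession ids: {dupes}")
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValidationError(f"invalid call values {sorted(bad)}; expected 0/1/2/missing")
        if self.populations is not None:
            unlabelled = [a for a in self.accession_ids if a not in self.populations]
            if unlabelled:
                raise ValidationError(f"accessions without population label: {unlabelled}")

    # -- conveniences --------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.loci]

    def population_series(self) -> pd.Series:
        """Population label per accession, in row order."""
        if self.populations is None:
            raise ValidationError("no population map attached")
        return pd.Series(
            [self.populations[a] for a in self.accession_ids],
            index=self.accession_ids,
            name="population",
        )

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.population_series()))

    def accession_indices(self, subset: Sequence[str] | str = "all") -> np.ndarray:
        """Row indices for a subset of accession ids (or all rows)."""
        if isinstance(subset, str):
            if subset != "all":
                raise ValueError("subset must be a sequence of ids or 'all'")
            return np.arange(self.n_accessions)
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([pos[a] for a in subset], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown accession id {e.args[0]!r}") from None

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_indices(ids)
        pops = None
        if self.populations is not None:
            pops = {a: self.populations[a] for a in ids}
        return GenotypeMatrix(list(ids), list(self.loci), self.calls[idx].copy(), pops)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        loci = [self.loci[j] for j in keep]
        pops = dict(self.populations) if self.populations is not None else None
        return GenotypeMatrix(list(self.accession_ids), loci, self.calls[:, keep].copy(), pops)

    def dosage_float(self) -> np.ndarray:
        """Calls as float with NaN for missing (working representation)."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str | None = None,
    meta_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dosage dialect.

    ``format`` is inferred from the file suffix when omitted
    (``.vcf``/``.vcf.gz`` -> vcf, otherwise tsv).  For TSV input the
    locus metadata side file defaults to ``<stem>.loci.tsv`` next to the
    genotype file and is optional (placeholder metadata is synthesised
    when absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path, meta_path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as e:
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vf.header.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate accession id in VCF sample header")
    loci: list[LocusMeta] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        is_snp = (
            len(alts) == 1
            and rec.ref is not None
            and len(rec.ref) == 1
            and len(alts[0]) == 1
            and alts[0] != rec.ref
            and alts[0] in "ACGT"
            and rec.ref in "ACGT"
        )
        if not is_snp:
            skipped += 1
            continue
        name = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        loci.append(LocusMeta(name, str(rec.chrom), int(rec.pos), rec.ref, alts[0]))
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            # half-calls and phased separators accepted; any missing allele -> MISSING
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            col[i] = int(gt[0] > 0) + int(gt[1] > 0)
        columns.append(col)
    vf.close()
    if not loci and skipped == 0:
        raise FormatError(f"no variant records in {path}")
    if skipped:
        logger.info("VCF %s: skipped %d non-biallelic/non-SNP records", path.name, skipped)
    calls = np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, loci, calls)


def _read_tsv(path: Path, meta_path: str | Path | None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        raise FormatError(f"cannot parse genotype TSV {path}: {e}") from e
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate accession ids: {dupes}")
    raw = df.to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    ok_mask = np.isin(raw, ["0", "1", "2"])
    calls[ok_mask] = raw[ok_mask].astype(np.int8)
    bad = ~ok_mask & ~np.isin(raw, ["NA", "", "nan"]) & (raw == raw)  # raw==raw filters NaN
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid cell {raw[i, j]!r} at accession {df.index[i]}, locus {df.columns[j]}"
        )

    if meta_path is None:
        stem = str(path)[: -len(path.suffix)] if path.suffix else str(path)
        candidate = Path(stem + ".loci.tsv")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        meta = pd.read_csv(
            meta_path, sep="\t", header=None,
            names=["locus", "chrom", "pos", "ref", "alt"], dtype=str,
        )
        table = {r.locus: r for r in meta.itertuples()}
        loci = []
        for name in df.columns:
            if name not in table:
                raise ValidationError(f"locus {name} missing from metadata file {meta_path}")
            r = table[name]
            loci.append(LocusMeta(name, r.chrom, int(r.pos), r.ref, r.alt))
    else:
        # placeholder metadata keeps the matrix usable for statistics
        loci = [LocusMeta(name, "0", j + 1, "A", "T") for j, name in enumerate(df.columns)]
    return GenotypeMatrix(list(df.index), loci, calls)


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a genotype matrix (TSV dialect with side metadata file, or VCF)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        cells = G.calls.astype(object)
        df = pd.DataFrame(cells, index=G.accession_ids, columns=G.locus_names)
        df = df.where(G.calls != MISSING, "NA")
        df.index.name = "accession"
        df.to_csv(path, sep="\t")
        meta = pd.DataFrame(
            [(m.name, m.chromosome, m.position, m.ref_allele, m.alt_allele) for m in G.loci]
        )
        meta.to_csv(str(path)[: -len(path.suffix)] + ".loci.tsv",
                    sep="\t", header=False, index=False)
    elif format == "vcf":
        _write_vcf(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(m.chromosome for m in G.loci):
        header.contigs.add(chrom)
    for a in G.accession_ids:
        header.add_sample(a)
    _GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, m in enumerate(G.loci):
            rec = out.new_record(
                contig=m.chromosome, start=m.position - 1, stop=m.position,
                alleles=(m.ref_allele, m.alt_allele), id=m.name,
            )
            for i, a in enumerate(G.accession_ids):
                rec.samples[a]["GT"] = _GT[int(G.calls[i, j])]
            out.write(rec)


def write_population_map(populations: Mapping[str, str], path: str | Path) -> None:
    pd.Series(dict(populations)).to_csv(path, sep="\t", header=False)


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def filter_loci(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.5,
) -> GenotypeMatrix:
    """Keep loci with MAF >= ``maf_min`` and call rate >= ``call_rate_min``.

    Both thresholds are inclusive.  MAF is computed on non-missing calls
    only; call rate ("integrity") is the fraction of accessions with a
    non-missing genotype at the locus.  The accession set is unchanged,
    and surviving call values are untouched.
    """
    for t, label in ((maf_min, "maf_min"), (call_rate_min, "call_rate_min")):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{label} must be in [0, 1], got {t}")
    called = G.calls != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / max(G.n_accessions, 1)
    with np.errstate(invalid="ignore"):
        p = np.where(called, G.calls, 0).sum(axis=0) / np.where(n_called > 0, 2 * n_called, np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (call_rate >= call_rate_min) & (n_called > 0) & (maf >= maf_min)
    kept, removed = int(keep.sum()), int((~keep).sum())
    logger.info("filter_loci: kept %d, removed %d (maf>=%g, call_rate>=%g)",
                kept, removed, maf_min, call_rate_min)
    if kept == 0:
        logger.warning("filter_loci removed every locus")
    return G.subset_loci(keep)


def attach_populations(G: GenotypeMatrix, map_path: str | Path | Mapping[str, str]) -> GenotypeMatrix:
    """Attach a population label to every accession from a two-column TSV map.

    Unknown accessions in the map are ignored with a warning; accessions
    of ``G`` absent from the map are an error (listed by id).
    """
    if isinstance(map_path, Mapping):
        mapping = dict(map_path)
    else:
        df = pd.read_csv(map_path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 2:
            raise FormatError(f"population map must have 2 columns, got {df.shape[1]}")
        mapping = dict(zip(df[0], df[1]))
    known = set(G.accession_ids)
    extra = sorted(set(mapping) - known)
    if extra:
        logger.warning("population map: %d ids not in matrix (e.g. %s)", len(extra), extra[:3])
    missing = [a for a in G.accession_ids if a not in mapping]
    if missing:
        raise ValidationError(f"accessions missing from population map: {missing}")
    pops = {a: mapping[a] for a in G.accession_ids}
    return replace_populations(G, pops)


def replace_populations(G: GenotypeMatrix, pops: dict[str, str]) -> GenotypeMatrix:
    return GenotypeMatrix(list(G.accession_ids), list(G.loci), G.calls.copy(), pops)
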