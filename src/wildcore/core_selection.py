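"""Core-collection construction.

The core set is built with population priority: one seed accession per
population is always retained, the remaining slots are filled greedily
and then improved by steepest-ascent single-swap local search on a
weighted objective

    score(S) = w_mr * MR(S) + w_sh * SH(S)

where ``MR(S)`` is the mean pairwise modified Rogers distance within the
subset and ``SH(S)`` is the Shannon entropy of the pooled allele
frequencies of the subset, normalised to [0, 1].  With the default
weights 0.7 / 0.3 the search favours spread-out subsets while protecting
allelic richness.  A greedy maximum-allele-coverage ranking provides the
coverage-versus-size curve and the default target size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .distance_phylo import DistanceMatrix, modified_rogers_matrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Allele presence and coverage
# ----------------------------------------------------------------------

def allele_presence(G: GenotypeMatrix) -> np.ndarray:
    """Boolean (N, 2L) matrix: accession carries [ref_l..., alt_l...]."""
    calls = G.calls
    ref = (calls == 0) | (calls == 1)
    alt = (calls == 1) | (calls == 2)
    return np.concatenate([ref, alt], axis=1)


def coverage(G: GenotypeMatrix, subset: Sequence[str]) -> float:
    """Fraction of the full collection's observed alleles present in ``subset``."""
    pres = allele_presence(G)
    total = pres.any(axis=0)
    idx = G.accession_indices(subset)
    got = pres[idx].any(axis=0)
    denom = int(total.sum())
    return float((got & total).sum() / denom) if denom else 1.0


@dataclass
class CoverageCurve:
    """Greedy maximum-coverage accession ranking with coverage at each size."""

    ranking: list[str]
    coverage_at_k: np.ndarray  # index k-1 -> coverage of top-k

    def smallest_k(self, target: float) -> int:
        """Smallest k whose greedy coverage reaches ``target``."""
        hit = np.flatnonzero(self.coverage_at_k >= target)
        return int(hit[0]) + 1 if hit.size else len(self.ranking)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"rank": np.arange(1, len(self.ranking) + 1),
             "accession": self.ranking,
             "coverage": self.coverage_at_k}
        ).to_csv(path, sep="\t", index=False)


def coverage_ranking(G: GenotypeMatrix) -> CoverageCurve:
    """Rank accessions by greedy marginal new-allele gain (ties by id).

    Rank 1 carries the most distinct alleles; each later rank adds the
    most alleles not yet covered.  Exhausted gain (coverage 1) falls back
    to id order.
    """
    if G.n_loci < 1:
        raise ValueError("need at least one locus")
    pres = allele_presence(G)
    denom = int(pres.any(axis=0).sum())
    order = np.array(G.accession_ids)
    # pre-sort by id so argmax picks the lexicographically smallest on ties
    id_order = np.argsort(order, kind="stable")
    pres_f = pres[id_order].astype(np.float64)
    uncovered = np.ones(pres.shape[1])
    uncovered[~pres.any(axis=0)] = 0.0
    remaining = list(range(len(order)))
    ranking: list[str] = []
    cov: list[float] = []
    covered = 0.0
    while remaining:
        gains = pres_f[remaining] @ uncovered
        best = int(np.argmax(gains))  # first max = smallest id among ties
        row = remaining.pop(best)
        newly = pres_f[row] * uncovered
        covered += float(newly.sum())
        uncovered -= newly
        ranking.append(str(order[id_order[row]]))
        cov.append(covered / denom if denom else 1.0)
    return CoverageCurve(ranking, np.array(cov))


# ----------------------------------------------------------------------
# Seeds
# ----------------------------------------------------------------------

def stratified_seed(G: GenotypeMatrix, mr: DistanceMatrix | None = None) -> list[str]:
    """One seed accession per population: the member with maximal mean
    modified Rogers distance to the other members of its population
    (the population's most divergent representative); ties and singleton
    populations resolve to the lexicographically smallest id."""
    if mr is None:
        mr = modified_rogers_matrix(G)
    pos = {a: i for i, a in enumerate(mr.labels)}
    series = G.population_series()
    seeds: list[str] = []
    for pop in G.population_labels():
        members = sorted(series.index[series == pop])
        if len(members) == 1:
            seeds.append(members[0])
            continue
        idx = np.array([pos[a] for a in members])
        sub = mr.d[np.ix_(idx, idx)]
        mean_d = sub.sum(axis=1) / (len(members) - 1)
        best = int(np.argmax(mean_d))  # members sorted, so first max = smallest id
        seeds.append(members[best])
    return seeds


# ----------------------------------------------------------------------
# Objective
# ----------------------------------------------------------------------

def _shannon_pooled(G: GenotypeMatrix, idx: np.ndarray) -> float:
    """Normalised Shannon entropy of pooled allele frequencies of rows ``idx``.

    Each allele's pooled share is its within-locus frequency divided by
    the number of loci with defined frequency, so shares sum to 1; the
    entropy is divided by ln(2 * n_defined_loci) to land in [0, 1].
    """
    calls = G.calls[idx]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    ok = n_called > 0
    if not ok.any():
        return 0.0
    alt = np.where(called, calls, 0).sum(axis=0)[ok]
    p = alt / (2.0 * n_called[ok])
    l_def = int(ok.sum())
    f = np.concatenate([p, 1.0 - p]) / l_def
    f = f[f > 0]
    raw = float(-(f * np.log(f)).sum())
    return raw / np.log(2.0 * l_def)


def subset_objective(
    G: GenotypeMatrix,
    S: Sequence[str],
    w_mr: float = 0.7,
    w_sh: float = 0.3,
    mr: DistanceMatrix | None = None,
) -> float:
    """Weighted mean-pairwise-MR + normalised pooled-Shannon score of a subset."""
    if len(S) < 2:
        raise ValueError("subset must contain at least 2 accessions")
    if abs(w_mr + w_sh - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if mr is None:
        mr = modified_rogers_matrix(G)
    pos = {a: i for i, a in enumerate(mr.labels)}
    idx = np.array([pos[a] for a in S])
    sub = mr.d[np.ix_(idx, idx)]
    mr_term = float(sub.sum() / (len(S) * (len(S) - 1)))
    sh_term = _shannon_pooled(G, G.accession_indices(list(S)))
    return w_mr * mr_term + w_sh * sh_term


def mean_nearest_mr(G: GenotypeMatrix, S: Sequence[str], mr: DistanceMatrix | None = None) -> float:
    """Entry-to-nearest-entry variant of the MR term (alternate config)."""
    if mr is None:
        mr = modified_rogers_matrix(G)
    sub = mr.submatrix(list(S)).d.copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


# ----------------------------------------------------------------------
# Optimizer
# ----------------------------------------------------------------------

@dataclass
class CoreSelection:
    """A chosen core subset with its score and Table-2-style bookkeeping."""

    selected: list[str]
    objective: float
    coverage: float
    per_region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.selected)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"size": self.size, "objective": self.objective,
             "coverage": self.coverage,
             "per_region_counts": self.per_region_counts,
             "selected": self.selected}, indent=1) + "\n")


class _ObjectiveEngine:
    """Incremental evaluation of score(S) over row-index subsets.

    The MR term is maintained through row sums of the distance matrix;
    the Shannon term uses the identity (for L loci with defined pooled
    frequencies)  SH = (ln L + mean_l H_l) / ln(2L)  with H_l the
    per-locus entropy, so candidate moves are evaluated from per-locus
    allele counts alone.
    """

    def __init__(self, G: GenotypeMatrix, mr: DistanceMatrix, w_mr: float, w_sh: float):
        pos = {a: i for i, a in enumerate(mr.labels)}
        self.row_of = {a: i for i, a in enumerate(G.accession_ids)}
        order = [pos[a] for a in G.accession_ids]
        self.d = mr.d[np.ix_(order, order)]  # aligned with G rows
        self.w_mr, self.w_sh = w_mr, w_sh
        calls = G.calls
        self.called = (calls != MISSING).astype(np.int64)
        self.alt = np.where(calls != MISSING, calls, 0).astype(np.int64)

    def score_rows(self, rows: np.ndarray) -> float:
        k = len(rows)
        sub = self.d[np.ix_(rows, rows)]
        mr_term = float(sub.sum() / (k * (k - 1))) if k > 1 else 0.0
        return self.w_mr * mr_term + self.w_sh * self._sh(
            self.alt[rows].sum(axis=0), self.called[rows].sum(axis=0))

    def _sh(self, alt_sum: np.ndarray, called_sum: np.ndarray) -> float:
        ok = called_sum > 0
        l_def = int(ok.sum())
        if l_def == 0:
            return 0.0
        p = alt_sum[ok] / (2.0 * called_sum[ok])
        h = _entropy2(p)
        return (np.log(l_def) + float(h.mean())) / np.log(2.0 * l_def)

    def batch_scores(
        self, base_alt: np.ndarray, base_called: np.ndarray,
        cand_rows: np.ndarray, k: int,
        base_pairsum: float, base_rowsums: np.ndarray,
    ) -> np.ndarray:
        """Score of (base + one candidate row) for every candidate, vectorised."""
        alt = base_alt[None, :] + self.alt[cand_rows]
        called = base_called[None, :] + self.called[cand_rows]
        ok = called > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, alt / (2.0 * np.maximum(called, 1)), 0.0)
        h = np.where(ok, _entropy2(p), 0.0)
        l_def = ok.sum(axis=1)
        sh = np.where(
            l_def > 0,
            (np.log(np.maximum(l_def, 1)) + h.sum(axis=1) / np.maximum(l_def, 1))
            / np.log(2.0 * np.maximum(l_def, 1)),
            0.0,
        )
        pairsum = base_pairsum + base_rowsums[cand_rows]
        mr_term = 2.0 * pairsum / (k * (k - 1)) if k > 1 else np.zeros(len(cand_rows))
        return self.w_mr * mr_term + self.w_sh * sh


def _entropy2(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(q > 0, q * np.log(q), 0.0)
    return h


def optimize_core(
    G: GenotypeMatrix,
    size: int,
    w_mr: float = 0.7,
    w_sh: float = 0.3,
    seed_set: Sequence[str] | None = None,
    restarts: int = 1,
    max_no_improve: int = 3,
    rng_seed: int = 0,
    mr: DistanceMatrix | None = None,
    max_sweeps: int = 200,
) -> CoreSelection:
    """Population-priority core optimisation.

    ``seed_set`` (default: :func:`stratified_seed`) is always contained
    in the result.  Restart 1 fills the remaining slots greedily by
    objective gain; further restarts fill them randomly.  Each start is
    improved by steepest-ascent single-swap local search (only non-seed
    members may leave) until no swap improves or ``max_sweeps`` is hit;
    the search stops early after ``max_no_improve`` consecutive restarts
    without improving the incumbent.  Deterministic for a given
    ``rng_seed``.
    """
    if mr is None:
        mr = modified_rogers_matrix(G)
    if seed_set is None:
        seed_set = stratified_seed(G, mr) if G.populations else []
    if size < len(seed_set):
        raise ValueError(
            f"size {size} below the {len(seed_set)} population seeds"
        )
    if size > G.n_accessions:
        raise ValueError("size exceeds number of accessions")
    engine = _ObjectiveEngine(G, mr, w_mr, w_sh)
    seed_rows = np.array(sorted(engine.row_of[a] for a in seed_set), dtype=int)
    all_rows = np.arange(G.n_accessions)
    rng = np.random.default_rng(rng_seed)

    if size == G.n_accessions:
        sel = list(G.accession_ids)
        return _finalise(G, sel, engine.score_rows(all_rows), mr)

    best_rows: np.ndarray | None = None
    best_score = -np.inf
    stale = 0
    for restart in range(max(restarts, 1)):
        if restart == 0:
            start = _greedy_fill(engine, seed_rows, all_rows, size)
        else:
            pool = np.setdiff1d(all_rows, seed_rows)
            extra = rng.choice(pool, size=size - len(seed_rows), replace=False)
            start = np.sort(np.concatenate([seed_rows, extra]))
        rows, score = _local_search(engine, start, seed_rows, all_rows, max_sweeps)
        logger.info("restart %d: objective %.6f", restart, score)
        if score > best_score + 1e-12:
            best_rows, best_score = rows, score
            stale = 0
        else:
            stale += 1
            if stale >= max_no_improve:
                break
    assert best_rows is not None
    sel = [G.accession_ids[i] for i in sorted(best_rows)]
    return _finalise(G, sel, best_score, mr)


def _greedy_fill(
    engine: _ObjectiveEngine, seed_rows: np.ndarray, all_rows: np.ndarray, size: int
) -> np.ndarray:
    current = list(seed_rows)
    in_set = np.zeros(len(all_rows), dtype=bool)
    in_set[seed_rows] = True
    alt_sum = engine.alt[seed_rows].sum(axis=0)
    called_sum = engine.called[seed_rows].sum(axis=0)
    rowsums = engine.d[:, seed_rows].sum(axis=1)
    pairsum = float(engine.d[np.ix_(seed_rows, seed_rows)].sum() / 2.0)
    while len(current) < size:
        cand = all_rows[~in_set]
        scores = engine.batch_scores(alt_sum, called_sum, cand, len(current) + 1,
                                     pairsum, rowsums)
        pick = int(cand[np.argmax(scores)])  # ties -> smallest row index
        in_set[pick] = True
        current.append(pick)
        alt_sum += engine.alt[pick]
        called_sum += engine.called[pick]
        pairsum += rowsums[pick]
        rowsums += engine.d[:, pick]
    return np.sort(np.array(current))


def _local_search(
    engine: _ObjectiveEngine,
    rows: np.ndarray,
    seed_rows: np.ndarray,
    all_rows: np.ndarray,
    max_sweeps: int,
) -> tuple[np.ndarray, float]:
    rows = np.array(sorted(rows))
    k = len(rows)
    score = engine.score_rows(rows)
    seed_mask = np.isin(rows, seed_rows)
    for _ in range(max_sweeps):
        in_set = np.zeros(len(all_rows), dtype=bool)
        in_set[rows] = True
        outside = all_rows[~in_set]
        if outside.size == 0:
            break
        alt_all = engine.alt[rows].sum(axis=0)
        called_all = engine.called[rows].sum(axis=0)
        rowsums = engine.d[:, rows].sum(axis=1)
        pairsum = float(engine.d[np.ix_(rows, rows)].sum() / 2.0)
        best_gain, best_move = 0.0, None
        removable = rows[~seed_mask]
        for o in removable:
            base_alt = alt_all - engine.alt[o]
            base_called = called_all - engine.called[o]
            base_pair = pairsum - rowsums[o]
            base_rowsums = rowsums - engine.d[:, o]
            cand_scores = engine.batch_scores(
                base_alt, base_called, outside, k, base_pair, base_rowsums)
            b = int(np.argmax(cand_scores))
            gain = float(cand_scores[b]) - score
            if gain > best_gain + 1e-12:
                best_gain, best_move = gain, (int(o), int(outside[b]))
        if best_move is None:
            break
        o, i = best_move
        rows = np.sort(np.append(rows[rows != o], i))
        seed_mask = np.isin(rows, seed_rows)
        score += best_gain
    return rows, engine.score_rows(rows)


def _finalise(G: GenotypeMatrix, selected: list[str], score: float, mr: DistanceMatrix) -> CoreSelection:
    cov = coverage(G, selected)
    counts: dict[str, int] = {}
    if G.populations:
        series = G.population_series()
        counts = {pop: 0 for pop in G.population_labels()}
        for a in selected:
            counts[series[a]] += 1
    return CoreSelection(selected, float(score), cov, counts)
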