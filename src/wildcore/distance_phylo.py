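"""Genetic distances, neighbour-joining trees and PCA.

Distances
---------
* Modified Rogers between accessions ``i`` and ``j`` over the loci called
  in both (``L_ij`` of them), with ``x`` the alternate-allele dosage::

      MR_ij = sqrt( sum_l (x_il - x_jl)^2 / (4 * L_ij) )

  Bounded in [0, 1]; a metric on complete data.
* Nei (1972) standard genetic distance between populations from their
  per-locus allele-frequency profiles::

      I = J_xy / sqrt(J_x * J_y),   D = -ln I

  where ``J_xy = sum_l (p1 p2 + q1 q2)`` etc.  ``I = 0`` pairs get a
  configurable finite cap (default 10) so tree building stays defined.

Trees
-----
Saitou-Nei neighbour joining, deterministic: Q-matrix ties are broken by
the lexicographically smallest sorted pair of node labels (internal
nodes carry the smallest leaf label of their clade), and negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .diversity_stats import allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])


# ----------------------------------------------------------------------
# Modified Rogers distance
# ----------------------------------------------------------------------

def modified_rogers_matrix(
    G: GenotypeMatrix, subset: Sequence[str] | str = "all"
) -> DistanceMatrix:
    """Pairwise modified Rogers distances over pairwise-complete loci."""
    idx = G.accession_indices(subset)
    labels = [G.accession_ids[i] for i in idx]
    X = G.dosage_float()[idx]
    M = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    A2 = A * A
    # sum over shared loci of (x - y)^2, via masked cross products
    sq = A2 @ M.T + M @ A2.T - 2.0 * (A @ A.T)
    shared = M @ M.T
    no_shared = shared < 0.5
    np.fill_diagonal(no_shared, False)
    if no_shared.any():
        i, j = np.argwhere(no_shared)[0]
        raise ValueError(
            f"accessions {labels[i]!r} and {labels[j]!r} share no called locus"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / (4.0 * np.maximum(shared, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, 1.0)
    return DistanceMatrix(labels, 0.5 * (d + d.T))


# ----------------------------------------------------------------------
# Nei (1972) distance between populations
# ----------------------------------------------------------------------

def nei_distance_matrix(G: GenotypeMatrix, cap: float = 10.0) -> DistanceMatrix:
    """Nei standard genetic distance among attached populations.

    Loci with an undefined frequency in either population of a pair are
    excluded from that pair's identity sums.  A pair with zero gene
    identity gets the finite ``cap`` with a warning.
    """
    pops = G.population_labels()
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    series = G.population_series()
    P = np.vstack([
        allele_frequencies(G, list(series.index[series == pop]))[0] for pop in pops
    ])  # (n_pops, L), NaN where undefined
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(P[i]) & ~np.isnan(P[j])
            p1, p2 = P[i, ok], P[j, ok]
            q1, q2 = 1.0 - p1, 1.0 - p2
            jxy = float(np.sum(p1 * p2 + q1 * q2))
            jx = float(np.sum(p1 * p1 + q1 * q1))
            jy = float(np.sum(p2 * p2 + q2 * q2))
            ident = jxy / np.sqrt(jx * jy) if jx > 0 and jy > 0 else 0.0
            if ident <= 0:
                logger.warning("Nei identity 0 for pair (%s, %s); capping at %g",
                               pops[i], pops[j], cap)
                dist = cap
            else:
                dist = min(-np.log(ident), cap)
                dist = max(dist, 0.0)  # guard tiny negative from rounding when I ~ 1
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(pops), d)


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the NJ result is rooted at the final join."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        # gather (leaf, depth) lists per subtree, combine pairwise at joins
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name or "", 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(leaf, depth + bl) for leaf, depth in walk(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            return [x for g in groups for x in g]

        leaves = sorted(l for l, _ in walk(self))
        df = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for (a, b), v in dists.items():
            df.loc[a, b] = df.loc[b, a] = v
        return df


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; exact on additive matrices."""
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    # working matrix is compacted in place: slot `bi` takes the merged node,
    # slot `ai` is filled with the last active slot, so no O(n^2) reallocations
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    # tie-break key per active node: smallest leaf label in its clade
    keys: list[str] = list(D.labels)
    d = D.d.copy()
    slot_nodes = list(range(n))  # slot -> index into nodes/keys
    m = n
    while m > 3:
        sub = d[:m, :m]
        r = sub.sum(axis=1)
        # np.add.outer keeps q exactly symmetric, so exact-equality ties
        # always appear in the upper triangle
        q = (m - 2) * sub - np.add.outer(r, r)
        np.fill_diagonal(q, np.inf)
        ties = np.argwhere(q == q.min())
        _, ai, bi = min(
            (tuple(sorted((keys[slot_nodes[a]], keys[slot_nodes[b]]))), a, b)
            for a, b in ties if a < b
        )
        i, j = slot_nodes[ai], slot_nodes[bi]
        dij = d[ai, bi]
        bl_i = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        bl_i, bl_j = _clamp_pair(bl_i, dij - bl_i)
        parent = TreeNode(children=[(nodes[i], bl_i), (nodes[j], bl_j)])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        new_row = 0.5 * (d[ai, :m] + d[bi, :m] - dij)
        d[bi, :m] = new_row
        d[:m, bi] = new_row
        d[bi, bi] = 0.0
        slot_nodes[bi] = len(nodes) - 1
        last = m - 1
        if ai != last:
            d[ai, :m] = d[last, :m]
            d[:m, ai] = d[:m, last]
            d[ai, ai] = 0.0
            slot_nodes[ai] = slot_nodes[last]
        m -= 1
    # final 3-way join
    i, j, k = slot_nodes[0], slot_nodes[1], slot_nodes[2]
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    bl_i = 0.5 * (d01 + d02 - d12)
    bl_j = 0.5 * (d01 + d12 - d02)
    bl_k = 0.5 * (d02 + d12 - d01)
    bl_i, bl_j, bl_k = (max(b, 0.0) for b in (bl_i, bl_j, bl_k))
    return TreeNode(children=[(nodes[i], bl_i), (nodes[j], bl_j), (nodes[k], bl_k)])


def _clamp_pair(a: float, b: float) -> tuple[float, float]:
    # negative branch clamped to 0, deficit moved to the sister branch
    if a < 0:
        b, a = b + a, 0.0
    if b < 0:
        a, b = max(a + b, 0.0), 0.0
    return a, b


def cut_tree(tree: TreeNode, height: float) -> dict[str, int]:
    """Cluster leaves by removing internal edges longer than ``height``.

    Returns leaf -> cluster id (ids ordered by smallest member label).
    Mirrors reading a dendrogram at a fixed tree scale: long internal
    edges separate clusters, leaves joined by short edges stay together.
    """
    # union-find over leaves, merging across every edge <= height
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    ids: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> int:
        nid = id(node)
        parent.setdefault(nid, nid)
        ids[nid] = node
        for child, bl in node.children:
            cid = walk(child)
            keep_together = child.is_leaf or bl <= height
            if keep_together:
                union(nid, cid)
        return nid

    walk(tree)
    clusters: dict[int, list[str]] = {}
    for nid, node in ids.items():
        if node.is_leaf:
            clusters.setdefault(find(nid), []).append(node.name or "")
    ordered = sorted(clusters.values(), key=lambda ls: min(ls))
    return {leaf: ci for ci, leaves in enumerate(ordered) for leaf in leaves}


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def pca(G: GenotypeMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of the dosage matrix (locus-mean imputation, per-locus centring).

    Returns ``(scores, loadings, variance_fractions)``; scores is an
    accessions x k DataFrame with columns ``PC1..PCk``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(G.n_accessions, G.n_loci):
        raise ValueError(f"k={k} exceeds min(N, L)")
    X = G.dosage_float()
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)  # all-missing locus centres at 0
    X = np.where(np.isnan(X), mu, X) - mu
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s * s))
    varfrac = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-magnitude loading positive
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            vt[c] *= -1
            scores[:, c] *= -1
    df = pd.DataFrame(scores, index=G.accession_ids,
                      columns=[f"PC{i+1}" for i in range(k)])
    df.index.name = "accession"
    return df, vt[:k].T, varfrac
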