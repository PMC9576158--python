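"""Distances, neighbour joining and PCA against analytic and library oracles."""

import itertools
import math

import numpy as np
import pytest

import wildcore as wc
from wildcore import DistanceMatrix

from conftest import make_matrix, random_matrix


# ----------------------------------------------------------------------
# modified Rogers
# ----------------------------------------------------------------------

def test_mr_identical_accessions_zero():
    G = make_matrix([[0, 1, 2], [0, 1, 2]])
    assert wc.modified_rogers_matrix(G).d[0, 1] == 0.0


def test_mr_opposite_homozygotes_is_one():
    G = make_matrix([[0, 0, 0], [2, 2, 2]])
    assert wc.modified_rogers_matrix(G).d[0, 1] == pytest.approx(1.0)


def test_mr_hand_value():
    # dosages (0,0) vs (1,2): sum (x-y)^2 = 1 + 4 = 5 over 4*L = 8
    G = make_matrix([[0, 0], [1, 2]])
    assert wc.modified_rogers_matrix(G).d[0, 1] == pytest.approx(math.sqrt(5 / 8))
    assert wc.modified_rogers_matrix(G).d[0, 1] == pytest.approx(0.7906, abs=1e-4)


def test_mr_pairwise_complete_loci():
    # locus 2 missing in acc2: distance uses locus 1 only
    G = make_matrix([[0, 0], [2, None]])
    assert wc.modified_rogers_matrix(G).d[0, 1] == pytest.approx(1.0)


def test_mr_no_shared_locus_error_names_pair():
    G = make_matrix([[0, None], [None, 2]])
    with pytest.raises(ValueError, match="acc1.*acc2"):
        wc.modified_rogers_matrix(G)


def test_mr_matches_naive_loops_and_triangle_inequality():
    rng = np.random.default_rng(42)
    for _ in range(5):
        G = random_matrix(rng, n=6, l=15, missing_rate=0.0)
        d = wc.modified_rogers_matrix(G).d
        # naive oracle
        for i, j in itertools.combinations(range(6), 2):
            s = sum((int(a) - int(b)) ** 2 for a, b in zip(G.calls[i], G.calls[j]))
            assert d[i, j] == pytest.approx(math.sqrt(s / (4 * G.n_loci)))
        # metric on complete data
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


# ----------------------------------------------------------------------
# Nei distance
# ----------------------------------------------------------------------

def _two_pop_matrix(col_a, col_b):
    ids = [f"a{i}" for i in range(len(col_a))] + [f"b{i}" for i in range(len(col_b))]
    pops = {i: ("A" if i.startswith("a") else "B") for i in ids}
    return make_matrix([[v] for v in col_a + col_b], ids=ids, populations=pops)


def test_nei_zero_for_identical_frequencies():
    pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    G = make_matrix([[0, 1], [2, 1], [0, 1], [2, 1]],
                    ids=list(pops), populations=pops)
    assert wc.nei_distance_matrix(G).d[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_hand_value_single_locus():
    # p1 = 0.8 (dosages 2,2,1,1,2 over 5 -> 8/10), p2 = 0.3 (3/10)
    G = _two_pop_matrix([2, 2, 1, 1, 2], [1, 1, 1, 0, 0])
    d = wc.nei_distance_matrix(G).d[0, 1]
    ident = (0.8 * 0.3 + 0.2 * 0.7) / math.sqrt((0.64 + 0.04) * (0.09 + 0.49))
    assert ident == pytest.approx(0.6051, abs=1e-4)
    assert d == pytest.approx(-math.log(ident))
    assert d == pytest.approx(0.5024, abs=1e-4)


def test_nei_opposite_fixation_capped(caplog):
    G = _two_pop_matrix([0, 0], [2, 2])
    with caplog.at_level("WARNING"):
        d = wc.nei_distance_matrix(G, cap=10.0)
    assert d.d[0, 1] == 10.0


def test_nei_invariant_to_allele_label_swap():
    rng = np.random.default_rng(9)
    pops = {f"x{i}": ("A" if i < 5 else "B") for i in range(10)}
    G = random_matrix(rng, n=10, l=12, missing_rate=0.1, populations=None)
    G = wc.attach_populations(G, dict(zip(G.accession_ids, pops.values())))
    d0 = wc.nei_distance_matrix(G).d
    flipped = G.calls.copy()
    col = flipped[:, 3]
    col[col >= 0] = 2 - col[col >= 0]  # swap ref/alt at locus 4
    G2 = make_matrix(flipped.tolist(), ids=G.accession_ids, populations=G.populations)
    np.testing.assert_allclose(wc.nei_distance_matrix(G2).d, d0, atol=1e-12)


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------

ADDITIVE4 = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float),
)


def test_nj_four_taxon_additive_exact():
    tree = wc.neighbor_joining(ADDITIVE4)
    pd = tree.leaf_distances()
    np.testing.assert_allclose(
        pd.loc[ADDITIVE4.labels, ADDITIVE4.labels].to_numpy(), ADDITIVE4.d, atol=1e-9
    )
    # topology AB|CD with branches A:2 B:3 internal:1 C:4 D:5
    nwk = tree.to_newick()
    assert "(A:2,B:3)" in nwk.replace(" ", "")


def test_nj_three_taxa_two_point_equations():
    D = DistanceMatrix(["x", "y", "z"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = wc.neighbor_joining(D)
    bl = {c.name: l for c, l in tree.children}
    assert bl["x"] == pytest.approx(0.5 * (3 + 4 - 5))
    assert bl["y"] == pytest.approx(0.5 * (3 + 5 - 4))
    assert bl["z"] == pytest.approx(0.5 * (4 + 5 - 3))


def test_nj_rejects_fewer_than_three():
    with pytest.raises(ValueError):
        wc.neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_nj_equidistant_tie_breaks_deterministically():
    D = DistanceMatrix(["d", "c", "b", "a"], np.ones((4, 4)) - np.eye(4))
    t1 = wc.neighbor_joining(D).to_newick()
    t2 = wc.neighbor_joining(D).to_newick()
    assert t1 == t2
    # lexicographically smallest label pair (a, b) joins first
    assert "(b:0.5,a:0.5)" in t1 or "(a:0.5,b:0.5)" in t1


def test_nj_label_permutation_invariance():
    rng = np.random.default_rng(5)
    # random additive matrix from a random tree via random leaf heights
    base = wc.neighbor_joining(ADDITIVE4)
    perm = [2, 0, 3, 1]
    D2 = DistanceMatrix([ADDITIVE4.labels[i] for i in perm],
                        ADDITIVE4.d[np.ix_(perm, perm)])
    pd1 = wc.neighbor_joining(ADDITIVE4).leaf_distances()
    pd2 = wc.neighbor_joining(D2).leaf_distances()
    np.testing.assert_allclose(pd1.to_numpy(), pd2.loc[pd1.index, pd1.columns].to_numpy(),
                               atol=1e-9)


def test_nj_additive_five_taxa_matches_skbio():
    """Cross-check against scikit-bio's independent NJ on an additive matrix."""
    skbio = pytest.importorskip("skbio")
    # additive matrix from the known 5-leaf tree ((a:1,b:2):1.5,(c:0.5,d:1):2,e:3)
    labels = ["a", "b", "c", "d", "e"]
    coords = {
        "a": ("u", 1.0), "b": ("u", 2.0), "c": ("v", 0.5), "d": ("v", 1.0),
        "e": ("r", 3.0),
    }
    up = {"u": 1.5, "v": 2.0}

    def dist(x, y):
        nx, dx = coords[x]
        ny, dy = coords[y]
        if nx == ny:
            return dx + dy
        tx = dx + (up[nx] if nx != "r" else 0)
        ty = dy + (up[ny] if ny != "r" else 0)
        return tx + ty

    d = np.zeros((5, 5))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                d[i, j] = dist(x, y)
    D = DistanceMatrix(labels, d)
    mine = wc.neighbor_joining(D).leaf_distances()
    np.testing.assert_allclose(mine.loc[labels, labels].to_numpy(), d, atol=1e-9)
    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
    ref_d = ref.tip_tip_distances(labels)
    np.testing.assert_allclose(mine.loc[labels, labels].to_numpy(), ref_d.data, atol=1e-6)


def test_cut_tree_separates_long_edges():
    tree = wc.neighbor_joining(ADDITIVE4)
    one_cluster = wc.cut_tree(tree, height=10)
    assert len(set(one_cluster.values())) == 1
    fine = wc.cut_tree(tree, height=0.5)  # internal edge (length 1) cut
    assert fine["A"] == fine["B"]
    assert fine["A"] != fine["C"]


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def test_pca_identical_rows_zero_variance():
    G = make_matrix([[1, 0, 2]] * 5)
    _, _, varfrac = wc.pca(G, 2)
    np.testing.assert_allclose(varfrac, 0.0, atol=1e-12)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    G = random_matrix(rng, n=6, l=8, missing_rate=0.0)
    scores, loadings, varfrac = wc.pca(G, 3)
    X = G.calls.astype(float)
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    np.testing.assert_allclose(np.abs(scores.to_numpy()),
                               np.abs(Xc @ evecs[:, :3]), atol=1e-8)
    np.testing.assert_allclose(varfrac, evals[:3] / evals.sum(), atol=1e-10)
    assert np.all(np.diff(varfrac) <= 1e-12) and varfrac.sum() <= 1 + 1e-12


def test_pca_separates_simulated_demes():
    from sklearn.metrics import silhouette_score

    cfg = wc.SimulationConfig(deme_labels=["A", "B"], deme_sizes=[40, 40],
                              n_loci=300, fst=0.3, rng_seed=12)
    G, _ = wc.simulate(cfg)
    scores, _, _ = wc.pca(G, 2)
    labels = [G.populations[a] for a in scores.index]
    assert silhouette_score(scores[["PC1"]], labels) > 0.5


def test_pca_k_validation(toy_matrix):
    with pytest.raises(ValueError):
        wc.pca(toy_matrix, 0)
    with pytest.raises(ValueError):
        wc.pca(toy_matrix, 99)
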