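"""Distances, neighbor joining, bootstrap, consensus and tree comparison.

Independent oracles: tree-additive matrices (NJ must be exact), dendropy for
Robinson-Foulds and bipartition counting, closed forms for distances.
"""

from collections import Counter

import dendropy
import numpy as np
import pytest

from qsoxphylo.align import Alignment
from qsoxphylo.models import AA_ORDER, get_model
from qsoxphylo.phylo import (DistanceMatrix, bipartition_frequencies,
                             bootstrap_columns, concat_alignments, consensus,
                             distance_matrix, nj_tree, pairwise_distance,
                             pairwise_distance_full, rf_distance)
from qsoxphylo.simulate import caterpillar_tree, simulate_yule_tree
from qsoxphylo.trees import Tree


def dendropy_rf(t1: Tree, t2: Tree) -> int:
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                           taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


# ---------------------------------------------------------------------------
# substitution models


def test_model_transition_matrices_are_stochastic():
    for name in ("proportional", "dayhoff", "jtt"):
        m = get_model(name)
        assert m.pi.sum() == pytest.approx(1.0)
        for t in (0.0, 0.1, 1.0, 5.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(20), atol=1e-10)
        # reversibility: detailed balance pi_a P_ab = pi_b P_ba
        P = m.transition_matrix(0.7)
        F = m.pi[:, None] * P
        assert np.allclose(F, F.T, atol=1e-10)


def test_unknown_model_name():
    with pytest.raises(ValueError, match="unknown"):
        get_model("wag19")


# ---------------------------------------------------------------------------
# pairwise distances


def test_proportional_closed_form_at_p_019():
    row_a = "A" * 100
    row_b = "C" * 19 + "A" * 81
    d = pairwise_distance(row_a, row_b, "proportional")
    assert d == pytest.approx(-0.95 * np.log(0.8), abs=1e-12)


def test_identical_rows_have_zero_distance_under_every_model():
    row = "ACDEFGHIKLMNPQRSTVWY" * 3
    for name in ("proportional", "dayhoff", "jtt"):
        assert pairwise_distance(row, row, name) == 0.0


def test_gapped_and_unknown_sites_are_excluded():
    a = "AAAA-XAA"
    b = "AACC CCAA".replace(" ", "")[:8]
    b = "AACCCCAA"
    res = pairwise_distance_full(a, b, "proportional")
    assert res.n_sites == 6  # two columns dropped


def test_all_gap_rows_raise():
    with pytest.raises(ValueError, match="usable"):
        pairwise_distance("----", "AAAA", "proportional")


def test_saturated_pair_returns_cap_with_flag():
    res = pairwise_distance_full("A" * 50, "C" * 50, "proportional", cap=10.0)
    assert res.value == 10.0 and res.saturated


def test_jtt_distance_recovers_simulated_divergence():
    """Parameter recovery: sequences simulated at d=0.3 under JTT."""
    m = get_model("jtt")
    rng = np.random.default_rng(17)
    P = m.transition_matrix(0.3)
    cum = np.cumsum(P, axis=1)
    ests = []
    for _ in range(5):
        anc = rng.choice(20, size=5000, p=m.pi)
        child = (rng.random(5000)[:, None] > cum[anc]).sum(axis=1)
        ra = "".join(AA_ORDER[i] for i in anc)
        rb = "".join(AA_ORDER[i] for i in child)
        ests.append(pairwise_distance(ra, rb, "jtt"))
    assert np.mean(ests) == pytest.approx(0.3, abs=0.03)


def test_distance_error_decreases_with_length():
    m = get_model("jtt")
    errs = {}
    for L in (200, 20000):
        rng = np.random.default_rng(3)
        P = m.transition_matrix(0.4)
        cum = np.cumsum(P, axis=1)
        devs = []
        for _ in range(8):
            anc = rng.choice(20, size=L, p=m.pi)
            child = (rng.random(L)[:, None] > cum[anc]).sum(axis=1)
            d = pairwise_distance("".join(AA_ORDER[i] for i in anc),
                                  "".join(AA_ORDER[i] for i in child), "jtt")
            devs.append(abs(d - 0.4))
        errs[L] = np.mean(devs)
    assert errs[20000] < errs[200]


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_recovers_worked_additive_example():
    # planted tree ((A:1,B:2):1,C:3,D:4)
    labels = ["A", "B", "C", "D"]
    D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float)
    t = nj_tree(DistanceMatrix(labels, D))
    # the single split AB|CD, canonically encoded as the side without 'A'
    assert t.bipartitions() == {frozenset("CD")}
    pat = t.patristic()
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            assert pat[(a, b)] == pytest.approx(D[labels.index(a),
                                                  labels.index(b)], abs=1e-12)


def test_nj_three_taxa_exact_lengths():
    D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    t = nj_tree(DistanceMatrix(["A", "B", "C"], D))
    lengths = {n.name: n.length for n in t.root.children}
    assert lengths["A"] == pytest.approx(0.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


@pytest.mark.parametrize("seed", range(10))
def test_nj_exact_on_random_additive_matrices(seed):
    """NJ consistency: additive input -> planted topology and lengths."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    planted = simulate_yule_tree(n, 1.0, seed=seed + 100)
    pat = planted.patristic()
    labels = sorted(planted.leaf_set)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = pat[(a, b)]
    recovered = nj_tree(DistanceMatrix(labels, D))
    assert rf_distance(recovered, planted) == 0
    rp = recovered.patristic()
    for key, v in pat.items():
        assert rp[key] == pytest.approx(v, abs=1e-9)


def test_nj_determinism():
    rng = np.random.default_rng(0)
    n = 9
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"t{i}" for i in range(n)]
    t1 = nj_tree(DistanceMatrix(labels, D))
    t2 = nj_tree(DistanceMatrix(labels, D))
    assert t1.newick() == t2.newick()


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"], D)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_width_one_replicates_equal_input():
    msa = Alignment(["a", "b"], ["M", "K"])
    for rep in bootstrap_columns(msa, 5, seed=1):
        assert rep.rows == msa.rows


def test_bootstrap_determinism_and_shape():
    msa = Alignment(["a", "b", "c"], ["MKLVA", "MKLVC", "MRLVA"])
    r1 = bootstrap_columns(msa, 10, seed=9)
    r2 = bootstrap_columns(msa, 10, seed=9)
    assert [x.rows for x in r1] == [x.rows for x in r2]
    assert all(rep.width == msa.width for rep in r1)


def test_bootstrap_column_counts_match_multinomial_expectation():
    msa = Alignment(["a"], ["ACDEFGHIKL"])  # 10 distinct columns
    reps = bootstrap_columns(msa, 2000, seed=4)
    counts = Counter("".join(rep.rows[0] for rep in reps))
    for c in "ACDEFGHIKL":
        assert counts[c] / 2000 == pytest.approx(1.0, abs=0.08)


def test_bootstrap_empty_alignment_raises():
    with pytest.raises(ValueError):
        bootstrap_columns(Alignment([], []), 3, seed=0)


# ---------------------------------------------------------------------------
# consensus


def _t(nwk: str) -> Tree:
    return Tree.from_newick(nwk, rooted=False)


def test_consensus_of_identical_trees_has_full_support():
    trees = [_t("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(10)]
    c = consensus(trees, "majority")
    assert rf_distance(c, trees[0]) == 0
    assert set(c.clade_supports().values()) == {100}


def test_two_of_three_bipartition_gets_support_67():
    trees = [_t("((A:1,B:1):1,C:1,D:1);"), _t("((A:1,B:1):1,C:1,D:1);"),
             _t("((A:1,C:1):1,B:1,D:1);")]
    c = consensus(trees, "majority")
    sup = c.clade_supports()
    assert len(sup) == 1
    assert list(sup.values()) == [67]


def test_strict_vs_majority_rules():
    trees = [_t("((A:1,B:1):1,C:1,D:1);"), _t("((A:1,B:1):1,C:1,D:1);"),
             _t("((A:1,C:1):1,B:1,D:1);")]
    assert consensus(trees, "strict").bipartitions() == set()
    assert len(consensus(trees, "majority_extended").bipartitions()) == 1


def test_majority_extended_adds_compatible_minority_bipartitions():
    trees = [_t("(((A:1,B:1):1,C:1):1,D:1,E:1);"),
             _t("(((A:1,B:1):1,C:1):1,D:1,E:1);"),
             _t("((A:1,B:1):1,(C:1,D:1):1,E:1);"),
             _t("((A:1,C:1):1,(B:1,D:1):1,E:1);")]
    ext = consensus(trees, "majority_extended")
    maj = consensus(trees, "majority")
    assert maj.bipartitions() < ext.bipartitions()


@pytest.mark.parametrize("seed", range(5))
def test_bipartition_frequencies_match_brute_force(seed):
    """Counting oracle: dendropy-derived bipartition multiset."""
    rng = np.random.default_rng(seed)
    trees = [simulate_yule_tree(6, 1.0, seed=int(rng.integers(2**31)))
             for _ in range(7)]
    freqs = bipartition_frequencies(trees)
    # oracle: count splits via dendropy leaf-set encodings
    counter = Counter()
    tns = dendropy.TaxonNamespace()
    all_leaves = trees[0].leaf_set
    ref = min(all_leaves)
    for t in trees:
        dt = dendropy.Tree.get(data=t.newick(), schema="newick",
                               taxon_namespace=tns)
        dt.encode_bipartitions()
        for edge in dt.preorder_edge_iter():
            bp = edge.bipartition
            if bp is None:
                continue
            side = {x.label for x in tns
                    if bp.leafset_bitmask & tns.taxon_bitmask(x)}
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = frozenset(all_leaves - side if ref in side else side)
                counter[canon] += 1
    # dendropy iterates each edge once; trivial splits were filtered
    expected = {bp: c / len(trees) for bp, c in counter.items()}
    assert freqs == expected


def test_consensus_leafset_mismatch_raises():
    with pytest.raises(ValueError):
        consensus([_t("((A:1,B:1):1,C:1,D:1);"),
                   _t("((A:1,B:1):1,C:1,E:1);")])


# ---------------------------------------------------------------------------
# Robinson-Foulds


def test_rf_identical_and_disjoint_quartets():
    t1 = _t("((A:1,B:1):1,C:1,D:1);")
    t2 = _t("((A:1,C:1):1,B:1,D:1);")
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2


@pytest.mark.parametrize("seed", range(8))
def test_rf_agrees_with_dendropy_and_respects_bound(seed):
    n = 8 + seed % 4
    t1 = simulate_yule_tree(n, 1.0, seed=seed)
    t2 = simulate_yule_tree(n, 1.0, seed=seed + 50)
    rf = rf_distance(t1, t2)
    assert rf == dendropy_rf(t1, t2)
    assert 0 <= rf <= 2 * (n - 3) + 2  # rooted trees carry one extra split


def test_rf_leaf_mismatch_raises():
    with pytest.raises(ValueError):
        rf_distance(simulate_yule_tree(5, 1, 0), simulate_yule_tree(6, 1, 0))


# ---------------------------------------------------------------------------
# concatenation


def test_concat_widths_and_roundtrip():
    a = Alignment(["x", "y"], ["MK-V", "MKLV"])
    b = Alignment(["y", "x"], ["DE", "D-"])
    cat = concat_alignments(a, b)
    assert cat.width == 6
    assert cat.meta["blocks"] == [(0, 4), (4, 6)]
    assert cat.degapped("x") == "MKV" + "D"
    assert cat.degapped("y") == "MKLV" + "DE"


def test_concat_disjoint_ids_raise_and_lenient_drops():
    a = Alignment(["x"], ["MK"])
    b = Alignment(["y"], ["DE"])
    with pytest.raises(ValueError):
        concat_alignments(a, b)
    c = Alignment(["x", "z"], ["MK", "ML"])
    d = Alignment(["x"], ["DE"])
    cat = concat_alignments(c, d, lenient=True)
    assert cat.ids == ["x"]


def test_concatenated_family_recovers_planted_topology():
    """Concordant domains concatenated -> NJ recovers the planted tree."""
    from qsoxphylo.simulate import simulate_alignment
    labels = [f"s{i:02d}" for i in range(10)]
    planted = caterpillar_tree(labels, internal=0.1, terminal=0.1)
    m1 = simulate_alignment(planted, 300, "jtt", seed=1)
    m2 = simulate_alignment(planted, 300, "jtt", seed=2)
    cat = concat_alignments(m1, m2)
    t = nj_tree(distance_matrix(cat, "jtt"))
    assert rf_distance(t, planted) == 0
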