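import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from oracles import conservation_tally
from ptbscan.errors import AlignmentError, ParameterError
from ptbscan.msa_phylo import (
    annotate_conservation,
    midpoint_root,
    nj_tree,
    pdistance_matrix,
    read_newick,
    write_newick,
)
from ptbscan.seq_io import alignment_from_strings
from ptbscan.synthetic import gen_additive_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- conservation ---------------------------------------------------------

def test_conservation_all_identical_column():
    aln = alignment_from_strings([("ref1", "K"), ("ref2", "K"), ("o1", "K"), ("o2", "K")], "protein")
    ann = annotate_conservation(aln, ("ref1", "ref2"))
    assert ann.categories["o1"] == ["reference-identical"]
    assert ann.categories["o2"] == ["reference-identical"]


def test_conservation_shared_and_nonconserved():
    aln = alignment_from_strings(
        [("ref1", "K"), ("ref2", "K"), ("o1", "R"), ("o2", "R"), ("o3", "Q")], "protein"
    )
    ann = annotate_conservation(aln, ("ref1", "ref2"))
    assert ann.categories["o1"] == ["shared-in-≥2"]
    assert ann.categories["o2"] == ["shared-in-≥2"]
    assert ann.categories["o3"] == ["nonconserved"]


def test_conservation_disagreeing_references_flag_ambiguous():
    aln = alignment_from_strings([("ref1", "K"), ("ref2", "R"), ("o1", "R"), ("o2", "Q")], "protein")
    ann = annotate_conservation(aln, ("ref1", "ref2"))
    assert ann.categories["o1"] == ["reference-identical"]
    assert ann.ambiguous["o1"] == [True]
    assert ann.categories["o2"] == ["nonconserved"]


def test_conservation_gaps_nonconserved_and_partition():
    aln = alignment_from_strings([("ref1", "K-"), ("ref2", "K-"), ("o1", "-K"), ("o2", "KK")], "protein")
    ann = annotate_conservation(aln, ("ref1", "ref2"))
    assert ann.categories["o1"][0] == "nonconserved"
    counts = ann.counts()
    assert sum(counts.values()) == 2 * aln.length  # every annotated cell categorized


def test_conservation_matches_brute_force_tally():
    rng = np.random.default_rng(31)
    ids = ["ref1", "ref2", "o1", "o2", "o3", "o4"]
    for _ in range(30):
        L = int(rng.integers(5, 40))
        rows = {}
        for rid in ids:
            rows[rid] = "".join(
                "-" if rng.random() < 0.1 else rng.choice(list(AA[:6])) for _ in range(L)
            )
        aln = alignment_from_strings([(i, rows[i]) for i in ids], "protein")
        ann = annotate_conservation(aln, ("ref1", "ref2"))
        columns = [{i: rows[i][j] for i in ids} for j in range(L)]
        expected = conservation_tally(columns, ("ref1", "ref2"))
        for rid in ["o1", "o2", "o3", "o4"]:
            assert ann.categories[rid] == [expected[j][rid] for j in range(L)]


def test_conservation_reference_validation():
    aln = alignment_from_strings([("a", "K"), ("b", "K"), ("c", "K")], "protein")
    with pytest.raises(AlignmentError):
        annotate_conservation(aln, ("a", "zz"))
    with pytest.raises(ParameterError):
        annotate_conservation(aln, ("a",))


# --- distances ------------------------------------------------------------

def test_pdistance_examples():
    aln = alignment_from_strings([("a", "KKKKKKKKKK"), ("b", "KKKKKKKKKR")], "protein")
    dm = pdistance_matrix(aln)
    assert dm["a", "b"] == pytest.approx(0.1)
    dmp = pdistance_matrix(aln, correction="poisson")
    assert dmp["a", "b"] == pytest.approx(-math.log(0.9))
    ident = alignment_from_strings([("a", "MKWV"), ("b", "MKWV")], "protein")
    assert pdistance_matrix(ident)["a", "b"] == 0.0


def test_pdistance_gap_handling_and_errors():
    aln = alignment_from_strings([("a", "K-KK"), ("b", "KR-K")], "protein")
    # compared columns: 0 and 3 only
    assert pdistance_matrix(aln)["a", "b"] == 0.0
    disjoint = alignment_from_strings([("a", "K--"), ("b", "--K"), ("c", "KKK")], "protein")
    with pytest.raises(AlignmentError, match="a.*b"):
        pdistance_matrix(disjoint)


def test_poisson_correction_dominates_p():
    rng = np.random.default_rng(17)
    ancestor = rng.choice(list(AA), size=60)
    rows = []
    for rid in "abcd":
        row = ancestor.copy()
        for p in rng.choice(60, size=25, replace=False):
            row[p] = rng.choice(list(AA))
        rows.append((rid, "".join(row)))
    aln = alignment_from_strings(rows, "protein")
    p = pdistance_matrix(aln)
    pc = pdistance_matrix(aln, correction="poisson")
    for i in "abcd":
        for j in "abcd":
            if i != j:
                assert 0 <= p[i, j] <= 1
                assert pc[i, j] >= p[i, j]


# --- NJ -------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float), ids=list("ABC"))
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0), "C": pytest.approx(4.0)}


def test_nj_recovers_additive_trees_exactly():
    """On additive matrices NJ reconstructs topology (RF 0) and branch lengths."""
    for seed in range(40):
        true_tree, dm, _ = gen_additive_tree(8, seed=seed)
        est = nj_tree(dm)
        assert est.compare_rfd(true_tree) == 0.0
        got = est.tip_tip_distances(list(dm.ids))
        assert np.allclose(got.data, dm.data, atol=1e-9)


def test_nj_identical_taxa_zero_cherry():
    dm = DistanceMatrix(
        np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], dtype=float), ids=list("ABC")
    )
    tree = nj_tree(dm)
    a = tree.find("A")
    b = tree.find("B")
    assert a.length == 0.0 and b.length == 0.0


def test_nj_input_validation():
    with pytest.raises(ParameterError):
        nj_tree(DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=list("AB")))


# --- midpoint rooting -----------------------------------------------------

def test_midpoint_two_leaf_definition():
    tree = read_newick("(A:2,B:4);")
    rooted = midpoint_root(tree)
    depths = {t.name: rooted.distance(t) for t in rooted.tips()}
    assert depths["A"] == pytest.approx(3.0)
    assert depths["B"] == pytest.approx(3.0)


def _deepest_per_child(rooted):
    out = []
    for child in rooted.children:
        base = child.length or 0.0
        if child.children:
            out.append(max(base + child.distance(t) for t in child.tips()))
        else:
            out.append(base)
    return out


def test_midpoint_balances_random_trees():
    """The two sides of the root reach equally deep (verified against path enumeration)."""
    for seed in range(40):
        tree, dm, _ = gen_additive_tree(int(5 + seed % 6), seed=seed)
        rooted = midpoint_root(nj_tree(dm))
        sides = sorted(_deepest_per_child(rooted))
        diameter = max(dm.data.flatten())
        assert abs(sides[-1] - sides[-2]) < 1e-9
        assert sides[-1] == pytest.approx(diameter / 2)


def test_midpoint_tie_break_is_lexicographic():
    # two equal diameters: (A,B) and (A,C) both length 10; sorted pair (A,B) wins
    tree = read_newick("((B:5,C:5):1,A:4);")
    rooted = midpoint_root(tree)
    depths = {t.name: rooted.distance(t) for t in rooted.tips()}
    assert depths["A"] == pytest.approx(5.0)
    assert depths["B"] == pytest.approx(5.0)


def test_midpoint_all_zero_lengths_roots_arbitrarily():
    tree = read_newick("((A:0,B:0):0,C:0);")
    rooted = midpoint_root(tree)
    assert {t.name for t in rooted.tips()} == {"A", "B", "C"}


# --- newick ---------------------------------------------------------------

def test_newick_round_trip_topology_and_lengths():
    for seed in range(10):
        tree, dm, _ = gen_additive_tree(7, seed=seed)
        text = write_newick(tree)
        back = read_newick(text)
        assert back.compare_rfd(tree) == 0.0
        assert np.allclose(
            back.tip_tip_distances(list(dm.ids)).data,
            tree.tip_tip_distances(list(dm.ids)).data,
        )


def test_newick_metacharacter_labels_quoted():
    tree, _, _ = gen_additive_tree(3, seed=0)
    for tip, name in zip(tree.tips(), ["needs space", "paren(label", "plain"]):
        tip.name = name
    text = write_newick(tree)
    back = read_newick(text)
    assert {t.name for t in back.tips()} == {"needs space", "paren(label", "plain"}


def test_unrooted_three_leaf_tree_trifurcates():
    tree, _, _ = gen_additive_tree(3, seed=1)
    assert len(tree.children) == 3
    text = write_newick(tree)
    assert text.count("(") == 1
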