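"""Distances, neighbor joining, grouping, consensus, discrete gamma."""

import itertools
import math

import numpy as np
import pytest

from wrkykit.phylo import (
    AlignedBlock,
    ConsensusTier,
    DistanceMatrix,
    DistanceModel,
    PhyloTree,
    UndefinedDistanceError,
    assign_groups,
    consensus_motif,
    discrete_gamma_rates,
    fit_gamma_alpha,
    group_overlap_report,
    neighbor_joining,
    pairwise_distances,
    read_alignment,
)
from wrkykit.synthetic_data import generate_labeled_families


def test_identical_rows_distance_zero():
    block = AlignedBlock(ids=["a", "b"], rows=["WRKYGQKACD", "WRKYGQKACD"])
    dm = pairwise_distances(block)
    assert dm.matrix[0, 1] == 0.0


def test_p_and_poisson_closed_form():
    block = AlignedBlock(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAAAAACC"])
    p = pairwise_distances(block, model=DistanceModel.P_DISTANCE).matrix[0, 1]
    assert p == pytest.approx(0.2)
    poisson = pairwise_distances(block, model=DistanceModel.POISSON).matrix[0, 1]
    assert poisson == pytest.approx(-math.log(0.8), abs=1e-12)


def test_saturated_pair_rejected_under_poisson():
    block = AlignedBlock(ids=["a", "b"], rows=["AAAA", "CCCC"])
    with pytest.raises(UndefinedDistanceError, match=r"\(a, b\)"):
        pairwise_distances(block, model=DistanceModel.POISSON)


def test_site_coverage_filter_removes_gappy_columns():
    # first column has 2/3 coverage: dropped at 0.95; the mismatch there
    # must not contribute
    block = AlignedBlock(ids=["a", "b", "c"], rows=["-AAA", "CAAA", "GAAA"])
    dm = pairwise_distances(block, model=DistanceModel.P_DISTANCE)
    assert np.all(dm.matrix == 0.0)


# ---------------------------------------------------------------------------
# neighbor joining

def _tree_distance_matrix(adj, leaves):
    n = len(leaves)
    D = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, other in enumerate(leaves):
            D[i, j] = dist[other]
    return D


def test_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(ids=ids, matrix=D, model=DistanceModel.P_DISTANCE))
    labels, P = tree.path_length_matrix()
    order = [labels.index(i) for i in ids]
    assert np.allclose(P[np.ix_(order, order)], D, atol=1e-12)


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree: (a:0.1, b:0.2)----0.3----(c:0.4, d:0.5)
    adj = {
        "a": {"u": 0.1}, "b": {"u": 0.2}, "c": {"v": 0.4}, "d": {"v": 0.5},
        "u": {"a": 0.1, "b": 0.2, "v": 0.3}, "v": {"c": 0.4, "d": 0.5, "u": 0.3},
    }
    leaves = ["a", "b", "c", "d"]
    D = _tree_distance_matrix(adj, leaves)
    tree = neighbor_joining(DistanceMatrix(ids=leaves, matrix=D, model=DistanceModel.P_DISTANCE))
    labels, P = tree.path_length_matrix()
    order = [labels.index(i) for i in leaves]
    assert np.allclose(P[np.ix_(order, order)], D, atol=1e-12)
    # four-point condition sanity on the input itself
    assert D[0, 1] + D[2, 3] <= max(D[0, 2] + D[1, 3], D[0, 3] + D[1, 2])


def test_all_fifteen_five_taxon_topologies_recovered():
    """NJ is exact on additive matrices: every unrooted 5-leaf topology."""
    leaves = list("abcde")
    rng = np.random.default_rng(1)
    seen = set()
    # every 5-leaf unrooted binary tree has two cherries: choose them
    for cherry1 in itertools.combinations(leaves, 2):
        rest = [x for x in leaves if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            key = frozenset([frozenset(cherry1), frozenset(cherry2)])
            if key in seen:
                continue
            seen.add(key)
            (e,) = [x for x in rest if x not in cherry2]
            bl = rng.uniform(0.05, 1.0, size=7)
            adj = {
                cherry1[0]: {"u": bl[0]}, cherry1[1]: {"u": bl[1]},
                cherry2[0]: {"v": bl[2]}, cherry2[1]: {"v": bl[3]},
                e: {"w": bl[4]},
                "u": {cherry1[0]: bl[0], cherry1[1]: bl[1], "w": bl[5]},
                "v": {cherry2[0]: bl[2], cherry2[1]: bl[3], "w": bl[6]},
                "w": {e: bl[4], "u": bl[5], "v": bl[6]},
            }
            D = _tree_distance_matrix(adj, leaves)
            tree = neighbor_joining(
                DistanceMatrix(ids=leaves, matrix=D, model=DistanceModel.P_DISTANCE)
            )
            labels, P = tree.path_length_matrix()
            order = [labels.index(i) for i in leaves]
            assert np.allclose(P[np.ix_(order, order)], D, atol=1e-9)
    assert len(seen) == 15


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(5)
    block, _, _, _ = generate_labeled_families(3, 0.05, 0.5, n_per_group=3, seed=2)
    dm = pairwise_distances(block)
    tree1 = neighbor_joining(dm)
    perm = rng.permutation(len(dm.ids))
    dm2 = DistanceMatrix(
        ids=[dm.ids[i] for i in perm],
        matrix=dm.matrix[np.ix_(perm, perm)],
        model=dm.model,
    )
    tree2 = neighbor_joining(dm2)
    splits1 = {s for s, _ in tree1.splits() if 1 < len(s) < len(dm.ids) - 1}
    splits2 = {s for s, _ in tree2.splits() if 1 < len(s) < len(dm.ids) - 1}
    assert splits1 == splits2


def test_asymmetric_matrix_rejected():
    m = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(ids=["a", "b"], matrix=m, model=DistanceModel.P_DISTANCE)


def test_newick_round_trip_preserves_splits_and_lengths():
    block, _, _, _ = generate_labeled_families(3, 0.05, 0.5, n_per_group=3, seed=4)
    tree = neighbor_joining(pairwise_distances(block))
    back = PhyloTree.from_newick(tree.to_newick())
    l1, P1 = tree.path_length_matrix()
    l2, P2 = back.path_length_matrix()
    assert l1 == l2
    assert np.allclose(P1, P2, atol=1e-6)


def test_read_alignment_fasta_and_clustal(tmp_path):
    fa = tmp_path / "a.afa"
    fa.write_text(">s1\nWRKY-QK\n>s2\nWRKYGQK\n")
    block = read_alignment(fa)
    assert block.ids == ["s1", "s2"] and block.n_sites == 7
    cl = tmp_path / "a.aln"
    cl.write_text("CLUSTAL W (1.82) multiple sequence alignment\n\n"
                  "s1   WRKY-QK\ns2   WRKYGQK\n")
    block2 = read_alignment(cl)
    assert block2.rows == block.rows


# ---------------------------------------------------------------------------
# group assignment

def test_query_sister_to_labeled_leaf_inherits_group():
    tree = PhyloTree.from_newick("((query:0.1,ref1:0.1):0.5,(ref2:0.1,ref3:0.1):0.5);")
    assignment = assign_groups(tree, {"ref1": "I", "ref2": "II", "ref3": "II"})
    assert assignment.labels["query"] == "I"
    assert not assignment.conflicts


def test_query_inside_mixed_clade_is_unassigned():
    tree = PhyloTree.from_newick("((query:0.1,ref1:0.1):0.1,(ref2:0.1,x:0.1):0.1);")
    # every enclosing side mixes I and II
    assignment = assign_groups(
        tree, {"ref1": "I", "ref2": "II", "x": "I"}
    )
    # smallest unanimous side for query is {query, ref1} -> I
    assert assignment.labels["query"] == "I"
    tree2 = PhyloTree.from_newick("(((q:0.1,r1:0.1):0.1,r2:0.1):0.1,(r3:0.1,r4:0.1):0.1);")
    a2 = assign_groups(tree2, {"r1": "I", "r2": "II", "r3": "I", "r4": "II"})
    assert a2.labels["q"] == "I"  # sister r1 is unanimous at the cherry


def test_fully_mixed_neighborhood_flags_conflict():
    # q's smallest non-empty sides always contain both I and II
    tree = PhyloTree.from_newick(
        "((q:0.1,(r1:0.1,r2:0.1):0.1):0.1,(r3:0.1,r4:0.1):0.1);"
    )
    a = assign_groups(tree, {"r1": "I", "r2": "II", "r3": "I", "r4": "II"})
    assert a.labels["q"] == "UNASSIGNED"
    assert a.conflicts == {"q"}


def test_assignment_invariant_to_serialization_rerooting():
    block, refs, truth, _ = generate_labeled_families(4, 0.05, 0.5, seed=11)
    tree = neighbor_joining(pairwise_distances(block))
    a1 = assign_groups(tree, refs)
    a2 = assign_groups(PhyloTree.from_newick(tree.to_newick()), refs)
    assert a1.labels == a2.labels


def test_no_labeled_leaves_is_configuration_error():
    tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
    with pytest.raises(ValueError, match="no labelled"):
        assign_groups(tree, {})


def test_overlap_report_flags_multi_group_families():
    from wrkykit.phylo import GroupAssignment

    assignment = GroupAssignment(
        labels={"a": "I", "b": "II", "c": "I", "d": "UNASSIGNED"}
    )
    report = group_overlap_report(assignment, {"a": 5, "b": 5, "c": 46, "d": 46})
    assert report == {5: {"I", "II"}}
    assert group_overlap_report(assignment, {"a": 1, "b": 2, "c": 3}) == {}


# ---------------------------------------------------------------------------
# consensus

def test_consensus_tiers_definitions():
    # col 0: 10/10 W (HIGH); col 1: 6/10 K (LOW); col 2: 4/10 plurality (NONE)
    third = ["A", "A", "A", "A", "C", "C", "C", "G", "G", "G"]
    block = AlignedBlock(
        ids=[f"s{i}" for i in range(10)],
        rows=["W" + ("K" if i < 6 else "R") + third[i] for i in range(10)],
    )
    result = consensus_motif(block)
    assert (result.symbols[0], result.tiers[0]) == ("W", ConsensusTier.HIGH)
    assert (result.symbols[1], result.tiers[1]) == ("K", ConsensusTier.LOW)
    assert result.tiers[2] is ConsensusTier.NONE


def test_gap_never_reported_as_consensus():
    block = AlignedBlock(ids=["a", "b", "c"], rows=["-A", "-A", "CA"])
    result = consensus_motif(block)
    assert result.symbols[0] == "C"
    assert result.tiers[0] is ConsensusTier.NONE  # 1/3 < 0.5


def test_raising_high_threshold_never_grows_high_set():
    block, _, _, _ = generate_labeled_families(2, 0.2, 0.4, seq_length=100, seed=6)
    lo = consensus_motif(block, high=0.80)
    hi = consensus_motif(block, high=0.95)
    high_lo = {i for i, t in enumerate(lo.tiers) if t is ConsensusTier.HIGH}
    high_hi = {i for i, t in enumerate(hi.tiers) if t is ConsensusTier.HIGH}
    assert high_hi <= high_lo


def test_planted_heptapeptide_recovered_in_high_run():
    rng = np.random.default_rng(8)
    template = "LMNP" + "WRKYGQK" + "STVW"
    rows = []
    for _ in range(40):
        row = list(template)
        # background columns vary; heptapeptide conserved at ~95%
        for i in list(range(4)) + list(range(11, 15)):
            row[i] = "ACDE"[rng.integers(4)]
        if rng.random() < 0.05:
            pos = 4 + int(rng.integers(7))
            row[pos] = "A"
        rows.append("".join(row))
    result = consensus_motif(AlignedBlock(ids=[f"s{i}" for i in range(40)], rows=rows))
    assert any("WRKYGQK" in run for run in result.motifs())


# ---------------------------------------------------------------------------
# discrete gamma

def test_large_alpha_limit_all_rates_one():
    # category means approach 1 like ~1.4/sqrt(alpha) for the outer
    # quintiles (normal limit), so alpha must be >~2e6 for a 1e-3 bound
    rates = discrete_gamma_rates(1e8).category_rates
    assert np.allclose(rates, 1.0, atol=1e-3)


@pytest.mark.parametrize("alpha", [0.05, 0.3, 1.0, 2.5, 10.0, 250.0])
def test_category_rates_average_to_one(alpha):
    model = discrete_gamma_rates(alpha)
    assert model.category_rates.sum() == pytest.approx(model.ncat, abs=1e-9)
    assert np.all(np.diff(model.category_rates) > 0)


def test_nonpositive_alpha_rejected():
    with pytest.raises(ValueError):
        discrete_gamma_rates(0.0)


PRINTED_RATE_SETS = [
    [0.15, 0.42, 0.75, 1.23, 2.45],
    [0.15, 0.42, 0.75, 1.23, 2.44],
    [0.13, 0.40, 0.73, 1.23, 2.51],
    [0.11, 0.36, 0.70, 1.22, 2.60],
]


@pytest.mark.parametrize("target", PRINTED_RATE_SETS)
def test_alpha_search_recovers_printed_category_sets(target):
    alpha, max_dev = fit_gamma_alpha(target)
    assert max_dev <= 0.01
    rates = discrete_gamma_rates(alpha).category_rates
    assert np.all(np.abs(rates - np.array(target)) <= 0.01)
    # each printed set itself averages to ~1 (sums to ~5)
    assert sum(target) == pytest.approx(5.0, abs=0.1)
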