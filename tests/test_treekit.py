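"""JC distances, neighbor joining, tree comparison and the rate filter."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from epicmarkers.intron_filters import FilterConfig
from epicmarkers.msa_clean import Alignment
from epicmarkers.treekit import (
    MarkerDivergenceStats,
    bipartition_lengths,
    build_nj_tree,
    clade_terminal_sum,
    compare_trees,
    concatenate,
    jc_distance,
    nj_tree,
    phylo_filter,
    read_newick,
    scale_tree,
    total_branch_length,
    write_newick,
)


def test_jc_distance_closed_form():
    assert jc_distance(0.10) == pytest.approx(0.10732, abs=1e-5)
    assert jc_distance(0.0) == 0.0


def test_jc_distance_saturation_cap():
    assert jc_distance(0.75, saturation_cap=5.0) == 5.0
    assert jc_distance(0.9) == 5.0


def _patristic(tree, a, b):
    ta = tree.find(a)
    tb = tree.find(b)
    return ta.distance(tb)


def test_nj_recovers_additive_matrix_exactly():
    """On an additive distance matrix NJ reconstructs the generating tree,
    including branch lengths (checked via patristic distances)."""
    ids = ["a", "b", "c", "d"]
    mat = np.array(
        [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 5], [8, 7, 5, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(mat, ids))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i < j:
                assert _patristic(tree, x, y) == pytest.approx(mat[i, j])


def test_identical_sequences_give_star_tree_with_zero_branches():
    aln = Alignment(taxa=("a", "b", "c", "d"), rows=("ACGTACGT",) * 4)
    tree = build_nj_tree(aln)
    assert total_branch_length(tree) == 0.0


def test_fewer_than_three_taxa_is_hard_error():
    aln = Alignment(taxa=("a", "b"), rows=("ACGT", "ACGT"))
    with pytest.raises(ValueError, match="at least 3"):
        build_nj_tree(aln)


def test_pair_with_no_shared_columns_is_hard_error():
    aln = Alignment(taxa=("a", "b", "c"), rows=("AC--", "--GT", "ACGT"))
    with pytest.raises(ValueError, match="'a'.*'b'"):
        build_nj_tree(aln)


def test_newick_round_trip_preserves_topology_and_lengths():
    text = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.025);"
    tree = read_newick(text)
    again = read_newick(write_newick(tree))
    assert bipartition_lengths(again) == pytest.approx(bipartition_lengths(tree))


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def test_concatenate_appends_columns_and_records_partitions():
    a1 = Alignment(taxa=("a", "b"), rows=("A" * 100, "C" * 100))
    a2 = Alignment(taxa=("a", "b"), rows=("G" * 50, "T" * 50))
    cat, parts = concatenate([a1, a2], ["a", "b"])
    assert cat.n_columns == 150
    assert parts == [(0, 100), (100, 150)]


def test_concatenate_pads_missing_taxon_with_gaps():
    a1 = Alignment(taxa=("a", "b", "c"), rows=("A" * 10, "C" * 10, "G" * 10))
    a2 = Alignment(taxa=("a", "b"), rows=("G" * 50, "T" * 50))
    cat, _ = concatenate([a1, a2], ["a", "b", "c"])
    assert cat.row("c") == "G" * 10 + "-" * 50


def test_concatenate_empty_list_is_error():
    with pytest.raises(ValueError):
        concatenate([], ["a"])


# ---------------------------------------------------------------------------
# tree comparison
# ---------------------------------------------------------------------------

TREE5 = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1,e:0.25);"


def test_identity_comparison_is_one_and_zero():
    t = read_newick(TREE5)
    res = compare_trees(t, read_newick(TREE5))
    assert res.scaling_factor == pytest.approx(1.0)
    assert res.k_score == pytest.approx(0.0, abs=1e-12)


def test_doubling_branches_halves_scaling_factor():
    """A tree with every branch doubled is twice as divergent as the
    reference: K = 0.5 and the score stays 0 (pure rate difference)."""
    ref = read_newick(TREE5)
    res = compare_trees(scale_tree(ref, 2.0), ref)
    assert res.scaling_factor == pytest.approx(0.5)
    assert res.k_score == pytest.approx(0.0, abs=1e-12)


def test_scale_equivariance(rng):
    ref = read_newick(TREE5)
    t = read_newick("(((a:0.2,c:0.1):0.07,b:0.3):0.02,d:0.2,e:0.33);")
    base = compare_trees(t, ref).scaling_factor
    for c in (0.5, 2.0, 3.7):
        assert compare_trees(scale_tree(t, c), ref).scaling_factor == pytest.approx(
            base / c
        )


def _random_tree(rng, taxa):
    """Random binary topology with uniform branch lengths."""
    nodes = [f"{t}:{rng.uniform(0.05, 0.5):.4f}" for t in taxa]
    nodes = list(nodes)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 0.5):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return read_newick("(" + ",".join(nodes) + ");")


def test_scaling_factor_matches_independent_1d_minimizer(rng):
    """K from the closed form equals the argmin of sum((K t - r)^2) found by
    an independent scalar minimizer, on random 5-taxon tree pairs."""
    taxa = list("abcde")
    for _ in range(10):
        t = _random_tree(rng, taxa)
        r = _random_tree(rng, taxa)
        res = compare_trees(t, r)
        bt, br = bipartition_lengths(t), bipartition_lengths(r)
        keys = sorted(bt.keys() | br.keys(), key=lambda k: sorted(map(sorted, k)))
        tv = np.array([bt.get(k, 0.0) for k in keys])
        rv = np.array([br.get(k, 0.0) for k in keys])
        obj = lambda K: float(np.sum((K * tv - rv) ** 2))
        opt = minimize_scalar(obj, bounds=(0.0, 50.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.scaling_factor == pytest.approx(opt.x, abs=1e-6)
        assert res.k_score == pytest.approx(
            math.sqrt(obj(res.scaling_factor) / len(keys)), abs=1e-12
        )


def test_leaf_set_mismatch_names_difference():
    t = read_newick("((a:1,b:1):1,c:1);")
    r = read_newick("((a:1,b:1):1,d:1);")
    with pytest.raises(ValueError, match="c.*d"):
        compare_trees(t, r)


def test_zero_length_comparison_tree_is_error():
    t = read_newick("((a:0,b:0):0,c:0);")
    r = read_newick("((a:1,b:1):1,c:1);")
    with pytest.raises(ValueError, match="zero total branch length"):
        compare_trees(t, r)


def test_scaling_factor_anticorrelates_with_total_length(rng):
    """Across a batch of randomly rate-scaled trees, the scaling factor and
    the total branch length are negatively rank-correlated."""
    ref = read_newick(TREE5)
    ks, totals = [], []
    for _ in range(30):
        c = rng.uniform(0.3, 3.0)
        t = scale_tree(ref, c)
        # jitter branch lengths slightly so trees are not exact multiples
        for node in t.traverse(include_self=False):
            if node.length is not None:
                node.length *= rng.uniform(0.9, 1.1)
        ks.append(compare_trees(t, ref).scaling_factor)
        totals.append(total_branch_length(t))
    rho = spearmanr(ks, totals).statistic
    assert rho < -0.9


# ---------------------------------------------------------------------------
# terminal sums and the rate filter
# ---------------------------------------------------------------------------


def test_clade_terminal_sum_examples():
    tree = read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    assert clade_terminal_sum(tree, ["A", "B"]) == pytest.approx(0.3)
    assert clade_terminal_sum(tree, ["C"]) == pytest.approx(0.3)
    zero = read_newick("((A:0,B:0):0,C:0);")
    assert clade_terminal_sum(zero, ["A", "B", "C"]) == 0.0


def test_clade_terminal_sum_unknown_taxon_is_error():
    tree = read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    with pytest.raises(KeyError, match="Z"):
        clade_terminal_sum(tree, ["Z"])


@pytest.mark.parametrize(
    "sf,k,kept", [(0.79, 0.089, True), (0.8, 0.05, False), (0.5, 0.09, False)]
)
def test_phylo_filter_strict_boundaries(sf, k, kept):
    """Both thresholds are strict: scaling factor < 0.8 and score < 0.09."""
    stats = MarkerDivergenceStats("m", sf, k, 1.0, 0.1)
    assert phylo_filter(stats, FilterConfig()) is kept


def test_phylo_filter_nonfinite_stats_error():
    stats = MarkerDivergenceStats("m", float("nan"), 0.01, 1.0, 0.1)
    with pytest.raises(ValueError):
        phylo_filter(stats, FilterConfig())
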