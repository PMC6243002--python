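"""Alignment trimming/concatenation, phylogenetic diversity, taxonomy."""

import random

import pytest

from soilgv import phylo, synth
from soilgv.io import tree_from_string
from soilgv.phylo import (MSAlignment, assign_taxonomy_by_tree, concatenate,
                          pd_increase, pd_increase_two_trees,
                          phylogenetic_diversity, prune_to_taxa,
                          subset_diversity, trim_columns)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _aln_from_columns(cols, n_rows):
    rows = {f"s{i}": "".join(col[i] for col in cols) for i in range(n_rows)}
    return MSAlignment(rows=rows)


def test_gappy_column_below_ten_percent_removed():
    # 9 of 100 rows have a residue in column 0 -> removed; column 1 is full
    col_gappy = ["A"] * 9 + ["-"] * 91
    col_full = ["K"] * 100
    aln = _aln_from_columns([col_gappy, col_full], 100)
    out = trim_columns(aln, min_info_fraction=0.10)
    assert out.n_columns == 1
    assert set(out.rows["s0"]) == {"K"}


def test_exactly_ten_percent_kept():
    col = ["A"] * 10 + ["-"] * 90
    aln = _aln_from_columns([col, ["K"] * 100], 100)
    assert trim_columns(aln, 0.10).n_columns == 2


def test_gap_free_alignment_unchanged():
    aln = MSAlignment(rows={"a": "MKLV", "b": "MKIV"})
    out = trim_columns(aln, 0.10)
    assert out.rows == aln.rows


def test_trim_matches_per_column_oracle():
    rng = random.Random(11)
    n_rows, n_cols = 12, 80
    rows = {f"s{i}": "".join(rng.choice("ACDEFG-") for _ in range(n_cols))
            for i in range(n_rows)}
    aln = MSAlignment(rows=rows)
    thr = 0.4
    out = trim_columns(aln, thr)
    expected = 0
    for j in range(n_cols):
        non_gap = sum(1 for i in range(n_rows) if rows[f"s{i}"][j] != "-")
        if non_gap / n_rows >= thr:
            expected += 1
    assert out.n_columns == expected


def test_trim_tiny_threshold_is_identity():
    aln = MSAlignment(rows={"a": "M-LV", "b": "-KI-", "c": "MK--"})
    out = trim_columns(aln, min_info_fraction=1e-9)
    assert out.rows == aln.rows


def test_trim_all_columns_errors():
    aln = MSAlignment(rows={"a": "--", "b": "--", "c": "A-"})
    with pytest.raises(ValueError, match="every column"):
        trim_columns(aln, min_info_fraction=0.9)


def test_conservation_rule_optional():
    # column 0: perfectly conserved; column 1: maximally diverse
    aln = MSAlignment(rows={"a": "MA", "b": "MC", "c": "MD", "d": "ME"})
    assert trim_columns(aln, 0.1).n_columns == 2
    out = trim_columns(aln, 0.1, min_conservation=0.5)
    assert out.n_columns == 1


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def test_concatenation_length_additive():
    a = MSAlignment(rows={"x": "A" * 10, "y": "C" * 10})
    b = MSAlignment(rows={"x": "D" * 15, "y": "E" * 15})
    cat, parts = concatenate([a, b], ["x", "y"])
    assert cat.n_columns == 25
    assert parts == [(0, 10), (10, 25)]


def test_missing_partition_gap_filled():
    a = MSAlignment(rows={"x": "AAAA", "y": "CCCC"})
    b = MSAlignment(rows={"y": "GG", "z": "TT"})
    cat, _ = concatenate([a, b], ["x", "y", "z"])
    assert cat.rows["x"] == "AAAA--"
    assert cat.rows["z"] == "----TT"


def test_concatenate_row_set_is_union():
    rng = random.Random(3)
    universe = [f"g{i}" for i in range(12)]
    alns = []
    for _ in range(5):
        ids = rng.sample(universe, rng.randint(2, 12))
        width = rng.randint(5, 30)
        alns.append(MSAlignment(rows={
            i: "".join(rng.choice("MKLV") for _ in range(width)) for i in ids}))
    cat, parts = concatenate(alns, universe)
    assert set(cat.ids) == set(universe)
    assert cat.n_columns == sum(a.n_columns for a in alns)


def test_concatenate_rejects_foreign_ids():
    a = MSAlignment(rows={"x": "AA", "q": "CC"})
    with pytest.raises(ValueError, match="q"):
        concatenate([a], ["x", "y"])


# ---------------------------------------------------------------------------
# phylogenetic diversity
# ---------------------------------------------------------------------------

def test_pd_is_sum_of_branch_lengths():
    tree = tree_from_string("(A:0.1,B:0.2):0;")
    assert phylogenetic_diversity(tree) == pytest.approx(0.3)


def test_pruning_oracle_three_leaves():
    # removing C drops its 0.3 pendant; the 0.4 internal edge merges into B
    tree = tree_from_string("(A:0.1,(B:0.2,C:0.3):0.4);")
    assert phylogenetic_diversity(tree) == pytest.approx(1.0)
    pruned = prune_to_taxa(tree, ["A", "B"])
    assert phylogenetic_diversity(pruned) == pytest.approx(0.7)
    assert subset_diversity(tree, ["A", "B"]) == pytest.approx(0.7)


def test_pd_increase_formula_consistency():
    """pd_with = 1.21 x pd_without must report a 21% increase."""
    without = tree_from_string("(A:1.0,B:1.0):0;")
    with_ = tree_from_string("((A:1.0,B:1.0):0.0,N:0.42):0;")
    res = pd_increase_two_trees(with_, without)
    assert res.pd_without == pytest.approx(2.0)
    assert res.pd_with == pytest.approx(2.42)
    assert res.increase_percent == pytest.approx(21.0)


def test_pd_increase_prune_mode_monotone_random_trees(truth):
    tree = tree_from_string(truth.tree_newick)
    leaves = sorted(phylo.leaf_labels(tree))
    rng = random.Random(2)
    novel = rng.sample(leaves, 7)
    res = pd_increase(tree, novel)
    assert res.pd_with >= res.pd_without >= 0
    # independent split-based computation agrees with prune-and-sum
    assert res.pd_without == pytest.approx(
        subset_diversity(tree, set(leaves) - set(novel)), abs=1e-9)


def test_pd_invariant_under_rerooting(truth):
    tree = tree_from_string(truth.tree_newick)
    pd0 = phylogenetic_diversity(tree)
    node = tree.seed_node.child_nodes()[0]
    tree.reroot_at_node(node, update_bipartitions=False)
    assert phylogenetic_diversity(tree) == pytest.approx(pd0, rel=1e-9)


def test_pd_increase_empty_novel_warns():
    tree = tree_from_string("(A:0.1,B:0.2):0;")
    res = pd_increase(tree, [])
    assert res.increase_percent == 0.0


def test_prune_below_two_leaves_errors():
    tree = tree_from_string("(A:0.1,B:0.2):0;")
    with pytest.raises(ValueError):
        pd_increase(tree, ["A", "B"])
    with pytest.raises(ValueError):
        prune_to_taxa(tree, ["A"])


def test_generator_truth_pd_recovered(small_truth):
    """pd_increase on the synthetic tree reproduces the generator-recorded
    PD values exactly (pruning mode)."""
    novel = small_truth.ncldv_ids()
    tree_with, tree_without = synth.emit_tree(small_truth, novel)
    res = pd_increase(tree_with, novel)
    assert res.pd_with == pytest.approx(small_truth.pd_with, abs=1e-9)
    assert res.pd_without == pytest.approx(small_truth.pd_without, abs=1e-9)
    assert phylogenetic_diversity(tree_without) == pytest.approx(
        res.pd_without, abs=1e-9)
    # the accumulator recorded at generation time agrees too
    assert small_truth.pd_with == pytest.approx(small_truth.pd_total, abs=1e-9)


def test_prune_zero_leaves_identity(small_truth):
    tree_with, tree_without = synth.emit_tree(small_truth, [])
    assert (phylogenetic_diversity(tree_with)
            == pytest.approx(phylogenetic_diversity(tree_without)))


# ---------------------------------------------------------------------------
# taxonomy transfer
# ---------------------------------------------------------------------------

def test_query_sister_to_single_reference():
    tree = tree_from_string("((Q:0.1,R1:0.1):0.2,(R2:0.1,R3:0.1):0.2):0;")
    labels = {"R1": "Klosneuvirinae", "R2": "Megamimivirinae",
              "R3": "Megamimivirinae"}
    out = assign_taxonomy_by_tree(tree, labels, ["Q"])
    assert out == {"Q": "Klosneuvirinae"}


def test_mixed_label_clade_unassigned():
    tree = tree_from_string("((Q:0.1,(R1:0.1,R2:0.1):0.1):0.2,R3:0.3):0;")
    labels = {"R1": "A", "R2": "B", "R3": "A"}
    out = assign_taxonomy_by_tree(tree, labels, ["Q"])
    assert out["Q"] == "unassigned"


def test_query_not_in_tree_errors():
    tree = tree_from_string("(A:0.1,B:0.2):0;")
    with pytest.raises(ValueError, match="Z"):
        assign_taxonomy_by_tree(tree, {"A": "x"}, ["Z"])


def test_grafted_queries_recover_lineages(truth):
    """Synthetic queries placed inside labeled lineage clades recover their
    lineages from reference leaves."""
    tree = tree_from_string(truth.tree_newick)
    refs = truth.reference_lineages()
    queries = truth.ncldv_ids()
    out = assign_taxonomy_by_tree(tree, refs, queries)
    truth_lineage = {g.genome_id: g.lineage for g in truth.genomes if g.is_ncldv}
    assigned = {q: lab for q, lab in out.items() if lab != "unassigned"}
    correct = sum(assigned[q] == truth_lineage[q] for q in assigned)
    assert len(assigned) >= 0.8 * len(queries)
    assert correct >= 0.9 * len(assigned)
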