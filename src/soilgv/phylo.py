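"""Alignment trimming, concatenation, phylogenetic diversity, and
tree-based taxonomy transfer.

Phylogenetic diversity (PD) is Faith's measure: the sum of branch lengths
spanned by the leaves of a tree.  The diversity contribution of newly
discovered genomes is quantified as the percentage increase of PD between
the tree containing them and the tree without them.  The "without" tree can
either be obtained by pruning the novel leaves (default, exactly
reproducible) or supplied as an independently inferred tree (two-tree mode).

Alignment columns with less than 10% sequence information (non-gap
characters) are removed before tree building, mirroring common trimAl
usage.  An optional secondary rule drops columns whose most frequent
non-gap residue falls below a conservation fraction; it is off by default
because no parameter for it is fixed by the workflow this reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from .io import SequenceSet, read_fasta, write_fasta

log = logging.getLogger("soilgv")

GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class MSAlignment:
    """A multiple sequence alignment as an ordered id -> row mapping."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def aligned_residues(self, seq_id: str) -> int:
        """Number of non-gap characters in one row."""
        return sum(1 for c in self.rows[seq_id] if c not in GAP_CHARS)


def read_alignment(path) -> MSAlignment:
    seqs = read_fasta(path)
    return MSAlignment(rows={rid: res for rid, _d, res in seqs.records})


def write_alignment(aln: MSAlignment, path) -> None:
    seqs = SequenceSet(records=[(rid, "", row) for rid, row in aln.rows.items()],
                       alphabet="protein")
    write_fasta(seqs, path)


def trim_columns(
    aln: MSAlignment,
    min_info_fraction: float = 0.10,
    min_conservation: float | None = None,
) -> MSAlignment:
    """Remove gappy (and optionally low-conservation) alignment columns.

    A column is kept iff its fraction of non-gap characters is at least
    ``min_info_fraction``.  When ``min_conservation`` is given, columns whose
    most frequent non-gap residue has frequency (among non-gap characters)
    below it are also removed.  Row order is preserved.
    """
    if not (0 < min_info_fraction <= 1):
        raise ValueError("min_info_fraction must be in (0, 1]")
    n_rows = len(aln.rows)
    keep: list[int] = []
    cols = list(zip(*aln.rows.values()))
    for j, col in enumerate(cols):
        residues = [c for c in col if c not in GAP_CHARS]
        if len(residues) / n_rows < min_info_fraction:
            continue
        if min_conservation is not None and residues:
            top = max(residues.count(r) for r in set(residues))
            if top / len(residues) < min_conservation:
                continue
        keep.append(j)
    if not keep:
        raise ValueError("column trimming removed every column")
    return MSAlignment(rows={
        rid: "".join(row[j] for j in keep) for rid, row in aln.rows.items()
    })


def concatenate(alignments: list[MSAlignment], id_universe: Iterable[str]
                ) -> tuple[MSAlignment, list[tuple[int, int]]]:
    """Concatenate marker alignments into one supermatrix over
    ``id_universe``, gap-filling ids missing from a partition.

    Returns the concatenated alignment and the partition boundaries as
    half-open ``(start, end)`` column ranges.
    """
    universe = list(dict.fromkeys(id_universe))
    for aln in alignments:
        extra = set(aln.ids) - set(universe)
        if extra:
            raise ValueError(f"alignment ids outside universe: {sorted(extra)}")
    parts: list[tuple[int, int]] = []
    rows = {rid: [] for rid in universe}
    offset = 0
    for aln in alignments:
        ncol = aln.n_columns
        parts.append((offset, offset + ncol))
        offset += ncol
        for rid in universe:
            rows[rid].append(aln.rows.get(rid, "-" * ncol))
    return MSAlignment(rows={rid: "".join(chunks) for rid, chunks in rows.items()}), parts


# ---------------------------------------------------------------------------
# phylogenetic diversity
# ---------------------------------------------------------------------------

@dataclass
class PDResult:
    pd_with: float
    pd_without: float
    increase_percent: float


def phylogenetic_diversity(tree: dendropy.Tree) -> float:
    """Faith's PD over all leaves: the sum of branch lengths of the tree.

    Independent of rooting — re-rooting redistributes but does not change
    the total branch length.
    """
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            total += edge.length
    return total


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}


def prune_to_taxa(tree: dendropy.Tree, keep_labels: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to ``keep_labels``, with
    unifurcations collapsed and their branch lengths summed."""
    keep = set(keep_labels)
    present = leaf_labels(tree)
    missing = keep - present
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise ValueError("pruning would leave fewer than 2 leaves")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    # extraction can leave a length-bearing root edge from the original
    # attachment point; PD sums only edges internal to the spanned subtree
    if pruned.seed_node.edge.length:
        pruned.seed_node.edge.length = None
    return pruned


def subset_diversity(tree: dendropy.Tree, keep_labels: Iterable[str]) -> float:
    """PD spanned by a leaf subset, computed without pruning.

    An edge contributes its length iff the split it induces separates kept
    leaves, i.e. at least one kept leaf lies on each side.  Equivalent to
    pruning-then-summing but algorithmically independent of it.
    """
    keep = set(keep_labels)
    present = leaf_labels(tree)
    missing = keep - present
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    n_keep = len(keep)
    below: dict[int, int] = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = int(node.taxon is not None and node.taxon.label in keep)
        else:
            below[id(node)] = sum(below[id(c)] for c in node.child_nodes())
        k = below[id(node)]
        if node.edge.length and 0 < k < n_keep:
            total += node.edge.length
    return total


def pd_increase(tree_with: dendropy.Tree, novel_ids: Iterable[str]) -> PDResult:
    """PD gain contributed by ``novel_ids``: prune them from ``tree_with``
    and compare total branch lengths."""
    novel = set(novel_ids)
    pd_with = phylogenetic_diversity(tree_with)
    if not novel:
        log.warning("pd_increase called with no novel ids; increase is 0")
        return PDResult(pd_with=pd_with, pd_without=pd_with, increase_percent=0.0)
    present = leaf_labels(tree_with)
    missing = novel - present
    if missing:
        raise ValueError(f"novel ids not in tree: {sorted(missing)}")
    keep = present - novel
    pruned = prune_to_taxa(tree_with, keep)
    pd_without = phylogenetic_diversity(pruned)
    return PDResult(
        pd_with=pd_with,
        pd_without=pd_without,
        increase_percent=100.0 * (pd_with - pd_without) / pd_without,
    )


def pd_increase_two_trees(tree_with: dendropy.Tree,
                          tree_without: dendropy.Tree) -> PDResult:
    """Two-tree mode: both trees inferred independently (the 'without' tree
    is not required to be a pruning of the 'with' tree)."""
    pd_with = phylogenetic_diversity(tree_with)
    pd_without = phylogenetic_diversity(tree_without)
    return PDResult(
        pd_with=pd_with,
        pd_without=pd_without,
        increase_percent=100.0 * (pd_with - pd_without) / pd_without,
    )


# ---------------------------------------------------------------------------
# tree-based taxonomy transfer
# ---------------------------------------------------------------------------

def assign_taxonomy_by_tree(
    tree: dendropy.Tree,
    reference_labels: Mapping[str, str],
    query_ids: Iterable[str],
    unassigned: str = "unassigned",
) -> dict[str, str]:
    """Assign taxonomy to query leaves from labeled reference leaves.

    For each query the tree is walked toward the root until the smallest
    clade containing at least one reference leaf is found; if every
    reference leaf in that clade carries the same label the query inherits
    it, otherwise it stays ``unassigned`` (mixed-label clades are treated as
    uninformative rather than guessed at).
    """
    if not reference_labels:
        raise ValueError("reference_labels must cover at least one leaf")
    queries = set(query_ids)
    overlap = queries & set(reference_labels)
    if overlap:
        raise ValueError(f"query ids also carry reference labels: {sorted(overlap)}")
    leaf_by_label = {leaf.taxon.label: leaf
                     for leaf in tree.leaf_node_iter() if leaf.taxon}
    out: dict[str, str] = {}
    for q in sorted(queries):
        if q not in leaf_by_label:
            raise ValueError(f"query {q!r} not in tree")
        node = leaf_by_label[q].parent_node
        assigned = unassigned
        while node is not None:
            labels = {
                reference_labels[leaf.taxon.label]
                for leaf in node.leaf_iter()
                if leaf.taxon and leaf.taxon.label in reference_labels
            }
            if labels:
                if len(labels) == 1:
                    assigned = labels.pop()
                break
            node = node.parent_node
        out[q] = assigned
    return out
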