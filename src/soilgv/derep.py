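"""Genome dereplication by average nucleotide identity (ANI).

Genomes are clustered at 95% ANI with at least 100 kb of aligned sequence,
using single-linkage connected components, and one representative is kept
per cluster.  ANI estimators are asymmetric; the two orientations of a pair
are symmetrized by the arithmetic mean of the ANI values and the minimum of
the aligned lengths.  All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .io import ANIPair


@dataclass
class ClusterSet:
    """A partition of genomes into ANI clusters, each with a representative."""

    clusters: list[tuple[frozenset, str]]  # (members, representative)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representatives(self) -> list[str]:
        return sorted(rep for _members, rep in self.clusters)

    def member_map(self) -> dict[str, str]:
        """genome_id -> representative of its cluster"""
        out = {}
        for members, rep in self.clusters:
            for m in members:
                out[m] = rep
        return out


def build_edges(
    pairs: Iterable[ANIPair],
    ani_threshold: float = 95.0,
    aligned_min: int = 100_000,
) -> set[frozenset]:
    """Symmetrize directed ANI estimates and keep an edge iff the mean ANI
    >= ``ani_threshold`` and the minimum aligned length >= ``aligned_min``."""
    if ani_threshold <= 0 or aligned_min <= 0:
        raise ValueError("thresholds must be positive")
    acc: dict[frozenset, list] = {}
    for p in pairs:
        key = frozenset((p.genome_a, p.genome_b))
        acc.setdefault(key, []).append(p)
    edges: set[frozenset] = set()
    for key, ps in acc.items():
        mean_ani = sum(p.ani for p in ps) / len(ps)
        min_aln = min(p.aligned_bp for p in ps)
        if mean_ani >= ani_threshold and min_aln >= aligned_min:
            edges.add(key)
    return edges


def cluster(
    genomes: Iterable[str],
    edges: Iterable[frozenset],
    lengths: dict[str, int] | None = None,
    mode: str = "single_linkage",
) -> ClusterSet:
    """Cluster genomes over the kept ANI edges.

    ``single_linkage`` (default) takes connected components, so clusters are
    the transitive closure of pairwise similarity and edge-less genomes are
    singletons.  ``greedy_centroid`` is a sensitivity-check mode that seeds
    clusters from the longest genome and admits only direct neighbours of
    the seed.  The representative is the longest member (ties broken by the
    lexicographically smallest id); without lengths, the smallest id.
    """
    genomes = sorted(set(genomes))
    genome_set = set(genomes)
    edge_list = []
    for e in edges:
        a, b = sorted(e)
        if a not in genome_set or b not in genome_set:
            raise ValueError(f"edge endpoint outside genome set: {a}, {b}")
        edge_list.append((a, b))

    def rep_longest(members: frozenset) -> str:
        if not lengths:
            return min(members)
        best_len = max(lengths.get(g, 0) for g in members)
        return min(g for g in members if lengths.get(g, 0) == best_len)

    clusters: list[tuple[frozenset, str]] = []
    if mode == "single_linkage":
        g = nx.Graph()
        g.add_nodes_from(genomes)
        g.add_edges_from(edge_list)
        for comp in nx.connected_components(g):
            members = frozenset(comp)
            clusters.append((members, rep_longest(members)))
    elif mode == "greedy_centroid":
        adj: dict[str, set[str]] = {g: set() for g in genomes}
        for a, b in edge_list:
            adj[a].add(b)
            adj[b].add(a)
        order = sorted(genomes, key=lambda g: (-(lengths or {}).get(g, 0), g))
        assigned: set[str] = set()
        for seed in order:
            if seed in assigned:
                continue
            members = frozenset({seed} | (adj[seed] - assigned))
            assigned |= members
            clusters.append((members, seed))
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    clusters.sort(key=lambda c: c[1])
    return ClusterSet(clusters=clusters)


def dereplicate(
    genomes: Iterable[str],
    pairs: Iterable[ANIPair],
    ani_threshold: float = 95.0,
    aligned_min: int = 100_000,
    lengths: dict[str, int] | None = None,
) -> ClusterSet:
    """End-to-end dereplication: symmetrize, threshold, cluster."""
    edges = build_edges(pairs, ani_threshold=ani_threshold, aligned_min=aligned_min)
    return cluster(genomes, edges, lengths=lengths)


def write_clusters(cs: ClusterSet, path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("cluster_id\trepresentative\tmembers\n")
        for i, (members, rep) in enumerate(cs.clusters, 1):
            fh.write(f"C{i:04d}\t{rep}\t{','.join(sorted(members))}\n")
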