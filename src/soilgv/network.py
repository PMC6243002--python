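"""Gene-sharing network over NCLDV genomes from an orthogroup table.

For each genome pair the shared orthogroups are those with at least one
member from both genomes.  Each genome's directed percentage is the number
of its proteins that fall in shared orthogroups (paralogs included — the
quantity is a percentage of *proteins*, not of groups), relative to its
total protein count.  The undirected edge weight is the arithmetic mean of
the two directed percentages; edges are kept at a weight of 18% or more.
Genomes sharing nothing remain in the network as isolated nodes.

An alternative union-based weight (shared proteins over the union of both
protein sets) is available behind ``mode="union"`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx


@dataclass
class OrthogroupTable:
    """Orthogroup membership counts: ``groups[og_id][genome_id] -> n``
    proteins, plus per-genome total protein counts (singletons included,
    so per-genome sums over groups never exceed the total)."""

    groups: dict[str, dict[str, int]]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        assigned: dict[str, int] = {}
        for og, counts in self.groups.items():
            for g, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative count in {og} for {g}")
                assigned[g] = assigned.get(g, 0) + c
        for g, n in assigned.items():
            if g not in self.totals:
                raise ValueError(f"genome {g!r} missing from totals")
            if n > self.totals[g]:
                raise ValueError(
                    f"genome {g!r}: {n} assigned proteins exceed total {self.totals[g]}")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.totals)


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected weighted edge; endpoints in canonical (sorted) order."""

    genome_a: str
    genome_b: str
    weight: float

    def __post_init__(self) -> None:
        if self.genome_a >= self.genome_b:
            raise ValueError("endpoints must be in canonical order a < b")
        if not (0.0 <= self.weight <= 100.0):
            raise ValueError(f"weight {self.weight} outside [0, 100]")


def edge_weight(table: OrthogroupTable, a: str, b: str, mode: str = "mean") -> float:
    """Percentage of proteins in orthogroups shared between genomes ``a``
    and ``b``, averaged over the two genomes' own totals."""
    if a == b:
        raise ValueError("edge weight needs two distinct genomes")
    for g in (a, b):
        if table.totals.get(g, 0) <= 0:
            raise ValueError(f"genome {g!r} has zero total protein count")
    shared_a = shared_b = 0
    for counts in table.groups.values():
        ca, cb = counts.get(a, 0), counts.get(b, 0)
        if ca > 0 and cb > 0:
            shared_a += ca
            shared_b += cb
    if mode == "mean":
        pct_a = 100.0 * shared_a / table.totals[a]
        pct_b = 100.0 * shared_b / table.totals[b]
        return (pct_a + pct_b) / 2.0
    if mode == "union":
        return 100.0 * (shared_a + shared_b) / (table.totals[a] + table.totals[b])
    raise ValueError(f"unknown weight mode {mode!r}")


def build_network(
    table: OrthogroupTable,
    min_weight: float = 18.0,
    exclude: Iterable[str] | None = None,
    mode: str = "mean",
) -> nx.Graph:
    """Score all genome pairs and keep edges with weight >= ``min_weight``
    (inclusive).  Excluded genomes (e.g. an over-represented clade supplied
    as an exclude list) are dropped entirely; isolated genomes stay as
    degree-0 nodes."""
    excluded = set(exclude or ())
    genomes = [g for g in table.genomes if g not in excluded]
    if len(genomes) < 2:
        raise ValueError("network needs at least 2 genomes")
    g = nx.Graph()
    g.add_nodes_from(genomes)
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            w = edge_weight(table, a, b, mode=mode)
            if w >= min_weight:
                g.add_edge(a, b, weight=w)
    return g


def network_edges(g: nx.Graph) -> list[NetworkEdge]:
    out = [NetworkEdge(genome_a=min(a, b), genome_b=max(a, b), weight=d["weight"])
           for a, b, d in g.edges(data=True)]
    return sorted(out, key=lambda e: (e.genome_a, e.genome_b))


@dataclass
class ConnectivityReport:
    degrees: dict[str, int]
    components: list[frozenset]
    isolated: list[str]


def connectivity_report(g: nx.Graph) -> ConnectivityReport:
    """Per-node degrees, connected components, and isolated genomes."""
    comps = sorted((frozenset(c) for c in nx.connected_components(g)),
                   key=lambda c: (-len(c), min(c)))
    return ConnectivityReport(
        degrees={n: int(d) for n, d in g.degree()},
        components=comps,
        isolated=sorted(n for n, d in g.degree() if d == 0),
    )
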