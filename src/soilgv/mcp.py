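"""Major-capsid-protein (MCP) survey: the filter cascade and fraction
accounting applied to candidate MCPs pulled from bulk metagenomes, MAGs and
reference genomes.

The cascade runs in a fixed order mirroring the discovery workflow:

1. e-value cutoff (1e-6) on the profile search hit,
2. redundancy reduction by greedy longest-first clustering at 95% identity,
3. a false-positive guard: candidates whose database search returned hits
   but no NCLDV MCP within the top 10 are excluded (candidates with no hits
   at all are kept — novelty is not penalized),
4. removal of candidates with fewer than 50 aligned amino acids left after
   alignment trimming.

Each stage only annotates or drops, so survivor sets are nested along the
cascade and the cascade is idempotent.  Dropped candidates are retained
with a ``dropped_at`` stage tag for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .phylo import MSAlignment

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

STAGES = ("evalue", "cluster", "top10", "aligned_len")


@dataclass
class MCPCandidate:
    """One candidate MCP with its contig context and filter provenance."""

    protein_id: str
    contig_id: str
    source: str  # reference | mag | bulk_unbinned
    evalue: float
    contig_len_bp: int = 0
    contig_cov: float = 0.0
    length_aa: int = 0
    sequence: str | None = None
    aligned_aa_after_trim: int | None = None
    cluster_rep: bool = False
    top10_rescued: bool = False
    taxonomy: str = "unassigned"
    dropped_at: str | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.source not in ("reference", "mag", "bulk_unbinned"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.dropped_at is not None and self.dropped_at not in STAGES:
            raise ValueError(f"unknown stage {self.dropped_at!r}")

    @property
    def alive(self) -> bool:
        return self.dropped_at is None


def survivors(candidates: Iterable[MCPCandidate]) -> list[MCPCandidate]:
    return [c for c in candidates if c.alive]


def filter_evalue(candidates: list[MCPCandidate], cutoff: float = 1e-6
                  ) -> list[MCPCandidate]:
    """Keep candidates with hit e-value <= ``cutoff``; drops are tagged."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    for c in candidates:
        if c.alive and c.evalue > cutoff:
            c.dropped_at = "evalue"
    return candidates


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit distance / longer length."""
    if edlib is None:  # pragma: no cover
        raise RuntimeError("edlib not available for sequence identity")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_95(
    candidates: list[MCPCandidate],
    identity: Callable[[MCPCandidate, MCPCandidate], float] | None = None,
    threshold: float = 0.95,
) -> list[MCPCandidate]:
    """Greedy longest-first redundancy clustering.

    Candidates are visited in order of decreasing length (ties broken by
    protein id); each joins the first existing representative with identity
    >= ``threshold``, otherwise founds a new cluster.  Non-representatives
    are tagged ``dropped_at="cluster"``; exactly one representative survives
    per cluster.
    """
    if identity is None:
        def identity(x: MCPCandidate, y: MCPCandidate) -> float:
            if x.sequence is None or y.sequence is None:
                raise ValueError(
                    f"no sequence for {x.protein_id} or {y.protein_id}; "
                    "supply an identity function")
            return sequence_identity(x.sequence, y.sequence)

    def length_of(c: MCPCandidate) -> int:
        return len(c.sequence) if c.sequence is not None else c.length_aa

    alive = survivors(candidates)
    reps: list[MCPCandidate] = []
    for c in sorted(alive, key=lambda c: (-length_of(c), c.protein_id)):
        for rep in reps:
            if identity(c, rep) >= threshold:
                c.cluster_rep = False
                c.dropped_at = "cluster"
                break
        else:
            c.cluster_rep = True
            reps.append(c)
    return candidates


def _default_is_mcp_label(label: str) -> bool:
    return "MCP" in label.upper() and "NCLDV" in label.upper()


def top10_rescue(
    candidates: list[MCPCandidate],
    nr_hits: Mapping[str, list[str]],
    is_mcp_label: Callable[[str], bool] = _default_is_mcp_label,
    top_n: int = 10,
) -> list[MCPCandidate]:
    """Exclude candidates whose database hits contain no NCLDV MCP in the
    top ``top_n`` ranks; candidates with no database hits at all are kept.

    ``nr_hits`` maps protein id to its ranked hit labels (best first; the
    original ranking is by bitscore, with e-value then label as tie-breaks).
    """
    for c in survivors(candidates):
        hits = nr_hits.get(c.protein_id, [])
        if not hits:
            c.top10_rescued = True  # novel protein, no hits: kept
            continue
        if any(is_mcp_label(lab) for lab in hits[:top_n]):
            c.top10_rescued = True
        else:
            c.dropped_at = "top10"
    return candidates


def filter_aligned_length(
    candidates: list[MCPCandidate],
    trimmed_alignment: MSAlignment,
    min_aa: int = 50,
) -> list[MCPCandidate]:
    """Drop candidates with fewer than ``min_aa`` non-gap residues in the
    trimmed alignment (>= 50 survives; the bound excludes only <50)."""
    for c in survivors(candidates):
        if c.protein_id not in trimmed_alignment.rows:
            raise ValueError(f"candidate {c.protein_id!r} missing from alignment")
        c.aligned_aa_after_trim = trimmed_alignment.aligned_residues(c.protein_id)
        if c.aligned_aa_after_trim < min_aa:
            c.dropped_at = "aligned_len"
    return candidates


def run_cascade(
    candidates: list[MCPCandidate],
    nr_hits: Mapping[str, list[str]],
    trimmed_alignment: MSAlignment | None = None,
    identity: Callable[[MCPCandidate, MCPCandidate], float] | None = None,
    evalue_cutoff: float = 1e-6,
    cluster_identity: float = 0.95,
    min_aligned_aa: int = 50,
    is_mcp_label: Callable[[str], bool] = _default_is_mcp_label,
) -> list[MCPCandidate]:
    """Run the full cascade in the fixed stage order."""
    filter_evalue(candidates, cutoff=evalue_cutoff)
    cluster_95(candidates, identity=identity, threshold=cluster_identity)
    top10_rescue(candidates, nr_hits, is_mcp_label=is_mcp_label)
    if trimmed_alignment is not None:
        filter_aligned_length(candidates, trimmed_alignment, min_aa=min_aligned_aa)
    return candidates


@dataclass
class FractionReport:
    """Survivor accounting behind the survey summary plots."""

    total: int
    by_source: dict[str, int]
    bulk_total: int
    bulk_unbinned: int
    unbinned_percent: float | None
    long_contig: int   # bulk survivors on contigs > 1 kb (strict)
    short_contig: int  # bulk survivors on contigs <= 1 kb
    boundary_1kb: int  # contigs of exactly 1000 bp (counted short, flagged)
    low_coverage: int  # bulk survivors on contigs with read coverage < 2
    scatter: pd.DataFrame  # per-survivor (contig length, coverage) pairs


def fraction_report(
    candidates: Iterable[MCPCandidate],
    depth: pd.DataFrame | None = None,
    length_boundary_bp: int = 1000,
    low_cov_threshold: float = 2.0,
) -> FractionReport:
    """Summarize cascade survivors by source and contig class.

    ``depth`` (contig_id, length_bp, mean_depth, bin_id) overrides the
    per-candidate contig length/coverage when provided; a surviving bulk
    candidate whose contig is absent from it is an error.  Contigs of
    exactly the 1 kb boundary are counted in the short class (the strict
    ">1 kb" reading) and reported separately.
    """
    alive = survivors(list(candidates))
    depth_idx = None
    if depth is not None:
        depth_idx = depth.set_index("contig_id")

    by_source: dict[str, int] = {"reference": 0, "mag": 0, "bulk_unbinned": 0}
    rows = []
    long_c = short_c = boundary = low_cov = 0
    for c in alive:
        by_source[c.source] += 1
        length, cov = c.contig_len_bp, c.contig_cov
        if depth_idx is not None:
            if c.contig_id in depth_idx.index:
                length = int(depth_idx.at[c.contig_id, "length_bp"])
                cov = float(depth_idx.at[c.contig_id, "mean_depth"])
            elif c.source != "reference":
                raise ValueError(f"contig {c.contig_id!r} missing from depth table")
        rows.append((c.protein_id, c.source, length, cov))
        if c.source in ("mag", "bulk_unbinned"):
            if length > length_boundary_bp:
                long_c += 1
            else:
                short_c += 1
                if length == length_boundary_bp:
                    boundary += 1
            if cov < low_cov_threshold:
                low_cov += 1

    bulk_total = by_source["mag"] + by_source["bulk_unbinned"]
    unbinned_pct = (round(100.0 * by_source["bulk_unbinned"] / bulk_total, 1)
                    if bulk_total else None)
    return FractionReport(
        total=len(alive),
        by_source=by_source,
        bulk_total=bulk_total,
        bulk_unbinned=by_source["bulk_unbinned"],
        unbinned_percent=unbinned_pct,
        long_contig=long_c,
        short_contig=short_c,
        boundary_1kb=boundary,
        low_coverage=low_cov,
        scatter=pd.DataFrame(rows, columns=["protein_id", "source",
                                            "contig_len_bp", "contig_cov"]),
    )


def write_provenance(candidates: Iterable[MCPCandidate], path,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("protein_id\tcontig_id\tsource\tevalue\tdropped_at\t"
                 "cluster_rep\ttop10_rescued\taligned_aa\ttaxonomy\n")
        for c in candidates:
            fh.write(f"{c.protein_id}\t{c.contig_id}\t{c.source}\t"
                     f"{c.evalue:.3g}\t{c.dropped_at or 'none'}\t"
                     f"{int(c.cluster_rep)}\t{int(c.top10_rescued)}\t"
                     f"{'' if c.aligned_aa_after_trim is None else c.aligned_aa_after_trim}\t"
                     f"{c.taxonomy}\n")
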