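"""Readers and writers for every external format the pipeline touches.

The pipeline consumes the output of standard bioinformatics tools —
``hmmsearch`` domain tables, ``fastANI``-style pairwise tables, OrthoFinder
orthogroup listings, newick trees, aligned/unaligned FASTA — and re-implements
only the decision logic applied to them.  All parsing of those formats is
confined to this module so that coordinate conventions (1-based inclusive in
tabular files, half-open 0-based internally) never leak into the analysis
code.

Bin membership travels via an explicit contig→bin TSV map rather than
query-id parsing tricks, because binning tools differ in their naming
conventions.  When a protein id is not itself a key of the map, the contig id
is derived by stripping a trailing ``_<n>`` gene index (the prodigal /
GeneMark convention ``<contig>_<gene_number>``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("soilgv")

_NUC_CHARS = set("ACGTUNRYSWKMBDHV-.")

UNBINNED = "unbinned"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered FASTA-backed collection of sequences.

    ``records`` holds ``(id, description, residues)`` triples; ids are unique
    within a set and residues are non-empty.  ``alphabet`` is ``nucleotide``
    or ``protein``.
    """

    records: list[tuple[str, str, str]]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, _desc, residues in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not residues:
                raise ValueError(f"empty sequence record {rid!r}")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def ids(self) -> list[str]:
        return [rid for rid, _, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, _, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)


def _guess_alphabet(records: list[tuple[str, str, str]]) -> str:
    chars = set()
    for _, _, s in records:
        chars.update(s.upper())
    return "nucleotide" if chars <= _NUC_CHARS else "protein"


def read_fasta(path: str | Path, alphabet: str = "auto") -> SequenceSet:
    """Read a FASTA file (wrapped or single-line) into a :class:`SequenceSet`.

    Duplicate ids and empty records are hard errors; the offending id is
    named in the message.
    """
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append((rec.id, desc, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if alphabet == "auto":
        alphabet = _guess_alphabet(records)
    return SequenceSet(records=records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(res), id=rid, description=desc)
        for rid, desc, res in seqs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# marker hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One best-scoring marker hit for a (protein, marker) pair.

    ``aligned_len`` is the aligned length in amino acids of the best domain.
    """

    query_id: str
    bin_id: str
    marker_id: str
    evalue: float
    bitscore: float
    aligned_len: int = 0

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        if self.aligned_len < 0:
            raise ValueError("aligned_len must be >= 0")


def _better(a: HitRecord, b: HitRecord) -> HitRecord:
    """Best of two hits for the same (query, marker) pair.

    E-values are compared on the log10 scale; an exact tie is broken by the
    higher bitscore.
    """
    la, lb = math.log10(a.evalue), math.log10(b.evalue)
    if la != lb:
        return a if la < lb else b
    return a if a.bitscore >= b.bitscore else b


def read_contig_bin_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``contig_id<TAB>bin_id`` sidecar map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def resolve_bin(query_id: str, contig_bin_map: dict[str, str] | None) -> str:
    """Map a protein query id to its bin via the sidecar contig→bin map.

    The protein id itself is tried first, then the contig id obtained by
    stripping a trailing ``_<gene index>``; otherwise ``unbinned``.
    """
    if contig_bin_map is None:
        return UNBINNED
    if query_id in contig_bin_map:
        return contig_bin_map[query_id]
    contig = query_id.rsplit("_", 1)[0]
    return contig_bin_map.get(contig, UNBINNED)


def _collapse_best(hits: Iterable[HitRecord]) -> list[HitRecord]:
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.marker_id)
        best[key] = _better(best[key], h) if key in best else h
    return list(best.values())


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: unparsable numeric field {token!r}") from exc


def _read_domtbl(path: Path, contig_bin_map: dict[str, str] | None) -> list[HitRecord]:
    # hmmsearch --domtblout layout: 22 whitespace-separated columns then a
    # free-text description.  Per-domain rows for the same (target, query
    # profile) pair are collapsed to the best-scoring one.
    raw: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, 22)
            if len(parts) < 22:
                raise ValueError(f"{path}:{lineno}: expected >=22 domtbl columns")
            target, query = parts[0], parts[3]
            ievalue = _parse_float(parts[12], path, lineno)
            score = _parse_float(parts[13], path, lineno)
            ali_from = int(_parse_float(parts[17], path, lineno))
            ali_to = int(_parse_float(parts[18], path, lineno))
            raw.append(HitRecord(
                query_id=target,
                bin_id=resolve_bin(target, contig_bin_map),
                marker_id=query,
                evalue=ievalue,
                bitscore=score,
                aligned_len=ali_to - ali_from + 1,  # 1-based inclusive coords
            ))
    return _collapse_best(raw)


_TSV_COLS = ["query_id", "bin_id", "marker_id", "evalue", "bitscore", "aligned_len"]


def _read_plain_tsv(path: Path, contig_bin_map: dict[str, str] | None) -> list[HitRecord]:
    raw: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            bin_id = parts[1] or resolve_bin(parts[0], contig_bin_map)
            raw.append(HitRecord(
                query_id=parts[0],
                bin_id=bin_id,
                marker_id=parts[2],
                evalue=_parse_float(parts[3], path, lineno),
                bitscore=_parse_float(parts[4], path, lineno),
                aligned_len=int(_parse_float(parts[5], path, lineno)),
            ))
    return _collapse_best(raw)


def read_hit_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    contig_bin_map: dict[str, str] | None = None,
) -> list[HitRecord]:
    """Read marker hits from ``hmmer_domtbl`` or ``plain_tsv`` dialects.

    Multiple domain rows for one (query, marker) pair collapse to the
    lowest-e-value row (ties broken by higher bitscore).
    """
    path = Path(path)
    if dialect == "hmmer_domtbl":
        return _read_domtbl(path, contig_bin_map)
    if dialect == "plain_tsv":
        return _read_plain_tsv(path, contig_bin_map)
    raise ValueError(f"unknown hit-table dialect {dialect!r}")


def write_hit_table(hits: list[HitRecord], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TSV_COLS) + "\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.bin_id}\t{h.marker_id}\t{h.evalue:.6g}\t"
                     f"{h.bitscore:.6g}\t{h.aligned_len}\n")


# ---------------------------------------------------------------------------
# ANI tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ANIPair:
    """One directed ANI estimate between two genomes (percent, aligned bp)."""

    genome_a: str
    genome_b: str
    ani: float
    aligned_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ani <= 100.0):
            raise ValueError(f"ANI {self.ani} outside [0, 100]")
        if self.aligned_bp < 0:
            raise ValueError("aligned_bp must be >= 0")


def read_ani_table(path: str | Path) -> list[ANIPair]:
    """Read a fastANI-style TSV: genome_a, genome_b, ani%, aligned_bp.

    Self-pairs are skipped with a warning; asymmetric orientations (A→B and
    B→A) are both retained for downstream symmetrization.
    """
    path = Path(path)
    pairs: list[ANIPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_a"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            a, b = parts[0], parts[1]
            if a == b:
                log.warning("%s:%d: self-pair %s skipped", path, lineno, a)
                continue
            pairs.append(ANIPair(
                genome_a=a, genome_b=b,
                ani=_parse_float(parts[2], path, lineno),
                aligned_bp=int(_parse_float(parts[3], path, lineno)),
            ))
    return pairs


def write_ani_table(pairs: list[ANIPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\tani\taligned_bp\n")
        for p in pairs:
            fh.write(f"{p.genome_a}\t{p.genome_b}\t{p.ani:.4g}\t{p.aligned_bp}\n")


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

DEPTH_COLS = ["contig_id", "length_bp", "mean_depth", "bin_id"]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read a contig depth TSV (contig_id, length_bp, mean_depth, bin_id)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"contig_id": str, "bin_id": str})
    missing = [c for c in DEPTH_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"depth table {path} missing columns {missing}")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise ValueError(f"duplicate contig_id {dup!r} in depth table")
    if (df["length_bp"] < 1).any():
        raise ValueError("length_bp must be >= 1")
    return df[DEPTH_COLS]


def write_depth_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[DEPTH_COLS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; every non-root edge must carry a branch length
    (otherwise phylogenetic diversity is undefined and a ``ValueError`` is
    raised)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            leaf = next(edge.head_node.leaf_iter(), None)
            where = leaf.taxon.label if leaf and leaf.taxon else "internal node"
            raise ValueError(
                f"newick tree {path} has an edge without branch length "
                f"(near {where}); phylogenetic diversity is undefined")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    # branch lengths kept to >= 10 significant digits so round trips are
    # value-preserving
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True,
               real_value_format_specifier=".12g")


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path, totals_path: str | Path | None = None):
    """Read an OrthoFinder-style orthogroup listing.

    Row layout: ``OG0000001: genomeA|prot1 genomeA|prot2 genomeB|prot9``.
    Per-genome totals (all proteins, including singletons outside any group)
    come from an optional two-column TSV; without it the totals default to the
    per-genome sum of assigned proteins, a lower bound.
    """
    from .network import OrthogroupTable

    groups: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'OG: members' layout")
            og_id, members = line.split(":", 1)
            og_id = og_id.strip()
            counts: dict[str, int] = {}
            for token in members.split():
                if "|" not in token:
                    raise ValueError(
                        f"{path}:{lineno}: member {token!r} lacks 'genome|protein' form")
                genome = token.split("|", 1)[0]
                counts[genome] = counts.get(genome, 0) + 1
            groups[og_id] = counts

    if totals_path is not None:
        totals: dict[str, int] = {}
        with open(totals_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("genome_id"):
                    continue
                parts = line.split("\t")
                totals[parts[0]] = int(parts[1])
    else:
        totals = {}
        for counts in groups.values():
            for g, c in counts.items():
                totals[g] = totals.get(g, 0) + c
    return OrthogroupTable(groups=groups, totals=totals)


def write_orthogroups(table, path: str | Path, totals_path: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        for og_id in sorted(table.groups):
            members = []
            for genome in sorted(table.groups[og_id]):
                n = table.groups[og_id][genome]
                members.extend(f"{genome}|p{i}" for i in range(1, n + 1))
            fh.write(f"{og_id}: " + " ".join(members) + "\n")
    if totals_path is not None:
        with open(totals_path, "w") as fh:
            fh.write("genome_id\ttotal\n")
            for g in sorted(table.totals):
                fh.write(f"{g}\t{table.totals[g]}\n")


def write_edge_list(edges, path: str | Path, header_comment: str | None = None) -> None:
    """Write network edges as TSV (node_a, node_b, weight_percent)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("node_a\tnode_b\tweight_percent\n")
        for e in edges:
            fh.write(f"{e.genome_a}\t{e.genome_b}\t{e.weight:.6g}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline with their published defaults.

    ``marker_min_distinct`` is a strict lower bound: a bin is a candidate if
    it has *more than* this many distinct ancestral markers, and/or the major
    capsid protein marker.
    """

    marker_min_distinct: int = 5
    mcp_marker_id: str = "NCVOG0022"
    ancestral_marker_count: int = 20
    screen_evalue_cutoff: float = 1e-6
    ani_threshold: float = 95.0          # percent
    aligned_fraction_min: int = 100_000  # bp
    column_info_min: float = 0.10
    mcp_evalue_cutoff: float = 1e-6
    mcp_cluster_identity: float = 0.95
    mcp_min_aligned_aa: int = 50
    edge_weight_min: float = 18.0        # percent
    pool_size: int = 100
    contig_min_len: int = 2000           # bp
    contig_min_cov: float = 2.0
    contig_end_trim: int = 200           # bp
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = ["marker_min_distinct", "ancestral_marker_count",
                    "screen_evalue_cutoff", "ani_threshold",
                    "aligned_fraction_min", "column_info_min",
                    "mcp_evalue_cutoff", "mcp_cluster_identity",
                    "mcp_min_aligned_aa", "edge_weight_min", "pool_size",
                    "contig_min_len", "contig_min_cov", "contig_end_trim"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.column_info_min <= 1):
            raise ValueError("column_info_min must be in (0, 1]")
        if not (0 < self.mcp_cluster_identity <= 1):
            raise ValueError("mcp_cluster_identity must be in (0, 1]")
        if not (0 < self.ani_threshold <= 100):
            raise ValueError("ani_threshold must be in (0, 100]")

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
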