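"""Synthetic soil community with rare giant viruses: ground truth for every
downstream stage.

The generator emulates the statistical structure the analysis assumes,
without sequence content (downstream stages operate on tables and trees):

* a community of many cellular genomes plus a handful of NCLDV genomes,
  all viral abundances below a ceiling except one designated "abundant"
  virus whose bulk coverage reaches the detectable regime (~9x) while the
  rare viruses stay below 1x;
* NCLDV marker complements drawn from the 20-marker ancestral set as a
  mixture of complete (20/20), partial, and sub-threshold (<3 core marker)
  genomes, with truncated-geometric paralog copy numbers;
* an orthogroup table whose sharing probability decays with lineage
  distance, so within-lineage gene-sharing edge weights exceed
  cross-lineage ones;
* a lineage-structured tree with known total branch length (PD), plus a
  set of labeled reference genomes for taxonomy transfer;
* an ANI table in which reference genomes include planted near-duplicate
  pairs while the novel soil genomes share <95% ANI with everything, so
  they must come out of dereplication as singletons.

All randomness flows through integer-keyed generator streams derived from
one seed, so output is reproducible across platforms and call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import dendropy

from .io import ANIPair, HitRecord, tree_from_string
from .markers import MarkerDefinition, DEFAULT_MARKERS
from .network import OrthogroupTable
from . import phylo

LINEAGE_NAMES = (
    "Klosneuvirinae", "Megamimivirinae", "Mesomimivirinae", "Cafeteriavirus",
    "Marseilleviridae", "Pithoviridae", "Ascoviridae", "Phycodnaviridae",
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SyntheticGenome:
    genome_id: str
    klass: str  # "cellular" | "ncldv" | "reference"
    lineage: str
    length_bp: int
    marker_complement: dict[str, int]
    abundance: float
    bulk_depth: float
    category: str | None = None  # complete | partial | subthreshold
    is_abundant: bool = False

    @property
    def is_ncldv(self) -> bool:
        return self.klass == "ncldv"


@dataclass
class SyntheticTruth:
    """Everything the generator knows, for parameter-recovery scoring."""

    genomes: list[SyntheticGenome]
    markers: MarkerDefinition
    lineages: list[str]
    tree_newick: str
    pd_total: float               # sum of drawn branch lengths (independent accumulator)
    orthogroups: OrthogroupTable
    ani_pairs: list[ANIPair]
    seed: int
    pd_with: float | None = None
    pd_without: float | None = None

    def community(self) -> list[SyntheticGenome]:
        return [g for g in self.genomes if g.klass != "reference"]

    def ncldv_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes if g.klass == "ncldv"]

    def reference_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes if g.klass == "reference"]

    def abundances(self) -> dict[str, float]:
        return {g.genome_id: g.abundance for g in self.community()}

    def lengths(self) -> dict[str, int]:
        return {g.genome_id: g.length_bp for g in self.genomes}

    def reference_lineages(self) -> dict[str, str]:
        return {g.genome_id: g.lineage for g in self.genomes
                if g.klass == "reference"}


# ---------------------------------------------------------------------------
# marker complements
# ---------------------------------------------------------------------------

def _copy_number(rng: np.random.Generator, p: float = 0.77, cmax: int = 5) -> int:
    # truncated geometric, mean ~1.3: a light paralog-expansion mimic
    return int(min(rng.geometric(p), cmax))


def _draw_complement(
    category: str,
    markers: MarkerDefinition,
    rng: np.random.Generator,
    retention: float = 0.6,
) -> dict[str, int]:
    core = set(markers.core5_ids)
    non_core_non_mcp = [m for m in markers.marker_ids
                        if m not in core and m != markers.mcp_id]
    if category == "complete":
        return {m: _copy_number(rng) for m in markers.marker_ids}
    if category == "partial":
        while True:
            kept = [m for m in markers.marker_ids if rng.random() < retention]
            if kept and len(core & set(kept)) >= 3:
                return {m: _copy_number(rng) for m in kept}
    if category == "subthreshold":
        # <3 core markers and never a screening candidate: <=5 distinct, no MCP
        total = int(rng.integers(1, 6))
        n_core = int(min(rng.integers(0, 3), total))
        chosen = list(rng.choice(sorted(core), size=n_core, replace=False))
        n_extra = min(total - n_core, len(non_core_non_mcp))
        chosen += list(rng.choice(non_core_non_mcp, size=n_extra, replace=False))
        if not chosen:
            chosen = [non_core_non_mcp[0]]
        return {m: 1 for m in chosen}
    raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _join_random(labels: list[str], rng: np.random.Generator,
                 scale: float) -> tuple[str, float]:
    """Sequentially join shuffled labels into a random newick subtree;
    returns (newick fragment, total branch length drawn)."""
    nodes = [str(x) for x in labels]
    order = rng.permutation(len(nodes))
    nodes = [nodes[i] for i in order]
    total = 0.0
    while len(nodes) > 1:
        a = nodes.pop()
        b = nodes.pop()
        la = round(float(rng.exponential(scale)) + 0.02, 6)
        lb = round(float(rng.exponential(scale)) + 0.02, 6)
        total += la + lb
        nodes.append(f"({a}:{la},{b}:{lb})")
    return nodes[0], total


def _build_tree(
    by_lineage: dict[str, list[str]],
    rng: np.random.Generator,
    within_scale: float = 0.15,
    between_scale: float = 0.6,
) -> tuple[str, float]:
    subtrees = []
    total = 0.0
    for lineage in sorted(by_lineage):
        frag, t = _join_random(by_lineage[lineage], rng, within_scale)
        subtrees.append(frag)
        total += t
    if len(subtrees) == 1:
        return subtrees[0] + ";", total
    top, t = _join_random(subtrees, rng, between_scale)
    return top + ";", total + t


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def generate_community(
    n_cellular: int = 60,
    n_ncldv: int = 12,
    viral_abundance_ceiling: float = 2e-4,
    lineage_count: int = 4,
    seed: int = 0,
    n_references: int = 20,
    bulk_yield: float = 2e10,
    abundant_boost: float = 9.0,
    category_weights: tuple[float, float, float] = (0.3, 0.5, 0.2),
    marker_retention: float = 0.6,
    markers: MarkerDefinition = DEFAULT_MARKERS,
    n_duplicate_ref_pairs: int = 4,
) -> SyntheticTruth:
    """Generate a rare-virus soil community with full ground truth.

    One NCLDV genome (always with a complete marker complement) is boosted
    to ``abundant_boost`` times the viral abundance ceiling so its bulk
    coverage lands near 9x, while the remaining viruses are drawn below the
    ceiling and stay under 1x bulk coverage; cellular genomes absorb the
    rest of the abundance mass.  ``category_weights`` are the mixture
    weights of (complete, partial, subthreshold) marker complements.
    """
    if n_cellular < 1 or n_ncldv < 1 or lineage_count < 1:
        raise ValueError("counts must be >= 1")
    if not (0 < viral_abundance_ceiling < 1):
        raise ValueError("viral_abundance_ceiling must be in (0, 1)")
    w = np.asarray(category_weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("category weights must be non-negative, not all zero")
    w = w / w.sum()

    lineages = [LINEAGE_NAMES[i] if i < len(LINEAGE_NAMES) else f"lineage_{i + 1:02d}"
                for i in range(lineage_count)]

    rng_len = _rng(seed, 10)
    rng_cat = _rng(seed, 11)
    rng_ab = _rng(seed, 12)
    rng_og = _rng(seed, 13)
    rng_tree = _rng(seed, 14)
    rng_ani = _rng(seed, 15)

    cell_ids = [f"cell_{i + 1:04d}" for i in range(n_cellular)]
    gv_ids = [f"gv_{i + 1:03d}" for i in range(n_ncldv)]
    ref_ids = [f"ref_{i + 1:03d}" for i in range(n_references)]

    cell_len = rng_len.uniform(2e6, 6e6, size=n_cellular).astype(int)
    gv_len = rng_len.uniform(3e5, 1.5e6, size=n_ncldv).astype(int)
    ref_len = rng_len.uniform(3e5, 1.5e6, size=max(n_references, 1)).astype(int)

    categories = list(np.array(["complete", "partial", "subthreshold"])[
        rng_cat.choice(3, size=n_ncldv, p=w)])
    categories[0] = "complete"  # the designated abundant, bulk-detectable virus

    complements = [_draw_complement(c, markers, rng_cat, marker_retention)
                   for c in categories]

    # abundances: rare viruses below the ceiling, one boosted virus above it
    gv_ab = rng_ab.uniform(0.1, 0.9, size=n_ncldv) * viral_abundance_ceiling
    gv_ab[0] = abundant_boost * viral_abundance_ceiling
    cell_raw = rng_ab.lognormal(mean=0.0, sigma=1.0, size=n_cellular)
    cell_ab = cell_raw / cell_raw.sum() * (1.0 - gv_ab.sum())
    if viral_abundance_ceiling >= cell_ab.max():
        import logging
        logging.getLogger("soilgv").warning(
            "viral abundance ceiling %.3g >= max cellular abundance %.3g: "
            "regime is not rare-virus", viral_abundance_ceiling, cell_ab.max())

    denom = float(np.dot(cell_ab, cell_len) + np.dot(gv_ab, gv_len))
    genomes: list[SyntheticGenome] = []
    for i, gid in enumerate(cell_ids):
        genomes.append(SyntheticGenome(
            genome_id=gid, klass="cellular", lineage="cellular",
            length_bp=int(cell_len[i]), marker_complement={},
            abundance=float(cell_ab[i]),
            bulk_depth=bulk_yield * float(cell_ab[i]) / denom))
    for i, gid in enumerate(gv_ids):
        genomes.append(SyntheticGenome(
            genome_id=gid, klass="ncldv",
            lineage=lineages[i % lineage_count],
            length_bp=int(gv_len[i]), marker_complement=complements[i],
            abundance=float(gv_ab[i]),
            bulk_depth=bulk_yield * float(gv_ab[i]) / denom,
            category=categories[i], is_abundant=(i == 0)))
    for i, gid in enumerate(ref_ids):
        genomes.append(SyntheticGenome(
            genome_id=gid, klass="reference",
            lineage=lineages[i % lineage_count],
            length_bp=int(ref_len[i]),
            marker_complement={m: _copy_number(rng_cat) for m in markers.marker_ids},
            abundance=0.0, bulk_depth=0.0, category="complete"))

    orthogroups = _generate_orthogroups(genomes, rng_og)

    by_lineage: dict[str, list[str]] = {}
    for g in genomes:
        if g.klass in ("ncldv", "reference"):
            by_lineage.setdefault(g.lineage, []).append(g.genome_id)
    newick, pd_total = _build_tree(by_lineage, rng_tree)

    ani_pairs = _generate_ani(gv_ids, ref_ids, by_lineage, rng_ani,
                              n_duplicate_ref_pairs)

    return SyntheticTruth(
        genomes=genomes, markers=markers, lineages=lineages,
        tree_newick=newick, pd_total=pd_total, orthogroups=orthogroups,
        ani_pairs=ani_pairs, seed=seed)


def _generate_orthogroups(genomes: list[SyntheticGenome],
                          rng: np.random.Generator,
                          n_universal: int = 30,
                          n_per_lineage: int = 40,
                          n_private: int = 15,
                          p_in_universal: float = 0.95,
                          p_in_lineage: float = 0.9,
                          p_cross_lineage: float = 0.05) -> OrthogroupTable:
    """Lineage-structured orthogroups: universal groups span everyone,
    lineage groups are mostly confined to one lineage (sharing probability
    decays with lineage distance), plus private per-genome groups."""
    viral = [g for g in genomes if g.klass in ("ncldv", "reference")]
    lineages = sorted({g.lineage for g in viral})
    groups: dict[str, dict[str, int]] = {}
    k = 0

    def new_og() -> str:
        nonlocal k
        k += 1
        return f"OG{k:05d}"

    for _ in range(n_universal):
        counts = {g.genome_id: _copy_number(rng)
                  for g in viral if rng.random() < p_in_universal}
        if len(counts) >= 2:
            groups[new_og()] = counts
    for lineage in lineages:
        for _ in range(n_per_lineage):
            counts = {}
            for g in viral:
                p = p_in_lineage if g.lineage == lineage else p_cross_lineage
                if rng.random() < p:
                    counts[g.genome_id] = _copy_number(rng)
            if len(counts) >= 2:
                groups[new_og()] = counts
    for g in viral:
        for _ in range(n_private):
            groups[new_og()] = {g.genome_id: 1}

    assigned: dict[str, int] = {g.genome_id: 0 for g in viral}
    for counts in groups.values():
        for gid, c in counts.items():
            assigned[gid] += c
    totals = {gid: n + int(rng.integers(10, 40)) for gid, n in assigned.items()}
    return OrthogroupTable(groups=groups, totals=totals)


def _generate_ani(gv_ids: list[str], ref_ids: list[str],
                  by_lineage: dict[str, list[str]],
                  rng: np.random.Generator,
                  n_duplicate_ref_pairs: int) -> list[ANIPair]:
    pairs: list[ANIPair] = []
    # below-threshold within-lineage background: novel soil genomes never
    # reach 95% with anything, so they must remain derep singletons
    for members in by_lineage.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.random() < 0.5:
                    ani = float(rng.uniform(78, 90))
                    aligned = int(rng.uniform(5e4, 3e5))
                    pairs.append(ANIPair(a, b, round(ani, 2), aligned))
                    pairs.append(ANIPair(b, a, round(min(100.0, ani + float(rng.normal(0, 0.3))), 2),
                                         aligned + int(rng.integers(-5000, 5000))))
    # planted near-duplicate reference pairs (redundant published genomes)
    n_dup = min(n_duplicate_ref_pairs, len(ref_ids) // 2)
    for i in range(n_dup):
        a, b = ref_ids[2 * i], ref_ids[2 * i + 1]
        ani = float(rng.uniform(96, 99.5))
        aligned = int(rng.uniform(1.5e5, 4e5))
        pairs.append(ANIPair(a, b, round(ani, 2), aligned))
        pairs.append(ANIPair(b, a, round(min(100.0, ani + float(rng.normal(0, 0.2))), 2),
                             aligned + int(rng.integers(-2000, 2000))))
    return pairs


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def emit_hit_table(
    truth: SyntheticTruth,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    evalue_cutoff: float = 1e-6,
    bin_ids: Iterable[str] | None = None,
) -> list[HitRecord]:
    """Simulate a marker search over the community's bins.

    Each marker copy of an NCLDV genome yields one hit with an e-value
    log-uniform well below the cutoff; false negatives drop each such hit
    with probability ``noise[1]``, and false positives inject one spurious
    sub-cutoff hit per (cellular genome, marker) pair with probability
    ``noise[0]``.  ``bin_ids`` restricts emission to the bins actually
    recovered (e.g. genomes assembled from sorted pools).
    """
    fp_rate, fn_rate = noise
    if not (0 <= fp_rate < 1 and 0 <= fn_rate <= 1):
        raise ValueError("noise rates must be in [0, 1)")
    rng = _rng(seed, 20)
    allowed = set(bin_ids) if bin_ids is not None else None
    hits: list[HitRecord] = []
    for g in truth.community():
        if allowed is not None and g.genome_id not in allowed:
            continue
        if g.is_ncldv:
            pidx = 0
            for marker in sorted(g.marker_complement):
                for _copy in range(g.marker_complement[marker]):
                    pidx += 1
                    if rng.random() < fn_rate:
                        continue
                    evalue = 10.0 ** rng.uniform(-30, np.log10(evalue_cutoff) - 1)
                    hits.append(HitRecord(
                        query_id=f"{g.genome_id}_p{pidx}",
                        bin_id=g.genome_id, marker_id=marker,
                        evalue=float(evalue),
                        bitscore=float(rng.uniform(60, 500)),
                        aligned_len=int(rng.uniform(100, 400))))
        else:
            for j, marker in enumerate(truth.markers.marker_ids):
                if rng.random() < fp_rate:
                    evalue = 10.0 ** rng.uniform(np.log10(evalue_cutoff) - 1.5,
                                                 np.log10(evalue_cutoff) - 0.05)
                    hits.append(HitRecord(
                        query_id=f"{g.genome_id}_fp{j}",
                        bin_id=g.genome_id, marker_id=marker,
                        evalue=float(evalue),
                        bitscore=float(rng.uniform(30, 80)),
                        aligned_len=int(rng.uniform(50, 200))))
    return hits


def truth_to_dict(truth: SyntheticTruth) -> dict:
    """JSON-serializable dump of the ground truth (for stage manifests)."""
    return {
        "seed": truth.seed,
        "lineages": list(truth.lineages),
        "tree_newick": truth.tree_newick,
        "pd_total": truth.pd_total,
        "pd_with": truth.pd_with,
        "pd_without": truth.pd_without,
        "markers": {
            "marker_ids": list(truth.markers.marker_ids),
            "mcp_id": truth.markers.mcp_id,
            "core5_ids": list(truth.markers.core5_ids),
        },
        "genomes": [{
            "genome_id": g.genome_id, "klass": g.klass, "lineage": g.lineage,
            "length_bp": g.length_bp, "marker_complement": g.marker_complement,
            "abundance": g.abundance, "bulk_depth": g.bulk_depth,
            "category": g.category, "is_abundant": g.is_abundant,
        } for g in truth.genomes],
        "orthogroups": {"groups": truth.orthogroups.groups,
                        "totals": truth.orthogroups.totals},
        "ani_pairs": [[p.genome_a, p.genome_b, p.ani, p.aligned_bp]
                      for p in truth.ani_pairs],
    }


def truth_from_dict(d: dict) -> SyntheticTruth:
    markers = MarkerDefinition(
        marker_ids=tuple(d["markers"]["marker_ids"]),
        mcp_id=d["markers"]["mcp_id"],
        core5_ids=tuple(d["markers"]["core5_ids"]))
    genomes = [SyntheticGenome(**g) for g in d["genomes"]]
    return SyntheticTruth(
        genomes=genomes, markers=markers, lineages=list(d["lineages"]),
        tree_newick=d["tree_newick"], pd_total=d["pd_total"],
        orthogroups=OrthogroupTable(groups=d["orthogroups"]["groups"],
                                    totals=d["orthogroups"]["totals"]),
        ani_pairs=[ANIPair(a, b, ani, bp) for a, b, ani, bp in d["ani_pairs"]],
        seed=d["seed"], pd_with=d["pd_with"], pd_without=d["pd_without"])


def emit_mcp_catalog(
    truth: SyntheticTruth,
    seed: int = 0,
    n_bulk_unbinned: int = 243,
    n_bulk_binned: int = 2,
    n_redundant: int = 12,
    n_above_cutoff: int = 6,
    n_false_positive: int = 8,
    n_short_aligned: int = 5,
    evalue_cutoff: float = 1e-6,
):
    """Synthetic candidate-MCP catalog exercising every cascade stage.

    Emulates the survey substrate: one MCP per reference genome, one per
    MCP-carrying community MAG, and a large bulk fraction dominated by
    unbinned short low-coverage contigs (the default unbinned/binned split
    reproduces the ~99% unbinned regime).  Planted perturbations: redundant
    near-copies (collapsed at the clustering stage), hits above the e-value
    cutoff, false positives without an NCLDV MCP in their top-10 database
    hits, and survivors left with <50 aligned residues after trimming.

    Returns ``(candidates, nr_hits, trimmed_alignment, depth_rows, manifest)``
    where ``manifest`` records the planted fate of every candidate.
    """
    from .mcp import MCPCandidate
    from .phylo import MSAlignment

    rng = _rng(seed, 30)
    candidates: list[MCPCandidate] = []
    nr_hits: dict[str, list[str]] = {}
    expected_fate: dict[str, str] = {}  # survivor | evalue | cluster | top10 | aligned_len
    family_of: dict[str, int] = {}
    depth_rows: list[tuple[str, int, float, str]] = []
    fam = 0

    def good_evalue() -> float:
        return float(10.0 ** rng.uniform(-40, np.log10(evalue_cutoff) - 2))

    def add(pid, contig, source, evalue, length_aa, fate, family,
            contig_len, contig_cov, bin_id, mcp_in_top10=True, no_hits=False):
        candidates.append(MCPCandidate(
            protein_id=pid, contig_id=contig, source=source, evalue=evalue,
            contig_len_bp=contig_len, contig_cov=contig_cov,
            length_aa=length_aa))
        family_of[pid] = family
        expected_fate[pid] = fate
        if no_hits:
            nr_hits[pid] = []
        elif mcp_in_top10:
            rank = int(rng.integers(0, 10))
            labels = [f"hypothetical_protein_{i}" for i in range(10)]
            labels[rank] = "NCLDV major capsid protein MCP"
            nr_hits[pid] = labels
        else:
            nr_hits[pid] = [f"cellular_chaperone_{i}" for i in range(12)]
        if source != "reference":
            depth_rows.append((contig, contig_len, contig_cov, bin_id))

    for gid in truth.reference_ids():
        fam += 1
        add(f"{gid}_mcp", f"{gid}_c1", "reference", good_evalue(),
            int(rng.integers(400, 600)), "survivor", fam,
            int(rng.integers(50_000, 500_000)), 30.0, gid)

    for g in truth.genomes:
        if g.is_ncldv and truth.markers.mcp_id in g.marker_complement:
            fam += 1
            add(f"{g.genome_id}_mcp", f"{g.genome_id}_c1", "mag", good_evalue(),
                int(rng.integers(400, 600)), "survivor", fam,
                int(rng.integers(10_000, 200_000)), float(rng.uniform(3, 30)),
                g.genome_id)

    n_clean = n_bulk_unbinned - n_above_cutoff - n_false_positive - n_short_aligned
    if n_clean < 0:
        raise ValueError("planted perturbations exceed n_bulk_unbinned")
    for i in range(n_bulk_unbinned):
        fam += 1
        pid = f"bulk_{i + 1:04d}"
        # most bulk MCPs sit on short, low-coverage contigs
        short = rng.random() < 0.8
        contig_len = int(rng.integers(300, 1000)) if short else int(rng.integers(1001, 20_000))
        contig_cov = float(rng.uniform(0.3, 1.9)) if rng.random() < 0.85 else float(rng.uniform(2.0, 8.0))
        if i < n_above_cutoff:
            ev = float(10.0 ** rng.uniform(np.log10(evalue_cutoff) + 0.2, -2))
            add(pid, f"{pid}_c", "bulk_unbinned", ev,
                int(rng.integers(100, 400)), "evalue", fam,
                contig_len, contig_cov, "unbinned")
        elif i < n_above_cutoff + n_false_positive:
            add(pid, f"{pid}_c", "bulk_unbinned", good_evalue(),
                int(rng.integers(100, 400)), "top10", fam,
                contig_len, contig_cov, "unbinned", mcp_in_top10=False)
        elif i < n_above_cutoff + n_false_positive + n_short_aligned:
            add(pid, f"{pid}_c", "bulk_unbinned", good_evalue(),
                int(rng.integers(60, 120)), "aligned_len", fam,
                contig_len, contig_cov, "unbinned")
        else:
            novel = rng.random() < 0.3  # some bulk MCPs have no database hits
            add(pid, f"{pid}_c", "bulk_unbinned", good_evalue(),
                int(rng.integers(150, 500)), "survivor", fam,
                contig_len, contig_cov, "unbinned", no_hits=novel)

    for i in range(n_bulk_binned):
        fam += 1
        pid = f"bulkmag_{i + 1:02d}"
        add(pid, f"{pid}_c", "mag", good_evalue(), int(rng.integers(300, 500)),
            "survivor", fam, int(rng.integers(5_000, 60_000)),
            float(rng.uniform(5, 15)), f"bulk_bin_{i + 1}")

    # redundant near-copies of existing survivors: shorter members of the
    # same identity family, removed at the clustering stage
    survivor_pool = [c for c in candidates if expected_fate[c.protein_id] == "survivor"]
    for i in range(min(n_redundant, len(survivor_pool))):
        donor = survivor_pool[i]
        fam_id = family_of[donor.protein_id]
        pid = f"{donor.protein_id}_dup"
        add(pid, f"{pid}_c", donor.source, good_evalue(),
            max(60, donor.length_aa - int(rng.integers(5, 40))), "cluster",
            fam_id, donor.contig_len_bp, donor.contig_cov, "unbinned")

    def identity(a, b) -> float:
        return 0.99 if family_of[a.protein_id] == family_of[b.protein_id] else 0.40

    # trimmed-alignment stand-in: aligned residue counts only (columns are
    # positional padding)
    width = 700
    rows = {}
    for c in candidates:
        n_aligned = c.length_aa
        if expected_fate[c.protein_id] == "aligned_len":
            n_aligned = int(rng.integers(5, 50))
        n_aligned = min(n_aligned, width)
        rows[c.protein_id] = "A" * n_aligned + "-" * (width - n_aligned)
    trimmed = MSAlignment(rows=rows)

    manifest = {"expected_fate": expected_fate, "family_of": family_of,
                "identity": identity}
    return candidates, nr_hits, trimmed, depth_rows, manifest


def emit_tree(truth: SyntheticTruth, novel_ids: Iterable[str]
              ) -> tuple[dendropy.Tree, dendropy.Tree]:
    """The lineage tree with and without the novel genomes.

    The "without" tree is the "with" tree pruned of the novel leaves with
    unifurcations collapsed; the true PD of both is recorded on the truth
    object (the "without" value via the split-based subset computation,
    independent of the pruning code path).
    """
    novel = set(novel_ids)
    tree_with = tree_from_string(truth.tree_newick)
    leaves = phylo.leaf_labels(tree_with)
    if not novel <= leaves:
        raise ValueError(f"novel ids not in tree: {sorted(novel - leaves)}")
    keep = leaves - novel
    if not keep:
        raise ValueError("pruning all leaves leaves no tree")
    truth.pd_with = phylo.phylogenetic_diversity(tree_with)
    if novel:
        tree_without = phylo.prune_to_taxa(tree_with, keep)
        truth.pd_without = phylo.subset_diversity(tree_with, keep)
    else:
        tree_without = tree_from_string(truth.tree_newick)
        truth.pd_without = truth.pd_with
    return tree_with, tree_without
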