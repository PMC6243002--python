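"""End-to-end orchestration of the discovery pipeline with stage manifests.

Stage order: simulate → screen → derep → pd → network → mcp-survey →
benchmark.  Every stage records a JSON manifest (inputs and outputs with
content digests, the configuration snapshot digest, and the seed); a stage
is skipped on re-run when its manifest still matches the files on disk, so
deleting one stage's output re-executes only that stage and the ones after
it.  All data outputs are TSV/newick/JSON files whose content depends only
on configuration and seed, so a re-run with the same seed is byte-identical.

Presets
-------
``barre-woods``
    The default synthetic forest-soil community: many cellular genomes,
    twelve rare NCLDV genomes, one of which is abundant enough to be
    bulk-detectable, sorted as pools of 100 particles.
``mock5``
    A five-member bacterial mock community sorted as 59 pools of 10 cells,
    used to benchmark chimera formation.
``gv12``
    A simulated community of 12 giant viruses (one per major lineage) used
    to benchmark the binning workflow on viral data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import derep, mcp, network, phylo, screen, sim, synth
from .io import (RunConfig, write_ani_table, write_hit_table, write_newick,
                 write_orthogroups, write_edge_list, read_newick, tree_from_string,
                 read_hit_table, read_ani_table, read_orthogroups)

log = logging.getLogger("soilgv")

STAGES = ("simulate", "screen", "derep", "pd", "network", "mcp-survey",
          "benchmark")

PRESETS = {
    "barre-woods": dict(n_cellular=60, n_ncldv=12, lineage_count=4,
                        n_pools=360, pool_size=100,
                        clump=(0.3, 20), kind="soil"),
    "mock5": dict(n_cellular=5, n_ncldv=0, lineage_count=1,
                  n_pools=59, pool_size=10, clump=None, kind="mock"),
    "gv12": dict(n_cellular=0, n_ncldv=12, lineage_count=4,
                 n_pools=12, pool_size=100, clump=None, kind="mock"),
}

BULK_DETECTION_DEPTH = 1.0  # genomes below ~1x bulk coverage are not binnable
POOL_YIELD = 6e9            # amplified bases sequenced per sorted pool


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(stage: str, cfg: RunConfig, seed: int) -> str:
    return f"stage={stage} config={_config_digest(cfg)} seed={seed}"


@dataclass
class StageManifest:
    stage: str
    seed: int
    config_digest: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    timestamp: float

    def path(self, outdir: Path) -> Path:
        return outdir / f"manifest_{self.stage.replace('-', '_')}.json"

    def save(self, outdir: Path) -> None:
        with open(self.path(outdir), "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _stage_current(stage: str, outdir: Path, cfg: RunConfig, seed: int) -> bool:
    mpath = outdir / f"manifest_{stage.replace('-', '_')}.json"
    if not mpath.exists():
        return False
    try:
        m = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if m.get("seed") != seed or m.get("config_digest") != _config_digest(cfg):
        return False
    for rel, digest in {**m.get("inputs", {}), **m.get("outputs", {})}.items():
        p = outdir / rel
        if not p.exists() or _digest(p) != digest:
            return False
    return True


def _finish(stage: str, outdir: Path, cfg: RunConfig, seed: int,
            inputs: list[Path], outputs: list[Path]) -> StageManifest:
    man = StageManifest(
        stage=stage, seed=seed, config_digest=_config_digest(cfg),
        inputs={str(p.relative_to(outdir)): _digest(p) for p in inputs},
        outputs={str(p.relative_to(outdir)): _digest(p) for p in outputs},
        timestamp=time.time())
    man.save(outdir)
    return man


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path, seed: int,
                   preset: str = "barre-woods") -> list[Path]:
    p = PRESETS[preset]
    if p["kind"] == "soil":
        truth = synth.generate_community(
            n_cellular=p["n_cellular"], n_ncldv=p["n_ncldv"],
            lineage_count=p["lineage_count"], seed=seed)
    elif preset == "mock5":
        truth = synth.generate_community(
            n_cellular=5, n_ncldv=1, lineage_count=1, seed=seed,
            n_references=2, viral_abundance_ceiling=1e-6)
        # mock5 is a purely bacterial community: the token virus only keeps
        # the generator invariants satisfied and is excluded from sorting
    else:  # gv12
        truth = synth.generate_community(
            n_cellular=1, n_ncldv=12, lineage_count=4, seed=seed,
            viral_abundance_ceiling=0.08, abundant_boost=1.0)

    abundances = truth.abundances()
    if preset == "mock5":
        cell = [g.genome_id for g in truth.community() if g.klass == "cellular"]
        abundances = {g: 1.0 / len(cell) for g in cell}

    pools = sim.draw_pools(
        abundances, n_pools=p["n_pools"], pool_size=p["pool_size"],
        clump=p["clump"], clump_candidates=truth.ncldv_ids() or None,
        seed=seed)
    lengths = truth.lengths()
    amplified = [sim.amplify(pool, lengths, bias_sigma=1.0,
                             total_yield=POOL_YIELD, seed=seed)
                 for pool in pools]
    depth_df = sim.pools_to_depth_table(amplified)

    # a genome is recoverable from the sorted pools if some pool covers it
    # at assembly depth; recoverable from bulk if its bulk coverage reaches
    # the binning regime
    max_pool_depth = depth_df.groupby("genome_id")["depth"].max()
    mini_bins = sorted(g for g, d in max_pool_depth.items()
                       if d >= cfg.contig_min_cov)
    bulk_bins = sorted(g.genome_id for g in truth.community()
                       if g.bulk_depth >= BULK_DETECTION_DEPTH)

    hits_mini = synth.emit_hit_table(truth, noise=(0.0, 0.0), seed=seed,
                                     evalue_cutoff=cfg.screen_evalue_cutoff,
                                     bin_ids=mini_bins)
    hits_bulk = synth.emit_hit_table(truth, noise=(0.0, 0.0), seed=seed,
                                     evalue_cutoff=cfg.screen_evalue_cutoff,
                                     bin_ids=bulk_bins)

    hdr = _header("simulate", cfg, seed)
    out: list[Path] = []

    def w(name: str) -> Path:
        path = outdir / name
        out.append(path)
        return path

    truth_doc = synth.truth_to_dict(truth)
    truth_doc["_provenance"] = hdr
    truth_doc["mini_bins"] = mini_bins
    truth_doc["bulk_bins"] = bulk_bins
    with open(w("truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)

    with open(w("pools.tsv"), "w") as fh:
        fh.write(f"# {hdr}\npool_id\tgenome_id\tcount\tclump_events\n")
        for pool in pools:
            for g, c in sorted(pool.counts.items()):
                fh.write(f"{pool.pool_id}\t{g}\t{c}\t{pool.clump_events}\n")

    with open(w("pool_depths.tsv"), "w") as fh:
        fh.write(f"# {hdr}\n")
        depth_df.to_csv(fh, sep="\t", index=False)

    write_hit_table(hits_mini, w("hits_mini.tsv"), header_comment=hdr)
    write_hit_table(hits_bulk, w("hits_bulk.tsv"), header_comment=hdr)
    write_ani_table(truth.ani_pairs, w("ani.tsv"))
    write_orthogroups(truth.orthogroups, w("orthogroups.tsv"),
                      totals_path=w("og_totals.tsv"))
    tree = tree_from_string(truth.tree_newick)
    write_newick(tree, w("tree.nwk"))
    return out


def stage_screen(cfg: RunConfig, outdir: Path, seed: int) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "hits_mini.tsv", outdir / "hits_bulk.tsv",
              outdir / "truth.json"]
    truth_doc = json.loads((outdir / "truth.json").read_text())
    truth = synth.truth_from_dict(truth_doc)
    hdr = _header("screen", cfg, seed)
    outputs = []
    for label, bins_key in (("mini", "mini_bins"), ("bulk", "bulk_bins")):
        hits = read_hit_table(outdir / f"hits_{label}.tsv", dialect="plain_tsv")
        profiles = screen.profile_bins(
            hits, markers=truth.markers,
            evalue_cutoff=cfg.screen_evalue_cutoff,
            known_bins=truth_doc[bins_key],
            min_distinct=cfg.marker_min_distinct)
        path = outdir / f"bin_profiles_{label}.tsv"
        screen.write_bin_profiles(profiles, path, header_comment=hdr)
        outputs.append(path)
    return inputs, outputs


def stage_derep(cfg: RunConfig, outdir: Path, seed: int) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "ani.tsv", outdir / "truth.json"]
    truth = synth.truth_from_dict(json.loads((outdir / "truth.json").read_text()))
    pairs = read_ani_table(outdir / "ani.tsv")
    genomes = truth.ncldv_ids() + truth.reference_ids()
    cs = derep.dereplicate(genomes, pairs, ani_threshold=cfg.ani_threshold,
                           aligned_min=cfg.aligned_fraction_min,
                           lengths=truth.lengths())
    path = outdir / "clusters.tsv"
    derep.write_clusters(cs, path, header_comment=_header("derep", cfg, seed))
    return inputs, [path]


def stage_pd(cfg: RunConfig, outdir: Path, seed: int) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "tree.nwk", outdir / "truth.json",
              outdir / "bin_profiles_mini.tsv"]
    truth = synth.truth_from_dict(json.loads((outdir / "truth.json").read_text()))
    tree = read_newick(outdir / "tree.nwk")
    # novel taxa = phylogeny-eligible candidate NCLDV genomes from the screen
    prof = pd.read_csv(outdir / "bin_profiles_mini.tsv", sep="\t", comment="#")
    eligible = set(prof.loc[(prof.is_candidate == 1) &
                            (prof.phylogeny_eligible == 1), "bin_id"])
    novel = sorted(eligible & set(truth.ncldv_ids()) & phylo.leaf_labels(tree))
    result = phylo.pd_increase(tree, novel)
    path = outdir / "pd.tsv"
    with open(path, "w") as fh:
        fh.write(f"# {_header('pd', cfg, seed)}\n")
        fh.write("pd_with\tpd_without\tincrease_percent\tn_novel\n")
        fh.write(f"{result.pd_with:.6f}\t{result.pd_without:.6f}\t"
                 f"{result.increase_percent:.2f}\t{len(novel)}\n")
    return inputs, [path]


def stage_network(cfg: RunConfig, outdir: Path, seed: int) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "orthogroups.tsv", outdir / "og_totals.tsv"]
    table = read_orthogroups(outdir / "orthogroups.tsv",
                             totals_path=outdir / "og_totals.tsv")
    g = network.build_network(table, min_weight=cfg.edge_weight_min)
    edges = network.network_edges(g)
    rep = network.connectivity_report(g)
    hdr = _header("network", cfg, seed)
    epath = outdir / "network_edges.tsv"
    write_edge_list(edges, epath, header_comment=hdr)
    cpath = outdir / "network_components.tsv"
    with open(cpath, "w") as fh:
        fh.write(f"# {hdr}\ncomponent\tsize\tmembers\n")
        for i, comp in enumerate(rep.components, 1):
            fh.write(f"{i}\t{len(comp)}\t{','.join(sorted(comp))}\n")
        fh.write(f"# isolated: {','.join(rep.isolated) or 'none'}\n")
    return inputs, [epath, cpath]


def stage_mcp_survey(cfg: RunConfig, outdir: Path, seed: int) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "truth.json"]
    truth = synth.truth_from_dict(json.loads((outdir / "truth.json").read_text()))
    candidates, nr_hits, trimmed, depth_rows, manifest = synth.emit_mcp_catalog(
        truth, seed=seed, evalue_cutoff=cfg.mcp_evalue_cutoff)
    mcp.run_cascade(candidates, nr_hits, trimmed_alignment=trimmed,
                    identity=manifest["identity"],
                    evalue_cutoff=cfg.mcp_evalue_cutoff,
                    cluster_identity=cfg.mcp_cluster_identity,
                    min_aligned_aa=cfg.mcp_min_aligned_aa)
    depth_df = pd.DataFrame(depth_rows, columns=["contig_id", "length_bp",
                                                 "mean_depth", "bin_id"])
    report = mcp.fraction_report(candidates, depth=depth_df)
    hdr = _header("mcp-survey", cfg, seed)
    ppath = outdir / "mcp_provenance.tsv"
    mcp.write_provenance(candidates, ppath, header_comment=hdr)
    spath = outdir / "mcp_summary.tsv"
    with open(spath, "w") as fh:
        fh.write(f"# {hdr}\nmetric\tvalue\n")
        fh.write(f"total_survivors\t{report.total}\n")
        for src, n in sorted(report.by_source.items()):
            fh.write(f"source_{src}\t{n}\n")
        fh.write(f"unbinned_percent\t{report.unbinned_percent}\n")
        fh.write(f"contigs_gt1kb\t{report.long_contig}\n")
        fh.write(f"contigs_le1kb\t{report.short_contig}\n")
        fh.write(f"low_coverage_lt2\t{report.low_coverage}\n")
    return inputs, [ppath, spath]


def stage_benchmark(cfg: RunConfig, outdir: Path, seed: int,
                    n_chimeras: int = 0) -> tuple[list[Path], list[Path]]:
    inputs = [outdir / "truth.json", outdir / "pool_depths.tsv"]
    truth = synth.truth_from_dict(json.loads((outdir / "truth.json").read_text()))
    depth_df = pd.read_csv(outdir / "pool_depths.tsv", sep="\t", comment="#")
    max_depth = depth_df.groupby("genome_id")["depth"].max()
    recovered = [g for g in truth.community()
                 if max_depth.get(g.genome_id, 0.0) >= cfg.contig_min_cov]

    # assembly abstraction: each recovered genome yields a few clean
    # single-source contigs; chimeras are injected, not emergent
    contig_sources: dict[str, list[str]] = {}
    contig_lengths: dict[str, int] = {}
    for g in recovered:
        n_contig = 5
        for i in range(n_contig):
            cid = f"{g.genome_id}_c{i + 1}"
            contig_sources[cid] = [g.genome_id]
            contig_lengths[cid] = g.length_bp // (n_contig + 1)
    for i in range(n_chimeras):
        if len(recovered) < 2:
            break
        a, b = recovered[i % len(recovered)], recovered[(i + 1) % len(recovered)]
        cid = f"chimera_{i + 1}"
        contig_sources[cid] = [a.genome_id, b.genome_id]
        contig_lengths[cid] = 5000

    genome_lengths = {g.genome_id: g.length_bp for g in recovered}
    result = sim.benchmark_mock(contig_sources, contig_lengths, genome_lengths,
                                detection=depth_df)
    path = outdir / "benchmark.tsv"
    with open(path, "w") as fh:
        fh.write(f"# {_header('benchmark', cfg, seed)}\n")
        fh.write(f"# chimera_rate\t{result.chimera_rate:.6f}\n")
        fh.write("genome_id\trecovered_fraction\tpurity\n")
        for g in sorted(genome_lengths):
            fh.write(f"{g}\t{result.recovered_fraction[g]:.4f}\t"
                     f"{result.purity[g]:.4f}\n")
    return inputs, [path]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    cfg: RunConfig | None = None,
    outdir: str | Path = "soilgv_out",
    seed: int | None = None,
    preset: str = "barre-woods",
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> list[StageManifest]:
    """Run the stage chain, skipping stages whose manifests are current."""
    cfg = cfg or RunConfig()
    seed = cfg.rng_seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")

    required_inputs = {
        "simulate": [],
        "screen": ["hits_mini.tsv", "hits_bulk.tsv", "truth.json"],
        "derep": ["ani.tsv", "truth.json"],
        "pd": ["tree.nwk", "truth.json", "bin_profiles_mini.tsv"],
        "network": ["orthogroups.tsv", "og_totals.tsv"],
        "mcp-survey": ["truth.json"],
        "benchmark": ["truth.json", "pool_depths.tsv"],
    }

    manifests: list[StageManifest] = []
    upstream_stale = force
    for stage in STAGES:
        if stage not in stages:
            continue
        if not upstream_stale and _stage_current(stage, outdir, cfg, seed):
            log.info("stage %s is current; skipping", stage)
            continue
        upstream_stale = True
        missing = [n for n in required_inputs[stage]
                   if not (outdir / n).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {stage}: missing upstream outputs {missing}")
        log.info("running stage %s", stage)
        if stage == "simulate":
            outputs = stage_simulate(cfg, outdir, seed, preset=preset)
            inputs: list[Path] = []
        elif stage == "screen":
            inputs, outputs = stage_screen(cfg, outdir, seed)
        elif stage == "derep":
            inputs, outputs = stage_derep(cfg, outdir, seed)
        elif stage == "pd":
            inputs, outputs = stage_pd(cfg, outdir, seed)
        elif stage == "network":
            inputs, outputs = stage_network(cfg, outdir, seed)
        elif stage == "mcp-survey":
            inputs, outputs = stage_mcp_survey(cfg, outdir, seed)
        elif stage == "benchmark":
            inputs, outputs = stage_benchmark(cfg, outdir, seed)
        else:  # pragma: no cover
            raise ValueError(stage)
        manifests.append(_finish(stage, outdir, cfg, seed, inputs, outputs))
    return manifests
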