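# Methods

This note documents the models, decision rules, and numerical choices
behind `soilgv`, and what the synthetic-data generator does and does not
emulate.

## Screening model

A bin's marker profile is built from best-per-(protein, marker) hits at an
e-value cutoff of 1e-6. E-values are compared on the log10 scale with exact
ties broken by the higher bitscore, which avoids spurious reordering from
floating-point noise near denormals. "More than five different hits" is
interpreted as **more than five distinct marker identities**, not raw hit
rows: the phrase contrasts with copy number, and completeness is likewise
defined over distinct markers. The alternative hit-row reading is available
via `count_mode="hit_rows"`. The MCP (NCVOG0022) is a member of the
20-marker ancestral set but is additionally applied as an independent
selection condition ("and/or"), so a bin containing only the MCP is a
candidate at completeness 1/20. The screening e-value cutoff itself is a
configuration default of 1e-6 — the value documented for the MCP survey —
since no separate cutoff is fixed for bin screening.

The canonical membership of the 20 ancestral NCVOGs is curated in prior
literature rather than enumerated here; the marker module pins the six ids
the pipeline treats specially (the MCP and the five core phylogenomic
markers) and ships configurable stand-in labels for the remainder. All
downstream logic depends only on set membership, so substituting the real
ids changes nothing structurally.

Bin membership travels through an explicit contig→bin sidecar map. When a
protein id is not a key of the map, the contig id is derived by stripping a
trailing `_<gene index>` (the prodigal/GeneMark convention); anything else
is `unbinned`. Tabular coordinates are 1-based inclusive (HMMER
convention); internal slicing is half-open 0-based; conversion happens only
in readers/writers.

## Dereplication

ANI estimators are asymmetric, so the two orientations of a pair are
symmetrized by the arithmetic mean of ANI values and the minimum of aligned
lengths; an edge is kept iff mean ANI ≥ 95% **and** min aligned ≥ 100 kb
(all comparisons inclusive, following the "at least" phrasing). "100 kb
aligned fraction" is read as absolute aligned bases, not a percentage of
genome length. Clusters are single-linkage connected components — the
simplest rule consistent with "clusters and singletons"; a greedy-centroid
mode is provided behind a flag for sensitivity checks. The representative
is the longest member, ties broken by the lexicographically smallest id.

## Phylogenetic diversity

PD is the sum of branch lengths of the tree spanned by its leaves (Faith's
measure); it is invariant under re-rooting, and unrooted trees are handled
by traversing from an arbitrary seed node. The "without" tree is obtained
by pruning the novel leaves and collapsing unifurcations with branch
lengths summed; a two-tree mode accepts an independently inferred
"without" tree, since with/without tree pairs can also come from two
inference runs. The package also ships a second, split-based subset-PD
computation (an edge counts iff both sides of its split contain kept
leaves) used to cross-check the pruning path.

Column trimming keeps a column iff its fraction of non-gap characters is
≥ 10%. The additional "low information content" heuristic of trimAl is not
parameterized in the workflow this reproduces, so it is implemented as an
optional conservation rule (drop columns whose modal non-gap residue
frequency is below a threshold) and is **off by default**.

Taxonomy transfer walks from a query leaf toward the root to the smallest
clade containing at least one labeled reference leaf; the label is assigned
only if all reference leaves in that clade agree, otherwise the query stays
`unassigned` — mixed clades are treated as uninformative rather than
resolved by majority, mirroring how tree-based MCP classification leaves
ambiguous leaves unassigned.

## MCP cascade

Stage order is fixed: e-value → redundancy clustering → top-10 database
check → aligned-length, mirroring the narrative order of the original
workflow; each stage only drops or annotates, so survivor sets are nested
and the cascade is idempotent. Clustering is greedy longest-first at 95%
identity; identity defaults to global-alignment identity computed with
edlib (1 − edit distance / longer length) when sequences are present, or is
supplied as a function/matrix — the cd-hit word heuristic is a speed
optimization, not part of the semantics the result depends on. Proteins
with *no* database hits are kept at the top-10 stage (novelty is not
penalized); ranking is by bitscore with e-value and label tie-breaks. The
1 kb contig-class boundary is strict (`> 1000` bp is "long"); contigs of
exactly 1000 bp are counted short and reported separately since the
boundary case is otherwise undefined.

## Gene-sharing network

For genomes *a, b*: shared orthogroups are those with ≥1 member from both;
each genome's directed percentage counts **all its proteins** in shared
groups (paralogs included — the quantity is a percentage of proteins, not
of groups) over its own total protein count, and the edge weight is the
mean of the two directed percentages. A union-based weight is available
behind `mode="union"` for sensitivity analysis. Per-genome totals are an
explicit input column (they include singleton proteins outside every
group); absent a totals file the reader falls back to the per-genome sum of
assigned proteins, a documented lower bound. The 18% filter is inclusive;
isolated genomes remain as degree-0 nodes, and clade removal (e.g. an
over-represented virus family) is a generic exclude-list input rather than
hard-coded taxa.

## Simulator

Pools are multinomial draws of 100 particles from the particle-abundance
vector. With a per-pool clumping probability, one NCLDV genome
(abundance-weighted among candidates — the vacuole scenario) receives a
fixed number of extra clonal particles, displacing uniformly chosen other
particles so pool size is preserved. The closed forms
`P(present) = 1 − (1−p)^n` and
`P(≥2) = 1 − (1−p)^n − np(1−p)^(n−1)` use the binomial marginal of the
multinomial component — exact for two species and asymptotically accurate
for rare ones — to quantify how unlikely multiple identical rare particles
are without clumping (≈ 26% at p = 0.01 versus ≈ 0.005% at p = 1e-4).

MDA bias is modeled as an i.i.d. lognormal(0, σ) amplification factor per
particle, σ = 1.0 by default: in this analysis bias matters only as the
reason per-contig coverage is uninformative for binning, so no
sequence-position model is attempted. Amplified mass per genome is the
factor sum times genome length; depths are normalized so that
Σ depth×length equals the configured pool yield exactly, and σ = 0 gives
factors ≡ 1 and depth exactly proportional to particle counts.

Assembly is abstracted to depth emission plus a contig→source manifest;
chimeras are therefore *injected* for benchmarking, not emergent, and the
default injection count is zero (matching the observation that the sorted
workflow produces no chimeric contigs). Contig QC trims 200 bp from each
end, then keeps contigs with trimmed length ≥ 2 kb and coverage ≥ 2 (both
inclusive).

## Synthetic community (study conditions)

Defaults emulate the rare-virus regime: 60 cellular genomes (2–6 Mb,
lognormal abundances), 12 NCLDV genomes (0.3–1.5 Mb) across 4 lineages,
20 labeled reference genomes, and a bulk sequencing yield of 2×10¹⁰ bp.
Viral abundances are drawn below a ceiling of 2×10⁻⁴ except one designated
abundant virus boosted 9-fold, which places the abundant virus near 9×
bulk coverage and the rest below 1× — the regime in which bulk binning
recovers exactly one giant virus while pool sorting recovers the rest. 360
pools of 100 particles are sorted per run (four samples × 90 pools), with
vacuole clumping at probability 0.3 per pool delivering 20 clonal copies.

Marker complements are a mixture of complete (20/20), partial (per-marker
retention 0.6, constrained to ≥3 core markers), and sub-threshold (<3 core
markers, ≤5 distinct, never the MCP — genomes that no marker screen can
recover) at weights 0.3/0.5/0.2; copy numbers are truncated-geometric with
mean ≈ 1.3 as a light paralog-expansion mimic. Orthogroup sharing decays
with lineage distance (universal groups, lineage groups present at 0.9
in-lineage versus 0.05 across, private groups), which makes within-lineage
edge weights exceed cross-lineage ones. The tree is built by random joins
within lineages (exponential branch lengths, scale 0.15) and between
lineage roots (scale 0.6), with total branch length recorded
independently of any tree library as the generator's PD ground truth. ANI
pairs place all within-lineage backgrounds at 78–90% (below threshold) and
plant near-duplicate reference pairs at 96–99.5%, so novel genomes must
dereplicate to singletons.

What the generator does **not** emulate: sequence content and its
evolution (generators emit labeled records, since every downstream stage
operates on tables and trees), read-level error and assembly, emergent MDA
chimerism, and database-versioning effects on e-values. Passing tests
therefore demonstrate the correctness of the decision logic and statistics
under the assumed statistical structure, not robustness to alignment or
assembly artifacts of real data.

All randomness flows through integer-keyed `numpy` generator streams
derived from one seed (one stream per sub-generator, pool streams keyed by
CRC32 of the pool id), so results are reproducible across platforms and
insensitive to call order.

## Pipeline and problem sizes

Stages run as simulate → screen → derep → pd → network → mcp-survey →
benchmark, each writing a JSON manifest of input/output content digests,
configuration digest and seed; a stage re-runs only when its manifest no
longer matches the files on disk. Data outputs carry a provenance header
(`# stage=… config=… seed=…`) except JSON (provenance key) and newick
(digest recorded in the manifest only, as comments in newick are not
portable). The default problem sizes — 72-genome community, 360 pools,
10,000-pool calibration batches, 200 random graphs for the clustering
oracle — keep the full suite and the acceptance script in the seconds
range while leaving Monte-Carlo standard errors small enough for 3-s.e.
checks to be meaningful.

## Known limitations

* Chimera rates and clump frequency have no published quantitative values;
  both are free parameters with the documented defaults.
* The headline field numbers (16 MAGs, 245 bulk MCPs, 132 ANI clusters)
  arise from terabase-scale metagenomes and live database versions and are
  not reproducible at desk scale; the package reproduces the *rules and
  statistics* that generated them, validated on synthetic ground truth.
* The PD-gain figures for the real with/without trees require the study's
  deposited trees as input (`soilgv.phylo.pd_increase` or the two-tree
  mode applied to downloaded newick files); desk-scale validation uses
  synthetic trees with known PD.
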