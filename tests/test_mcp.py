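"""The MCP filter cascade: stage boundaries, nesting, idempotence, and the
binned/unbinned fraction accounting."""

import random

import pandas as pd
import pytest

from soilgv import mcp, synth
from soilgv.mcp import (MCPCandidate, cluster_95, filter_aligned_length,
                        filter_evalue, fraction_report, run_cascade,
                        survivors, top10_rescue)
from soilgv.phylo import MSAlignment


def _cand(pid, evalue=1e-10, source="bulk_unbinned", length_aa=300,
          seq=None, contig_len=5000, cov=1.0):
    return MCPCandidate(protein_id=pid, contig_id=f"{pid}_c", source=source,
                        evalue=evalue, length_aa=length_aa, sequence=seq,
                        contig_len_bp=contig_len, contig_cov=cov)


# ---------------------------------------------------------------------------
# e-value stage
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("evalue, kept", [
    (1e-7, True), (1e-6, True), (1e-5, False),
])
def test_evalue_cutoff_boundary(evalue, kept):
    c = _cand("p", evalue=evalue)
    filter_evalue([c], cutoff=1e-6)
    assert c.alive is kept
    if not kept:
        assert c.dropped_at == "evalue"


def test_evalue_empty_input():
    assert filter_evalue([]) == []


# ---------------------------------------------------------------------------
# 95% clustering
# ---------------------------------------------------------------------------

def test_identical_sequences_one_representative():
    a = _cand("a", seq="MKLVWGA" * 20)
    b = _cand("b", seq="MKLVWGA" * 20)
    cluster_95([a, b])
    reps = [c for c in (a, b) if c.cluster_rep]
    assert len(reps) == 1
    assert reps[0].protein_id == "a"  # equal length, id tie-break


def test_dissimilar_sequences_all_representatives():
    cands = [_cand("a", seq="MKLV" * 30), _cand("b", seq="WWGA" * 30),
             _cand("c", seq="CCHY" * 30)]
    cluster_95(cands)
    assert all(c.cluster_rep for c in cands)


def test_greedy_longest_first_matches_explicit_replay():
    rng = random.Random(23)
    n = 18
    fam = {f"p{i}": rng.randint(0, 5) for i in range(n)}
    lengths = {f"p{i}": rng.randint(100, 500) for i in range(n)}
    cands = [_cand(p, length_aa=lengths[p]) for p in fam]

    def ident(x, y):
        return 0.99 if fam[x.protein_id] == fam[y.protein_id] else 0.3

    cluster_95(cands, identity=ident)

    # explicit-loop oracle
    order = sorted(fam, key=lambda p: (-lengths[p], p))
    reps = []
    assign = {}
    for p in order:
        for r in reps:
            if fam[p] == fam[r]:
                assign[p] = r
                break
        else:
            reps.append(p)
            assign[p] = p
    got_reps = {c.protein_id for c in cands if c.cluster_rep}
    assert got_reps == set(reps)


def test_cluster_without_sequences_requires_identity_fn():
    with pytest.raises(ValueError, match="identity"):
        cluster_95([_cand("a"), _cand("b")])


# ---------------------------------------------------------------------------
# top-10 rescue
# ---------------------------------------------------------------------------

def test_no_database_hits_kept():
    c = _cand("p")
    top10_rescue([c], {"p": []})
    assert c.alive


def test_ten_non_mcp_hits_dropped():
    c = _cand("p")
    top10_rescue([c], {"p": [f"chaperone_{i}" for i in range(10)]})
    assert c.dropped_at == "top10"


def test_mcp_at_rank_ten_exactly_kept():
    hits = [f"other_{i}" for i in range(9)] + ["NCLDV MCP major capsid"]
    c = _cand("p")
    top10_rescue([c], {"p": hits})
    assert c.alive and c.top10_rescued


def test_mcp_at_rank_eleven_dropped():
    hits = [f"other_{i}" for i in range(10)] + ["NCLDV MCP major capsid"]
    c = _cand("p")
    top10_rescue([c], {"p": hits})
    assert c.dropped_at == "top10"


# ---------------------------------------------------------------------------
# aligned-length stage
# ---------------------------------------------------------------------------

def _trimmed(counts, width=100):
    return MSAlignment(rows={p: "A" * n + "-" * (width - n)
                             for p, n in counts.items()})


@pytest.mark.parametrize("aligned, kept", [(49, False), (50, True), (0, False)])
def test_aligned_length_boundary(aligned, kept):
    c = _cand("p")
    other = _cand("q")
    aln = _trimmed({"p": aligned, "q": 80})
    filter_aligned_length([c, other], aln, min_aa=50)
    assert c.alive is kept
    if not kept:
        assert c.dropped_at == "aligned_len"


def test_candidate_missing_from_alignment_errors():
    c = _cand("p")
    with pytest.raises(ValueError, match="p"):
        filter_aligned_length([c], _trimmed({"q": 80, "r": 90}))


# ---------------------------------------------------------------------------
# whole cascade
# ---------------------------------------------------------------------------

def _catalog(truth, seed=5):
    return synth.emit_mcp_catalog(truth, seed=seed)


def test_cascade_survivor_sets_nested(small_truth):
    cands, nr_hits, trimmed, _depths, man = _catalog(small_truth)
    sets = []
    filter_evalue(cands)
    sets.append({c.protein_id for c in survivors(cands)})
    cluster_95(cands, identity=man["identity"])
    sets.append({c.protein_id for c in survivors(cands)})
    top10_rescue(cands, nr_hits)
    sets.append({c.protein_id for c in survivors(cands)})
    filter_aligned_length(cands, trimmed)
    sets.append({c.protein_id for c in survivors(cands)})
    for earlier, later in zip(sets, sets[1:]):
        assert later <= earlier


def test_cascade_idempotent(small_truth):
    cands, nr_hits, trimmed, _d, man = _catalog(small_truth)
    run_cascade(cands, nr_hits, trimmed_alignment=trimmed,
                identity=man["identity"])
    state1 = [(c.protein_id, c.dropped_at, c.cluster_rep) for c in cands]
    run_cascade(cands, nr_hits, trimmed_alignment=trimmed,
                identity=man["identity"])
    state2 = [(c.protein_id, c.dropped_at, c.cluster_rep) for c in cands]
    assert state1 == state2


def test_injected_false_positives_all_removed_at_top10(small_truth):
    cands, nr_hits, trimmed, _d, man = _catalog(small_truth)
    run_cascade(cands, nr_hits, trimmed_alignment=trimmed,
                identity=man["identity"])
    fate = man["expected_fate"]
    for c in cands:
        if fate[c.protein_id] == "top10":
            assert c.dropped_at == "top10"
        elif fate[c.protein_id] == "survivor":
            assert c.alive, (c.protein_id, c.dropped_at)
        else:
            assert c.dropped_at == fate[c.protein_id], c.protein_id


# ---------------------------------------------------------------------------
# fraction accounting
# ---------------------------------------------------------------------------

def test_unbinned_share_ninety_nine_percent():
    cands = [_cand(f"u{i}", source="bulk_unbinned") for i in range(99)]
    cands.append(_cand("m", source="mag"))
    rep = fraction_report(cands)
    assert rep.bulk_total == 100
    assert rep.unbinned_percent == 99.0


def test_empty_survivor_report():
    rep = fraction_report([])
    assert rep.total == 0
    assert rep.unbinned_percent is None
    assert rep.long_contig == rep.short_contig == 0


def test_length_boundary_one_kb_counted_short():
    cands = [_cand("a", contig_len=1000), _cand("b", contig_len=1001),
             _cand("c", contig_len=999)]
    rep = fraction_report(cands)
    assert rep.long_contig == 1
    assert rep.short_contig == 2
    assert rep.boundary_1kb == 1


def test_low_coverage_flag_counts():
    cands = [_cand("a", cov=1.9), _cand("b", cov=2.0), _cand("c", cov=0.5)]
    rep = fraction_report(cands)
    assert rep.low_coverage == 2


def test_report_counts_match_truth_manifest(small_truth):
    cands, nr_hits, trimmed, depth_rows, man = _catalog(small_truth)
    run_cascade(cands, nr_hits, trimmed_alignment=trimmed,
                identity=man["identity"])
    depth = pd.DataFrame(depth_rows, columns=["contig_id", "length_bp",
                                              "mean_depth", "bin_id"])
    rep = fraction_report(cands, depth=depth)
    expected_survivors = [p for p, f in man["expected_fate"].items()
                          if f == "survivor"]
    assert rep.total == len(expected_survivors)


def test_survivor_contig_missing_from_depth_errors():
    c = _cand("p", source="bulk_unbinned")
    depth = pd.DataFrame([("other", 5000, 1.0, "unbinned")],
                         columns=["contig_id", "length_bp", "mean_depth", "bin_id"])
    with pytest.raises(ValueError, match="p_c"):
        fraction_report([c], depth=depth)
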