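"""The FACS-pool / MDA simulator: pool draws, clumping, amplification,
contig QC, and benchmark metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilgv import sim
from soilgv.sim import (AmplifiedPool, SortPool, amplify, benchmark_mock,
                        clonal_copy_probability, contig_qc, draw_pools,
                        estimate_abundances, presence_probability)


def _uniform_abundances(n):
    return {f"g{i}": 1.0 / n for i in range(n)}


# ---------------------------------------------------------------------------
# pool draws
# ---------------------------------------------------------------------------

def test_single_species_pools_are_pure():
    pools = draw_pools({"only": 1.0}, n_pools=5, pool_size=100, seed=1)
    assert all(p.counts == {"only": 100} for p in pools)


def test_pool_size_invariant_with_and_without_clumping():
    ab = {"cell": 0.99, "gv": 0.01}
    pools = draw_pools(ab, n_pools=200, pool_size=100,
                       clump=(0.5, 20), clump_candidates=["gv"], seed=3)
    assert all(p.total() == 100 for p in pools)
    assert sum(p.clump_events for p in pools) > 0


def test_clump_copies_must_fit_pool():
    with pytest.raises(ValueError):
        draw_pools({"a": 1.0}, 1, pool_size=10, clump=(0.5, 10), seed=0)


def test_determinism_under_seed():
    ab = _uniform_abundances(5)
    a = draw_pools(ab, 20, seed=9)
    b = draw_pools(ab, 20, seed=9)
    assert [(p.pool_id, p.counts) for p in a] == [(p.pool_id, p.counts) for p in b]
    c = draw_pools(ab, 20, seed=10)
    assert [p.counts for p in a] != [p.counts for p in c]


def test_distinct_seeds_statistically_indistinguishable():
    """Pooled counts from two seeds should agree by a chi-square test."""
    ab = _uniform_abundances(6)
    totals = []
    for seed in (1, 2):
        pools = draw_pools(ab, 300, seed=seed)
        agg = {}
        for p in pools:
            for g, c in p.counts.items():
                agg[g] = agg.get(g, 0) + c
        totals.append([agg[f"g{i}"] for i in range(6)])
    _stat, pval, *_ = stats.chi2_contingency(np.array(totals))
    assert pval > 1e-4


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_clonal_copy_probability_limits():
    assert clonal_copy_probability(1e-9, 100) < 1e-13
    assert clonal_copy_probability(1 - 1e-12, 100) == pytest.approx(1.0)


def test_clonal_copy_probability_matches_pmf_summation():
    p, n = 0.01, 100
    expected = sum(stats.binom.pmf(k, n, p) for k in range(2, n + 1))
    assert clonal_copy_probability(p, n) == pytest.approx(expected, rel=1e-9)


def test_presence_probability_closed_form():
    assert presence_probability(0.01, 100) == pytest.approx(1 - 0.99 ** 100)


# ---------------------------------------------------------------------------
# amplification
# ---------------------------------------------------------------------------

def test_zero_bias_gives_unit_factors_and_proportional_depth():
    pool = SortPool("pool_1", {"a": 60, "b": 40})
    lengths = {"a": 1_000_000, "b": 500_000}
    amp = amplify(pool, lengths, bias_sigma=0.0, total_yield=1e9, seed=4)
    assert amp.amplification == {"a": 1.0, "b": 1.0}
    # depth ratio equals particle-count ratio exactly when factors are 1
    assert amp.emitted_depth["a"] / amp.emitted_depth["b"] == pytest.approx(60 / 40)


def test_yield_normalization_exact():
    pool = SortPool("pool_2", {"a": 10, "b": 5, "c": 85})
    lengths = {"a": 2_000_000, "b": 300_000, "c": 4_000_000}
    amp = amplify(pool, lengths, bias_sigma=1.0, total_yield=5e8, seed=4)
    total = sum(amp.emitted_depth[g] * lengths[g] for g in amp.emitted_depth)
    assert total == pytest.approx(5e8, rel=1e-9)


def test_lognormal_bias_cv_matches_closed_form():
    """CV of per-particle factors over many draws ~ sqrt(exp(sigma^2)-1)."""
    sigma = 0.8
    pool = SortPool("pool_cv", {"a": 1})
    lengths = {"a": 1_000_000}
    draws = []
    for i in range(4000):
        p = SortPool(f"pool_{i}", {"a": 1})
        amp = amplify(p, lengths, bias_sigma=sigma, total_yield=1.0, seed=6)
        draws.append(amp.amplification["a"])
    draws = np.asarray(draws)
    cv = draws.std() / draws.mean()
    expected = np.sqrt(np.exp(sigma ** 2) - 1)
    assert cv == pytest.approx(expected, rel=0.1)


# ---------------------------------------------------------------------------
# contig QC
# ---------------------------------------------------------------------------

def _contigs(rows):
    return pd.DataFrame(rows, columns=["contig_id", "length_bp", "mean_depth"])


def test_contig_qc_trim_then_filter_rules():
    df = _contigs([
        ("short", 1900, 10.0),     # post-trim 1500 < 2000: discarded
        ("lowcov", 5000, 1.5),     # coverage < 2: discarded
        ("boundary", 2400, 2.0),   # post-trim exactly 2000, cov exactly 2: kept
        ("good", 10_000, 8.0),
    ])
    out = contig_qc(df)
    assert sorted(out["contig_id"]) == ["boundary", "good"]
    assert out.loc[out.contig_id == "boundary", "trimmed_len_bp"].iloc[0] == 2000


def test_contig_qc_tiny_contig_trims_to_zero():
    out = contig_qc(_contigs([("tiny", 300, 50.0)]))
    assert out.empty


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

def test_chimera_free_assembly_rate_zero():
    sources = {f"c{i}": ["gA"] for i in range(50)}
    lengths = {f"c{i}": 10_000 for i in range(50)}
    res = benchmark_mock(sources, lengths, {"gA": 600_000})
    assert res.chimera_rate == 0.0
    assert res.purity["gA"] == 1.0


def test_single_injected_chimera_rate():
    sources = {f"c{i}": ["gA"] for i in range(99)}
    sources["chim"] = ["gA", "gB"]
    lengths = {c: 1000 for c in sources}
    res = benchmark_mock(sources, lengths, {"gA": 500_000, "gB": 500_000})
    assert res.chimera_rate == pytest.approx(0.01)
    assert res.purity["gA"] < 1.0


def test_contig_without_source_errors():
    with pytest.raises(ValueError):
        benchmark_mock({"c1": []}, {"c1": 100}, {"g": 1000})


def test_mock5_ten_cell_sorts_detect_every_genome():
    """Five-genome mock community, 59 sorts of 10 cells: every genome
    appears in at least one sort with positive depth."""
    ab = _uniform_abundances(5)
    pools = draw_pools(ab, n_pools=59, pool_size=10, seed=12)
    lengths = {g: 4_000_000 for g in ab}
    detected = set()
    for pool in pools:
        amp = amplify(pool, lengths, bias_sigma=1.0, total_yield=1e9, seed=12)
        detected |= {g for g, d in amp.emitted_depth.items() if d > 0}
    assert detected == set(ab)


# ---------------------------------------------------------------------------
# statistical recovery
# ---------------------------------------------------------------------------

def test_abundance_recovery_within_three_se():
    ab = {"a": 0.5, "b": 0.3, "c": 0.15, "d": 0.05}
    n_pools, pool_size = 1000, 100
    pools = draw_pools(ab, n_pools, pool_size=pool_size, seed=21)
    est = estimate_abundances(pools)
    n = n_pools * pool_size
    for g, p in ab.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(est[g] - p) <= 3 * se, g


def test_rare_virus_bulk_vs_pool_contrast():
    """A virus detectable in bulk stays at depth >= threshold there, while a
    rarer one is invisible in bulk yet reaches high within-pool depth when a
    clump event delivers clonal copies."""
    lengths = {"cell": 4_000_000, "gv_abundant": 600_000, "gv_rare": 600_000}
    ab = {"cell": 1 - 1.8e-3 - 1e-4, "gv_abundant": 1.8e-3, "gv_rare": 1e-4}
    bulk_yield = 2e10
    denom = sum(ab[g] * lengths[g] for g in ab)
    bulk_depth = {g: bulk_yield * ab[g] / denom for g in ab}
    assert bulk_depth["gv_abundant"] >= 1.0
    assert bulk_depth["gv_rare"] < 1.0
    pools = draw_pools(ab, 400, pool_size=100, clump=(1.0, 20),
                       clump_candidates=["gv_rare"], seed=33)
    clumped = [p for p in pools if p.clump_events and p.counts.get("gv_rare", 0) >= 20]
    assert clumped
    amp = amplify(clumped[0], lengths, bias_sigma=0.0, total_yield=6e9, seed=33)
    assert amp.emitted_depth["gv_rare"] >= 2.0
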