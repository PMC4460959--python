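"""Probe-gene linking: U tests, permutation empirical p, clustering, characterization."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerlink.pairing import (
    PermutationEngine,
    _batch_mwu_less,
    adjacent_genes,
    cluster_probes,
    distance_null_histogram,
    empirical_pvalue,
    find_pairs,
    loop_overlap_enrichment,
    nearest_rank_profile,
    pair_utest,
    variability_filter,
)
from enhancerlink.types import GeneModel, GenomicInterval, Probe


class TestAdjacentGenes:
    def test_symmetric_layout(self):
        probe = Probe("p", "chr1", 1_000_000)
        genes = [GeneModel(f"g{d:+d}", "chr1", "+", 1_000_000 + d * 10_000)
                 for d in range(-10, 11) if d != 0]
        out = adjacent_genes(probe, genes)
        assert len(out) == 20
        assert set(out.loc[out["rank"] <= 2, "gene_id"]) == {"g-1", "g+1"}
        assert (out.groupby("side").size() == 10).all()

    def test_truncation_near_contig_edge(self):
        probe = Probe("p", "chr1", 100_000)
        genes = [GeneModel(f"u{i}", "chr1", "+", 100_000 - (i + 1) * 5_000)
                 for i in range(3)]
        genes += [GeneModel(f"d{i}", "chr1", "+", 100_000 + (i + 1) * 5_000)
                  for i in range(15)]
        out = adjacent_genes(probe, genes)
        assert len(out) == 13
        assert (out["side"] == "upstream").sum() == 3

    def test_missing_chromosome_empty(self):
        out = adjacent_genes(Probe("p", "chrZ", 5_000),
                             [GeneModel("g", "chr1", "+", 1)])
        assert len(out) == 0

    def test_random_layout_against_sort_oracle(self, rng):
        probe = Probe("p", "chr1", 500_000)
        genes = [GeneModel(f"g{i}", "chr1", "+", int(t))
                 for i, t in enumerate(rng.integers(1, 1_000_000, size=60))]
        out = adjacent_genes(probe, genes)
        for side, sign in (("upstream", -1), ("downstream", 1)):
            cands = sorted(
                ((abs(g.tss - probe.pos), g.gene_id) for g in genes
                 if (g.tss - probe.pos < 0) == (sign < 0)),
            )[:10]
            got = out[out["side"] == side].sort_values(["rank"])
            assert list(got["gene_id"]) == [g for _, g in sorted(
                ((d, g) for d, g in cands))][: len(got)]


class TestVariabilityFilter:
    def test_boundary_inclusive(self):
        betas = [0.4] * 5 + [0.1] * 95
        assert variability_filter(betas, direction="hypo") is True

    def test_flat_low_fails_hypo(self):
        assert variability_filter([0.05] * 50, direction="hypo") is False

    def test_hyper_mirrored(self):
        betas = [0.1] * 5 + [0.9] * 95
        assert variability_filter(betas, direction="hyper") is True
        assert variability_filter([0.9] * 50, direction="hyper") is False

    def test_random_counting_oracle(self, rng):
        for _ in range(20):
            betas = rng.random(40)
            expected = bool((betas > 0.3).mean() >= 0.05)
            assert variability_filter(betas, direction="hypo") is expected


def enumeration_mwu_less(x_m, x_u):
    """Exhaustive permutation oracle for P(expr(M) < expr(U)), one-sided."""
    pooled = list(x_m) + list(x_u)
    k = len(x_m)
    def u_stat(m_vals, u_vals):
        return sum((m < u) + 0.5 * (m == u) for m in m_vals for u in u_vals)
    obs = u_stat(x_u, x_m)  # observed U of M group = #(u < m) pairs orientation
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), k):
        m = [pooled[i] for i in comb]
        u = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if u_stat(u, m) <= obs:
            count += 1
    return count / total


class TestPairUTest:
    def test_exact_small_case(self):
        # M = two highest-beta samples with expr {1,2}; U with expr {10,11}
        betas = [0.9, 0.8, 0.1, 0.2]
        expr = [1.0, 2.0, 10.0, 11.0]
        p = pair_utest(betas, expr, fraction=0.5)
        assert p == pytest.approx(1 / 6)

    def test_constant_expression_uninformative(self):
        p = pair_utest([0.9, 0.8, 0.7, 0.1, 0.2, 0.3], [5.0] * 6, fraction=0.34)
        assert p >= 0.5

    def test_rank_invariance_under_log(self, rng):
        betas = rng.random(30)
        expr = rng.random(30) * 1000
        ids = [f"s{i:02d}" for i in range(30)]
        p1 = pair_utest(betas, expr, sample_ids=ids)
        p2 = pair_utest(betas, np.log2(expr + 1), sample_ids=ids)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 13))
            vals = rng.permutation(100)[:n].astype(float)  # tie-free
            betas = rng.random(n)
            frac = 0.5 if n <= 8 else 0.34
            ids = [f"s{i:02d}" for i in range(n)]
            from enhancerlink.diffmeth import extreme_indices

            m_idx = extreme_indices(betas, frac, "high", ids=ids)
            u_idx = extreme_indices(betas, frac, "low", ids=ids)
            if len(m_idx) < 2 or set(m_idx) & set(u_idx):
                continue
            p = pair_utest(betas, vals, fraction=frac, sample_ids=ids)
            oracle = enumeration_mwu_less(vals[m_idx], vals[u_idx])
            assert p == pytest.approx(oracle, rel=1e-12)


class TestBatchMWU:
    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(10):
            k = int(rng.integers(5, 20))
            x_m = rng.integers(0, 8, size=(6, k)).astype(float)  # with ties
            x_u = rng.integers(0, 8, size=(6, k)).astype(float)
            got = _batch_mwu_less(x_m, x_u)
            for r in range(6):
                ref = stats.mannwhitneyu(x_m[r], x_u[r], alternative="less",
                                         method="asymptotic").pvalue
                assert got[r] == pytest.approx(ref, rel=1e-10)

    def test_all_tied_gives_one(self):
        p = _batch_mwu_less(np.ones((2, 5)), np.ones((2, 5)))
        assert (p == 1.0).all()


@pytest.fixture(scope="module")
def engine():
    rng = np.random.default_rng(3)
    pool = pd.DataFrame(rng.random((200, 40)),
                        index=[f"bg{i}" for i in range(200)],
                        columns=[f"S{i:02d}" for i in range(40)])
    return PermutationEngine(pool)


class TestEmpiricalPvalue:

    def test_formula_floor_and_ceiling(self, engine, rng):
        expr = rng.random(40) * 100
        rows = engine.sample_rows(100, np.random.default_rng(5))
        assert empirical_pvalue(0.0, expr, engine, rows=rows) == pytest.approx(1 / 101)
        assert empirical_pvalue(1.0, expr, engine, rows=rows) == pytest.approx(1.0)

    def test_formula_matches_manual_count(self, engine, rng):
        expr = rng.random(40) * 100
        rows = engine.sample_rows(150, np.random.default_rng(6))
        p_r = 0.2
        null = engine.null_pvalues(expr, rows)
        expected = (int((null <= p_r).sum()) + 1) / 151
        assert empirical_pvalue(p_r, expr, engine, rows=rows) == expected

    def test_pseudocount_arithmetic(self):
        # count = 9 at nperm = 10,000 gives exactly 10/10001
        assert (9 + 1) / (10_000 + 1) == pytest.approx(10 / 10001)

    def test_small_pool_samples_with_replacement(self, engine):
        rows = engine.sample_rows(500, np.random.default_rng(1))
        assert len(rows) == 500  # pool of 200 -> replacement path


class TestFindPairs:
    def test_recovers_planted_links(self, cohort, pairs):
        found = set(zip(pairs["probe_id"], pairs["gene_id"]))
        truth = set(cohort.truth.links)
        tp = len(found & truth)
        assert tp / len(truth) >= 0.9       # recall
        assert tp / len(found) >= 0.9       # precision

    def test_pe_thresholds_bracket_all_and_none(self, cohort, diff_calls):
        few = diff_calls.head(3)
        common = dict(universe=cohort.universe, beta=cohort.beta,
                      expr=cohort.expr, genes=cohort.genes, sheet=cohort.sheet,
                      nperm=50, seed=9)
        everything = find_pairs(few, pe_max=1.01, **common)
        assert len(everything) == 3 * 20
        nothing = find_pairs(few, pe_max=0.0, **common)
        assert len(nothing) == 0

    def test_pe_invariant_to_monotone_expression_transform(self, cohort, diff_calls):
        from enhancerlink.types import ExpressionMatrix

        few = diff_calls.head(2)
        common = dict(universe=cohort.universe, beta=cohort.beta,
                      genes=cohort.genes, sheet=cohort.sheet,
                      nperm=200, seed=11, pe_max=1.01)
        a = find_pairs(few, expr=cohort.expr, **common)
        logged = ExpressionMatrix(np.log2(cohort.expr.df + 1))
        b = find_pairs(few, expr=logged, **common)
        pd.testing.assert_frame_equal(a, b)

    def test_variability_gate_blocks_probe(self, cohort, diff_calls):
        call = diff_calls.head(1)
        out = find_pairs(call, cohort.universe, cohort.beta, cohort.expr,
                         cohort.genes, cohort.sheet, nperm=50, seed=2,
                         pe_max=1.01, variability_min_frac=1.01)
        assert len(out) == 0


class TestClusterProbes:
    def test_chaining_rule(self):
        probes = [Probe("a", "chr1", 100), Probe("b", "chr1", 550),
                  Probe("c", "chr1", 1200)]
        clusters = cluster_probes(probes, gap=500)
        assert [c.probe_ids for c in clusters] == [("a", "b"), ("c",)]
        assert clusters[0].span == (100, 550)

    def test_singleton(self):
        (c,) = cluster_probes([Probe("x", "chr3", 42)])
        assert c.probe_ids == ("x",) and c.span == (42, 42)

    def test_gap_extremes(self):
        probes = [Probe(f"p{i}", "chr1", 10 * (i + 1)) for i in range(5)]
        assert len(cluster_probes(probes, gap=0)) == 5
        assert len(cluster_probes(probes, gap=10**9)) == 1

    def test_random_against_union_find_oracle(self, rng):
        probes = [Probe(f"p{i}", f"chr{rng.integers(1, 3)}",
                        int(rng.integers(1, 3000))) for i in range(120)]
        gap = 100
        clusters = cluster_probes(probes, gap=gap)
        # oracle: transitive closure of the <=gap relation via union-find
        parent = {p.id: p.id for p in probes}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for a in probes:
            for b in probes:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= gap:
                    parent[find(a.id)] = find(b.id)
        oracle = {}
        for p in probes:
            oracle.setdefault(find(p.id), set()).add(p.id)
        got = {frozenset(c.probe_ids) for c in clusters}
        assert got == {frozenset(v) for v in oracle.values()}


class TestCharacterization:
    def test_rank_profile_omission_rules(self):
        pairs = pd.DataFrame({
            "probe_id": ["p1", "p2", "p2", "p3", "p4"],
            "gene_id": ["gA", "gB", "gC", "gD", "gD"],
            "gene_rank": [1, 2, 3, 5, 5],
        })
        # p2 links two genes; gD linked by two probes -> only p1 survives
        prof = nearest_rank_profile(pairs)
        assert prof.loc[1] == 1.0 and prof.drop(1).sum() == 0

    def test_rank_profile_empty_after_filters(self):
        pairs = pd.DataFrame({"probe_id": ["p", "p"], "gene_id": ["a", "b"],
                              "gene_rank": [1, 2]})
        assert nearest_rank_profile(pairs).sum() == 0

    def test_distance_histogram_normalization_and_first_bin(self, cohort, pairs):
        hists = distance_null_histogram(
            pairs, cohort.universe.distal, cohort.universe, cohort.genes,
            n_datasets=50, n_probes=200, seed=4)
        for width, df in hists.items():
            assert df["observed"].sum() == pytest.approx(1.0)
            assert np.allclose(df["null_mean"].sum(), 1.0)
        # planted links sit at ~8.6 kb, inside the first 50 kb bin
        assert hists[50_000]["observed"].iloc[0] == pytest.approx(1.0)

    def test_null_histogram_matches_analytic_candidate_distribution(self, cohort):
        # with every probe-gene distance < one bin, the null concentrates there
        pairs = pd.DataFrame({
            "probe_id": ["cg00020"], "gene_id": ["G00021"],
            "distance": [8600], "gene_rank": [3], "p_r": [0.0], "p_e": [0.0]})
        hists = distance_null_histogram(
            pairs, cohort.universe.distal, cohort.universe, cohort.genes,
            bin_widths=(200_000,), n_datasets=40, n_probes=100, seed=8)
        df = hists[200_000]
        # all synthetic candidates lie within ~60 kb of their probe
        assert df["null_mean"].iloc[0] == pytest.approx(1.0)
        assert df["null_sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestLoopOverlap:
    def _loops_covering(self, cohort, pairs):
        tss = {g.gene_id: (g.chrom, g.tss) for g in cohort.genes}
        probe_map = cohort.universe.probe_by_id()
        loops = []
        for r in pairs.itertuples(index=False):
            p = probe_map[r.probe_id]
            gc, gt = tss[r.gene_id]
            loops.append((GenomicInterval(p.chrom, p.pos - 10, p.pos + 10),
                          GenomicInterval(gc, gt - 10, gt + 10)))
        return loops

    def test_saturating_loops_count_every_pair(self, cohort, pairs):
        loops = self._loops_covering(cohort, pairs)
        res = loop_overlap_enrichment(pairs, loops, cohort.universe,
                                      cohort.genes, n_random=5, seed=1)
        assert res["observed"] == len(pairs)

    def test_wrong_chromosome_no_overlap(self, cohort, pairs):
        loops = [(GenomicInterval("chrZ", 0, 10**7),
                  GenomicInterval("chrZ", 0, 10**7))]
        res = loop_overlap_enrichment(pairs, loops, cohort.universe,
                                      cohort.genes, n_random=3, seed=1)
        assert res["observed"] == 0

    def test_empty_loop_set_not_applicable(self, cohort, pairs):
        res = loop_overlap_enrichment(pairs, [], cohort.universe,
                                      cohort.genes, n_random=3, seed=1)
        assert math.isnan(res["fold"]) and "note" in res

    def test_randomizer_preserves_link_counts(self, cohort, pairs):
        # loops spanning whole contigs: every random pair overlaps, so each
        # random count must equal the total true link count exactly
        chroms = {p.chrom for p in cohort.probes}
        loops = [(GenomicInterval(c, 0, 10**8), GenomicInterval(c, 0, 10**8))
                 for c in chroms]
        res = loop_overlap_enrichment(pairs, loops, cohort.universe,
                                      cohort.genes, n_random=8, seed=3)
        assert res["random_counts"] == [len(pairs)] * 8
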