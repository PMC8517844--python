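"""Relative usage, binomial deletion test, BH adjustment, haplotype Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from iglight import (
    CohortConfig,
    GermlineAllele,
    allele_bias,
    assign_calls,
    bayes_factor_single_vs_both,
    binomial_tail,
    deletion_test,
    infer_haplotypes,
    relative_usage,
)
from statsmodels.stats.multitest import multipletests

from conftest import make_reads, random_dna


def exact_binomial_tail(x: int, n: int, p: float) -> float:
    """PMF summation oracle in 50-digit decimal arithmetic.

    The float p converts to Decimal exactly; the term recurrence
    t_{k+1} = t_k * (n-k)/(k+1) * p/q keeps every term accurate to far
    beyond the 1e-12 comparison tolerance.
    """
    import decimal

    ctx = decimal.Context(prec=50)
    dp = decimal.Decimal(p)
    dq = ctx.subtract(decimal.Decimal(1), dp)
    t = ctx.power(dq, n)  # k = 0 term
    total = t
    for k in range(x):
        t = ctx.divide(
            ctx.multiply(ctx.multiply(t, decimal.Decimal(n - k)), dp),
            ctx.multiply(decimal.Decimal(k + 1), dq),
        )
        total = ctx.add(total, t)
    return float(min(total, decimal.Decimal(1)))


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestUsage:
    def test_fraction_arithmetic_and_conservation(self, rng):
        genes = {
            "IGKV1-5": GermlineAllele("IGKV1-5", "01", random_dna(rng, 90)),
            "IGKV3-7": GermlineAllele("IGKV3-7", "01", random_dna(rng, 90)),
        }
        j = GermlineAllele("IGKJ1", "01", random_dna(rng, 30))
        cfg = CohortConfig(min_sequences_per_individual=100)
        reads = assign_calls(
            make_reads(
                "S00",
                [genes["IGKV1-5"].sequence + j.sequence] * 400
                + [genes["IGKV3-7"].sequence + j.sequence] * 3600,
            ),
            list(genes.values()) + [j],
        )
        usage = relative_usage(reads, cfg)
        v = usage[usage.segment == "V"].set_index("gene")
        assert v.loc["IGKV1-5", "fraction"] == pytest.approx(0.10)
        assert v.loc["IGKV3-7", "fraction"] == pytest.approx(0.90)
        for seg in ("V", "J"):
            assert usage[usage.segment == seg].fraction.sum() == pytest.approx(1.0)

    def test_ambiguous_read_split_half(self, rng):
        base = random_dna(rng, 90)
        a = GermlineAllele("IGKV1-5", "01", base)
        b = GermlineAllele("IGKV1D-7", "01", base[:45] + base[45:])  # identical seq
        cfg = CohortConfig(min_sequences_per_individual=50)
        reads = assign_calls(make_reads("S00", [base] * 100), [a, b])
        assert sorted(reads[0].v_genes) == ["IGKV1-5", "IGKV1D-7"]
        usage = relative_usage(reads, cfg)
        fr = usage[usage.segment == "V"].set_index("gene").fraction
        assert fr["IGKV1-5"] == pytest.approx(0.5)
        assert fr["IGKV1D-7"] == pytest.approx(0.5)


class TestBinomialDeletion:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10000),
        st.integers(1, 10000),
        st.floats(1e-4, 0.5),
    )
    def test_tail_matches_exact_summation(self, x, n, p):
        x = min(x, n)
        assert binomial_tail(x, n, p) == pytest.approx(
            exact_binomial_tail(x, n, p), abs=1e-12
        )

    def test_zero_count_closed_form(self):
        # Pr(X <= 0) = (1 - P)^N
        assert binomial_tail(0, 5000, 0.004) == pytest.approx(
            (1 - 0.004) ** 5000, rel=1e-9
        )

    def test_bh_matches_oracle_and_is_monotone(self, rng):
        p = rng.random(40) ** 3
        adj = multipletests(p, method="fdr_bh")[1]
        oracle = bh_oracle(list(p))
        assert adj == pytest.approx(oracle, abs=1e-12)
        assert (adj >= p - 1e-15).all()
        single = multipletests([0.037], method="fdr_bh")[1]
        assert single[0] == pytest.approx(0.037)

    @staticmethod
    def _usage_frame(fracs_by_gene, total=5000):
        rows = []
        inds = [f"S{i:02d}" for i in range(len(next(iter(fracs_by_gene.values()))))]
        for gene, fracs in fracs_by_gene.items():
            for ind, f in zip(inds, fracs):
                rows.append(
                    {
                        "individual_id": ind,
                        "segment": "V",
                        "gene": gene,
                        "count": f * total,
                        "total": total,
                        "fraction": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_deleted_individual_detected(self, default_cfg):
        fracs = {"IGKV2-29": [0.05] * 9 + [0.0], "IGKV1-5": [0.95] * 9 + [1.0]}
        usage = self._usage_frame(fracs)
        calls = deletion_test(usage, default_cfg)
        row = calls[(calls.gene == "IGKV2-29") & (calls.individual_id == "S09")]
        assert row.call.iloc[0] == "deleted"
        assert row.p_adjusted.iloc[0] < default_cfg.significance
        others = calls[(calls.gene == "IGKV2-29") & (calls.individual_id != "S09")]
        assert (others.call == "present").all()

    def test_typical_individual_is_present(self, default_cfg):
        fracs = {"IGKV2-29": [0.05] * 10, "IGKV1-5": [0.95] * 10}
        calls = deletion_test(self._usage_frame(fracs), default_cfg)
        assert (calls[calls.gene == "IGKV2-29"].call == "present").all()
        # X at the reference frequency itself: p-value near or above one half
        x = int(0.05 * 5000)
        assert binomial_tail(x, 5000, 0.05) >= 0.5

    def test_gene_below_floor_is_unknown(self, default_cfg):
        fracs = {"IGLJ6": [0.00005] * 10, "IGLJ1": [0.99995] * 10}
        usage = self._usage_frame(fracs)
        usage["segment"] = "J"
        calls = deletion_test(usage, default_cfg)
        assert (calls[calls.gene == "IGLJ6"].call == "unknown").all()
        assert calls[calls.gene == "IGLJ6"].p_value.isna().all()

    def test_type_one_error_rate_on_null_cohorts(self, default_cfg):
        # 20 seeded null replicates, 50 individuals, no deletions planted
        n_calls = 0
        n_tests = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            base = rng.dirichlet(np.full(10, 12.0))
            fracs_by_gene = {}
            mat = np.vstack(
                [rng.multinomial(5000, rng.dirichlet(base * 200)) for _ in range(50)]
            ) / 5000.0
            for gi in range(10):
                fracs_by_gene[f"IGKV1-{gi + 2}"] = mat[:, gi]
            calls = deletion_test(self._usage_frame(fracs_by_gene), default_cfg)
            tested = calls[calls.call != "unknown"]
            n_tests += len(tested)
            n_calls += (tested.call == "deleted").sum()
        assert n_tests > 0
        assert n_calls / n_tests <= 0.02


class TestHaplotype:
    def test_bayes_factor_oracle_values(self, default_cfg):
        eps = default_cfg.leak_rate

        def oracle(k1, k2):
            n = k1 + k2
            one = 0.5 * (
                binom.pmf(k1, n, 1 - eps) + binom.pmf(k1, n, eps)
            )
            both = binom.pmf(k1, n, 0.5)
            return one / both

        for k1, k2 in [(60, 0), (30, 30), (3, 1), (45, 2), (0, 80)]:
            assert bayes_factor_single_vs_both(k1, k2, eps) == pytest.approx(
                oracle(k1, k2), rel=1e-9
            )
        assert bayes_factor_single_vs_both(60, 0, eps) > 1000
        assert 1.0 / bayes_factor_single_vs_both(30, 30, eps) > 1000
        bf31 = bayes_factor_single_vs_both(3, 1, eps)
        assert bf31 < 1000 and 1.0 / bf31 < 1000  # insufficient evidence

    def test_planted_single_deletions_phased(self, default_study):
        res = default_study
        from iglight import haplotype_frame

        hf = haplotype_frame(res.haplotypes)
        truth = res.simulated.cohort.truth["deletions"]
        singles = truth[truth.type == "single"]
        gmap = res.collapse_report.gene_map()
        for row in singles.itertuples(index=False):
            gene = gmap.get(row.gene, row.gene)
            got = hf[(hf.individual_id == row.individual_id) & (hf.gene == gene)]
            assert len(got) == 1
            side = got.iloc[0][f"chrom{row.chromosome}"]
            assert side == "deleted"
            assert got.iloc[0].deletion_bf > 1000

    def test_no_false_deletions_on_balanced_genes(self, default_study):
        from iglight import haplotype_frame

        res = default_study
        hf = haplotype_frame(res.haplotypes)
        truth = res.simulated.cohort.truth["deletions"]
        planted = {
            (r.individual_id, res.collapse_report.gene_map().get(r.gene, r.gene))
            for r in truth.itertuples(index=False)
        }
        deleted = hf[(hf.chrom1 == "deleted") | (hf.chrom2 == "deleted")]
        for row in deleted.itertuples(index=False):
            assert (row.individual_id, row.gene) in planted

    def test_individual_without_anchor_het_skipped(self, default_study):
        res = default_study
        haplotyped = {h.individual_id for h in res.haplotypes}
        het_truth = set(res.simulated.cohort.truth["anchor_het"].individual_id)
        assert haplotyped == het_truth


class TestAlleleBias:
    def test_biased_heterozygote_shares_recovered_per_j_gene(self):
        """An allele expressed twice as much as its partner shows a 2/3 share
        within heterozygotes, for every J gene it recombines with."""
        from iglight import Genotype, Rearrangement

        cfg = CohortConfig(min_sequences_per_individual=50)
        reads = []
        k = 0
        for jg in ("IGKJ1", "IGKJ2"):
            for aid, n in (("01", 40), ("03", 20)):
                for _ in range(n):
                    reads.append(
                        Rearrangement(
                            sequence_id=f"r{k}", individual_id="S00", sequence="A",
                            v_call=[f"IGKV1-5*{aid}"], j_call=[f"{jg}*01"],
                            v_mutation_count=0, v_region_start=0,
                        )
                    )
                    k += 1
        usage = relative_usage(reads, cfg)
        genos = [Genotype("S00", {"IGKV1-5": frozenset({"01", "03"})})]
        res = allele_bias(usage, genos, reads, "IGKV1-5", cfg)
        assert res.usage_by_genotype.genotype_group.iloc[0] == "01_03"
        het = res.het_shares
        for jg in ("IGKJ1", "IGKJ2"):
            share = het[(het.j_gene == jg) & (het.allele_id == "01")].share.iloc[0]
            assert share == pytest.approx(2.0 / 3.0)

    def test_simulated_expression_bias_recovered(self):
        from iglight import CohortConfig, SimulationConfig, run_simulated_study

        sim = SimulationConfig(
            seed=17,
            n_individuals=6,
            seqs_per_individual=3000,
            base_error_rate=0.0,
            novel_snp_table=[],
            double_deletion_table=[],
            single_deletion_table=[],
            upstream_retention_prob=0.0,
            allele_bias_table=[("IGKV1-7", {"01": 2.0, "02": 1.0})],
        )
        ccfg = CohortConfig(min_sequences_per_individual=1000)
        res = run_simulated_study(sim, ccfg)
        bias = allele_bias(res.usage, res.genotypes, res.reads, "IGKV1-7", ccfg)
        het = bias.het_shares
        assert not het.empty  # seeded draw contains heterozygotes
        shares = het[het.allele_id == "01"].groupby(
            het[het.allele_id == "01"].individual_id
        ).share.mean()
        assert shares.mean() == pytest.approx(2.0 / 3.0, abs=0.08)

    def test_homozygote_share_is_one(self, rng):
        base = random_dna(rng, 90)
        a = GermlineAllele("IGKV1-5", "01", base)
        j = GermlineAllele("IGKJ1", "01", random_dna(rng, 30))
        cfg = CohortConfig(min_sequences_per_individual=50)
        reads = assign_calls(make_reads("S00", [base + j.sequence] * 100), [a, j])
        usage = relative_usage(reads, cfg)
        from iglight import Genotype

        genos = [Genotype("S00", {"IGKV1-5": frozenset({"01"})})]
        res = allele_bias(usage, genos, reads, "IGKV1-5", cfg)
        assert res.usage_by_genotype.genotype_group.iloc[0] == "01"
        assert res.het_shares.empty
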