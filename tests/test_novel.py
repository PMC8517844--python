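"""Mismatch profiles, candidate detection, pattern classification, genotypes."""

import numpy as np
import pytest

from iglight import (
    CohortConfig,
    GermlineAllele,
    Rearrangement,
    assign_calls,
    build_profiles,
    classify_pattern,
    detect_candidates,
    filter_candidates,
    infer_genotypes,
    mismatch_frequency,
)
from iglight.novel import MismatchProfile, NovelAlleleCandidate

from conftest import make_reads, random_dna

CFG = CohortConfig(min_sequences_per_individual=50)


def _mutate(seq: str, pos0: int, base: str) -> str:
    assert seq[pos0] != base
    return seq[:pos0] + base + seq[pos0 + 1:]


@pytest.fixture
def one_allele_setup(rng):
    allele = GermlineAllele("IGKV1-5", "01", random_dna(rng, 100))
    return allele


class TestProfiles:
    def test_pure_germline_counts(self, one_allele_setup):
        allele = one_allele_setup
        reads = assign_calls(
            make_reads("S00", [allele.sequence] * 100), [allele]
        )
        profiles = build_profiles(reads, [allele], CFG)
        assert len(profiles) == 1
        p = profiles[0]
        ref_idx = "ACGT".index(allele.sequence[30])
        assert p.counts[ref_idx, 30] == 100
        assert p.counts.sum(axis=0)[30] == 100

    def test_mismatch_frequency_worked_values(self, one_allele_setup):
        allele = one_allele_setup
        pos0 = 30
        ref = allele.sequence[pos0]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        variant = _mutate(allele.sequence, pos0, alt)
        reads = assign_calls(
            make_reads("S00", [variant] * 40 + [allele.sequence] * 60), [allele]
        )
        p = build_profiles(reads, [allele], CFG)[0]
        assert mismatch_frequency(p, pos0 + 1, alt) == pytest.approx(0.40)
        assert mismatch_frequency(p, pos0 + 1, ref) == pytest.approx(0.60)

    def test_homozygous_and_absent_frequencies(self, one_allele_setup):
        allele = one_allele_setup
        pos0 = 10
        alt = "ACGT"[("ACGT".index(allele.sequence[pos0]) + 1) % 4]
        variant = _mutate(allele.sequence, pos0, alt)
        reads = assign_calls(make_reads("S00", [variant] * 80), [allele])
        p = build_profiles(reads, [allele], CFG)[0]
        assert mismatch_frequency(p, pos0 + 1, alt) == pytest.approx(1.00)
        other = "ACGT"[("ACGT".index(alt) + 1) % 4]
        assert mismatch_frequency(p, pos0 + 1, other) == pytest.approx(0.00)

    def test_ambiguous_read_contributes_half_depth(self, rng):
        base = random_dna(rng, 80)
        a1 = GermlineAllele("IGKV1-5", "01", base)
        a2 = GermlineAllele("IGKV1-5", "02", _mutate(base, 40,
                            "A" if base[40] != "A" else "C"))
        third = next(b for b in "ACGT" if b not in (a1.sequence[40], a2.sequence[40]))
        ambiguous = _mutate(base, 40, third)
        reads = assign_calls(make_reads("S00", [ambiguous] * 60), [a1, a2])
        assert reads[0].v_call == [a1.name, a2.name]
        profiles = build_profiles(reads, [a1, a2], CFG)
        assert {p.allele_name for p in profiles} == {a1.name, a2.name}
        for p in profiles:
            assert p.n_assigned == pytest.approx(30.0)
            assert p.depth[0] == pytest.approx(30.0)

    def test_individual_below_floor_excluded(self, one_allele_setup):
        allele = one_allele_setup
        reads = assign_calls(make_reads("S00", [allele.sequence] * 10), [allele])
        assert build_profiles(reads, [allele], CFG) == []

    def test_profile_frequencies_sum_to_one(self, one_allele_setup):
        allele = one_allele_setup
        reads = assign_calls(make_reads("S00", [allele.sequence] * 60), [allele])
        p = build_profiles(reads, [allele], CFG)[0]
        freqs = [
            mismatch_frequency(p, i + 1, b)
            for i in range(5)
            for b in "ACGT"
        ]
        sums = [sum(freqs[4 * i: 4 * i + 4]) for i in range(5)]
        assert sums == pytest.approx([1.0] * 5)


class TestPatternClassifier:
    def test_carrier_clusters_are_multimodal(self, default_cfg):
        freqs = dict(zip("abcde", [0.01, 0.02, 0.49, 0.51, 0.98]))
        assert classify_pattern(freqs, default_cfg) == "multimodal"

    def test_sub_cutoff_stack_is_stack_like(self, default_cfg):
        freqs = dict(zip("abcde", [0.08, 0.10, 0.11, 0.12, 0.13]))
        assert classify_pattern(freqs, default_cfg) == "stack_like"

    def test_too_few_defined_is_indeterminate(self, default_cfg):
        assert classify_pattern({"a": 0.0, "b": 0.0}, default_cfg) == "indeterminate"

    def test_supra_cutoff_without_gap_is_indeterminate(self, default_cfg):
        # a continuous ramp through the cutoff: no separating gap
        freqs = {f"i{k}": v for k, v in enumerate(np.linspace(0.05, 0.30, 10))}
        assert classify_pattern(freqs, default_cfg) == "indeterminate"


class TestCandidates:
    def _cohort_reads(self, allele, alt_pos0, alt, carriers, n_ind=5, depth=60):
        reads = []
        variant = _mutate(allele.sequence, alt_pos0, alt)
        for i in range(n_ind):
            ind = f"S{i:02d}"
            seqs = (
                [variant] * (depth // 2) + [allele.sequence] * (depth // 2)
                if ind in carriers
                else [allele.sequence] * depth
            )
            reads.extend(make_reads(ind, seqs, prefix=f"{ind}-"))
        return assign_calls(reads, [allele])

    def test_planted_het_snp_detected_with_half_frequencies(self, one_allele_setup):
        allele = one_allele_setup
        pos0 = 44
        alt = "ACGT"[("ACGT".index(allele.sequence[pos0]) + 1) % 4]
        reads = self._cohort_reads(allele, pos0, alt, carriers={"S01", "S03"})
        profiles = build_profiles(reads, [allele], CFG)
        cands = detect_candidates(profiles, [allele], CFG)
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.ref_base, c.alt_base) == (pos0 + 1, allele.sequence[pos0], alt)
        assert c.per_individual_freq["S01"] == pytest.approx(0.5)
        assert c.per_individual_freq["S00"] == pytest.approx(0.0)
        assert c.passes_cutoff and c.pattern == "multimodal"

    def test_per_gene_cap_keeps_top_supported(self, one_allele_setup):
        allele = one_allele_setup
        cfg = CFG
        profiles = []
        rngpos = [(20, 900), (50, 500), (70, 200)]
        n_ind = 4
        L = len(allele.sequence)
        for i in range(n_ind):
            counts = np.zeros((4, L))
            for pos in range(L):
                counts["ACGT".index(allele.sequence[pos]), pos] = 200
            for pos0, support in rngpos:
                alt_i = ("ACGT".index(allele.sequence[pos0]) + 1) % 4
                counts[alt_i, pos0] = support / n_ind
            profiles.append(
                MismatchProfile("S%02d" % i, allele.name, counts, 200)
            )
        cands = detect_candidates(profiles, [allele], cfg)
        assert [c.position for c in cands] == [21, 51]  # support 900 and 500 kept

    def test_error_only_position_below_floor_no_candidate(self, one_allele_setup):
        allele = one_allele_setup
        pos0 = 33
        alt = "ACGT"[("ACGT".index(allele.sequence[pos0]) + 1) % 4]
        variant = _mutate(allele.sequence, pos0, alt)
        reads = []
        for i in range(4):
            seqs = [variant] * 3 + [allele.sequence] * 57  # 5% - below floor
            reads.extend(make_reads(f"S{i:02d}", seqs, prefix=f"S{i:02d}-"))
        reads = assign_calls(reads, [allele])
        profiles = build_profiles(reads, [allele], CFG)
        assert detect_candidates(profiles, [allele], CFG) == []

    def test_extended_span_positions_suppressed(self, rng):
        base = random_dna(rng, 80)
        allele = GermlineAllele("IGLV1-44", "01", base, extended_5p_len=10)
        pos0 = 5  # inside the synthetic span
        alt = "ACGT"[("ACGT".index(base[pos0]) + 1) % 4]
        variant = _mutate(base, pos0, alt)
        reads = assign_calls(
            sum(
                (
                    make_reads(f"S{i}", [variant] * 30 + [base] * 30, prefix=f"S{i}-")
                    for i in range(3)
                ),
                [],
            ),
            [allele],
        )
        profiles = build_profiles(reads, [allele], CFG)
        assert detect_candidates(profiles, [allele], CFG) == []

    def test_monotonic_in_cutoff(self, one_allele_setup):
        allele = one_allele_setup
        pos0 = 44
        alt = "ACGT"[("ACGT".index(allele.sequence[pos0]) + 1) % 4]
        reads = self._cohort_reads(allele, pos0, alt, carriers={"S01"})
        profiles = build_profiles(reads, [allele], CFG)
        accepted_sizes = []
        for cutoff in (0.2, 0.4, 0.6):
            cfg = CohortConfig(
                min_sequences_per_individual=50, mismatch_cutoff=cutoff
            )
            cands = detect_candidates(profiles, [allele], cfg)
            acc, _ = filter_candidates(cands, cfg)
            accepted_sizes.append(len(acc))
        assert accepted_sizes == sorted(accepted_sizes, reverse=True)


class TestFilterAndGenotype:
    def _candidate(self, **kw):
        base = dict(
            base_allele="IGLV7-46*01",
            position=213,
            ref_base="A",
            alt_base="C",
            per_individual_freq={"S00": 0.01, "S01": 0.60, "S02": 0.02},
            support_count=100,
            pattern="multimodal",
            passes_cutoff=True,
        )
        base.update(kw)
        return NovelAlleleCandidate(**base)

    def test_flagged_multimodal_passer_accepted(self, default_cfg):
        c = self._candidate(flag_repeat=True, flag_ac=True)
        acc, rej = filter_candidates([c], default_cfg)
        assert acc == [c] and rej == []

    def test_stack_like_rejected_with_reason(self, default_cfg):
        c = self._candidate(
            pattern="stack_like",
            passes_cutoff=False,
            per_individual_freq={"S00": 0.10, "S01": 0.12, "S02": 0.11},
        )
        _, rej = filter_candidates([c], default_cfg)
        assert rej[0].reject_reason in ("stack_like", "below_cutoff")
        c2 = self._candidate(pattern="stack_like", passes_cutoff=True)
        _, rej2 = filter_candidates([c2], default_cfg)
        assert rej2[0].reject_reason == "stack_like"

    def test_below_cutoff_rejected(self, default_cfg):
        c = self._candidate(
            passes_cutoff=False,
            per_individual_freq={"S00": 0.20, "S01": 0.15, "S02": 0.0},
            pattern="indeterminate",
        )
        _, rej = filter_candidates([c], default_cfg)
        assert rej[0].reject_reason == "below_cutoff"

    def test_genotype_share_threshold(self, rng):
        base = random_dna(rng, 90)
        a1 = GermlineAllele("IGKV1-5", "01", base)
        a3_seq = _mutate(base, 45, "A" if base[45] != "A" else "G")
        a3 = GermlineAllele("IGKV1-5", "03", a3_seq)
        cfg = CohortConfig(min_sequences_per_individual=50)
        # S00: 55/45 split -> both; S01: 97/3 -> only *01
        reads = assign_calls(
            make_reads("S00", [base] * 55 + [a3_seq] * 45, prefix="a")
            + make_reads("S01", [base] * 97 + [a3_seq] * 3, prefix="b"),
            [a1, a3],
        )
        profiles = build_profiles(reads, [a1, a3], cfg)
        genos = infer_genotypes(profiles, [], cfg)
        by_ind = {g.individual_id: g for g in genos}
        assert by_ind["S00"].entries["IGKV1-5"] == frozenset({"01", "03"})
        assert by_ind["S01"].entries["IGKV1-5"] == frozenset({"01"})

    def test_noise_free_simulation_recovers_truth_genotypes(self, noise_free_study):
        res = noise_free_study
        gmap = res.collapse_report.gene_map()
        amap = res.collapse_report.allele_map()
        truth_chrom = res.simulated.cohort.chromosomes
        for g in res.genotypes:
            expect: dict[str, set] = {}
            for gene, chroms in truth_chrom[g.individual_id].items():
                if gene[3] != "V":
                    continue
                alleles = {a for a in chroms if a is not None}
                if not alleles:
                    continue
                new_gene = gmap.get(gene, gene)
                bucket = expect.setdefault(new_gene, set())
                for a in alleles:
                    mapped = amap.get(f"{gene}*{a}")
                    bucket.add(mapped.split("*")[1] if mapped else a)
            got = {k: set(v) for k, v in g.entries.items() if k[3] == "V"}
            assert got == expect
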