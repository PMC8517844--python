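"""End-to-end analysis over a simulated or externally provided repertoire."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import assign_calls
from .haplotype import HaplotypeCall, infer_haplotypes
from .model import CohortConfig, GermlineAllele, Genotype, GenomicVGene, Rearrangement
from .novel import (
    MismatchProfile,
    NovelAlleleCandidate,
    build_profiles,
    detect_candidates,
    eligible_reads,
    filter_candidates,
    infer_genotypes,
)
from .refprep import CollapseReport, prepare_reference
from .sim import SimulatedStudy, SimulationConfig, simulate_study
from .upstream import UpstreamVariant, infer_upstream_variants
from .usage import deletion_test, relative_usage


@dataclass
class StudyResults:
    reference: list[GermlineAllele]
    collapse_report: CollapseReport
    reads: list[Rearrangement]  # annotated
    profiles: list[MismatchProfile]
    candidates: list[NovelAlleleCandidate]
    accepted: list[NovelAlleleCandidate]
    rejected: list[NovelAlleleCandidate]
    genotypes: list[Genotype]
    usage: pd.DataFrame
    deletions: pd.DataFrame
    haplotypes: list[HaplotypeCall]
    upstream_variants: list[UpstreamVariant]
    simulated: SimulatedStudy | None = field(default=None, repr=False)


def analyze_repertoire(
    raw_reference: list[GermlineAllele],
    reads: list[Rearrangement],
    cfg: CohortConfig,
    genomic_genes: dict[str, GenomicVGene] | None = None,
    anchor_gene: str | None = None,
) -> StudyResults:
    """Run the full inference chain on annotated-or-raw reads.

    Prepares the reference (collapse + extend), annotates, builds mismatch
    profiles, detects/filters novel-allele candidates, infers genotypes,
    usage, double-deletion calls, J-anchored haplotypes (when ``anchor_gene``
    is given) and upstream splice variants (when genomic models are given).
    """
    reference, report = prepare_reference(raw_reference)
    annotated = assign_calls(reads, reference)
    profiles = build_profiles(annotated, reference, cfg)
    candidates = detect_candidates(profiles, reference, cfg)
    accepted, rejected = filter_candidates(candidates, cfg)
    genotypes = infer_genotypes(profiles, accepted, cfg)
    usage = relative_usage(annotated, cfg)
    deletions = deletion_test(usage, cfg)

    haplotypes: list[HaplotypeCall] = []
    if anchor_gene is not None:
        haplotypes = infer_haplotypes(
            eligible_reads(annotated, cfg), genotypes, cfg, anchor_gene
        )

    variants: list[UpstreamVariant] = []
    if genomic_genes is not None:
        gene_map = report.gene_map()
        models = {gene_map.get(g, g): m for g, m in genomic_genes.items()}
        variants = infer_upstream_variants(
            eligible_reads(annotated, cfg), models, cfg
        )
    return StudyResults(
        reference=reference,
        collapse_report=report,
        reads=annotated,
        profiles=profiles,
        candidates=candidates,
        accepted=accepted,
        rejected=rejected,
        genotypes=genotypes,
        usage=usage,
        deletions=deletions,
        haplotypes=haplotypes,
        upstream_variants=variants,
    )


def run_simulated_study(
    sim_cfg: SimulationConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
) -> StudyResults:
    """Simulate a cohort under the configured study conditions and analyse it."""
    sim_cfg = sim_cfg or SimulationConfig()
    cohort_cfg = cohort_cfg or CohortConfig()
    study = simulate_study(sim_cfg)
    results = analyze_repertoire(
        study.reference.alleles,
        study.reads,
        cohort_cfg,
        genomic_genes=study.reference.genomic_genes,
        anchor_gene=study.reference.anchor_gene,
    )
    results.simulated = study
    return results
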