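"""Upstream-sequence clustering and alternative-splice classification.

The upstream region of a light-chain transcript (5'UTR + L-PART1 + L-PART2,
everything 5' of the V-REGION) is built per allele and individual: reads
with an unambiguous V call are trimmed at the V-REGION start, grouped,
length-filtered, clustered at high identity and collapsed to consensus
sequences; per-individual consensus variants are then collapsed exactly
across the cohort.  Each cohort variant is compared to the gene's genomic
model: a variant matching the spliced 5'exon + L-PART2 junction is
*canonical*; a variant carrying a prefix of the intron between the exon end
and L-PART2 is *intron_retained* -- partial intron retention typically
shifts the leader reading frame and introduces a premature termination
codon (PTC), which is located by translating from the leader ATG.

All sequences are 3'-anchored (they end where the V-REGION starts), so
identities between unequal-length sequences are computed over the
3'-anchored overlap, and model matching compares suffixes.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .model import CohortConfig, GenomicVGene, Rearrangement

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class UpstreamVariant:
    """A cohort-level consensus upstream sequence of one allele."""

    allele_name: str
    consensus_seq: str
    n_individuals: int
    cohort_fraction: float
    splice_class: str = "unclassified"  # canonical | intron_retained | unclassified
    retained_len: int = 0
    ptc_codon_index: int | None = None  # 1-based codon from the leader ATG
    mismatch_pos: int | None = None  # first model mismatch when unclassified


def extract_upstream(
    reads: list[Rearrangement],
) -> dict[tuple[str, str], list[str]]:
    """Upstream portions grouped by (individual, unambiguous V allele call).

    Ambiguous-call reads and reads with an empty upstream are skipped.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in reads:
        if len(r.v_call) != 1 or r.v_region_start in (None, 0):
            continue
        groups[(r.individual_id, r.v_call[0])].append(r.upstream_seq)
    return dict(groups)


def length_filter(seqs: list[str], min_class_freq: float = 0.05) -> list[str]:
    """Drop rare length classes, then 5'-trim survivors to a shared length.

    Sequences are 3'-anchored, so trimming to the shortest surviving length
    class leaves every survivor covering the same V-proximal window.
    """
    if not seqs:
        return []
    lengths = Counter(len(s) for s in seqs)
    total = len(seqs)
    kept_lengths = {n for n, c in lengths.items() if c / total >= min_class_freq}
    if not kept_lengths:
        log.info("all length classes below %.2f; group dropped", min_class_freq)
        return []
    survivors = [s for s in seqs if len(s) in kept_lengths]
    lmin = min(kept_lengths)
    return [s[-lmin:] for s in survivors]


def _identity(a: str, b: str) -> float:
    """Identity over the 3'-anchored overlap; N matches anything."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    sa, sb = a[-n:], b[-n:]
    matches = sum(1 for x, y in zip(sa, sb) if x == y or x == "N" or y == "N")
    return matches / n


def cluster_and_consensus(
    seqs: list[str],
    ident: float = 0.999,
    length_cov: float = 0.5,
    cons_freq: float = 0.6,
    min_freq: float = 0.01,
    min_size: int = 5,
) -> list[tuple[int, str]]:
    """Single-linkage clusters with per-cluster majority consensus.

    Two sequences link when their identity over the 3'-anchored overlap is
    at least ``ident`` and the overlap covers at least ``length_cov`` of the
    shorter sequence.  Per cluster, a position keeps the majority base when
    its frequency reaches ``cons_freq``, else N.  Clusters with relative
    frequency below ``min_freq`` or fewer than ``min_size`` sequences are
    discarded.  Returns (size, consensus) pairs, largest cluster first.
    """
    if not seqs:
        return []
    uniq = Counter(seqs)
    keys = sorted(uniq)
    parent = list(range(len(keys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            # 3'-anchored overlap always spans the shorter sequence, so the
            # overlap >= length_cov * shorter condition is satisfied by
            # construction; identity alone decides linkage.
            if _identity(keys[i], keys[j]) >= ident:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[str]] = defaultdict(list)
    for i in range(len(keys)):
        clusters[find(i)].append(keys[i])

    total = len(seqs)
    out = []
    for members in clusters.values():
        size = sum(uniq[m] for m in members)
        if size < min_size or size / total < min_freq:
            continue
        lmin = min(len(m) for m in members)
        mat = np.array([list(m[-lmin:]) for m in members])
        weights = np.array([uniq[m] for m in members], dtype=float)
        cons = []
        for col in range(lmin):
            bases = mat[:, col]
            votes: dict[str, float] = defaultdict(float)
            for b, w in zip(bases, weights):
                if b != "N":
                    votes[b] += w
            tot = sum(votes.values())
            if tot == 0:
                cons.append("N")
                continue
            top_base = max(sorted(votes), key=lambda b: votes[b])
            cons.append(top_base if votes[top_base] / tot >= cons_freq else "N")
        out.append((size, "".join(cons)))
    return sorted(out, key=lambda t: (-t[0], t[1]))


def collapse_cohort(
    per_individual: dict[tuple[str, str], list[tuple[int, str]]],
    group_totals: dict[tuple[str, str], int],
) -> list[UpstreamVariant]:
    """Collapse per-individual consensus variants across the cohort.

    Collapse is by exact sequence identity.  ``cohort_fraction`` is the
    fraction of the allele's upstream sequences (cohort-wide) supporting the
    variant; ``n_individuals`` counts individuals contributing it.
    """
    by_allele: dict[str, dict[str, tuple[set, int]]] = defaultdict(dict)
    allele_totals: dict[str, int] = defaultdict(int)
    for (ind, allele), _total in group_totals.items():
        allele_totals[allele] += _total
    for (ind, allele), variants in per_individual.items():
        for size, cons in variants:
            inds, support = by_allele[allele].get(cons, (set(), 0))
            by_allele[allele][cons] = (inds | {ind}, support + size)

    out = []
    for allele in sorted(by_allele):
        for cons in sorted(by_allele[allele]):
            inds, support = by_allele[allele][cons]
            out.append(
                UpstreamVariant(
                    allele_name=allele,
                    consensus_seq=cons,
                    n_individuals=len(inds),
                    cohort_fraction=support / allele_totals[allele],
                )
            )
    return sorted(out, key=lambda v: (v.allele_name, -v.cohort_fraction, v.consensus_seq))


def _suffix_match(consensus: str, model: str) -> int | None:
    """None if consensus matches the model's 3' suffix (N wildcard); else the
    1-based consensus position of the first mismatch."""
    if len(consensus) > len(model):
        return 1
    tail = model[len(model) - len(consensus):]
    for i, (c, m) in enumerate(zip(consensus, tail)):
        if c != m and c != "N" and m != "N":
            return i + 1
    return None


def classify_splice(variant: UpstreamVariant, gene: GenomicVGene) -> UpstreamVariant:
    """Assign canonical / intron_retained (with PTC search) to one variant.

    Canonical means the consensus equals (a 3' suffix of) the spliced
    5'exon + L-PART2 junction.  Intron retention is matched only as an
    intron *prefix* adjacent to the donor site: the smallest prefix length
    whose model matches is reported.  For retained variants the leader is
    translated from the ATG across the retention and into the V-REGION, and
    the first stop codon's 1-based codon index is recorded.
    """
    if _suffix_match(variant.consensus_seq, gene.canonical_upstream) is None:
        variant.splice_class = "canonical"
        variant.retained_len = 0
        variant.ptc_codon_index = None
        return variant
    for r in range(1, len(gene.intron) + 1):
        if _suffix_match(variant.consensus_seq, gene.retained_upstream(r)) is None:
            variant.splice_class = "intron_retained"
            variant.retained_len = r
            leader = (
                gene.utr5_exon[gene.leader_start_offset:]
                + gene.intron[:r]
                + gene.lpart2
                + gene.v_region
            )
            variant.ptc_codon_index = None
            for ci in range(len(leader) // 3):
                if leader[3 * ci: 3 * ci + 3] in _STOPS:
                    variant.ptc_codon_index = ci + 1
                    break
            return variant
    variant.splice_class = "unclassified"
    variant.mismatch_pos = _suffix_match(variant.consensus_seq, gene.canonical_upstream)
    return variant


def infer_upstream_variants(
    reads: list[Rearrangement],
    genomic_genes: dict[str, GenomicVGene],
    cfg: CohortConfig,
) -> list[UpstreamVariant]:
    """Full upstream pipeline: extract, filter, cluster, collapse, classify.

    ``genomic_genes`` maps gene names (as they appear in v_call, i.e. after
    any reference collapsing) to their genomic models; variants of genes
    without a model are left unclassified with a logged notice.
    """
    groups = extract_upstream(reads)
    per_individual: dict[tuple[str, str], list[tuple[int, str]]] = {}
    totals: dict[tuple[str, str], int] = {}
    for key, seqs in groups.items():
        totals[key] = len(seqs)
        filtered = length_filter(seqs, cfg.upstream_length_class_min)
        if not filtered:
            continue
        per_individual[key] = cluster_and_consensus(
            filtered,
            ident=cfg.cluster_ident,
            length_cov=cfg.cluster_length_cov,
            cons_freq=cfg.consensus_freq,
            min_freq=cfg.cluster_min_freq,
            min_size=cfg.cluster_min_size,
        )
    variants = collapse_cohort(per_individual, totals)
    for v in variants:
        gene = v.allele_name.split("*")[0]
        model = genomic_genes.get(gene)
        if model is None:
            log.info("no genomic model for %s; variant left unclassified", gene)
            continue
        classify_splice(v, model)
    return variants


def variants_frame(variants: list[UpstreamVariant]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele": v.allele_name,
                "consensus": v.consensus_seq,
                "n_individuals": v.n_individuals,
                "fraction": v.cohort_fraction,
                "splice_class": v.splice_class,
                "retained_len": v.retained_len,
                "ptc_codon_index": v.ptc_codon_index,
            }
            for v in variants
        ]
    )
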