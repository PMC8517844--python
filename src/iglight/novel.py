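"""Novel-allele inference from per-individual mismatch-frequency profiles.

This is the analytical core of the package.  For every (individual, allele)
pair, all sequences annotated to that allele are piled up over the V-REGION
and the per-position base counts recorded (ambiguous calls contribute
fractionally, 1/k for a k-way tie; N bases never count).  The *mismatch
frequency* of a candidate polymorphism in an individual is the fraction of
that individual's sequences carrying the alternate base at the position: a
homozygous carrier sits near 1.00, a balanced heterozygote near 0.50, and an
individual expressing four equal variants of the gene near 0.25 -- which is
the rationale for the 0.25 acceptance cutoff (allowing copy-number variation
up to four expressed variants).

Cohort-wide, true germline polymorphisms produce a *multimodal* pattern
(non-carriers near 0, carriers clustered at 0.5/1.0), whereas recurrent
sequencing artefacts -- notably MiSeq A->C substitutions and repeat-motif
errors -- produce a *stack-like* pattern: every individual at a similar
sub-cutoff frequency.  Candidates are annotated with A->C and repeat-motif
flags (annotations only: flagged candidates can still be genuine) and
rejected when stack-like or when no individual reaches the cutoff.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .model import CohortConfig, GermlineAllele, Genotype, Rearrangement, encode

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"


@dataclass
class MismatchProfile:
    """Base pile-up of one individual's sequences annotated to one allele.

    ``counts`` is a (4, L) array of fractional sequence counts observing
    A/C/G/T at each V-REGION position; ``depth`` is their per-position sum
    (N observations are excluded, so depth <= assigned weight).
    """

    individual_id: str
    allele_name: str
    counts: np.ndarray
    n_assigned: float

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class NovelAlleleCandidate:
    """A (base allele, position, ref->alt) novel-polymorphism hypothesis."""

    base_allele: str
    position: int  # 1-based on the ungapped reference allele
    ref_base: str
    alt_base: str
    per_individual_freq: dict[str, float] = field(default_factory=dict)
    support_count: int = 0
    pattern: str = "indeterminate"
    flag_ac: bool = False
    flag_repeat: bool = False
    passes_cutoff: bool = False
    reject_reason: str | None = None  # None until filtered; then e.g. below_cutoff

    @property
    def label(self) -> str:
        """Field-standard variant label, e.g. ``IGKV1-5*01_T31C``."""
        return f"{self.base_allele}_{self.ref_base}{self.position}{self.alt_base}"

    @property
    def gene(self) -> str:
        return self.base_allele.split("*")[0]


def eligible_reads(
    reads: list[Rearrangement], cfg: CohortConfig
) -> list[Rearrangement]:
    """Annotated reads passing the naive-repertoire and cohort-depth filters.

    Keeps reads with a V call and fewer than ``max_v_mutations`` V-REGION
    mismatches, from individuals with at least the minimum sequence count;
    individuals below the floor are dropped with a logged warning.
    """
    per_ind = defaultdict(int)
    for r in reads:
        per_ind[r.individual_id] += 1
    shallow = {i for i, n in per_ind.items() if n < cfg.min_sequences_per_individual}
    for i in sorted(shallow):
        log.warning(
            "individual %s has %d sequences (< %d); excluded",
            i, per_ind[i], cfg.min_sequences_per_individual,
        )
    return [
        r
        for r in reads
        if r.individual_id not in shallow
        and r.v_call
        and r.v_mutation_count is not None
        and r.v_mutation_count < cfg.max_v_mutations
    ]


def build_profiles(
    reads: list[Rearrangement],
    reference: list[GermlineAllele],
    cfg: CohortConfig,
) -> list[MismatchProfile]:
    """Pile up sequences per (individual, allele), ambiguity split 1/k."""
    ref_len = {a.name: len(a.sequence) for a in reference}
    kept = eligible_reads(reads, cfg)
    groups: dict[tuple[str, str], list[tuple[int, float]]] = defaultdict(list)
    for idx, r in enumerate(kept):
        wgt = 1.0 / len(r.v_call)
        for name in r.v_call:
            groups[(r.individual_id, name)].append((idx, wgt))

    profiles = []
    for (ind, name), members in sorted(groups.items()):
        if name not in ref_len:
            raise KeyError(f"v_call {name} not in the reference")
        L = ref_len[name]
        counts = np.zeros((4, L))
        total = 0.0
        for idx, wgt in members:
            r = kept[idx]
            window = encode(r.sequence[r.v_region_start: r.v_region_start + L])
            if window.size != L:
                continue
            for b in range(4):
                counts[b, window == b + 1] += wgt
            total += wgt
        profiles.append(
            MismatchProfile(individual_id=ind, allele_name=name, counts=counts,
                            n_assigned=total)
        )
    return profiles


def mismatch_frequency(
    profile: MismatchProfile, position: int, alt_base: str
) -> float | None:
    """Fraction of the profile's depth carrying ``alt_base`` at a 1-based position.

    Returns None (missing, not 0) when nothing covers the position.
    """
    d = profile.depth[position - 1]
    if d <= 0:
        return None
    return float(profile.counts[_BASE_INDEX[alt_base], position - 1] / d)


def classify_pattern(freqs: dict[str, float], cfg: CohortConfig) -> str:
    """Classify a cohort frequency vector as multimodal / stack_like / indeterminate.

    Deterministic surrogate for visual judgement: frequencies above the
    noise floor form the signal set S.  *multimodal* requires a carrier at
    or above the cutoff separated from the sub-cutoff values (including 0)
    by a gap of at least ``multimodal_gap``; *stack_like* requires all of S
    below the cutoff within a span smaller than the gap.  Fewer than three
    defined frequencies -> indeterminate.
    """
    defined = [f for f in freqs.values() if f is not None]
    if len(defined) < 3:
        return "indeterminate"
    s = sorted(f for f in defined if f > cfg.noise_floor)
    cutoff = cfg.mismatch_cutoff
    if s and max(s) >= cutoff:
        below = max([0.0] + [f for f in s if f < cutoff])
        above = min(f for f in s if f >= cutoff)
        if above - below >= cfg.multimodal_gap:
            return "multimodal"
        return "indeterminate"
    if s and (s[-1] - s[0]) < cfg.multimodal_gap:
        return "stack_like"
    return "indeterminate"


def detect_candidates(
    profiles: list[MismatchProfile],
    reference: list[GermlineAllele],
    cfg: CohortConfig,
) -> list[NovelAlleleCandidate]:
    """Emit novel-allele candidates from the cohort's mismatch profiles.

    A (allele, position, alt) triple becomes a candidate when any individual
    reaches the candidate floor (default cutoff/2, deliberately below the
    acceptance cutoff so that borderline artefacts are generated, pattern-
    classified and rejected with a reason instead of silently missed).
    An individual's frequency only counts as defined when at least
    ``min_freq_depth`` sequences cover the position -- a frequency estimated
    from one or two stray sequences carries no genotype information.
    Positions inside consensus-extended reference spans are synthetic bases
    and are suppressed.  At most ``max_novel_per_gene`` candidates per gene
    are retained, ranked by cohort support (ties -> lower position).
    """
    by_allele: dict[str, list[MismatchProfile]] = defaultdict(list)
    for p in profiles:
        by_allele[p.allele_name].append(p)
    ref_by_name = {a.name: a for a in reference}

    candidates: list[NovelAlleleCandidate] = []
    for allele_name, plist in sorted(by_allele.items()):
        allele = ref_by_name[allele_name]
        ref_codes = allele.codes()
        valid = allele.valid_mask()
        counts = np.stack([p.counts for p in plist])  # (n_ind, 4, L)
        depth = counts.sum(axis=1)  # (n_ind, L)
        covered = depth >= cfg.min_freq_depth
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(covered[:, None, :], counts / depth[:, None, :], np.nan)
        if not covered.any():
            continue
        fmax = np.nanmax(freq, axis=0)  # (4, L) nan where nothing covered
        with np.errstate(invalid="ignore"):
            floor_hit = fmax >= cfg.candidate_floor
        for b in range(4):
            hit_pos = np.nonzero(floor_hit[b] & valid & (ref_codes != b + 1))[0]
            for pos in hit_pos:
                per_ind = {
                    p.individual_id: float(freq[i, b, pos])
                    for i, p in enumerate(plist)
                    if covered[i, pos]
                }
                ref_b = _INDEX_BASE[ref_codes[pos] - 1]
                alt_b = _INDEX_BASE[b]
                neighbours_repeat = (
                    0 < pos < len(allele.sequence) - 1
                    and allele.sequence[pos - 1] == alt_b
                    and allele.sequence[pos + 1] == alt_b
                )
                cand = NovelAlleleCandidate(
                    base_allele=allele_name,
                    position=int(pos) + 1,
                    ref_base=ref_b,
                    alt_base=alt_b,
                    per_individual_freq=per_ind,
                    support_count=int(round(counts[:, b, pos].sum())),
                    pattern=classify_pattern(per_ind, cfg),
                    flag_ac=(ref_b == "A" and alt_b == "C"),
                    flag_repeat=neighbours_repeat,
                    passes_cutoff=max(per_ind.values()) >= cfg.mismatch_cutoff,
                )
                candidates.append(cand)

    by_gene: dict[str, list[NovelAlleleCandidate]] = defaultdict(list)
    for c in candidates:
        by_gene[c.gene].append(c)
    kept: list[NovelAlleleCandidate] = []
    for gene in sorted(by_gene):
        ranked = sorted(
            by_gene[gene], key=lambda c: (-c.support_count, c.position, c.alt_base)
        )
        kept.extend(ranked[: cfg.max_novel_per_gene])
    return sorted(kept, key=lambda c: (c.base_allele, c.position, c.alt_base))


def filter_candidates(
    candidates: list[NovelAlleleCandidate], cfg: CohortConfig
) -> tuple[list[NovelAlleleCandidate], list[NovelAlleleCandidate]]:
    """Split candidates into accepted and rejected-with-reason.

    Accepted: at least one individual at or above the mismatch cutoff and a
    pattern other than stack-like (indeterminate-but-passing is accepted).
    The A->C and repeat-motif flags never reject on their own -- they are
    annotations; validated true polymorphisms exist in both flag classes.
    """
    accepted, rejected = [], []
    for c in candidates:
        if not c.passes_cutoff:
            c.reject_reason = "below_cutoff"
            rejected.append(c)
        elif c.pattern == "stack_like":
            c.reject_reason = "stack_like"
            rejected.append(c)
        else:
            c.reject_reason = None
            accepted.append(c)
    return accepted, rejected


def infer_genotypes(
    profiles: list[MismatchProfile],
    accepted: list[NovelAlleleCandidate],
    cfg: CohortConfig,
) -> list[Genotype]:
    """Per-individual genotypes from expression shares.

    For each gene, an allele (known, or accepted novel carved out of its
    base allele's profile by the individual's mismatch frequency) enters the
    genotype when its share of the gene's sequences is at least the mismatch
    cutoff; at most four alleles per gene, ranked by share.
    """
    cands_by_allele: dict[str, list[NovelAlleleCandidate]] = defaultdict(list)
    for c in accepted:
        cands_by_allele[c.base_allele].append(c)

    per_ind: dict[str, dict[str, dict[str, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float))
    )
    for p in profiles:
        gene, allele_id = p.allele_name.split("*")
        weights = per_ind[p.individual_id][gene]
        novel_total = 0.0
        for c in cands_by_allele.get(p.allele_name, []):
            f = mismatch_frequency(p, c.position, c.alt_base)
            if f:
                novel_id = f"{allele_id}_{c.ref_base}{c.position}{c.alt_base}"
                weights[novel_id] += f * p.n_assigned
                novel_total += f * p.n_assigned
        weights[allele_id] += max(0.0, p.n_assigned - novel_total)

    genotypes = []
    for ind in sorted(per_ind):
        entries = {}
        for gene, weights in per_ind[ind].items():
            total = sum(weights.values())
            if total <= 0:
                continue
            ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
            chosen = [
                aid for aid, w in ranked[:4] if w / total >= cfg.mismatch_cutoff
            ]
            if chosen:
                entries[gene] = frozenset(chosen)
        genotypes.append(Genotype(individual_id=ind, entries=entries))
    return genotypes


def candidates_frame(candidates: list[NovelAlleleCandidate]):
    """Candidate table for export (one row per candidate)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele": c.base_allele,
                "position": c.position,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "label": c.label,
                "support": c.support_count,
                "max_freq": max(c.per_individual_freq.values()) if c.per_individual_freq else np.nan,
                "pattern": c.pattern,
                "flag_ac": c.flag_ac,
                "flag_repeat": c.flag_repeat,
                "accepted": c.reject_reason is None,
                "reason": c.reject_reason or "",
            }
            for c in candidates
        ]
    )
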