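"""Relative gene usage, binomial double-deletion test, allele-bias analysis.

Relative usage of a gene in an individual is the fraction of that
individual's (depth- and mutation-filtered) sequences assigned to the gene;
ambiguous calls are split fractionally so that per-segment fractions sum to
one.  A gene deleted from both chromosomes leaves a hole in usage: the
binomial test asks, for each individual, how surprising their gene count X
out of N sequences would be if the gene were present at the lowest
non-deleted usage P seen in the cohort.  P is anchored at the usage closest
to the segment floor (0.001 for V, 0.005 for J -- J loci carry far fewer
genes) among individuals above the floor; genes whose cohort mean usage sits
below the floor cannot be tested and are reported unknown.  P-values are
Benjamini-Hochberg adjusted across all tests and called at significance
0.01.  Because "without a deletion event" is circular on a first pass, the
test iterates once: deletions called in round one are excluded from the
candidates defining P in round two.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CohortConfig, Genotype, Rearrangement
from .novel import eligible_reads

log = logging.getLogger(__name__)


def relative_usage(reads: list[Rearrangement], cfg: CohortConfig) -> pd.DataFrame:
    """Per-individual, per-gene usage fractions for V and J independently.

    Returns a frame with columns individual_id, segment, gene, count, total,
    fraction.  Ambiguity over k distinct genes contributes 1/k to each;
    individuals below the sequence floor are omitted (logged upstream).
    """
    kept = eligible_reads(reads, cfg)
    counts: dict[tuple[str, str, str], float] = defaultdict(float)
    totals: dict[tuple[str, str], float] = defaultdict(float)
    for r in kept:
        for segment, genes in (("V", r.v_genes), ("J", r.j_genes)):
            if not genes:
                continue
            w = 1.0 / len(genes)
            for g in genes:
                counts[(r.individual_id, segment, g)] += w
            totals[(r.individual_id, segment)] += 1.0
    rows = [
        {
            "individual_id": ind,
            "segment": seg,
            "gene": gene,
            "count": c,
            "total": totals[(ind, seg)],
            "fraction": c / totals[(ind, seg)],
        }
        for (ind, seg, gene), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def binomial_tail(x: int, n: int, p: float) -> float:
    """One-sided lower tail Pr(X <= x) for X ~ Binomial(n, p)."""
    if not (0 <= x <= n and 0.0 < p < 1.0):
        raise ValueError("require 0 <= X <= N and 0 < P < 1")
    return float(stats.binom.cdf(x, n, p))


@dataclass
class DeletionCall:
    individual_id: str
    gene_name: str
    segment: str
    x: int
    n: int
    p_ref: float | None
    p_value: float | None
    p_adjusted: float | None
    call: str  # deleted | present | unknown


def _deletion_pass(
    mat: pd.DataFrame, totals: pd.Series, floor: float, excluded: set
) -> dict[str, tuple[float, pd.Series]]:
    """Per testable gene: (P, p-values per individual) given excluded deletions."""
    out = {}
    for gene in mat.columns:
        fracs = mat[gene]
        if fracs.mean() < floor:
            continue
        cand = fracs[(fracs > floor) & ~fracs.index.map(
            lambda i: (i, gene) in excluded).values]
        if cand.empty:
            continue
        p_ref = float(cand.min())
        x = np.floor(fracs.values * totals.values).astype(int)
        pvals = stats.binom.cdf(x, totals.values.astype(int), p_ref)
        out[gene] = (p_ref, pd.Series(pvals, index=fracs.index))
    return out


def deletion_test(usage: pd.DataFrame, cfg: CohortConfig) -> pd.DataFrame:
    """Binomial double-chromosome-deletion test over a usage table.

    Returns one row per (individual, gene) with the test inputs, BH-adjusted
    p-value and a call in {deleted, present, unknown}.
    """
    results: list[DeletionCall] = []
    floors = {"V": cfg.v_usage_floor, "J": cfg.j_usage_floor}
    for segment, seg_floor in floors.items():
        seg = usage[usage["segment"] == segment]
        if seg.empty:
            continue
        mat = seg.pivot_table(
            index="individual_id", columns="gene", values="fraction", fill_value=0.0
        )
        totals = seg.groupby("individual_id")["total"].first().reindex(mat.index)

        passes = _deletion_pass(mat, totals, seg_floor, excluded=set())
        flat = [
            (segment, gene, ind, p)
            for gene, (_, pv) in passes.items()
            for ind, p in pv.items()
        ]
        excluded = set()
        if flat:
            rej = multipletests([p for *_, p in flat], alpha=cfg.significance,
                                method="fdr_bh")[0]
            excluded = {(ind, gene) for (seg_, gene, ind, _), r in zip(flat, rej) if r}
        passes = _deletion_pass(mat, totals, seg_floor, excluded=excluded)

        for gene in mat.columns:
            if gene not in passes:
                for ind in mat.index:
                    results.append(
                        DeletionCall(ind, gene, segment,
                                     int(math.floor(mat.loc[ind, gene] * totals[ind])),
                                     int(totals[ind]), None, None, None, "unknown")
                    )
                continue
            p_ref, pvals = passes[gene]
            for ind in mat.index:
                results.append(
                    DeletionCall(
                        ind, gene, segment,
                        int(math.floor(mat.loc[ind, gene] * totals[ind])),
                        int(totals[ind]), p_ref, float(pvals[ind]), None, "",
                    )
                )

    tested = [r for r in results if r.p_value is not None]
    if tested:
        adj = multipletests([r.p_value for r in tested], alpha=cfg.significance,
                            method="fdr_bh")[1]
        for r, a in zip(tested, adj):
            r.p_adjusted = float(max(a, r.p_value))
            r.call = "deleted" if r.p_adjusted < cfg.significance else "present"
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "segment": r.segment,
                "gene": r.gene_name,
                "X": r.x,
                "N": r.n,
                "P": r.p_ref,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "call": r.call,
            }
            for r in results
        ]
    )


@dataclass
class AlleleBiasResult:
    """Genotype-stratified usage of a focal gene plus heterozygote allele shares."""

    focal_gene: str
    usage_by_genotype: pd.DataFrame  # individual_id, genotype_group, fraction
    het_shares: pd.DataFrame  # individual_id, j_gene, allele_id, share


def allele_bias(
    usage: pd.DataFrame,
    genotypes: list[Genotype],
    reads: list[Rearrangement],
    focal_gene: str,
    cfg: CohortConfig,
) -> AlleleBiasResult:
    """Stratify a gene's usage by genotype and measure within-heterozygote
    allele shares per recombined J gene.

    ``genotype_group`` joins the sorted allele ids ("01", "01_03", ...).
    The heterozygote share table uses reads with unambiguous V and J calls.
    """
    geno_by_ind = {g.individual_id: g.entries.get(focal_gene) for g in genotypes}
    vu = usage[(usage["segment"] == "V") & (usage["gene"] == focal_gene)]
    rows = []
    for r in vu.itertuples(index=False):
        alleles = geno_by_ind.get(r.individual_id)
        if not alleles:
            continue
        rows.append(
            {
                "individual_id": r.individual_id,
                "genotype_group": "_".join(sorted(alleles)),
                "fraction": r.fraction,
            }
        )
    usage_by_genotype = pd.DataFrame(rows)

    het_inds = {i for i, a in geno_by_ind.items() if a and len(a) == 2}
    counts: dict[tuple[str, str, str], float] = defaultdict(float)
    for r in eligible_reads(reads, cfg):
        if r.individual_id not in het_inds or len(r.v_call) != 1 or len(r.j_call) != 1:
            continue
        gene, allele_id = r.v_call[0].split("*")
        if gene != focal_gene:
            continue
        counts[(r.individual_id, r.j_call[0].split("*")[0], allele_id)] += 1.0
    share_rows = []
    by_ij = defaultdict(dict)
    for (ind, jg, aid), c in counts.items():
        by_ij[(ind, jg)][aid] = c
    for (ind, jg), d in sorted(by_ij.items()):
        total = sum(d.values())
        for aid, c in sorted(d.items()):
            share_rows.append(
                {"individual_id": ind, "j_gene": jg, "allele_id": aid,
                 "share": c / total}
            )
    return AlleleBiasResult(
        focal_gene=focal_gene,
        usage_by_genotype=usage_by_genotype,
        het_shares=pd.DataFrame(share_rows),
    )
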