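"""J-anchored haplotype inference with Bayes-factor single-deletion calls.

A light-chain transcript expresses the V and J allele of the same
chromosome, so in an individual heterozygous for an "anchor" J gene (the
kappa locus reliably offers one) every V allele can be phased by counting
how often it pairs with each anchor allele.  For a V allele with pairing
counts (k1, k2):

* single-chromosome model: the allele sits on one chromosome only and the
  minority count is annotation leakage at rate eps (default 0.01), with a
  uniform prior over which chromosome:
  L1 = 1/2 [Binom(k1; n, 1-eps) + Binom(k1; n, eps)], n = k1 + k2
* both-chromosomes model: balanced pairing, L2 = Binom(k1; n, 1/2).

The Bayes factor BF = L1/L2 assigns the allele to its likelier chromosome
when BF exceeds the threshold (default 1000), to both chromosomes when 1/BF
exceeds it, and leaves it unknown otherwise.  A chromosome carrying none of
a gene's observed alleles, each phased away from it above threshold, is
called single-chromosome deleted.  Anchoring requires the individual's
anchor allele ratio to be no more extreme than 30:70.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .model import CohortConfig, Genotype, Rearrangement

log = logging.getLogger(__name__)


def bayes_factor_single_vs_both(k1: int, k2: int, eps: float = 0.01) -> float:
    """BF for 'present on one chromosome' vs 'present on both' given pairing counts."""
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must be in (0, 0.5)")
    n = k1 + k2
    if n == 0:
        return 1.0
    l_single = logsumexp(
        [binom.logpmf(k1, n, 1.0 - eps), binom.logpmf(k1, n, eps)]
    ) + np.log(0.5)
    l_both = binom.logpmf(k1, n, 0.5)
    return float(np.exp(l_single - l_both))


@dataclass
class AlleleAssignment:
    allele: str  # full allele name
    k1: int
    k2: int
    bayes_factor: float
    assignment: str  # chrom1 | chrom2 | both | unknown


@dataclass
class HaplotypeCall:
    """Phased V-gene content of one individual, anchored on a heterozygous J gene."""

    individual_id: str
    anchor_gene: str
    anchor_alleles: tuple[str, str]  # allele ids; chromosome 1 carries the first
    assignments: dict[str, list[AlleleAssignment]] = field(default_factory=dict)
    #: gene -> (chromosome-1 content, chromosome-2 content); content is an
    #: allele id, comma-joined ids, "deleted" or "unknown"
    genes: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: gene -> Bayes factor supporting a single-chromosome deletion call
    deletion_bf: dict[str, float] = field(default_factory=dict)


def infer_haplotypes(
    reads: list[Rearrangement],
    genotypes: list[Genotype],
    cfg: CohortConfig,
    anchor_gene: str,
) -> list[HaplotypeCall]:
    """Phase each anchor-heterozygous individual's V alleles; call deletions.

    Anchor heterozygosity is established from the reads themselves: the two
    most used anchor alleles must split at a ratio of at least
    ``het_min_ratio``; a per-individual genotype entry for the anchor gene,
    when available, restricts which alleles may anchor.  Individuals without
    a usable anchor heterozygote are skipped with a logged notice.  Only
    reads with unambiguous single V and J calls contribute counts.
    """
    geno = {g.individual_id: g for g in genotypes}
    anchor_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    usable = []
    for r in reads:
        if len(r.v_call) != 1 or len(r.j_call) != 1:
            continue
        jg, jid = r.j_call[0].split("*")
        if jg == anchor_gene:
            anchor_counts[r.individual_id][jid] += 1
            usable.append((r.individual_id, r.v_call[0], jid))

    anchors: dict[str, tuple[str, str]] = {}
    for ind, cnt in anchor_counts.items():
        allowed = geno.get(ind) and geno[ind].entries.get(anchor_gene)
        cand = {a: c for a, c in cnt.items() if not allowed or a in allowed}
        if len(cand) < 2:
            continue
        top = sorted(cand, key=lambda a: (-cand[a], a))[:2]
        anchors[ind] = (min(top), max(top))

    pair_counts: dict[str, dict[str, list[int]]] = defaultdict(
        lambda: defaultdict(lambda: [0, 0])
    )
    for ind, v_allele, jid in usable:
        if ind not in anchors:
            continue
        a1, a2 = anchors[ind]
        if jid == a1:
            pair_counts[ind][v_allele][0] += 1
        elif jid == a2:
            pair_counts[ind][v_allele][1] += 1

    calls: list[HaplotypeCall] = []
    for ind in sorted(geno):
        if ind not in anchors:
            log.info("%s: no anchor heterozygote at %s; skipped", ind, anchor_gene)
            continue
        a1, a2 = anchors[ind]
        n1, n2 = anchor_counts[ind].get(a1, 0), anchor_counts[ind].get(a2, 0)
        if n1 + n2 == 0 or min(n1, n2) / (n1 + n2) < cfg.het_min_ratio:
            log.info(
                "%s: anchor allele ratio %d:%d below %s; skipped",
                ind, n1, n2, cfg.het_min_ratio,
            )
            continue
        call = HaplotypeCall(individual_id=ind, anchor_gene=anchor_gene,
                             anchor_alleles=(a1, a2))
        per_gene: dict[str, list[AlleleAssignment]] = defaultdict(list)
        for v_allele, (k1, k2) in sorted(pair_counts[ind].items()):
            bf = bayes_factor_single_vs_both(k1, k2, cfg.leak_rate)
            if bf > cfg.bayes_factor_threshold:
                assignment = "chrom1" if k1 >= k2 else "chrom2"
            elif bf > 0 and 1.0 / bf > cfg.bayes_factor_threshold:
                assignment = "both"
            else:
                assignment = "unknown"
            per_gene[v_allele.split("*")[0]].append(
                AlleleAssignment(v_allele, k1, k2, bf, assignment)
            )
        call.assignments = dict(per_gene)
        for gene, asg in per_gene.items():
            content = {"chrom1": [], "chrom2": []}
            unknown = False
            for a in asg:
                aid = a.allele.split("*")[1]
                if a.assignment == "both":
                    content["chrom1"].append(aid)
                    content["chrom2"].append(aid)
                elif a.assignment in ("chrom1", "chrom2"):
                    content[a.assignment].append(aid)
                else:
                    unknown = True
            sides = []
            for side in ("chrom1", "chrom2"):
                if content[side]:
                    sides.append(",".join(sorted(content[side])))
                elif unknown:
                    sides.append("unknown")
                else:
                    # every observed allele phased to the other chromosome
                    sides.append("deleted")
                    call.deletion_bf[gene] = min(a.bayes_factor for a in asg)
            call.genes[gene] = (sides[0], sides[1])
        calls.append(call)
    return calls


def haplotype_frame(calls: list[HaplotypeCall]):
    """Wide per-gene haplotype table (one row per individual x gene)."""
    import pandas as pd

    rows = []
    for c in calls:
        for gene, (h1, h2) in sorted(c.genes.items()):
            rows.append(
                {
                    "individual_id": c.individual_id,
                    "anchor": f"{c.anchor_gene}*{c.anchor_alleles[0]}/{c.anchor_alleles[1]}",
                    "gene": gene,
                    "chrom1": h1,
                    "chrom2": h2,
                    "deletion_bf": c.deletion_bf.get(gene, float("nan")),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "anchor", "gene", "chrom1", "chrom2", "deletion_bf"],
    )
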