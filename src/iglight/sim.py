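"""Synthetic light-chain repertoire generator.

Produces a germline V/J reference, per-individual genotypes and AIRR-style
repertoires with the statistical structure the inference pipeline assumes:

* duplicated gene pairs sharing an identical allele (exercises collapsing)
  and terminally truncated reference alleles (exercises consensus extension);
* planted novel single-nucleotide polymorphisms at controlled carrier
  frequency and zygosity;
* double- and single-chromosome gene deletions, with a J "anchor" gene kept
  heterozygous in a configurable fraction of the cohort so that haplotypes
  can be phased against it;
* MiSeq-like substitution errors with an elevated A->C rate, plus
  repeat-motif error hotspots: positions whose reference neighbours are
  identical (e.g. CAC) where substitution to the neighbour base (CCC) occurs
  at an elevated, positionally fixed rate -- reproducing the cohort-wide
  sub-cutoff "stack" of artefact mismatch frequencies;
* per-transcript upstream regions (5'UTR + L-PART1 + L-PART2) in which a
  minority of transcripts of selected genes retain a prefix of the
  L-PART1/L-PART2 intron, introducing a premature stop codon.

Each transcript expresses the V and J allele of the *same* chromosome, which
is what makes J-anchored haplotyping informative.  Junctions are a fixed
short linker: the light-chain analyses here never use junction diversity.
Somatic hypermutation is not modelled beyond the residual error load -- the
simulated cohort is naive.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GermlineAllele, GenomicVGene, Rearrangement, encode

_STOPS = {"TAA", "TAG", "TGA"}
_ACGT = np.array(list("ACGT"))


@dataclass
class NovelSNP:
    """A planted germline SNP: new allele = base allele *01 with ref->alt at position."""

    gene: str
    position: int  # 1-based on the V-REGION
    alt: str | None = None  # None: pick the next base after the reference base
    carrier_freq: float = 0.4
    hom_fraction: float = 0.25  # fraction of carriers that are homozygous


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference scenario used throughout the test suite:
    20 individuals x 5000 sequences over 10 V genes (plus one duplicated
    sibling) and 5 J genes, V-REGION length 300 nt, substitution error rate
    1e-3 with a 6x elevated A->C channel, three repeat-motif error hotspots
    erring at rate 0.15, five planted novel SNPs carried by 40% of the
    cohort, two double- and two single-chromosome deletions, and intron
    retention in 15% of the transcripts of two genes (retained prefix 7 nt).
    """

    seed: int = 1
    n_individuals: int = 20
    n_v_genes: int = 10
    n_j_genes: int = 5
    v_len: int = 300
    j_len: int = 38
    seqs_per_individual: int = 5000
    base_error_rate: float = 0.001
    ac_error_multiplier: float = 6.0
    repeat_hotspot_rate: float = 0.15
    n_hotspots: int = 3
    duplicated_gene_pairs: int = 1
    truncated_allele_count: int = 2
    anchor_het_fraction: float = 0.25
    upstream_retention_prob: float = 0.15
    retained_intron_len: int = 7
    n_retention_genes: int = 2
    junction: str = "GCT"
    novel_snp_table: list[NovelSNP] | None = None
    double_deletion_table: list[tuple[str, list[str]]] | None = None
    single_deletion_table: list[tuple[str, str, int]] | None = None
    #: (gene, {allele_id: expression weight}) -- heterozygote transcription bias
    allele_bias_table: list[tuple[str, dict[str, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "repeat_hotspot_rate", "anchor_het_fraction",
                     "upstream_retention_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ac_error_multiplier < 1.0:
            raise ValueError("ac_error_multiplier must be >= 1")
        if self.novel_snp_table is None:
            self.novel_snp_table = self._default_snps()
        if self.double_deletion_table is None:
            self.double_deletion_table = self._default_double_deletions()
        if self.single_deletion_table is None:
            self.single_deletion_table = self._default_single_deletions()

    # -- deterministic gene naming ------------------------------------------
    def v_gene_name(self, i: int) -> str:
        return f"IGKV1-{i + 2}"

    def v_gene_sibling(self, i: int) -> str:
        return f"IGKV1D-{i + 2}"

    def j_gene_name(self, i: int) -> str:
        return f"IGKJ{i + 1}"

    @property
    def anchor_gene(self) -> str:
        return self.j_gene_name(1) if self.n_j_genes >= 2 else self.j_gene_name(0)

    def individuals(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_individuals)]

    # -- default planting layout -------------------------------------------
    # gene slots: 0 duplicated pair; 1..5 SNPs (1,2 also carry a truncated
    # reference allele); 6..8 error hotspots; retention on 3,4; double
    # deletions on 9 and 6; single deletions on 7 and 8.
    def _slot(self, i: int) -> str:
        return self.v_gene_name(i % self.n_v_genes)

    def snp_genes(self) -> list[str]:
        return [self._slot(i) for i in range(1, 6)]

    def hotspot_genes(self) -> list[str]:
        return [self._slot(6 + i) for i in range(self.n_hotspots)]

    def truncated_genes(self) -> list[str]:
        return [self._slot(1 + i) for i in range(self.truncated_allele_count)]

    def retention_genes(self) -> list[str]:
        return [self._slot(3 + i) for i in range(self.n_retention_genes)]

    def _default_snps(self) -> list[NovelSNP]:
        return [
            NovelSNP(gene=g, position=31 + 10 * k, carrier_freq=0.4, hom_fraction=0.25)
            for k, g in enumerate(self.snp_genes())
        ]

    def _default_double_deletions(self):
        inds = self.individuals()
        if self.n_individuals < 8:
            return []
        return [(self._slot(9), [inds[3]]), (self._slot(6), [inds[7]])]

    def _default_single_deletions(self):
        inds = self.individuals()
        if self.n_individuals < 6:
            return []
        return [(self._slot(7), inds[1], 1), (self._slot(8), inds[5], 2)]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Reference:
    """Generated germline reference plus the metadata later stages consume."""

    alleles: list[GermlineAllele]
    genomic_genes: dict[str, GenomicVGene]
    #: gene -> 0-based V-REGION hotspot position (reference base A between two C)
    hotspots: dict[str, int]
    #: raw gene name -> relative transcription weight (shared across the cohort)
    v_usage_weights: dict[str, float]
    anchor_gene: str

    def allele(self, name: str) -> GermlineAllele:
        return self._by_name[name]

    def __post_init__(self) -> None:
        self._by_name = {a.name: a for a in self.alleles}

    def gene_alleles(self, gene: str) -> list[GermlineAllele]:
        return [a for a in self.alleles if a.gene_name == gene]


@dataclass
class Cohort:
    genotypes: list  # list[Genotype]-compatible view built from chromosomes
    #: individual -> gene -> [chr1 allele_id or None, chr2 allele_id or None]
    chromosomes: dict[str, dict[str, list[str | None]]]
    #: novel alleles carried by the cohort but absent from the reference
    true_alleles: dict[str, str]  # full allele name -> sequence
    truth: dict[str, pd.DataFrame]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_ACGT, size=n))


def _random_nonstop_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def make_reference(cfg: SimulationConfig) -> Reference:
    """Generate the germline V/J reference and genomic V-gene models."""
    rng = np.random.default_rng([cfg.seed, 11])
    alleles: list[GermlineAllele] = []
    genomic: dict[str, GenomicVGene] = {}
    hotspots: dict[str, int] = {}
    hotspot_genes = set(cfg.hotspot_genes())
    truncated = set(cfg.truncated_genes())
    snp_positions = {s.gene: s.position for s in cfg.novel_snp_table}

    raw_gene_names: list[str] = []
    for i in range(cfg.n_v_genes):
        gene = cfg.v_gene_name(i)
        seq01 = list(_random_seq(rng, cfg.v_len))
        if gene in hotspot_genes:
            pos = int(rng.integers(100, 160))
            seq01[pos - 1], seq01[pos], seq01[pos + 1] = "C", "A", "C"
            hotspots[gene] = pos
        # allele *02 differs from *01 at three positions in [200, 260)
        diff_pos = rng.choice(np.arange(200, 260), size=3, replace=False)
        seq02 = list(seq01)
        for p in diff_pos:
            cur = seq02[p]
            seq02[p] = _ACGT[( "ACGT".index(cur) + 1) % 4]
        seq01, seq02 = "".join(seq01), "".join(seq02)
        alleles.append(GermlineAllele(gene, "01", seq01))
        alleles.append(GermlineAllele(gene, "02", seq02))
        raw_gene_names.append(gene)
        if gene in truncated:
            # reference-only truncated allele: internal SNP + 5' truncation
            p = int(rng.integers(265, 295))
            s = list(seq01)
            s[p] = _ACGT[("ACGT".index(s[p]) + 2) % 4]
            alleles.append(GermlineAllele(gene, "03", "".join(s)[12:]))

        utr5 = _random_seq(rng, 20)
        exon_from_atg = "ATG" + _random_nonstop_codons(rng, 11)  # 36 nt leader part 1
        intron = "GTCTAAG" + _random_seq(rng, 51) + "AG"  # 60 nt, GT...AG
        lpart2 = _random_seq(rng, 11)
        genomic[gene] = GenomicVGene(
            gene_name=gene,
            promoter=_random_seq(rng, 30),
            utr5_exon=utr5 + exon_from_atg,
            intron=intron,
            lpart2=lpart2,
            v_region=seq01,
            leader_start_offset=20,
        )
        if i < cfg.duplicated_gene_pairs:
            sib = cfg.v_gene_sibling(i)
            alleles.append(GermlineAllele(sib, "01", seq01))
            raw_gene_names.append(sib)
            genomic[sib] = dataclasses.replace(genomic[gene], gene_name=sib)
        if gene in snp_positions:
            assert snp_positions[gene] - 1 not in (
                set(int(p) for p in diff_pos) | {hotspots.get(gene)}
            )

    for i in range(cfg.n_j_genes):
        gene = cfg.j_gene_name(i)
        seq01 = _random_seq(rng, cfg.j_len)
        alleles.append(GermlineAllele(gene, "01", seq01))
        if gene == cfg.anchor_gene:
            s = list(seq01)
            for p in (10, 20):
                s[p] = _ACGT[("ACGT".index(s[p]) + 1) % 4]
            alleles.append(GermlineAllele(gene, "02", "".join(s)))

    w = rng.dirichlet(np.full(len(raw_gene_names), 12.0))
    weights = {g: float(x) for g, x in zip(raw_gene_names, w)}
    return Reference(
        alleles=alleles,
        genomic_genes=genomic,
        hotspots=hotspots,
        v_usage_weights=weights,
        anchor_gene=cfg.anchor_gene,
    )


def make_cohort(cfg: SimulationConfig, ref: Reference) -> Cohort:
    """Draw per-individual diploid genotypes and record the ground truth."""
    from .model import Genotype

    rng = np.random.default_rng([cfg.seed, 23])
    inds = cfg.individuals()
    known_genes = {a.gene_name for a in ref.alleles}
    for snp in cfg.novel_snp_table:
        if snp.gene not in known_genes:
            raise ValueError(f"novel SNP references unknown gene {snp.gene}")
    for gene, _ in cfg.double_deletion_table:
        if gene not in known_genes:
            raise ValueError(f"double deletion references unknown gene {gene}")
    for gene, _, _ in cfg.single_deletion_table:
        if gene not in known_genes:
            raise ValueError(f"single deletion references unknown gene {gene}")

    v_genes = sorted(g for g in known_genes if g[3] == "V")
    j_genes = sorted(g for g in known_genes if g[3] == "J")

    chromosomes: dict[str, dict[str, list[str | None]]] = {}
    for ind in inds:
        chromosomes[ind] = {}
        for g in v_genes:
            carried = [a.allele_id for a in ref.gene_alleles(g) if a.allele_id in ("01", "02")]
            chromosomes[ind][g] = [str(rng.choice(carried)) for _ in range(2)]
        for g in j_genes:
            chromosomes[ind][g] = ["01", "01"]

    # anchor heterozygosity: exactly round(fraction * n) individuals, forced to
    # include every single-deletion individual (they must be phaseable)
    n_het = int(round(cfg.anchor_het_fraction * cfg.n_individuals))
    forced = [i for _, i, _ in cfg.single_deletion_table]
    pool = [i for i in inds if i not in forced]
    extra = list(rng.choice(pool, size=max(0, n_het - len(forced)), replace=False))
    het_inds = sorted(set(forced) | set(extra))[:max(n_het, len(forced))]
    for ind in het_inds:
        chromosomes[ind][cfg.anchor_gene] = ["01", "02"]

    # planted novel SNPs
    true_alleles: dict[str, str] = {}
    snp_rows = []
    for snp in cfg.novel_snp_table:
        base = ref.allele(f"{snp.gene}*01")
        refb = base.sequence[snp.position - 1]
        alt = snp.alt or "ACGT"[("ACGT".index(refb) + 1) % 4]
        novel_id = f"01_{refb}{snp.position}{alt}"
        seq = base.sequence[: snp.position - 1] + alt + base.sequence[snp.position:]
        true_alleles[f"{snp.gene}*{novel_id}"] = seq
        n_carriers = int(round(snp.carrier_freq * cfg.n_individuals))
        carriers = sorted(rng.choice(inds, size=n_carriers, replace=False))
        for ind in carriers:
            hom = bool(rng.random() < snp.hom_fraction)
            if hom:
                chromosomes[ind][snp.gene] = [novel_id, novel_id]
            else:
                chromosomes[ind][snp.gene][int(rng.integers(2))] = novel_id
            snp_rows.append(
                {
                    "individual_id": ind,
                    "gene": snp.gene,
                    "position": snp.position,
                    "ref": refb,
                    "alt": alt,
                    "allele_id": novel_id,
                    "zygosity": "hom" if hom else "het",
                }
            )

    del_rows = []
    for gene, targets in cfg.double_deletion_table:
        for ind in targets:
            chromosomes[ind][gene] = [None, None]
            del_rows.append(
                {"individual_id": ind, "gene": gene, "type": "double", "chromosome": 0}
            )
    for gene, ind, chrom in cfg.single_deletion_table:
        chromosomes[ind][gene][chrom - 1] = None
        del_rows.append(
            {"individual_id": ind, "gene": gene, "type": "single", "chromosome": chrom}
        )

    hap_rows = [
        {
            "individual_id": ind,
            "gene": g,
            "chrom1": chromosomes[ind][g][0] or "deleted",
            "chrom2": chromosomes[ind][g][1] or "deleted",
        }
        for ind in inds
        for g in v_genes + j_genes
    ]
    splice_rows = [
        {
            "gene": g,
            "retained_len": cfg.retained_intron_len,
            "retention_prob": cfg.upstream_retention_prob,
        }
        for g in cfg.retention_genes()
    ]

    genotypes = [
        Genotype(
            individual_id=ind,
            entries={
                g: frozenset(x for x in chromosomes[ind][g] if x is not None)
                for g in chromosomes[ind]
                if any(x is not None for x in chromosomes[ind][g])
            },
        )
        for ind in inds
    ]
    truth = {
        "novel_snps": pd.DataFrame(snp_rows),
        "deletions": pd.DataFrame(del_rows),
        "haplotypes": pd.DataFrame(hap_rows),
        "splice_variants": pd.DataFrame(splice_rows),
        "anchor_het": pd.DataFrame({"individual_id": het_inds}),
    }
    return Cohort(
        genotypes=genotypes,
        chromosomes=chromosomes,
        true_alleles=true_alleles,
        truth=truth,
    )


def _apply_errors(
    rng: np.random.Generator,
    base_codes: np.ndarray,
    n_reads: int,
    cfg: SimulationConfig,
    hotspot_cols: list[int],
) -> np.ndarray:
    """Substitution errors over copies of one base sequence, vectorised.

    Per position the total substitution probability is ``base_error_rate``
    (split evenly over the three other bases), except that the A->C channel
    is multiplied by ``ac_error_multiplier`` and that designated hotspot
    columns (reference A flanked by two C) instead substitute to C at
    ``repeat_hotspot_rate``.  A zero ``base_error_rate`` disables all errors,
    hotspots included, so the noise-free limit is exactly germline.
    """
    n = base_codes.size
    reads = np.tile(base_codes, (n_reads, 1))
    if cfg.base_error_rate <= 0 or n_reads == 0:
        return reads
    is_a = base_codes == 1
    p = np.full(n, cfg.base_error_rate)
    p[is_a] = cfg.base_error_rate * (2.0 + cfg.ac_error_multiplier) / 3.0
    for c in hotspot_cols:
        p[c] = cfg.repeat_hotspot_rate
    err = rng.random((n_reads, n)) < p[None, :]
    if not err.any():
        return reads
    rows, cols = np.nonzero(err)
    u = rng.random(rows.size)
    new = np.empty(rows.size, dtype=np.uint8)
    for k, (r, c) in enumerate(zip(rows, cols)):
        b = base_codes[c]
        if c in hotspot_cols:
            new[k] = 2  # C, matching both neighbours
        elif b == 1:  # A: targets C, G, T with weights (mult, 1, 1)
            m = cfg.ac_error_multiplier
            w = np.array([m, 1.0, 1.0]) / (m + 2.0)
            new[k] = (2, 3, 4)[int(np.searchsorted(np.cumsum(w), u[k]))]
        else:
            others = [x for x in (1, 2, 3, 4) if x != b]
            new[k] = others[int(u[k] * 3)]
    reads[rows, cols] = new
    return reads


def make_repertoire(
    cfg: SimulationConfig, cohort: Cohort, ref: Reference
) -> list[Rearrangement]:
    """Generate error-bearing transcripts for every individual.

    Per transcript: a V gene is drawn by the cohort-shared usage weights
    (restricted to the individual's non-deleted genes), a chromosome is drawn
    among those carrying the gene (equal odds, or the configured heterozygote
    allele bias), and the J gene is drawn uniformly with its allele taken
    from the *same* chromosome.  The upstream region is the gene's canonical
    5'exon + L-PART2, or retains the configured intron prefix for a fraction
    of transcripts of the retention genes.
    """
    rng = np.random.default_rng([cfg.seed, 37])
    bias = {g: w for g, w in cfg.allele_bias_table}
    retention = set(cfg.retention_genes())
    j_genes = sorted({a.gene_name for a in ref.alleles if a.segment == "J"})
    from .model import decode

    def allele_seq(gene: str, allele_id: str) -> str:
        name = f"{gene}*{allele_id}"
        if name in cohort.true_alleles:
            return cohort.true_alleles[name]
        return ref.allele(name).sequence

    reads: list[Rearrangement] = []
    for ind in cfg.individuals():
        chrom = cohort.chromosomes[ind]
        genes = [g for g in chrom if g[3] == "V" and any(chrom[g])]
        w = np.array([ref.v_usage_weights[g] for g in genes])
        w = w / w.sum()
        gene_idx = rng.choice(len(genes), size=cfg.seqs_per_individual, p=w)
        chrom_u = rng.random(cfg.seqs_per_individual)
        j_idx = rng.integers(0, len(j_genes), size=cfg.seqs_per_individual)
        ret_u = rng.random(cfg.seqs_per_individual)

        # group reads by (gene, chromosome, j gene, retention) for vector errors
        groups: dict[tuple, list[int]] = {}
        for t in range(cfg.seqs_per_individual):
            g = genes[gene_idx[t]]
            present = [c for c in (0, 1) if chrom[g][c] is not None]
            if len(present) == 2:
                a0, a1 = chrom[g][0], chrom[g][1]
                if g in bias:
                    w0 = bias[g].get(a0.split("_")[0], bias[g].get(a0, 1.0))
                    w1 = bias[g].get(a1.split("_")[0], bias[g].get(a1, 1.0))
                    c = 0 if chrom_u[t] < w0 / (w0 + w1) else 1
                else:
                    c = 0 if chrom_u[t] < 0.5 else 1
            else:
                c = present[0]
            retained = g in retention and ret_u[t] < cfg.upstream_retention_prob
            groups.setdefault((g, c, int(j_idx[t]), retained), []).append(t)

        seqs: list[str | None] = [None] * cfg.seqs_per_individual
        for (g, c, ji, retained), members in sorted(groups.items()):
            jg = j_genes[ji]
            model = ref.genomic_genes[g]
            upstream = (
                model.retained_upstream(cfg.retained_intron_len)
                if retained
                else model.canonical_upstream
            )
            v_seq = allele_seq(g, chrom[g][c])
            j_seq = allele_seq(jg, chrom[jg][c])
            full = upstream + v_seq + cfg.junction + j_seq
            codes = encode(full)
            hotspot_cols = (
                [len(upstream) + ref.hotspots[g]] if g in ref.hotspots else []
            )
            block = _apply_errors(rng, codes, len(members), cfg, hotspot_cols)
            for row, t in zip(block, members):
                seqs[t] = decode(row)
        for t, s in enumerate(seqs):
            reads.append(
                Rearrangement(
                    sequence_id=f"{ind}-{t:05d}", individual_id=ind, sequence=s
                )
            )
    return reads


@dataclass
class SimulatedStudy:
    cfg: SimulationConfig
    reference: Reference
    cohort: Cohort
    reads: list[Rearrangement]


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    ref = make_reference(cfg)
    cohort = make_cohort(cfg, ref)
    reads = make_repertoire(cfg, cohort, ref)
    return SimulatedStudy(cfg=cfg, reference=ref, cohort=cohort, reads=reads)
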