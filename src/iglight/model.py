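"""Core domain types for light-chain germline inference.

The package works on naive B-cell-receptor repertoires of the human
immunoglobulin light-chain loci (IGK on chromosome 2, IGL on chromosome 22).
A light-chain transcript is an upstream region (5'UTR + split leader peptide)
followed by a rearranged V gene joined directly to a J gene -- light chains
carry no D segment.  The types here are shared by every analysis stage:
germline reference alleles, observed rearrangements, per-individual
genotypes, and the cohort-level configuration thresholds.

Coordinate convention: all internal coordinates are 0-based half-open;
positions shown to users in variant labels (``T31C``) are 1-based on the
ungapped reference allele, counting from position 1 of the V-REGION.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: integer codes used throughout for vectorised sequence comparison;
#: N (and any ambiguity code) maps to 0 and never counts as a mismatch.
_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

_BASES = "NACGT"  # index -> symbol for decode()


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=1, C=2, G=3, T=4, other=0)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


_GENE_RE = re.compile(
    r"^(?P<prefix>IG[KL][VJ])(?P<family>\d+[A-Z]*)?(?:-(?P<position>\w+))?$"
)


def parse_gene_name(name: str) -> tuple[str, str, str | None]:
    """Split e.g. ``IGKV1D-12`` into ('IGKV', '1D', '12'); ``IGKJ2`` -> ('IGKJ', '2', None)."""
    m = _GENE_RE.match(name)
    if not m:
        raise ValueError(f"unparseable gene name: {name!r}")
    return m.group("prefix"), m.group("family") or "", m.group("position")


def merged_gene_name(members: list[str]) -> str:
    """Name for a group of duplicated genes collapsed into one.

    The 'E' marker is inserted after the family number, before the hyphenated
    position token: IGKV1-12 + IGKV1D-12 -> IGKV1E-12.  The family digits and
    position are taken from the alphabetically first member.
    """
    prefix, family, position = parse_gene_name(sorted(members)[0])
    digits = re.match(r"\d+", family)
    fam = digits.group(0) if digits else family
    return f"{prefix}{fam}E-{position}" if position else f"{prefix}{fam}E"


@dataclass
class GermlineAllele:
    """One named germline reference allele of a V or J gene.

    ``extended_5p_len`` / ``extended_3p_len`` count terminal bases that were
    synthesised by consensus extension of a truncated reference allele; such
    positions are excluded from mismatch counting and candidate reporting.
    ``collapsed_from`` records the original gene names when duplicated genes
    sharing an identical allele were merged under an 'E' name.
    """

    gene_name: str
    allele_id: str
    sequence: str
    extended_5p_len: int = 0
    extended_3p_len: int = 0
    collapsed_from: list[str] = field(default_factory=list)
    functional: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")
        if self.extended_5p_len + self.extended_3p_len >= len(self.sequence):
            raise ValueError(f"{self.name}: extension spans cover whole sequence")
        if self.collapsed_from:
            _, family, _ = parse_gene_name(self.gene_name)
            if "E" not in family:
                raise ValueError(
                    f"{self.name}: collapsed allele must carry the 'E' gene marker"
                )

    @property
    def name(self) -> str:
        return f"{self.gene_name}*{self.allele_id}"

    @property
    def locus(self) -> str:
        return self.gene_name[:3]

    @property
    def segment(self) -> str:
        return self.gene_name[3]

    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def valid_mask(self) -> np.ndarray:
        """Positions that may count as mismatches: real bases outside extended spans."""
        mask = encode(self.sequence) != 0
        if self.extended_5p_len:
            mask[: self.extended_5p_len] = False
        if self.extended_3p_len:
            mask[-self.extended_3p_len:] = False
        return mask


@dataclass
class GenomicVGene:
    """Genomic context of a V gene used for splice classification.

    ``utr5_exon`` runs from the transcription start through L-PART1 and ends
    at the splice donor site; the leader reading frame starts at the ATG at
    ``leader_start_offset`` and continues across the exon junction into
    L-PART2 (no frame constraint is imposed on the junction itself).
    """

    gene_name: str
    promoter: str
    utr5_exon: str
    intron: str
    lpart2: str
    v_region: str
    leader_start_offset: int

    def __post_init__(self) -> None:
        if not (self.intron.startswith("GT") and self.intron.endswith("AG")):
            raise ValueError(f"{self.gene_name}: intron must start GT and end AG")
        if not (0 <= self.leader_start_offset < len(self.utr5_exon)):
            raise ValueError(f"{self.gene_name}: leader ATG outside the 5' exon")

    @property
    def canonical_upstream(self) -> str:
        return self.utr5_exon + self.lpart2

    def retained_upstream(self, retained_len: int) -> str:
        if not (1 <= retained_len <= len(self.intron)):
            raise ValueError("retained_len outside the intron")
        return self.utr5_exon + self.intron[:retained_len] + self.lpart2


@dataclass
class Rearrangement:
    """One observed repertoire sequence (upstream + V + junction + J)."""

    sequence_id: str
    individual_id: str
    sequence: str
    v_call: list[str] = field(default_factory=list)
    j_call: list[str] = field(default_factory=list)
    v_mutation_count: int | None = None
    v_region_start: int | None = None

    @property
    def upstream_seq(self) -> str:
        """Portion of the sequence before the V-REGION (empty until annotated)."""
        if self.v_region_start is None:
            return ""
        return self.sequence[: self.v_region_start]

    @property
    def v_genes(self) -> list[str]:
        """Distinct gene names among the V calls, sorted."""
        return sorted({c.split("*")[0] for c in self.v_call})

    @property
    def j_genes(self) -> list[str]:
        return sorted({c.split("*")[0] for c in self.j_call})

    def replace(self, **kw) -> "Rearrangement":
        return dataclasses.replace(self, **kw)


@dataclass
class Genotype:
    """Per-individual allele content: gene name -> set of allele ids (1-4)."""

    individual_id: str
    entries: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Cohort-level analysis thresholds.

    Defaults follow the inference strategy this package implements: only
    individuals with at least 2000 sequences enter the analysis; sequences
    with 3 or more V-REGION mismatches are treated as non-naive and dropped;
    the mismatch-frequency cutoff of 0.25 admits equal expression of up to
    four variants of one gene; gene-deletion candidate floors are 0.001 for
    V and 0.005 for J (fewer J genes, higher per-gene usage); deletion calls
    use Benjamini-Hochberg adjusted p-values at significance 0.01; haplotype
    anchoring needs a heterozygous J gene with allele ratio at least 30:70
    and single-chromosome deletion calls need a Bayes factor above 1000.
    """

    min_sequences_per_individual: int = 2000
    max_v_mutations: int = 3  # exclusive bound: keep v_mutation_count <= 2
    v_usage_floor: float = 0.001
    j_usage_floor: float = 0.005
    mismatch_cutoff: float = 0.25
    significance: float = 0.01
    het_min_ratio: float = 0.30
    bayes_factor_threshold: float = 1000.0
    max_novel_per_gene: int = 2
    # candidate generation / pattern classification
    candidate_floor: float | None = None  # defaults to mismatch_cutoff / 2
    min_freq_depth: float = 10.0  # sequences needed for a defined mismatch frequency
    noise_floor: float = 0.05
    multimodal_gap: float = 0.15
    # haplotype likelihood: cross-chromosome leak rate (annotation noise)
    leak_rate: float = 0.01
    # upstream clustering
    upstream_length_class_min: float = 0.05
    cluster_ident: float = 0.999
    cluster_length_cov: float = 0.5
    consensus_freq: float = 0.6
    cluster_min_freq: float = 0.01
    cluster_min_size: int = 5

    def __post_init__(self) -> None:
        for name in (
            "v_usage_floor", "j_usage_floor", "mismatch_cutoff", "significance",
            "het_min_ratio", "noise_floor", "multimodal_gap", "leak_rate",
            "upstream_length_class_min", "consensus_freq", "cluster_min_freq",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.candidate_floor is None:
            self.candidate_floor = self.mismatch_cutoff / 2.0
        if self.bayes_factor_threshold <= 0:
            raise ValueError("bayes_factor_threshold must be positive")
        if self.min_sequences_per_individual < 1 or self.max_v_mutations < 1:
            raise ValueError("count thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load a config from YAML; keys override the defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)
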