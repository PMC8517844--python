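"""Readers and writers: AIRR Rearrangement TSV and germline FASTA.

AIRR tables are tab-separated with one row per rearranged sequence and the
community-standard column names (sequence_id, sequence, v_call, j_call, ...).
Multi-valued calls are comma-separated within a cell.  Optional columns used
by this package: individual_id (subject_id accepted as an alias),
v_mutation_count, v_region_start.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GermlineAllele, GenomicVGene, Rearrangement

log = logging.getLogger(__name__)

_MANDATORY = ("sequence_id", "sequence", "v_call", "j_call")


class AirrFormatError(ValueError):
    pass


def _split_call(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return [c.strip() for c in str(value).split(",") if c.strip()]


def read_airr(path) -> list[Rearrangement]:
    """Read an AIRR Rearrangement TSV into Rearrangement records.

    An empty file (header only, or zero bytes) yields an empty list; a header
    missing a mandatory column raises :class:`AirrFormatError` naming it.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise AirrFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    ind_col = next(
        (c for c in ("individual_id", "subject_id", "repertoire_id") if c in df.columns),
        None,
    )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        vm = d.get("v_mutation_count", "")
        vs = d.get("v_region_start", "")
        records.append(
            Rearrangement(
                sequence_id=d["sequence_id"],
                individual_id=d[ind_col] if ind_col else "",
                sequence=d["sequence"].upper(),
                v_call=_split_call(d["v_call"]),
                j_call=_split_call(d["j_call"]),
                v_mutation_count=int(float(vm)) if vm not in ("", "NA") else None,
                v_region_start=int(float(vs)) if vs not in ("", "NA") else None,
            )
        )
    return records


def write_airr(reads: list[Rearrangement], path) -> None:
    """Write Rearrangement records as AIRR TSV (round-trips with read_airr)."""
    df = pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in reads],
            "individual_id": [r.individual_id for r in reads],
            "sequence": [r.sequence for r in reads],
            "v_call": [",".join(r.v_call) for r in reads],
            "j_call": [",".join(r.j_call) for r in reads],
            "v_mutation_count": [
                "" if r.v_mutation_count is None else r.v_mutation_count for r in reads
            ],
            "v_region_start": [
                "" if r.v_region_start is None else r.v_region_start for r in reads
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_fasta(alleles: list[GermlineAllele], path) -> None:
    """Write alleles as FASTA, headers ``gene_name*allele_id``, 60-col wrapped."""
    names = [a.name for a in alleles]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate allele names: {', '.join(dupes)}")
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="") for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[GermlineAllele]:
    """Read a germline FASTA whose headers are ``gene_name*allele_id``."""
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "*" in rec.id:
            gene, allele_id = rec.id.split("*", 1)
        else:
            gene, allele_id = rec.id, "01"
        alleles.append(GermlineAllele(gene, allele_id, str(rec.seq)))
    return alleles


def write_genomic_genes(genes: dict[str, GenomicVGene], path) -> None:
    """Write V-gene genomic segment coordinates/sequences as TSV."""
    rows = [
        {
            "gene_name": g.gene_name,
            "promoter": g.promoter,
            "utr5_exon": g.utr5_exon,
            "intron": g.intron,
            "lpart2": g.lpart2,
            "v_region": g.v_region,
            "leader_start_offset": g.leader_start_offset,
        }
        for g in genes.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genomic_genes(path) -> dict[str, GenomicVGene]:
    df = pd.read_csv(path, sep="\t", dtype={"leader_start_offset": int})
    out = {}
    for row in df.itertuples(index=False):
        g = GenomicVGene(
            gene_name=row.gene_name,
            promoter=row.promoter,
            utr5_exon=row.utr5_exon,
            intron=row.intron,
            lpart2=row.lpart2,
            v_region=row.v_region,
            leader_start_offset=int(row.leader_start_offset),
        )
        out[g.gene_name] = g
    return out
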