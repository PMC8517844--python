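"""Reference preparation: collapse duplicated genes, extend truncated alleles.

The kappa locus carries a large duplication; many duplicated gene pairs share
identical allele sequences, so an annotator cannot tell them apart.  Genes
sharing at least one identical allele sequence are therefore merged under a
single name carrying an 'E' marker (IGKV1-12 + IGKV1D-12 -> IGKV1E-12), with
the distinct sequences renumbered consecutively from 01.  Several reference
alleles are terminally truncated relative to their gene; these are extended
to the gene's full extent with a position-wise consensus over the other
alleles so that annotation is driven by sequence identity, not length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .model import GermlineAllele, merged_gene_name


@dataclass
class Merge:
    original_genes: list[str]
    new_gene: str
    #: (original gene, original allele_id) -> new allele_id
    renumbering: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class CollapseReport:
    merges: list[Merge] = field(default_factory=list)

    def gene_map(self) -> dict[str, str]:
        """Original gene name -> post-collapse gene name (identity if unmerged)."""
        return {g: m.new_gene for m in self.merges for g in m.original_genes}

    def allele_map(self) -> dict[str, str]:
        """Original full allele name -> post-collapse full allele name."""
        out = {}
        for m in self.merges:
            for (gene, aid), new_id in m.renumbering.items():
                out[f"{gene}*{aid}"] = f"{m.new_gene}*{new_id}"
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {"old_gene": g, "old_allele": a, "new_gene": m.new_gene, "new_allele": n}
            for m in self.merges
            for (g, a), n in sorted(m.renumbering.items())
        ]
        return pd.DataFrame(rows, columns=["old_gene", "old_allele", "new_gene", "new_allele"])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _allele_sort_key(allele_id: str):
    head = allele_id.split("_")[0]
    return (0, int(head)) if head.isdigit() else (1, head)


def collapse_duplicates(
    alleles: list[GermlineAllele],
) -> tuple[list[GermlineAllele], CollapseReport]:
    """Merge genes that share at least one identical allele sequence.

    The sharing relation is closed transitively (if A shares with B and B
    with C, all three merge).  Within a merged group identical sequences are
    kept once; distinct sequences are renumbered 01, 02, ... ordered by
    (original gene name, original allele number).  Sequences are never
    modified.  Singleton groups pass through unchanged.
    """
    genes = sorted({a.gene_name for a in alleles})
    uf = _UnionFind(genes)
    by_seq: dict[str, set[str]] = defaultdict(set)
    for a in alleles:
        by_seq[a.sequence].add(a.gene_name)
    for members in by_seq.values():
        members = sorted(members)
        for other in members[1:]:
            uf.union(members[0], other)

    groups: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        groups[uf.find(g)].append(g)

    merged_genes = {g for grp in groups.values() if len(grp) > 1 for g in grp}
    out = [a for a in alleles if a.gene_name not in merged_genes]
    report = CollapseReport()

    for grp in sorted(groups.values()):
        if len(grp) < 2:
            continue
        new_gene = merged_gene_name(grp)
        members = sorted(
            (a for a in alleles if a.gene_name in grp),
            key=lambda a: (a.gene_name, _allele_sort_key(a.allele_id)),
        )
        merge = Merge(original_genes=sorted(grp), new_gene=new_gene)
        seq_to_new: dict[str, str] = {}
        counter = 0
        for a in members:
            if a.sequence not in seq_to_new:
                counter += 1
                new_id = f"{counter:02d}"
                seq_to_new[a.sequence] = new_id
                out.append(
                    GermlineAllele(
                        gene_name=new_gene,
                        allele_id=new_id,
                        sequence=a.sequence,
                        extended_5p_len=a.extended_5p_len,
                        extended_3p_len=a.extended_3p_len,
                        collapsed_from=sorted(grp),
                        functional=a.functional,
                    )
                )
            merge.renumbering[(a.gene_name, a.allele_id)] = seq_to_new[a.sequence]
        report.merges.append(merge)
    return out, report


def extend_short_alleles(alleles: list[GermlineAllele]) -> list[GermlineAllele]:
    """Bring every allele of a gene to the gene's maximal length.

    Truncations must be terminal: each short allele is placed against the
    gene's longest allele at the ungapped offset minimising mismatches
    (ties -> smaller offset), and missing terminal bases are filled with the
    position-wise majority base over the other alleles covering the position
    (ties -> the base of the lowest-numbered covering allele).  The filled
    spans are recorded in extended_5p_len / extended_3p_len.
    """
    by_gene: dict[str, list[GermlineAllele]] = defaultdict(list)
    for a in alleles:
        by_gene[a.gene_name].append(a)

    out: list[GermlineAllele] = []
    for gene in sorted(by_gene):
        members = sorted(by_gene[gene], key=lambda a: _allele_sort_key(a.allele_id))
        lmax = max(len(a.sequence) for a in members)
        anchor = next(a for a in members if len(a.sequence) == lmax)

        offsets: dict[str, int] = {}
        for a in members:
            if len(a.sequence) == lmax:
                offsets[a.allele_id] = 0
                continue
            best, best_d = 0, None
            for o in range(lmax - len(a.sequence) + 1):
                d = sum(
                    1
                    for x, y in zip(a.sequence, anchor.sequence[o:])
                    if x != y and x != "N" and y != "N"
                )
                if best_d is None or d < best_d:
                    best, best_d = o, d
            offsets[a.allele_id] = best

        for a in members:
            if len(a.sequence) == lmax:
                out.append(a)
                continue
            o = offsets[a.allele_id]
            filled = list("?" * o) + list(a.sequence) + list("?" * (lmax - o - len(a.sequence)))
            for pos in list(range(o)) + list(range(o + len(a.sequence), lmax)):
                votes: dict[str, int] = defaultdict(int)
                first_base = None
                for other in members:
                    if other.allele_id == a.allele_id:
                        continue
                    oo = offsets[other.allele_id]
                    if oo <= pos < oo + len(other.sequence):
                        b = other.sequence[pos - oo]
                        if b == "N":
                            continue
                        votes[b] += 1
                        if first_base is None:
                            first_base = b
                if not votes:
                    raise RuntimeError(
                        f"{a.name}: position {pos + 1} covered by no other allele"
                    )
                top = max(votes.values())
                winners = [b for b in votes if votes[b] == top]
                filled[pos] = first_base if len(winners) > 1 else winners[0]
            out.append(
                GermlineAllele(
                    gene_name=a.gene_name,
                    allele_id=a.allele_id,
                    sequence="".join(filled),
                    extended_5p_len=o,
                    extended_3p_len=lmax - o - len(a.sequence),
                    collapsed_from=list(a.collapsed_from),
                    functional=a.functional,
                )
            )
    return out


def prepare_reference(
    alleles: list[GermlineAllele],
) -> tuple[list[GermlineAllele], CollapseReport]:
    """Collapse duplicated genes, then length-harmonise each gene's alleles."""
    collapsed, report = collapse_duplicates(alleles)
    return extend_short_alleles(collapsed), report
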