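"""Prepare a germline reference: collapse duplicated genes, extend short alleles.

The kappa locus carries duplicated genes with identical sequences (an
annotator cannot tell IGKV1-12 from IGKV1D-12), and some reference alleles
are terminally truncated, which makes annotation length-driven.  Both are
fixed before any analysis.
"""

from iglight import GermlineAllele, prepare_reference

SEQ = "ATGACCCAGTCTCCATCCTCCCTGTCTGCATCTGTAGGAGACAGAGTCACC"

raw = [
    GermlineAllele("IGKV1-12", "01", SEQ),
    GermlineAllele("IGKV1D-12", "01", SEQ),              # identical duplicate
    GermlineAllele("IGKV1D-12", "02", SEQ[:30] + "T" + SEQ[31:]),
    GermlineAllele("IGKV3-7", "01", SEQ[::-1]),
    GermlineAllele("IGKV3-7", "02", SEQ[::-1][8:]),      # 5'-truncated allele
]

prepared, report = prepare_reference(raw)

print("prepared reference:")
for a in prepared:
    flags = []
    if a.collapsed_from:
        flags.append(f"collapsed from {'+'.join(a.collapsed_from)}")
    if a.extended_5p_len or a.extended_3p_len:
        flags.append(f"extended 5'={a.extended_5p_len} 3'={a.extended_3p_len}")
    print(f"  {a.name:<16} len={len(a.sequence)}  {'; '.join(flags)}")

print("\nrenumbering map (old -> new):")
for old, new in sorted(report.allele_map().items()):
    print(f"  {old} -> {new}")

# The duplicated pair now appears once under the 'E' marker, and the
# truncated IGKV3-7*02 has been consensus-extended to full length; its
# synthetic terminal bases are excluded from all mismatch counting.
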