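# Methods

This note documents the models, parameters and design choices behind
`iglight`, in the spirit of the methods documentation of mature inference
packages: enough detail to reproduce or challenge every decision.

## Scope and data model

The package analyses naive B-cell-receptor repertoires of the human
immunoglobulin light-chain loci.  A repertoire is a list of rearrangement
records (AIRR TSV columns: `sequence_id`, `sequence`, `v_call`, `j_call`,
plus `individual_id`, `v_mutation_count`, `v_region_start`); the germline
reference is a FASTA of `gene*allele` entries.  Internally all coordinates
are 0-based half-open; user-facing variant labels (`T31C`) are 1-based on
the ungapped V-REGION, and N bases never count as mismatches nor vote in
any consensus.  Ambiguous V calls are kept as lists and every per-gene
tally counts such a sequence fractionally (1/k over the k tied genes), so
usage fractions conserve mass without double counting.

## Reference preparation

*Collapsing.*  Genes sharing at least one identical allele sequence are
merged under a name carrying an `E` after the family number
(IGKV1-12 + IGKV1D-12 → IGKV1E-12); distinct member sequences are
renumbered consecutively from 01, ordered by (original gene, original
allele number).  The sharing relation is closed **transitively**: real loci
can chain A–B–C, and transitive closure reduces to the pairwise case when
chains are absent.  Collapsing never alters a sequence, and it is
idempotent (property-tested).

*Extension.*  Every allele of a gene is brought to the gene's maximal
length.  A truncated allele is placed against the longest allele at the
ungapped offset minimising mismatches (ties → smaller offset), and each
missing terminal base is filled with the position-wise majority over the
other alleles covering it; on a tie the base of the lowest-numbered
covering allele wins — a deterministic tie-break chosen because the
lowest-numbered allele is conventionally the best-characterised one.
Filled spans are recorded and excluded from mismatch counting and from
candidate reporting: they are synthetic bases whose only purpose is to
stop length-driven misannotation.

## Annotation

A substitution-only Hamming scan: each read is scanned over all offsets
for each reference V allele; every allele achieving the global minimum
distance is kept (ties preserved), the minimum becomes
`v_mutation_count`, and the smallest best offset becomes
`v_region_start`.  The J segment is located the same way in the remaining
3′ tail.  For speed, candidate offsets are proposed by exact 20-mer
terminal anchors with an exhaustive fallback whenever anchors fail or the
anchored distance exceeds 6; an oracle test checks exact agreement with
the brute-force scan.  Indels are deliberately out of scope: the inference
targets are single-nucleotide variants.  This annotator is a behavioural
stand-in adequate for the synthetic data; its equivalence to a
production aligner on real reads is untested by design.

## Novel-allele inference

Profiles pile up base counts per (individual, allele) over reads that pass
the naive-repertoire filters: at least 2000 sequences per individual and
fewer than 3 V-REGION mismatches per read (i.e. ≤ 2).  The mismatch
frequency of (position, alt) is alt-count / depth; zero depth is reported
as missing, never as 0.

Candidates are emitted wherever some individual reaches the candidate
floor (cutoff/2 = 0.125 by default — deliberately below the acceptance
cutoff so borderline artefacts are generated, classified and rejected
*with a reason* rather than silently missed).  A frequency only counts as
defined when at least `min_freq_depth` (default 10) sequences cover the
position; frequencies from one or two stray mis-assigned reads carry no
genotype information and would otherwise create support-1 "homozygous"
candidates.  Per gene, at most 2 candidates are kept, ranked by cohort
support (ties → lower position) — a simple surrogate for
confidence-score-based filtering in established genotyping tools, whose
internal statistics are not reproduced here.

*Pattern classification* is a deterministic surrogate for visual
judgement.  With S the frequencies above the noise floor (0.05):
multimodal requires a carrier ≥ cutoff separated from the sub-cutoff
values (including 0) by a gap ≥ 0.15; stack-like requires all of S below
the cutoff within a span < 0.15; fewer than 3 defined frequencies, or
anything else, is indeterminate.  Both constants sit in `CohortConfig`
for sensitivity analysis.  Filtering accepts candidates that pass the
cutoff and are not stack-like; indeterminate-but-passing candidates are
accepted (the corresponding manual step would be case-by-case validation).
The A→C and repeat-motif flags are annotations only — validated true
polymorphisms exist in both flag classes.  The repeat flag fires when the
alternate base equals **both** immediate neighbours (creating a
homopolymer run); one-sided runs do not fire.

Genotypes include every allele (known or accepted novel, the latter carved
out of its base allele's profile by the individual's mismatch frequency)
whose expression share within the gene reaches the cutoff, at most four
per gene.

## Usage, deletions, haplotypes

Relative usage is per-individual, per-segment, fractionally split over
ambiguous genes.  The double-deletion binomial test uses
X = ⌊fractional count⌋ (flooring keeps the test exact), N = the
individual's segment total, and P = the lowest usage among above-floor,
non-deleted individuals; genes with cohort mean usage below the segment
floor (V 0.001, J 0.005) are untestable and reported `unknown`.  Because
"non-deleted" is circular on a first pass, the test runs twice: round-one
BH-significant deletions are excluded from the candidate set defining P in
round two (this converges in one round on all tested simulations).
P-values are BH-adjusted across all tests at significance 0.01.

Haplotyping anchors on a heterozygous J gene whose allele ratio is at
least 30:70 in the individual's reads.  The Bayes factor compares a
single-chromosome model (minority pairings are annotation leakage at rate
ε) with uniform prior over chromosomes against a balanced binomial.
ε = 0.01 by default; it is not a biologically measured quantity but an
annotation-noise allowance, and calls are insensitive over ε ∈ [0.001,
0.05] at the simulated depths.  An allele is assigned to one chromosome
when BF > 1000, to both when 1/BF > 1000, otherwise left unknown; a
chromosome holding none of a gene's observed alleles, all phased away
above threshold, is called single-chromosome deleted with the smallest
contributing BF.

## Upstream splice variants

Per (individual, unambiguously called allele): upstream portions are
3′-anchored at the V-REGION start; length classes below 5% are removed
and survivors 5′-trimmed to the shortest surviving class ("keep classes
≥ 0.05" is our reading of the ambiguous filtering rule; the knob is
configurable).  Single-linkage clustering links sequences at ≥ 0.999
identity over the 3′-anchored overlap (identity over unequal lengths is
computed on that overlap because all sequences share the V-proximal end);
clusters below 1% frequency **or** 5 sequences are discarded — the
stricter OR reading, since relaxed thresholds are exactly where noise
enters.  Per-cluster consensus keeps a base at ≥ 0.6 majority, else N.
Cohort collapse is by exact identity.

Classification matches a variant against the gene model 3′-suffix-wise
(N wildcards allowed): canonical = spliced 5′exon + L-PART2; intron
retention is matched only as an intron *prefix* adjacent to the donor
site (acceptor-side or internal retention is out of scope), taking the
smallest matching prefix length; retained variants are translated from
the leader ATG across the retention into the V-REGION and the first stop
codon's index recorded.  Unmatched variants are reported unclassified
with their first mismatch position.  `cohort_fraction` is the per-allele
sequence fraction (not an average over individuals).

## The synthetic cohort

The generator defines the study conditions the pipeline is tested under:
20 individuals × 5000 sequences, 10 V genes (V-REGION 300 nt; one
duplicated sibling pair sharing an identical allele; two terminally
truncated reference-only alleles) and 5 J genes (38 nt), substitution
error rate 10⁻³ with the A→C channel ×6, three repeat-motif hotspots
(reference `CAC` whose centre errs to C at rate 0.15 — a positionally
fixed, cohort-wide sub-cutoff stack), five novel SNPs carried by 40% of
individuals (25% of carriers homozygous, heterozygotes expressing the
novel allele at share 0.5), two double- and two single-chromosome
deletions, a J anchor heterozygous in 25% of the cohort (always including
single-deletion individuals, which must be phaseable), and intron
retention (7 nt prefix, 15% of transcripts) in two genes.  Junctions are
a fixed 3-nt linker: light-chain inference nowhere uses junction
diversity.  Somatic hypermutation appears only as the residual load the
≤ 2-mismatch filter removes — the cohort is naive.  Each transcript
draws its V gene from cohort-shared Dirichlet usage weights, a chromosome
from the carriers of that gene (equal odds or a configured heterozygote
expression bias), and the J allele from the *same* chromosome, which is
what makes anchored phasing informative.  With `base_error_rate = 0` no
errors at all are applied (hotspots included): the noise-free limit is
byte-identical germline, and inference then recovers the truth tables
exactly (tested).

What the generator does **not** emulate: V(D)J junction diversity and
N-nucleotides, clonal expansion, primer/amplification bias, indel
sequencing errors, real locus gene content and allele frequencies.
Passing tests therefore demonstrate correctness of the inference logic
under the modelled error structure, not performance on real MiSeq data.

## Numerical and scale choices

Binomial tails come from scipy and are verified against a 50-digit
decimal summation oracle to 10⁻¹²; BH adjustment comes from statsmodels
and is verified against a textbook step-up implementation.  All
randomness flows from explicit integer seeds through numpy Generators;
cluster and candidate orderings are fixed lexicographically so every
pipeline stage is deterministic.  The test suite runs the full reference
scenario once (about half a minute) and otherwise uses smaller seeded
cohorts; the acceptance script uses 100–400 sequences per worked example,
where the computed frequencies are exact by construction.

## Known limitations

Substitution-only annotation; single-anchor haplotyping (no multi-anchor
pooling or lineage-aware priors); repertoire-level deletion calls make no
claim about the genomic locus; upstream inference reports per-allele
variants without modelling allele-specific retention rates; promoter
variation is outside repertoire scope.
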