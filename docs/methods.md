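# Methods

This note documents the models and procedures implemented in
`crisprembryo`, the defaults chosen where the analysis required a
decision, and what the synthetic-data generator does and does not
emulate.

## Pipeline overview

The analysis consumes pooled amplicon sequencing of embryos edited at a
single Cas9 target per locus. Stages, in run order:

1. **CCS quality filter** — keep reads with passes ≥ `min_passes` (3),
   predicted accuracy ≥ `min_accuracy` (0.99) and length ≤ `max_length`
   (700 bp). All boundaries are inclusive; the rejection log records the
   first failing criterion in the order passes → accuracy → length.
2. **Demultiplexing** — dual flanking barcodes, forward-strand layout
   `bc_fwd + insert + revcomp(bc_rev)`; both orientations are tried and
   assigned reads are reoriented to the reference strand and trimmed. A
   read is assigned only when exactly one sample matches with each
   barcode within `max_mismatch` (default 1) substitutions; ambiguity
   discards the read.
3. **Allele calling** — affine-gap semi-global alignment of each read to
   its reference amplicon, indel-signature extraction in a cut-site
   window, tally with a noise floor.
4. **Mosaicism classification** and group summaries.
5. **Off-target enumeration / screening** and statistics, which are
   side branches sharing the same primitives.

## Alignment

Semi-global Gotoh dynamic programming: the read is aligned end to end,
reference overhangs are free. Scores: match +2, mismatch −4, gap open −6
(charged on the first gap base), gap extend −1. The implementation is a
numba-compiled three-state DP with full traceback; ties prefer diagonal
moves, then deletions over insertions, and all indels are subsequently
shifted to their leftmost equivalent placement (VCF-style
normalization) so identical alleles produce identical signatures
regardless of where the optimizer opened the gap. An optional diagonal
band accelerates production runs (the pipeline uses
`|len(read) − len(ref)| + 32`, generous for NHEJ-scale indels); tests of
optimality run the full matrix and check the score against both a
brute-force DP that enumerates every gap length explicitly and
Biopython's `PairwiseAligner` under the same scoring.

## Allele signatures and tally

The predicted blunt cut lies 3 bp 5′ of the NGG PAM (between protospacer
positions 17 and 18). An allele signature is the ordered list of indels
whose reference footprint intersects `[cut − w, cut + w)` with
`w = 10` bp by default; deletions intersect by interval, insertions are
point events. Indels outside the window are treated as sequencing error
or unrelated polymorphism, and substitutions never define alleles — the
allele classes of interest are NHEJ indel haplotypes. Reads with several
window indels form one compound allele rather than being split.

Tally noise floor: an allele is kept iff it has ≥ 2 reads **and** ≥ 1%
of the embryo's reads; reads of dropped alleles are removed before
fractions are renormalized. At the default sequencing depth of 500 the
floor is therefore 5 identical-signature reads, which comfortably
absorbs the residual indel-error rate (see the generator section).
Embryos with fewer than 20 surviving reads are QC failures — the
underlying studies discard low-read samples without publishing a cutoff,
so 20 is this package's own minimum for a stable fraction estimate.

## Mosaicism classification

Decision procedure over a QC-passing allele table, in order:

1. only WT → `non_edited`;
2. a single non-WT allele → `edited_non_mosaic`;
3. ≥ 2 alleles at an X-linked locus in a male → `mosaic`
   (hemizygosity: a single X cannot be biallelic);
4. exactly 2 alleles, both fractions within `het_tolerance` of 0.5 →
   `heterozygous`;
5. exactly 2 alleles, disproportionate → `mosaic`;
6. ≥ 3 alleles → `mosaic`.

`het_tolerance` defaults to 0.15 (heterozygous iff both fractions fall
in [0.35, 0.65]): the published decision rule is anchored only by the
example that a 75/25 wild-type/mutant split is mosaic rather than
heterozygous, so the band is centred between 50/50 and 75/25. An
alternative mode replaces the fixed band with a two-sided exact binomial
test of the major-allele count against 0.5 at α = 0.05, which adapts the
boundary to read depth.

Group summaries report: mutation rate = edited / analyzed (an embryo is
edited iff it carries ≥ 1 non-WT allele); % mosaic, % heterozygous and
% non-mosaic normalized on **edited** embryos; and mean allele number
and mean % WT reads ± SEM (sample SD / √n). The means are computed over
edited embryos by default, matching the convention of removing WT-only
samples from downstream statistics; `mean_mode="all"` includes them.

## Off-target model

A guide is a 20-nt protospacer + NGG PAM. Protospacer positions are
indexed 0-based from the PAM-distal end. The **seed region** is the
PAM-proximal block 8–11 bp upstream of the PAM — indices {9, 10, 11, 12}
— configurable, since the literature also uses "seed" for a 8–11-nt
*length*; the positional reading is implemented as the default.

Enumeration finds every site on both strands with an NGG PAM and ≤
`max_mm` protospacer mismatches (default 4, one beyond the acceptance
threshold so near-threshold sites are visible). Bulges are not searched
and genomic N counts as a mismatch; PAM matching is N-G-G exactly (no
NAG). The implementation is a vectorized PAM-anchored window comparison;
tests check exact set equality against a per-position Hamming-scan
oracle and against a whole-genome mismatch-profile scan, plus strand
symmetry under reverse complementation. The design filter accepts a
guide iff every off-target site has ≥ 3 mismatches and ≥ 1 seed
mismatch. The predicted cut coordinate is 3 bp 5′ of the PAM after
strand normalization; all coordinates are 0-based half-open.

The off-target amplicon scan reuses the aligner, windows indels at
± 50 bp (configurable) around the predicted cut, reports per-class
supporting reads and fractions of all reads, and flags indels whose
reference interval overlaps a supplied known-variant list as annotated
polymorphisms rather than putative edits. Genome-scale runs against real
livestock assemblies are out of scope; the algorithm is exercised on
synthetic genomes with planted sites.

## Statistics

- χ²: Pearson statistic without continuity correction,
  df = (R−1)(K−1); zero-margin tables return a NaN sentinel; expected
  counts below 1 raise, below 5 warn.
- Logistic regression: maximum-likelihood fit via statsmodels with
  categorical fixed effects (Cas9 form, gRNA). On perfect separation the
  fit is flagged and re-estimated with a light penalty
  (`fit_regularized`, α = 1e-4); penalized estimates carry NaN Wald
  p-values because the usual standard errors do not apply.
- One-way ANOVA: classical F test (scipy); the all-constant degenerate
  case returns NaN sentinels.
- Significance letters for summary tables come from pairwise Welch
  t-tests with Holm correction at α = 0.05 (the multiple-comparison
  procedure is this package's choice; none is published).

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated: 3 loci (one X-linked) × 2 reagent arms (Cas9 mRNA vs
protein) × 10 embryos, depth 500 reads per embryo, 400-bp amplicons with
the guide at offset 180. Each embryo's planted composition is drawn from
per-class templates — WT-only; a single homozygous indel allele; a
50/50 heterozygote; mosaic mixes (75/25 biallelic, or 3–4 alleles with
fractions 0.20–0.40) — using locus-specific indel menus (e.g. 4/7/11-bp
deletions and a 1-bp insertion at the polled locus) that mirror the
dominant NHEJ classes reported for each target. X-linked male embryos
are never planted as heterozygous. Sex is assigned in truth metadata,
not inferred from reads.

Error model (residual, post-consensus): substitutions 0.3%/bp, 1-bp
indel errors 0.2%/bp — plausible leftovers after circular-consensus
calling, and fully configurable. Per-read predicted accuracy is
Beta(597, 3) (mean 0.995) and passes are 1 + Poisson(7), so a realistic
few percent of reads fail the 3-pass/99% filter. Barcodes are dual 8-nt
tags with pairwise Hamming distance ≥ 3 (the real experiment's barcode
sequences are not published). Study amplicons are redrawn until the
cut-site window contains no homopolymer run ≥ 4 bp, emulating
guide-design practice of avoiding low-complexity contexts — indel
sequencing errors pile up at one left-aligned position inside a
homopolymer and would otherwise mimic a low-frequency allele.

Not emulated: PCR chimeras, whole-genome-amplification bias, per-embryo
depth variation, lineage dynamics, large structural variants, and real
genome backgrounds. Passing recovery tests therefore demonstrates
correctness of the analysis under a faithful error model, not robustness
to every artefact of real libraries.

## Problem sizes used in tests

The default suite runs in about half a minute: the end-to-end recovery
test simulates one full study (60 embryos × depth 500, ≈ 30k reads), the
noise-robustness property uses 30 seeded replicates at depth 500, the
alignment oracle checks 200 random ≤ 60-bp pairs against the brute-force
DP, and the off-target oracle covers 50 random guides against a 1-Mb
genome (set equality) plus planted-site filter rejections. The
acceptance script repeats the study simulation and the oracle
comparisons (10 guides × 200 kb; 100 alignment pairs) under the supplied
seed.

## Known limitations

- The aligner's banded mode is only optimal when the band covers the
  true indel diagonal; the pipeline's adaptive band is ample for
  NHEJ-scale events but a full-matrix call is the fallback for anything
  unusual.
- Alleles are indel classes: substitution-only edits and alleles that do
  not amplify or align (e.g. very large insertions) are invisible, so a
  `non_edited` call is conditional on the amplicon capturing the edit.
- Classification near the heterozygous/mosaic boundary is inherently
  depth-limited; at depth 500 the 0.15 tolerance separates 50/50 from
  75/25 with large margin, but shallow tables push calls toward the
  binomial-test mode.
- Off-target search has no bulge model and no cleavage-likelihood
  scoring; it enumerates and constrains by mismatch structure only.
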