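# crisprembryo

Amplicon deep-sequencing analysis of CRISPR/Cas9-edited embryos.

When Cas9 is injected into single-cell zygotes, repair of the double-strand
break by non-homologous end joining (NHEJ) produces insertion/deletion
(indel) alleles at the predicted cut site. Because cleavage can continue
after the first cell division, a single embryo often carries more than two
genetically distinct allele populations — **mosaicism** — which complicates
the production of non-mosaic founder animals. This package implements the
sequencing-side analysis of such experiments: from pooled, barcoded
circular-consensus (CCS) amplicon reads to per-embryo allele tables,
mosaicism calls, group-level editing statistics, and guide-RNA off-target
candidate enumeration and screening. A synthetic-data generator produces
every input the pipeline consumes, so the whole analysis is testable
without any sequencing data.

## What it computes

**Read processing.** CCS reads are kept iff passes ≥ 3, predicted accuracy
≥ 0.99 and length ≤ 700 bp (all inclusive), then demultiplexed to embryos
by dual 8-nt flanking barcodes (≤ 1 substitution per barcode; ambiguous
reads discarded). Paired-end reads for off-target screens are
overlap-merged, taking the higher-quality base at disagreements.

**Allele calling.** Each read is aligned to its reference amplicon with an
optimal affine-gap semi-global alignment (free reference end gaps; match
+2, mismatch −4, gap open −6, gap extend −1; indels left-aligned). Indels
whose reference footprint intersects the window `[cut − 10, cut + 10)`
around the predicted blunt cut site (3 bp 5′ of the NGG PAM) form the
read's allele signature, e.g. `D4@197` or `WT`; substitutions never define
alleles. Signatures are tallied per embryo, dropping alleles with < 2
reads or < 1% of reads.

**Mosaicism classification.** With allele fractions *f₁ ≥ f₂ ≥ …*:
only WT → `non_edited`; one non-WT allele → `edited_non_mosaic`; two
alleles with both fractions in 0.5 ± 0.15 → `heterozygous` (an exact
binomial test of the major-allele count against 0.5 is available as an
alternative); a disproportionate two-allele mix (e.g. 75% WT / 25%
mutant) or ≥ 3 alleles → `mosaic`. An X-linked locus in a male is
hemizygous, so any second allele is already mosaic. Group summaries
report the mutation rate (edited/analyzed), % mosaic normalized on edited
embryos, and mean allele number and % WT reads ± SEM over edited embryos.

**Off-target analysis.** Candidate guides are every 20-mer + NGG on either
strand. Off-target sites are enumerated genome-wide (≤ `max_mm`
protospacer mismatches, no bulges) with per-position mismatch maps and
seed-region counts — the seed being the protospacer bases 8–11 bp upstream
of the PAM. A guide passes the design filter iff every off-target site has
≥ 3 mismatches including ≥ 1 in the seed. Off-target amplicon reads are
scanned for indels near the predicted cut, with known annotated variants
flagged as polymorphisms.

**Statistics.** Pearson χ² (no continuity correction) for guide-testing
count tables; maximum-likelihood logistic regression with Cas9 form and
gRNA as fixed effects for blastocyst/mutation outcomes; classical one-way
ANOVA for allele number and % WT reads (WT-only embryos excluded).

## Worked example

```python
from crisprembryo import simulate_study, run_study_pipeline

scen = simulate_study(seed=1, n_per_group=10, depth=500)   # 60 embryos, 3 loci x 2 arms
res = run_study_pipeline(scen.reads, scen.sheet, scen.amplicons)

t = res.tables["POLLED_protein_015"]
for row in t.rows:
    print(row.signature.label, row.read_count, round(row.fraction, 3))
```

prints the embryo's allele table,

```
WT 173 0.386
D4@197 164 0.366
I1@196 111 0.248
```

i.e. 448 surviving reads split across the wild-type allele, a 4-bp
deletion at reference position 197 (the cut site) and a 1-bp insertion —
three alleles, so the embryo is called `mosaic` with 38.6% WT reads.
Group summaries (`res.summaries`) then give, per (locus, Cas9 form), e.g.

```
POLLED/protein   n=10 mutation_rate= 80.0% pct_mosaic= 75.0% mean_alleles=2.38
```

and pooling published per-locus counts reproduces arm-level rates:

```python
from crisprembryo import aggregate_mutation_rate
aggregate_mutation_rate([(36, 42), (35, 39), (73, 90)])   # 0.842 -> 84.2%
```

The same stages are available from the shell:

```
crisprembryo simulate --seed 1 --outdir sim
crisprembryo filter sim/reads.fastq --out kept.fastq
crisprembryo classify kept.fastq --sheet sim/barcode_sheet.tsv \
    --references sim/references.fasta --cut-sites sim/cut_sites.tsv --outdir out
crisprembryo offtargets --protospacer TTCCTGATCCTAGGGTTCAA --genome genome.fasta --out ot.tsv
```

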