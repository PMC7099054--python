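# bcrpipe

B-cell receptor heavy-chain (IGHV) repertoire analysis for IgG/IgM amplicon
sequencing, built around the observation that rheumatoid-arthritis donors
carry an expanded population of *hypomutated* IgG B cells — class-switched
receptors with fewer than 5 somatic mutations relative to their predicted
germline V segment — alongside elevated usage of the self-reactive IGHV4-34
gene with intact AVY (FR1, IMGT aa 24–26) and NHS (CDR2, aa 57–59) motifs.

The package implements the full analysis path from raw paired-end reads to
repertoire statistics, plus a calibrated synthetic-repertoire simulator so
every stage is testable without sequencing data:

- **simulate** — donor repertoires as overlapping 250 bp read pairs with
  per-read ground truth. Mutation counts per read follow a two-component
  mixture (truncated-geometric hypomutated + negative-binomial hypermutated);
  the named presets (`HC`, `ERA`, `ESRA`, `SJOGREN`) are calibrated to the
  published group means (e.g. ERA: 12.6% hypomutated, 12.8 mean mutations,
  2.41% IGHV4-34; HC: 2.8% and 0.65%). Paired blood/synovium donors with
  planted shared and egression clones are supported.
- **preprocess** — Q30 quality trimming and FLASH-style pair merging; pairs
  with best overlap below 15 bp or mismatch ratio ≥ 0.25 are excluded.
- **annotate** — germline V-allele assignment against a bundled synthetic
  IGHV mini-reference (21 alleles, families IGHV1–IGHV7), V-segment mutation
  counting (nucleotide differences read vs. predicted germline V), CDR3
  junction extraction (conserved Cys through the J-Trp), isotype assignment,
  duplicate collapsing and the 25,000-read donor-inclusion filter. Records
  are AIRR-style pandas DataFrames that round-trip through TSV.
- **stats** — per-donor statistics: mutation-count distributions (read- and
  clone-weighted), % hypomutated, adjusted Fisher–Pearson skewness
  G1 = √(n(n−1))/(n−2) · m₃/m₂^{3/2}, clonality Gini index
  G = 2·Σᵢ i·yᵢ /(n·Σᵢ yᵢ) − (n+1)/n over clonotype read counts,
  V-gene usage, and AVY/NHS motif-intactness percentages.
- **clonal** — clonal clusters (single-linkage, Hamming ≤ 1 on the CDR3
  within V gene/J gene/junction-length groups), the repertoire overlap score
  (reads in shared clusters ÷ summed reads, range 0–1), and
  nucleotide-identity sequence sharing between paired compartments.
- **lineage** — maximum-parsimony lineage trees of multi-compartmental
  clones rooted at the germline V (exhaustive search up to 7 unique
  sequences), synovium→blood egression calling, suspect-lineage discard and
  GML export.
- **cohort** — two-tailed Mann-Whitney / Wilcoxon / Kruskal-Wallis + Dunn
  comparisons with Holm-Šídák adjustment, and Pearson R² for paired donor
  summaries.

## Worked example

`python examples/simulate_and_summarize.py` simulates one early-RA donor
(5,000 IgG reads), runs merging and annotation, and prints:

```
donor ERA-s1: 5000 IgG reads, 4014 unique sequences
  mean V mutations per read : 12.71
  skewness (adj. Fisher-Pearson): 0.34
  % hypomutated (<5 mutations)  : 13.10
  Gini index over clonotypes    : 0.398
  % IGHV4-34 usage              : 1.20
  largest clonotype             : 3.24% of reads
```

13.1% of this donor's IgG reads carry fewer than 5 V mutations — the
hypomutated excess characteristic of the ERA preset (target 12.6%) and far
above a healthy control (~2.8%); the Gini index of 0.40 and a largest
clonotype at 3.2% of reads show a repertoire with moderate clonal expansion
on top of many singletons. The other scripts in `examples/` walk through
clonal overlap, IGHV4-34 motif analysis, paired blood/synovium egression
analysis and cohort-level testing.

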