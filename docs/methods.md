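# Methods

This note documents the models, algorithms and numerical choices behind
bcrpipe: what each stage computes, what the simulator does and does not
emulate, and where the design was genuinely open.

## The measurement model

The unit of analysis is one IgG (or IgM) heavy-chain amplicon read spanning a
framework-1 primer site through the rearranged V segment, the CDR3 junction,
the start of the J segment and a constant-region stub that identifies the
isotype. The central per-read variable is the **V-segment mutation count**:
the number of nucleotide differences between the read and its predicted
germline V allele, counted over the aligned V region only — junction and J
content never contribute. A read is **hypomutated** when this count is below
5 (strict inequality; counts 0–4), stored as a configurable constant.

Derived per-donor statistics:

- **% hypomutated** — read-weighted (each record weighted by its
  `duplicate_count`) percentage of reads below the threshold.
- **Skewness** — adjusted Fisher–Pearson standardized moment coefficient,
  G1 = √(n(n−1))/(n−2) · m₃/m₂^{3/2} with m₂, m₃ the biased sample moments.
  Undefined (None) for n < 3 or zero variance; variance is treated as zero
  when m₂ ≤ 1e−13·(mean²+1) to absorb floating-point residue of constant
  samples.
- **Gini index** — over clonotype read counts yᵢ (clonotype = identical CDR3
  amino-acid sequence + same predicted germline V allele), with counts sorted
  ascending and 1-based ranks i: G = 2·Σ i·yᵢ/(n·Σ yᵢ) − (n+1)/n. Tie order
  is irrelevant (equal values contribute identically). A single-clonotype
  table evaluates to 0 and is a flagged degenerate case. The property suite
  checks agreement with the independent mean-absolute-difference formulation
  to 1e−9.
- **Clone-weighted variants** — each clonotype contributes once, at the
  read-weighted mean mutation count of its members.
- **IGHV4-34 usage** — read-weighted percentage of isotype reads whose V call
  maps to gene IGHV4-34.
- **Motif intactness** — AVY (IMGT aa 24–26, FR1) and NHS (aa 57–59, CDR2)
  are judged at the amino-acid level: the observed codons are translated and
  compared to the germline residues, so synonymous substitutions never
  disrupt a motif. The biology of both motifs (a hydrophobic patch; an
  N-glycosylation sequon) is residue-level, which motivates this choice; a
  stricter N-X-S/T sequon mode exists for NHS but is off by default. Ambiguous
  bases inside the motif give an indeterminate (None) call, excluded from
  both numerator and denominator of intact percentages.

## Germline reference

The bundled reference is **synthetic**: 21 alleles (one per gene) across
families IGHV1–IGHV7, generated deterministically by
`scripts/build_reference.py` on the IMGT positional scaffold — 104 IMGT
positions, conserved 1st-CYS at 23, Trp at 41, 2nd-CYS at 104, a few gapped
positions per allele in CDR1/CDR2 — with IGHV4-34\*01 carrying germline AVY
and NHS motifs at the canonical IMGT positions. Two J segments (with the
W-G-x-G anchor) and IgG/IgM constant-region stubs accompany the V alleles.
All intervals are stored 0-based half-open on the ungapped sequence; IMGT
positions exist only in the gapped alignment they are derived from.

Random alleles are pairwise >100 nt apart, so V-allele assignment is
unambiguous at any realistic mutation load; this is what makes exact
mutation-count recovery testable. The reference is explicitly versioned
(`bcrpipe-synthetic-1`) and makes no claim to match any IMGT release.

## Synthetic repertoires

`simulate_donor` emulates the amplicon and the statistical structure the
analysis assumes:

- **Mutation-count mixture.** Per-read counts are drawn from
  w·TruncGeom(p=0.5 on {0..4}) + (1−w)·NegBin(mean μ, size r=8). The
  truncated geometric reproduces the hypomutated peak near zero; the negative
  binomial gives a realistically overdispersed hypermutated mode (SD ≈ 6 at
  μ ≈ 16). Preset calibration solves (w, μ) so that the mixture's total
  below-5 mass and overall mean hit the donor-group targets exactly,
  accounting for the NB tail that itself falls below 5.
- **Preset targets.** ERA: 12.6% hypomutated, mean 12.8; HC: 2.8%, mean 17.0;
  ESRA: 8.4%, mean 15.27; Sjögren's: 8.3%, mean 14.0. IGHV4-34 usage 2.41%
  (ERA), 0.65% (HC), 2.0% (ESRA), 1.5% (Sjögren's). The hypomutated
  fractions, the ERA mean and the ERA/HC usage rates are published group
  means; the remaining values are unpublished and chosen once as realistic
  fill-ins: healthy controls sit above the treated-RA mean (16.3), ESRA blood
  reuses the paired peripheral mean, and ESRA/Sjögren's usage sits between
  the ERA and HC rates.
- **Clonal structure.** Clonotype read counts follow a zipf law with exponent
  2.5 (≈75% singletons, occasional large clones), capped at 5% of reads; a
  dominant clonotype at 0.8% of reads is planted when none arises, matching
  the observation that most repertoires contain clonotypes above 0.5% of
  reads. Each clonotype has one V allele, one J and one in-frame junction
  (middle length Poisson(13) clipped to [3, 28] amino acids, giving a mean
  junction near 15 aa). Read duplication per unique variant is
  shifted-geometric with mean 1.8.
- **Mutation planting.** Exactly k unique substitution positions, uniform
  over the V segment excluding its final (conserved Cys) codon, so a clone's
  CDR3 amino-acid identity is stable across members while counting still
  covers the full aligned V. No indels, no sequencing errors; WRC/GYW hotspot
  weighting is deliberately absent (mutation *targeting* did not differ
  between groups and is not under inference).
- **Reads.** 250 bp mates from the two amplicon ends (total length 360–435
  nt, so planted overlaps are ≥ 65 bp), constant Q37 qualities except for
  deliberately planted low-quality tails and unmergeable mates, which are
  flagged in the ground truth.
- **Paired compartments.** Blood and synovium are simulated independently
  (peripheral mixture mean 15.27, synovial 19.65, synovial hypomutated
  fraction set to 3.0% — chosen; the synovium is the more-mutated
  compartment), then cross-compartment clones are planted explicitly:
  egression clones (synovial parent, blood child carrying the parent's
  mutations plus one) and non-egression shared clones (blood parent, synovial
  child) up to a read budget of `shared_clone_fraction` of synovial reads
  (default 0.05%, keeping planted sharing under the observed <0.1% ceiling).
  An index-misassignment injector re-emits blood variants under a synovium
  label with a truth flag, to exercise the suspect-lineage discard rule.

What the simulator does **not** emulate: sequencing errors and chimeras,
somatic indels, biased mutation targeting, light chains, real allele
polymorphism, amplification bias, or donors mixing IgG and IgM in one call.
Passing parameter-recovery tests therefore demonstrates that the pipeline
measures without bias the quantities the simulator controls — not that it is
robust to artifacts real data would add.

## Read preprocessing

Quality trimming removes 3′ sequence using the running-sum criterion (trim at
the position maximizing Σ(Q30 − qᵢ) over the suffix, when positive); a simple
hard cut at the first sub-threshold base is available by flag. Only 3′ ends
are trimmed. Merging reverse-complements mate 2 and scans every overlap
length from min(len₁, len₂) down to 15, scoring mismatches/overlap (the FLASH
definition); the lowest ratio wins, ties going to the longest overlap.
Disagreeing positions take the higher-quality base (mate 1 on quality ties).
Pairs are rejected — a counted outcome, not an error — when the best overlap
is < 15 bp or its ratio ≥ 0.25; both boundaries are tested exactly. A
vectorized batch path handles uniform-length pairs and is property-tested
against the scalar reference.

## Annotation

V assignment aligns each reference allele globally-in-germline /
locally-in-read (edlib infix mode, edit distance) and keeps the best
distance; ties break by allele-name order. Assignments below 70% identity, or
contigs under 100 nt, are unassignable and dropped with a logged reason.

Mutation counting distinguishes two regimes. Substitution-only reads are
counted as mismatches over the best germline-length contig window; the window
search is anchored at both ends of the edlib location (±3), because an
optimal edit-distance alignment of a heavily mutated read may spend balanced
indels near the V ends and would otherwise undercount. When the window needs
more than `distance + 15` differences the alignment genuinely contains
indels, and counting falls back to the alignment path: substitutions
individually, each indel run once. On simulator output (no indels) the
substitution path reproduces the planted count exactly for every read —
the oracle-equivalence suite checks 100,000+ reads.

The junction runs from the conserved V Cys (IMGT 104) through the first
downstream Trp of the W-G-x-G J anchor, translated in the V frame; junctions
shorter than 5 aa or with no anchor within 45 codons are dropped, and
stop-containing junctions are flagged nonproductive. The J gene is matched
over the post-junction sequence (≤ 2 mismatches), the isotype by the best
constant-region stub match (≤ 2 mismatches; ties undetermined). D-segment
assignment is omitted: V gene, J gene and junction length suffice for the
clustering definition used here.

Duplicate collapsing merges identical nucleotide sequences within a
donor+compartment, summing duplicate counts; `min_duplicates=2` (the paired
blood/synovium pathway) removes singleton sequences. The donor-inclusion
filter excludes repertoires with fewer than 25,000 processed reads
(boundary: 24,999 excluded, 25,000 included); simulated test cohorts run at
10,000 reads per donor with the filter disabled, a desk-scale choice.

## Clonal clustering, overlap and sharing

Records are first grouped by (V gene, J gene, junction length); within each
group, CDR3 amino-acid sequences are single-linkage clustered at Hamming
distance ≤ 1, so chains across intermediate junctions merge. The production
path finds Hamming-1 neighbors in near-linear time by bucketing each junction
under its length-many one-position-masked keys; it is property-tested for
exact equality against an all-pairs union-find oracle. Cluster indices are
deterministic (components ordered by lexicographically smallest member).

The overlap score between two jointly clustered samples is the summed read
count of both samples inside clusters containing at least one record from
each, divided by the two samples' total reads. "Reads" means duplicate-count
sums throughout. The both-samples numerator is the only reading that attains
1 for identical samples, consistent with the score's stated 0–1 range.
Sequence *sharing* between paired compartments uses the stricter identity —
CDR3 nucleotide sequence plus V and J genes — on duplicate-collapsed,
non-singleton records.

## Lineage trees and egression

Multi-compartmental clones (≥ 1 blood and ≥ 1 synovial member) are
reconstructed as maximum-parsimony trees rooted at the germline V. The
junction has no germline state: root junction/J positions are wildcards
resolved by parsimony. Clones with ≤ 7 unique sequences are solved exactly —
all (2n−3)!! leaf topologies scored by Fitch counting over the variable
columns — and larger clones use stepwise addition followed by rounds of
leaf re-insertion (a pruning-based refinement at least as strong as
nearest-neighbor interchange), which the tests require to match the
exhaustive optimum on random small clones. Ancestral states are assigned
top-down preferring the parent's state; zero-change edges are then
collapsed, so an inferred node identical to an observed sequence takes that
sequence's identity and observed sequences may sit at internal nodes.

Tissue is never imputed for inferred nodes. An **egression event** is a
transition from an observed synovial node to an observed blood node connected
directly or through inferred-only intermediates; blood→synovium transitions
are not events. On planted simulator lineages the caller achieves 100% recall
with no false positives across 50 seeded paired simulations. Whether an event
should also be allowed across intermediate *observed* blood nodes is an open
reading; the direct-transition definition implemented here is the
conservative one. Trees containing any sequence flagged for suspected index
misassignment are discarded whole; the flag is supplied externally (simulator
truth or a user column), never inferred. Trees export to GML (networkx) with
tissue, mutation-count, duplication and sequence attributes, losslessly
round-tripping.

## Cohort statistics

Two independent groups: Mann-Whitney U (exact null when both n ≤ 8 without
ties, tie-corrected normal approximation otherwise). Two paired groups:
Wilcoxon signed-rank. Three or more: Kruskal-Wallis with Dunn's tie-corrected
pairwise z tests. All p-values are two-tailed. The Holm-Šídák step-down —
adjustedᵢ = max over j ≤ i of 1 − (1 − p₍ⱼ₎)^(m−j+1), clipped to 1 — is
implemented in-repo and property-tested against statsmodels. Pearson R² is
provided for paired per-donor summaries and undefined at zero variance.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; identical seeds give
byte-identical simulator output. The test suite and the acceptance script use
desk-scale sizes chosen to exercise every claim while remaining quick on one
CPU: 20 donors × 10,000 reads per cohort preset, 8 paired donors × 5,000
reads per compartment, 100,000+ reads for exact mutation-count recovery,
1,000 random tables for the Gini oracle, 500 random groups for the clustering
oracle, and 50 seeded paired simulations for egression recall.

## Known limitations

- The synthetic reference is not IMGT; absolute allele sequences and family
  compositions carry no biological meaning beyond their structural contract.
- V assignment is edit-distance based; degenerate primers, novel alleles and
  heavy 5′ truncation are out of scope.
- Mutation counts include the FR1 primer-binding region of the V (the
  simulator plants no primer artifacts); real-data use may want to exclude
  it.
- Parsimony trees are unweighted (no transition/transversion or hotspot
  model), and egression calling ignores branch support.
- The cohort layer assumes per-donor summaries are exchangeable within
  groups; no covariate adjustment is provided.
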