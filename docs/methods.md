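# Methods

This note documents the models and procedures `bittermap` implements,
the defaults it ships, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Gene discovery

The discovery pipeline assumes the target family is intronless, so a
single genomic window contains the whole coding sequence.

**Translated search.** The built-in engine seeds candidate loci with
exact amino-acid 4-mers shared between a query protein and the
six-frame translation of each contig. Seeds are grouped on nearby
diagonals (band 16 residues); only groups of ≥ 3 near-colinear seeds —
which chance 4-mer matches essentially never produce — are re-aligned
with a local BLOSUM62 alignment (gap open 11, extend 1, via Biopython's
`PairwiseAligner`). Significance is a Karlin–Altschul-style e-value
`E = m·n·2^(−S′)` with bit score `S′ = (λS − ln K)/ln 2` using the
standard gapped BLOSUM62 parameters (λ = 0.267, K = 0.041), where `m`
is the query length and `n` the number of translated positions
searched. Alignments with raw score below 55 are not reported: at that
level a local alignment is indistinguishable from compositional noise.
Hits of one query whose subject intervals overlap keep only the best
scorer; this suppresses the reverse-frame "shadow" alignment that a
hydrophobic seven-helix protein produces on the opposite strand of a
real gene. Any search engine with the same interface (deterministic,
hit fields, significance estimate) can be injected instead; an optional
windowed-scan mode processes large contigs in overlapping chunks
(overlap = flank) with results invariant to chunking.

**Window extraction.** Each hit is extended by 1,500 bp on both sides,
clamped to the contig. When the alignment starts at query residue 1 the
true start codon is already inside the matched region, so the gene-5′
extension is suppressed to avoid upstream in-frame AUGs elongating the
called ORF (upstream of the hit on the + strand, downstream on the −
strand).

**ORF calling.** The largest ATG-initiated, stop-terminated ORF fully
inside the window, on either strand and any frame; ties break to the
smaller genomic start, then the + strand. The span includes the stop
codon, so `3·(len(protein)+1)` equals the ORF's nucleotide span.

**Filters.** A candidate is dropped if its originating hit's e-value
exceeds 1e-10, its protein is shorter than 200 aa or longer than 500 aa
(both boundaries kept), or its protein exactly equals an earlier kept
candidate's (first occurrence wins; the e-value attached to a candidate
is the original hit's, not recomputed after ORF extension). Candidates
from different queries that resolve to the same ORF locus are merged
before filtering, keeping the best e-value. Survivors must have a
reciprocal top hit against a reference genome that overlaps (≥ 1 bp) a
validated receptor interval, and exactly 7 predicted transmembrane
segments.

**Topology.** The built-in predictor is Kyte–Doolittle hydropathy:
19-residue windows with mean ≥ 1.6 are merged where they overlap and a
merged stretch counts as a helix when ≥ 15 residues. Note the window
mean admits up to ~5 loop residues at a helix border, so two helices
separated by a short (< ~15 aa) loop can merge into one segment; the
synthetic scaffold therefore uses loops of ≥ 20 residues with strongly
hydrophilic borders, which provably keeps the seven helices separate.
Any predictor returning disjoint segments can be injected.

## Cluster architecture

Two genes are clustered when their start codons are within a gap
threshold (default 1 Mb, inclusive); maximal runs of ≥ 2 genes on one
contig are clusters, singletons are not. The median method splits
fixed-gap clusters, in a single pass, at any internal gap exceeding 20×
the median gap of the original cluster (fragment medians are not
recomputed), so its output always refines the fixed-gap clustering.
Cluster span is measured min(member start) to max(member end); the
per-genome statistics are the cluster count, mean genes per cluster,
fraction of genes clustered, fraction in the biggest cluster, biggest
and total cluster lengths (kb) and kb per clustered receptor. The
nearest-in-cluster fraction asks, for each clustered gene, whether its
most similar other gene (default distance: 1 − global-alignment
identity; any symmetric distance can be injected; ties to the smaller
gene id) lies in the same cluster. Chromosome-end position is
`d = min((L−s)/L, s/L)` for start `s` on a chromosome of length `L`;
contigs count as chromosomes when their FASTA header contains one of
the tokens `Chromosome`, `chromosome`, `chr`, `linkage group`, `LG`
(case-sensitive substring). Distributions are compared with Welch's
t-test (Satterthwaite df) and the two-sided two-sample KS test. Repeat
context compares the per-class repeat fraction in the union of
[cluster ± 100 kb] windows with the mean over 10 random windows of the
same width (sampled with replacement, chromosomes weighted by length,
seeded), paired across genomes per repeat class; genomes without
clusters are excluded.

## Family evolution

**Partition heuristic.** The published analysis partitioned gene trees
manually; the packaged heuristic formalises its stated constraints.
Families are maximal clades in which no species repeats, except tips of
one species whose patristic divergence is below 0.05
substitutions/site (recent duplicates). Families spanning < 2 species
or whose species-tree MRCA is younger than 50 MY are greedily merged
into their parent clade while the repetition rule still holds;
unresolvable families are kept but flagged unusable. Family tables can
also be supplied directly, bypassing the heuristic.

**CNCO.** The expected species of a family are all tips under the
species-tree MRCA of its observed species. A family is a
copy-number-constrained ortholog when strictly fewer than 5% of
expected species have 2+ copies and strictly more than 50% have exactly
one. Cluster enrichment models each cluster gene as independently CNCO
with the genome-wide proportion `p`; with `X_c ~ Binomial(n_c, p)` the
expected conditional probability of a second CNCO given a first is
`Σ P(X_c ≥ 2) / Σ P(X_c ≥ 1)`, compared to the observed conditional
with a pooled two-proportion z-test. The published analysis does not
state the z-test's sample sizes; both are set to the observed number of
CNCO-containing clusters and reported.

**Trios.** The gene tree is rooted on the outgroup species' tips; each
maximal clade whose tips come exclusively from the two focal species is
classified by its tip counts: (1,1) one-to-one, (1,>1) one-to-many,
(≥2,≥2) many-to-many, single-species clades one-to-zero or
many-to-zero. Classification is topology-only by default; an optional
threshold collapses weakly supported internal nodes into polytomies
before classification.

**Model weights.** `w_i = exp(−½Δ_i)/Σ exp(−½Δ_k)` with
`Δ_i = score_i − min score`, computed after subtracting the minimum for
numerical stability; applies equally to AIC and pBIC scores.

## Synteny

A receptor locus (cluster span or singleton) collects the single-copy
markers whose intervals overlap its span ± 1 Mb; loci with < 2 markers
are excluded. Every cross-species locus pair is tested with the
upper-tail hypergeometric probability of sharing ≥ k markers given a
universe of N marker ids. N is not fixed by the published description;
the default is the number of distinct marker ids annotated across the
two species compared, overridable to a fixed universe, and is reported
with each link. P-values are Bonferroni-corrected over all tested pairs
(a global family; per-pair correction is exposed as a config choice).
Significant links form a graph whose connected components are conserved
locus groups, dated by the MRCA age of their species set on the
calibrated species tree — a minimum age only: rearranged or
marker-poor flanks are invisible to the test, so absence of a group is
never evidence of locus absence.

## Expression

FPKM is `counts · 10⁹ / (mapped_total · gene_length)` cellwise. A gene
is expressed in a tissue when FPKM strictly exceeds 0.01 in at least
one replicate (a replicate-mean mode is provided, since per-tissue
pooling is a plausible alternative reading of the source analyses).
Percent-expressed metrics use the genome's receptor count as
denominator; tissue-uniqueness and extra-oral-but-not-tongue
percentages use the expressed-gene count — both raw counts are emitted
so either convention is recoverable. Colocalization is the Spearman
matrix (average-rank ties) of replicate-mean FPKM vectors per tissue,
computed over all genes by default; constant vectors give NA. The
count-vs-extra-oral correlation reports Pearson r with
`t = r·√(n−2)/√(1−r²)` and a two-sided p on n−2 df.

## Assays

Well responses are trapezoidal AUC over the luminescence time series.
Agonist calls compare each substance's replicates to the pooled buffer
wells of the same receptor (basal responses differ between receptors)
with a two-sided Welch t-test; Benjamini–Hochberg runs within each
receptor's substance family (a global-family mode exists) and a call is
significant when adjusted p < 0.05. Relative activity is
`(mean_substance − mean_buffer)/(max_substance_mean − mean_buffer)`, so
the strongest substance scores 1; it is affine-invariant and
non-significant entries are NA. Dose–response series are screened with
one-sided Dunnett many-to-one comparisons against the lowest
concentration (scipy's implementation); the one-sided equicorrelated
critical value is also exposed via deterministic quadrature over the
multivariate-t representation (Gauss–Hermite × chi quantiles, accurate
to ~1e-3).

A known limitation: with the design's minimal replicate counts
(substance n = 6 vs pooled buffer n = 14), Welch–Satterthwaite p-values
are noticeably liberal in the far tail (~35% at p ≈ 2e-3), so the
per-plate family-wise false-call rate of the screen runs near 6–7%
rather than the nominal 5%. This is a property of the test at these
sample sizes, not of the implementation; designs with ≥ 8 substance
replicates are essentially calibrated.

## Synthetic data

Generators are pure functions of their parameters and one integer seed;
each draws from a named RNG stream with a fixed id, so adding a
generator never shifts another's draws.

**Assemblies.** Planted genes are intronless ORFs of ~300 codons built
from a receptor-like scaffold: seven 21-residue hydrophobic helices
(I/L/V/F with ≤ 4 milder A/C positions) separated by ≥ 20-residue
hydrophilic loops whose borders are strongly hydrophilic — bounds
chosen so the Kyte–Doolittle predictor provably finds exactly seven
segments in every mutant. Genes diverge from the emitted query proteins
by within-category substitutions capped at 15% (so ≥ 80% identity).
Back-translation avoids any `ATG`/`CAT` substring after the start
codon, so no stray start codon exists inside or opposite a planted
gene; histidine is excluded from the loop alphabet because its only
safe codon cannot precede an isoleucine codon. Coding blocks are
wrapped in short guards containing stop codons in all six frames, and
the intergenic background interleaves the same guards every ~100 bp, so
the largest ORF of any extracted window is the planted one by
construction. Each decoy fails exactly one filter: a weak-similarity
gene (one short conserved patch in an otherwise score-negative A/G/S/T
body) for the e-value filter; a premature stop at codon 151 (< 200 aa);
a 215-codon loop insertion (> 500 aa); an exact downstream copy of a
planted gene (duplicate); a start-codon-free, fully ATG/CAT-scrubbed
zone (no ORF); a ~40%-diverged paralog whose exact copy sits outside
the validated intervals of the reference (reciprocal failure); and a
six-helix variant (topology filter). Defaults plant two clusters
(5 and 3 genes) and one singleton on two 2.5-Mb chromosomes with > 1 Mb
separation, and place decoys downstream of all genes.

What this does **not** emulate: realistic sequence evolution (no
substitution model, no indels, no pseudogenes), genomic repeat
structure, GC heterogeneity, or ORFs that straddle window borders.
Passing recovery tests therefore demonstrates the pipeline's logic and
coordinate arithmetic, not its sensitivity on diverged real genomes.

**Trees and families.** Species trees are random ultrametric topologies
built by successive joins at strictly increasing ages, rescaled to a
requested root age. Trio gene trees interleave outgroup tips between
scripted focal clades so the scripted clades are exactly the maximal
focal-species clades. CNCO families occupy a random species-tree clade
with both child subtrees populated (so the expected-species rule
recovers exactly that clade); planted CNCO families have no multi-copy
species and a strict majority of single-copy species, non-CNCO families
violate exactly one threshold.

**Markers, counts, plates.** Planted conserved loci share 6 of 8
markers from a 3,000-marker universe, decoy loci draw uniformly —
random overlap is then far below the Bonferroni threshold. Counts are
negative-binomial (dispersion 0.3) around a mean of 80 in expressing
tissues, with at least one read guaranteed in the first replicate and
exact zeros elsewhere, so planted expression truth is exactly
recoverable at the 0.01 FPKM threshold; mapped totals are ~2×10⁷ ± 5%.
Plates draw buffer wells (n = 14) and substance wells (n = 6) from
normals with receptor-specific baselines (sd 20 RLU); planted agonists
add a 5-sd effect.

## Numerical choices and degenerate inputs

Coordinates are 1-based inclusive throughout (BED converted at the
boundary). Calibrated trees must be ultrametric within 1e-6 of their
height; tip ages are then exactly 0. Ties: largest-ORF (smaller start,
then + strand), biggest cluster (more genes, then longer, then id),
nearest neighbour (smaller gene id). `ic_weights` subtracts the minimum
score before exponentiation. Zero-variance comparisons raise errors
rather than returning NaN (both-groups-constant t-tests, constant
correlation inputs, max-equals-buffer normalisation). The
nearest-in-cluster fraction is undefined (None) without clusters or
with fewer than two genes; single-species synteny groups are reported
undated.

## Problem sizes

The bundled recovery analyses use 10–20 synthetic assemblies of ~5 Mb
(two 2.5-Mb chromosomes; 9 planted genes and 7 decoys each), 50 planted
families on a 20-species tree, marker landscapes of 12 species with two
planted groups and 10 decoy loci, 300-gene count matrices over 7
tissues × 3 replicates, and 28-substance plates (500–2,000 per
calibration run) — sizes at which every stage's truth is exactly
checkable while a full run stays in the minutes range on one CPU.
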