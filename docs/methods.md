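# Methods

This note documents the models, defaults and design decisions behind
rbpscape, and what the synthetic-data experiments do and do not show.

## Coordinates and overlap conventions

All internal coordinates are 0-based half-open (BED dialect); GTF input
(1-based inclusive) is converted on read and back on write. Two intervals
overlap iff they share at least one nucleotide on the same chromosome and
strand: CLIP libraries are stranded, so every overlap, assignment and
target-gene operation is same-strand. A cluster or read spanning several
overlapping genes counts toward each of them (the conservative target
definition); transcriptome-wide it is counted once.

## Gene models and region classes

A gene model is the union over isoforms: exons are merged, UTRs are kept as
annotated, and introns are derived as the gene-span complement of the
merged exonic space (exons ∪ UTRs). The region classes partition the
pre-mRNA: **exon** means exonic-minus-UTR nucleotides, **5′/3′ UTR** as
annotated, and intronic positions are **proximal** within 500 nt of an
exon–intron boundary, else **distal**. Cluster assignment is iterative with
priority exon > 3′ UTR > 5′ UTR > intron, so a cluster touching both coding
exon and UTR is exonic; intronic clusters are proximal when the minimum
distance from either cluster edge to the nearest exon–intron boundary of a
host gene is < 500 nt (the rule fixes the 500-nt cutoff but not the
measuring point; nearest-edge-to-nearest-boundary is the least surprising
choice and is exercised at the boundary in the tests). Region enrichment is
log₂(F_CLIP/F_region) with F_region the class's share of annotated
nucleotides summed over genes.

## Cluster calling

Candidate clusters are maximal intervals of contiguous nonzero read
coverage within a gene span (book-ended reads merge: coverage is what
matters). With k reads overlapping a candidate of length L, the two P
values are upper Poisson tails P(X ≥ k) at μ = rate·L under (i) the
transcriptome-wide rate, total gene-mapped reads over total pre-mRNA
length, and (ii) the gene-specific rate. Rates are stored as reads per
nucleotide — the dimensionally consistent form of the published
"frequency", whose quoted phrasing (length ÷ reads) is its reciprocal. A
candidate is significant when both P values are below α/M with α = 10⁻⁴
(the conventional reading of "P < 10e−4") and M the number of candidates
tested transcriptome-wide — the multiplicity unit is not specified in the
source convention; candidates-tested is the standard choice. The tails come
from `scipy.stats.poisson.sf` and are checked against direct pmf summation
to 1e−12 for all k ≤ 50, μ ≤ 20.

## k-mer enrichment and motif scans

Counting is by sliding window over {A,C,G,U}; windows containing any other
character (N, masked positions) are skipped, so masking shortens the
countable window set without shifting coordinates. The published delta
between real and background k-mer tables is rendered only as an unreadable
figure in the source; it is implemented as **percent enrichment above
background**, 100·(f_real − f_bg)/f_bg, which matches the axis wording of
the corresponding figures; counts (N) are retained for count-based
alternatives. Background clusters are drawn per real cluster: same length,
same region class, uniform over all possible placements in that class's
interval pool (intervals weighted by their number of valid start
positions); clusters whose class has no interval long enough are skipped
with a warning. Motif matching is exact on the sense strand with IUPAC
degeneracy (R = A/G etc.); positional histograms record motif-start offsets
relative to cluster centers in transcript orientation, floor-binned at
10 nt over a ±500 nt window, normalized globally to total matches (the
per-cluster vs global normalization choice is not documented anywhere;
global is simpler and preserves counts).

## RBNS

R(6-mer) = frequency in the pulldown over frequency in the input pool,
counted within the 20-nt random region only (flanking primers never enter a
window). Z standardizes R with the population mean and s.d. over all 6-mers
with defined R; significance is Z ≥ 2. The concentration analyzed is the
one with the highest overall enrichment, defined here as the maximum
single-6-mer R (the ENCODE-style convention; ties break toward the lower
concentration, and the 0 nM no-protein control is not a candidate). Logo
construction iterates: take the top-R significant 6-mer, record weight
R − 1, mask all its occurrences in both pools, recompute R and Z on the
masked windows, stop when no 6-mer reaches Z ≥ 2. Accepted 6-mers align to
an existing logo's seed at the offset (−5..+5) minimizing mismatches
(overhangs excluded); more than 2 mismatches seeds a new logo. PWM columns
are weight-weighted letter frequencies of the aligned 6-mers; a motif's
proportion is its weight share of the total accepted weight. Termination is
guaranteed because each accepted 6-mer is fully masked and cannot recur; a
guard errors after 4^k iterations.

A caveat the null simulations make explicit: because Z is standardized over
the *empirical* R distribution, roughly 2.5% of 6-mers exceed Z = 2 in any
finite sample even when pulldown and input are statistically identical.
The Z ≥ 2 rule therefore ranks specificity well (the planted motif is the
top R with Z ≫ 2 at realistic affinities) but cannot certify a null
library; the no-protein control is better summarized by the planted
motif's R staying near 1, which is what the unit tests assert.

## Decay kinetics

First-order decay N(t) = N(0)e^(−λt); λ = −slope of the OLS fit of ln RPKM
on time (hours), t₁/₂ = ln 2/λ, R² the squared correlation of that fit.
Genes enter fitting only if expressed at t = 0 (RPKM > 1); zero RPKMs are
floored at a pseudocount of 0.01 before the log (avoids −∞ while preserving
fit ranks) and genes with more than one zero are excluded. Inclusion
requires λ > 0 and R² > 0.6. Fits use unnormalized RPKMs; the
normalize-to-t0 transform in the published heatmaps is display-only. The
shuffled null permutes each gene's values across time points (uniform
seeded permutation, identity allowed) and compares R² distributions by
two-sample KS; R² is collected from every fittable gene regardless of the
inclusion filters, since the comparison is about fit quality itself.
Stability calls require inclusion in both conditions and use
|log₂(kd/ctrl t₁/₂)| > 1 (strict).

## Gene-set statistics

DE significance is |log₂FC| ≥ log₂(1.5) AND adjusted P < 0.05 — the
printed source rule has the fold-change inequality inverted, which would
select the unchanged genes; the direction is corrected here and the
threshold configurable. Overlap P values are upper hypergeometric tails
over the expressed background; Fisher's exact test is two-sided by the
conventional sum of margin-fixed tables with probability ≤ observed; both
are cross-checked against full enumeration in the tests. Regression of
paired log₂ fold changes defaults to genes significant in both tables
(per the stated procedure), with an `all` mode exposed. The long-intron
comparison uses the per-gene **sum** of intron lengths (the claim names no
statistic; the maximum is also reported) under a two-sided rank-sum test.
Splicing events pass at |Sep| > 0.5 and q < 0.05, strict as printed, with
the Sep sign annotated as inclusion/exclusion. Term enrichment applies
Benjamini–Hochberg across terms (the source states no adjustment; raw P
values are reported alongside).

## Synthetic-data generators

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; same seed ⇒ identical bytes.

- **Genome**: 50 genes by default on alternating strands of one toy
  chromosome (~0.75 Mb), each 5′UTR–exon/intron–3′UTR with 2–5 internal
  exons (100–300 nt) and introns of 0.5–3 kb; exactly ⌈0.1·n⌉ genes carry
  one 50 kb intron to exercise the long-intron analyses. Background
  sequence is i.i.d. with configurable GC (default 0.5).
- **CLIP**: 10,000 reads of 40 nt; 20 planted 50-nt sites in distinct
  genes, the motif written at each site center; reads are drawn with
  per-nucleotide weight 1 on pre-mRNA background and 50 (the enrichment
  multiplier) inside sites. Enrichment 0 with no sites is the null used
  for false-positive calibration.
- **RBNS**: random 20-mers; the assayed concentration series 0, 5, 20, 80,
  320 nM with affinities a = 0, 2, 5, 10, 7 (strongest at 80 nM, matching
  the concentration selected in the source study); pulldowns are drawn
  with replacement from a 20× oversampled candidate pool with weight
  1 + a·(planted-motif occurrences) — linear in occurrence count, the
  simplest monotone model, chosen so the expected R of any k-mer is
  exactly derivable (the tests enumerate all 4⁸ reads of an 8-mer
  analogue and match the empirical R within 3 s.e. at 100k reads).
- **Decay**: 500 genes, control half-lives log-uniform on 2–6 h, initial
  RPKM log-uniform on 5–500, six time points at 0–7.5 h (about two median
  half-lives), multiplicative log-normal noise σ = 0.1; 10% of genes get a
  4× (stabilized) and 10% a 0.25× (destabilized) knockdown half-life
  factor.
- **DE tables**: 2,000 background genes, 150 significant per table with a
  controlled shared fraction (default 0.3) and correlated (configurable
  sign) shared effects.

What these emulate — and do not. The generators reproduce the statistical
structure each stage assumes: Poisson-ish background coverage with planted
pileups, selection linear in motif content, first-order decay with
multiplicative noise. They do not model crosslink-site biochemistry,
sequencing error, fragment-length or GC bias, transcript isoform mixtures,
or count-level (negative-binomial) variance in expression. Passing the
recovery tests therefore certifies the estimators and their thresholds
under their own model assumptions, not robustness to every artifact of
real libraries.

## Numerical and degenerate-input choices

Poisson tails use `poisson.sf(k−1, μ)` with P(X ≥ 0) ≡ 1. Region
enrichment with zero clusters in a nonempty class reports −inf; a class
with clusters but zero annotated length is an error. k-mer enrichment
where f_bg = 0 is NaN and excluded from distribution tests. Degenerate
rank-sum comparisons (all lengths equal) report NaN rather than a fake P.
Logo alignment ties break toward the smaller absolute offset, then the
smaller signed offset; top-R ties resolve lexicographically via the index
order of the table. Empty candidate sets, empty gene sets, sets outside
their background, ragged tables and malformed records raise errors naming
the offender rather than coercing.

## Problem sizes

Defaults are desk-scale by design: ~0.75 Mb toy genome, 10⁴ CLIP reads,
10⁵ RBNS reads per library, 500 decay genes, 2,000 background genes. These
sizes give the recovery properties comfortable margins (e.g. the planted
6-mer's Z ≈ 45 at affinity 10) while keeping the full test suite and the
acceptance script runnable in minutes on one CPU.
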