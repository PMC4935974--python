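# rbpscape

Analysis toolkit for multisystem studies of the ALS-associated RNA-binding
proteins (TAF15, FUS, TDP-43 and their kin): where a protein binds the
transcriptome, what sequence it prefers, and what its loss does to mRNA
levels, stability and splicing. The package re-implements the full
computational chain as a tested library with a CLI, plus seeded
synthetic-data generators so every stage can be verified by parameter
recovery without any external download.

## What it computes

**CLIP-seq cluster calling** (`rbpscape.clip`). Candidate clusters are
maximal runs of contiguous read coverage inside a gene's pre-mRNA. Each
candidate with *k* overlapping reads is tested against two Poisson
expectations — a transcriptome-wide read rate and a gene-specific rate
(reads per pre-mRNA nucleotide) — and called significant when both
upper-tail P values pass a Bonferroni-corrected threshold α/M (α = 10⁻⁴,
M = candidates tested).

**Genic-region annotation and enrichment** (`rbpscape.annotation`).
Clusters are assigned iteratively — exon, then 3′ UTR, 5′ UTR, then
proximal (<500 nt from an exon–intron boundary) or distal intron — and
binding enrichment per region is log₂(F_CLIP / F_region), the fraction of
clusters over the fraction of annotated nucleotides.

**k-mer motif analysis** (`rbpscape.kmers`). Percent enrichment above
background, 100·(f_real − f_bg)/f_bg per k-mer, of cluster sequences
against random background clusters matched by region class; two-sample
Kolmogorov–Smirnov comparison of seed-containing k-mers vs the rest;
positional histograms of a motif around cluster centers (±500 nt, 10-nt
bins); per-gene motif presence scans.

**RNA Bind-n-Seq** (`rbpscape.rbns`). For each 6-mer,
R = freq(pulldown)/freq(input), standardized to Z-scores over all 4,096
6-mers; significant at Z ≥ 2. Motif logos are built iteratively: the top-R
significant 6-mer gets weight R − 1, all its occurrences are masked in both
pools, enrichments are recomputed, and the loop stops when no 6-mer reaches
Z ≥ 2; accepted 6-mers are aligned (≤2 mismatches) into position weight
matrices with per-motif proportions.

**mRNA decay kinetics** (`rbpscape.decay`). N(t) = N(0)·e^(−λt); λ from
log-linear OLS of ln(RPKM) on time, t₁/₂ = ln 2/λ. Genes are included when
λ > 0 and R² > 0.6; fit quality is validated against a within-gene
time-shuffled null (two-sample KS on R² distributions); genes are
stabilized/destabilized when |log₂(knockdown/control t₁/₂)| > 1.

**Gene-set statistics** (`rbpscape.genesets`). Hypergeometric overlap
against the expressed (RPKM > 1) background, Fisher's exact test of binding
vs regulation, OLS regression of paired log₂ fold changes, rank-sum
comparison of intron lengths, splicing-event filtering (|Sep| > 0.5,
q < 0.05), and GO-style term enrichment with Benjamini–Hochberg control.

**Synthetic data** (`rbpscape.simulate`). Seeded generators for a toy
genome with exon/intron/UTR structure (including ≥50 kb long-intron genes),
CLIP reads from a background + planted-site mixture, RBNS pools whose
pulldown sampling weight is 1 + a·(motif occurrences), decay time courses
with log-normal noise and planted half-life factors, and paired DE tables
with controlled overlap. Each returns a truth table for scoring recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate.py`, then 02…06). For example,
calling clusters on 10,000 simulated reads with 20 planted sites:

```
$ python analysis/02_call_clip_clusters.py
20 significant clusters in 20 target genes from 10,000 reads
planted-site recovery: 20/20 (100%)
region enrichment (log2 F_clip/F_region):
         region  f_clip  f_region  log2_fold
           exon    0.20  0.048723   2.037329
      three_utr    0.05  0.034745   0.525116
...
```

Every planted site is recovered with zero false calls, and binding looks
enriched in exons/3′ UTRs relative to region size because sites were
planted uniformly in gene bodies while introns dominate the nucleotide
budget. The RBNS driver then recovers the planted GGUAAG motif:

```
$ python analysis/04_rbns.py
selected concentration: 80 nM (highest overall enrichment across 5 libraries)
33 significant 6-mers (Z >= 2); top five:
        f_pulldown   f_input          R          Z  significant
GGUAAG    0.002557  0.000247  10.367568  44.260714         True
...
1 motif logo(s); dominant seed GGUAAG (100.0% of total weight)
```

and the decay driver recovers half-lives to ~5% median error with the real
R² distribution sharply separated from the shuffled null
(median 0.98 vs 0.14, KS P ≈ 10⁻²⁸⁷).

The same operations are available as subcommands of the `rbpscape` CLI
(`call-clusters`, `annotate`, `region-enrichment`, `kmer-enrich`,
`motif-hist`, `motif-scan`, `rbns`, `decay`, `stability`, `overlap`,
`fisher`, `regress`, `enrich`, `splice-filter`, `run`).

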