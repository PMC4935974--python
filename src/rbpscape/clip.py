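"""CLIP-seq cluster calling with a dual-frequency Poisson test.

Candidate clusters are maximal runs of contiguous read coverage inside a
gene's pre-mRNA span. Each candidate with k overlapping reads is tested
against two Poisson expectations: a transcriptome-wide read rate (reads per
pre-mRNA nucleotide over all genes) and a gene-specific rate. A cluster is
significant when both upper-tail P values pass a Bonferroni-corrected
threshold alpha / M, with M the number of candidates tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .annotation import GeneModel, GenomeAnnotation, RegionLabel, assign_region
from .intervals import GenomicInterval, merge_intervals

DEFAULT_ALPHA = 1e-4


@dataclass
class ReadSet:
    """Non-redundant aligned CLIP reads (PCR duplicates removed upstream)."""

    alignments: list[GenomicInterval]
    per_gene_index: dict[str, list[int]] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return len(self.alignments)

    @classmethod
    def from_intervals(
        cls, reads: Iterable[GenomicInterval], annotation: GenomeAnnotation
    ) -> "ReadSet":
        rs = cls(alignments=list(reads))
        for i, read in enumerate(rs.alignments):
            for gene in annotation.overlapping_genes(read):
                rs.per_gene_index.setdefault(gene.gene_id, []).append(i)
        return rs


@dataclass
class PoissonRates:
    rate_transcriptome: float  # reads per nucleotide over all pre-mRNA
    rate_gene: dict[str, float]  # per gene, reads per pre-mRNA nucleotide


@dataclass
class ClipCluster:
    interval: GenomicInterval
    gene_id: str
    read_count: int
    p_transcriptome: float
    p_gene: float
    region: RegionLabel = RegionLabel.UNASSIGNED
    significant: bool = False


def compute_rates(reads: ReadSet, annotation: GenomeAnnotation) -> PoissonRates:
    """Transcriptome-wide and gene-specific read rates (reads / nt).

    Reads overlapping no gene are excluded; a read spanning two genes counts
    in each gene's rate but once transcriptome-wide.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    total_len = sum(len(g.span) for g in annotation.genes.values())
    mapped = set()
    for gid, idxs in reads.per_gene_index.items():
        mapped.update(idxs)
    if not mapped:
        raise ValueError("no reads map to any gene")
    rate_gene = {
        gid: len(idxs) / len(annotation.genes[gid].span)
        for gid, idxs in reads.per_gene_index.items()
        if idxs
    }
    return PoissonRates(len(mapped) / total_len, rate_gene)


def find_candidate_regions(
    reads: ReadSet, gene: GeneModel
) -> list[GenomicInterval]:
    """Maximal intervals of contiguous nonzero read coverage within a gene."""
    idxs = reads.per_gene_index.get(gene.gene_id, [])
    if not idxs:
        return []
    clipped = []
    for i in idxs:
        r = reads.alignments[i]
        inter = r.intersection(gene.span)
        if inter is not None:
            clipped.append(inter)
    return merge_intervals(clipped)


def poisson_tail(k: int, rate: float, length: int) -> float:
    """P(X >= k) with X ~ Poisson(mu = rate * length); P(X >= 0) = 1."""
    if k < 0 or rate < 0 or length < 1:
        raise ValueError("poisson_tail requires k >= 0, rate >= 0, length >= 1")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, rate * length))


def call_clusters(
    reads: ReadSet,
    annotation: GenomeAnnotation,
    alpha: float = DEFAULT_ALPHA,
    return_all: bool = False,
) -> list[ClipCluster]:
    """Call significant CLIP clusters.

    Each candidate is tested at threshold alpha / M under both the
    transcriptome-wide and the gene-specific Poisson rate; by default only
    significant clusters are returned (sorted by coordinate and annotated
    with their genic region), ``return_all`` keeps every candidate.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rates = compute_rates(reads, annotation)
    candidates: list[tuple[str, GenomicInterval]] = []
    for gid in sorted(reads.per_gene_index):
        gene = annotation.genes[gid]
        for iv in find_candidate_regions(reads, gene):
            candidates.append((gid, iv))
    m = len(candidates)
    if m == 0:
        return []
    threshold = alpha / m
    out: list[ClipCluster] = []
    for gid, iv in candidates:
        k = 0
        for i in reads.per_gene_index[gid]:
            if reads.alignments[i].overlaps(iv):
                k += 1
        p_t = poisson_tail(k, rates.rate_transcriptome, len(iv))
        p_g = poisson_tail(k, rates.rate_gene[gid], len(iv))
        cluster = ClipCluster(
            interval=iv,
            gene_id=gid,
            read_count=k,
            p_transcriptome=p_t,
            p_gene=p_g,
            significant=(p_t < threshold and p_g < threshold),
        )
        if cluster.significant or return_all:
            out.append(cluster)
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.gene_id))
    for c in out:
        c.region = assign_region(c.interval, annotation)
    return out
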