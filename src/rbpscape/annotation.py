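"""Gene models, genic-region assignment and region-size-normalized enrichment.

A gene model is the union over isoforms: a nucleotide annotated as exonic in
any isoform counts as exonic. Region classes partition the pre-mRNA into
exon (exonic minus UTRs), 5' UTR, 3' UTR, and proximal/distal intron, where
an intronic position is proximal when it lies within ``proximal_boundary``
(default 500 nt) of an exon-intron boundary.

Clusters overlapping several classes are assigned iteratively with priority
exon > 3' UTR > 5' UTR > intron, and intronic clusters split into proximal
vs distal by the distance from the nearest cluster edge to the nearest
exon-intron boundary of the host gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
    total_length,
)

PROXIMAL_BOUNDARY_NT = 500


class RegionLabel(str, Enum):
    EXON = "exon"
    THREE_UTR = "three_utr"
    FIVE_UTR = "five_utr"
    PROXIMAL_INTRON = "proximal_intron"
    DISTAL_INTRON = "distal_intron"
    UNASSIGNED = "unassigned"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: Region classes that carry annotated nucleotides (everything but unassigned).
ASSIGNED_LABELS = (
    RegionLabel.EXON,
    RegionLabel.THREE_UTR,
    RegionLabel.FIVE_UTR,
    RegionLabel.PROXIMAL_INTRON,
    RegionLabel.DISTAL_INTRON,
)


class MalformedAnnotationError(ValueError):
    pass


class UndefinedEnrichmentError(ValueError):
    pass


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    five_utr: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in [*self.exons, *self.five_utr, *self.three_utr]:
            if iv.chrom != self.span.chrom or iv.strand != self.span.strand:
                raise MalformedAnnotationError(
                    f"{self.gene_id}: feature {iv} not on gene chrom/strand"
                )
            if iv.start < self.span.start or iv.end > self.span.end:
                raise MalformedAnnotationError(
                    f"{self.gene_id}: feature {iv} outside gene span {self.span}"
                )
        self.exons = merge_intervals(self.exons) if self.exons else []

    @property
    def exonic_space(self) -> list[GenomicInterval]:
        """Union of exons and UTRs (UTRs are exonic in mature transcripts)."""
        return merge_intervals([*self.exons, *self.five_utr, *self.three_utr])

    @property
    def introns(self) -> list[GenomicInterval]:
        return subtract_intervals([self.span], self.exonic_space)

    @property
    def exon_minus_utr(self) -> list[GenomicInterval]:
        return subtract_intervals(self.exonic_space, [*self.five_utr, *self.three_utr])

    def boundaries(self) -> list[int]:
        """Exon-intron boundary coordinates (intron edges)."""
        coords: list[int] = []
        for iv in self.introns:
            coords.extend((iv.start, iv.end))
        return coords

    def region_intervals(
        self, proximal_boundary: int = PROXIMAL_BOUNDARY_NT
    ) -> dict[RegionLabel, list[GenomicInterval]]:
        proximal: list[GenomicInterval] = []
        distal: list[GenomicInterval] = []
        for iv in self.introns:
            if len(iv) <= 2 * proximal_boundary:
                proximal.append(iv)
            else:
                proximal.append(
                    GenomicInterval(iv.chrom, iv.start, iv.start + proximal_boundary, iv.strand)
                )
                proximal.append(
                    GenomicInterval(iv.chrom, iv.end - proximal_boundary, iv.end, iv.strand)
                )
                distal.append(
                    GenomicInterval(
                        iv.chrom, iv.start + proximal_boundary, iv.end - proximal_boundary, iv.strand
                    )
                )
        return {
            RegionLabel.EXON: self.exon_minus_utr,
            RegionLabel.THREE_UTR: merge_intervals(self.three_utr) if self.three_utr else [],
            RegionLabel.FIVE_UTR: merge_intervals(self.five_utr) if self.five_utr else [],
            RegionLabel.PROXIMAL_INTRON: proximal,
            RegionLabel.DISTAL_INTRON: distal,
        }


class GenomeAnnotation:
    """Collection of gene models with a strand-aware interval index."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise MalformedAnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            key = (g.span.chrom, g.span.strand)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key][g.span.start : g.span.end] = g.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping_genes(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get((iv.chrom, iv.strand))
        if tree is None:
            return []
        hits = tree.overlap(iv.start, iv.end)
        return [self.genes[h.data] for h in sorted(hits, key=lambda h: (h.begin, h.data))]

    def region_sizes(
        self, proximal_boundary: int = PROXIMAL_BOUNDARY_NT
    ) -> dict[RegionLabel, int]:
        """Total annotated nucleotides per region class, summed over genes."""
        sizes = {label: 0 for label in ASSIGNED_LABELS}
        for g in self.genes.values():
            for label, ivs in g.region_intervals(proximal_boundary).items():
                sizes[label] += total_length(ivs)
        return sizes

    def region_interval_pool(
        self, proximal_boundary: int = PROXIMAL_BOUNDARY_NT
    ) -> dict[RegionLabel, list[GenomicInterval]]:
        """All intervals of each class across genes (for background sampling)."""
        pool: dict[RegionLabel, list[GenomicInterval]] = {l: [] for l in ASSIGNED_LABELS}
        for g in self.genes.values():
            for label, ivs in g.region_intervals(proximal_boundary).items():
                pool[label].extend(ivs)
        return pool


@dataclass(frozen=True)
class FeatureRecord:
    """One GTF-like feature row, already in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    feature: str  # gene | exon | five_utr | three_utr (synonyms accepted)
    gene_id: str


_FEATURE_SYNONYMS = {
    "gene": "gene",
    "exon": "exon",
    "five_utr": "five_utr",
    "five_prime_utr": "five_utr",
    "5utr": "five_utr",
    "utr5": "five_utr",
    "three_utr": "three_utr",
    "three_prime_utr": "three_utr",
    "3utr": "three_utr",
    "utr3": "three_utr",
}


def build_annotation(records: Iterable[FeatureRecord]) -> GenomeAnnotation:
    """Assemble gene models from feature rows.

    Introns are derived as the gene-span complement of the merged exonic
    space. When no explicit ``gene`` feature is present the span is the
    envelope of the gene's features. Exons outside an explicit gene span are
    a malformed-annotation error.
    """
    by_gene: dict[str, dict[str, list]] = {}
    order: list[str] = []
    for rec in records:
        kind = _FEATURE_SYNONYMS.get(rec.feature.lower())
        if kind is None:
            continue  # skip CDS/transcript/etc. rows
        if rec.strand not in ("+", "-"):
            raise MalformedAnnotationError(
                f"{rec.gene_id}: unknown strand {rec.strand!r}"
            )
        if rec.gene_id not in by_gene:
            by_gene[rec.gene_id] = {"gene": [], "exon": [], "five_utr": [], "three_utr": []}
            order.append(rec.gene_id)
        iv = GenomicInterval(rec.chrom, rec.start, rec.end, rec.strand)
        by_gene[rec.gene_id][kind].append(iv)

    genes: list[GeneModel] = []
    for gid in order:
        feats = by_gene[gid]
        parts = feats["exon"] + feats["five_utr"] + feats["three_utr"]
        if feats["gene"]:
            if len(feats["gene"]) > 1:
                raise MalformedAnnotationError(f"{gid}: multiple gene rows")
            span = feats["gene"][0]
        else:
            if not parts:
                raise MalformedAnnotationError(f"{gid}: no features")
            span = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                parts[0].strand,
            )
        genes.append(
            GeneModel(gid, span, feats["exon"], feats["five_utr"], feats["three_utr"])
        )
    return GenomeAnnotation(genes)


def assign_region(
    cluster: GenomicInterval,
    annotation: GenomeAnnotation,
    proximal_boundary: int = PROXIMAL_BOUNDARY_NT,
) -> RegionLabel:
    """Iterative genic-region assignment of one cluster.

    Priority exon > 3' UTR > 5' UTR > intron; intronic clusters are proximal
    when the minimum distance from a cluster edge to the nearest exon-intron
    boundary of any host gene is below ``proximal_boundary``.
    """
    genes = annotation.overlapping_genes(cluster)
    if not genes:
        return RegionLabel.UNASSIGNED

    def hits(ivs: Sequence[GenomicInterval]) -> bool:
        return any(cluster.overlaps(iv) for iv in ivs)

    if any(hits(g.exon_minus_utr) for g in genes):
        return RegionLabel.EXON
    if any(hits(g.three_utr) for g in genes):
        return RegionLabel.THREE_UTR
    if any(hits(g.five_utr) for g in genes):
        return RegionLabel.FIVE_UTR

    intronic_genes = [g for g in genes if hits(g.introns)]
    if not intronic_genes:
        # inside a gene span but only exonic space left (should not happen)
        return RegionLabel.UNASSIGNED
    min_dist = math.inf
    for g in intronic_genes:
        for b in g.boundaries():
            min_dist = min(min_dist, abs(cluster.start - b), abs(cluster.end - b))
    if min_dist < proximal_boundary:
        return RegionLabel.PROXIMAL_INTRON
    return RegionLabel.DISTAL_INTRON


@dataclass
class RegionEnrichment:
    """Per-region cluster fractions vs annotated-nucleotide fractions.

    log2_fold[region] = log2(F_clip / F_region); fold enrichment of binding
    relative to how much of the annotated transcriptome the region occupies.
    """

    f_clip: dict[RegionLabel, float]
    f_region: dict[RegionLabel, float]
    log2_fold: dict[RegionLabel, float]
    n_clusters: int


def region_fold_enrichment(
    labels: Sequence[RegionLabel],
    annotation: GenomeAnnotation,
    proximal_boundary: int = PROXIMAL_BOUNDARY_NT,
) -> RegionEnrichment:
    """Region-size-normalized binding enrichment from labeled clusters."""
    assigned = [l for l in labels if l != RegionLabel.UNASSIGNED]
    if not assigned:
        raise UndefinedEnrichmentError("no assigned clusters")
    sizes = annotation.region_sizes(proximal_boundary)
    total_size = sum(sizes.values())
    if total_size == 0:
        raise UndefinedEnrichmentError("annotation has no region nucleotides")
    f_clip = {
        label: sum(1 for l in assigned if l == label) / len(assigned)
        for label in ASSIGNED_LABELS
    }
    f_region = {label: sizes[label] / total_size for label in ASSIGNED_LABELS}
    log2_fold: dict[RegionLabel, float] = {}
    for label in ASSIGNED_LABELS:
        if f_region[label] == 0:
            if f_clip[label] > 0:
                raise UndefinedEnrichmentError(
                    f"clusters assigned to {label} but the region has zero annotated length"
                )
            log2_fold[label] = math.nan
        elif f_clip[label] == 0:
            log2_fold[label] = -math.inf
        else:
            log2_fold[label] = math.log2(f_clip[label] / f_region[label])
    return RegionEnrichment(f_clip, f_region, log2_fold, len(assigned))


def gene_targets(
    clusters: Sequence[GenomicInterval], annotation: GenomeAnnotation
) -> set[str]:
    """Genes containing at least one cluster (same-strand pre-mRNA overlap).

    A cluster spanning several overlapping genes counts toward each.
    """
    targets: set[str] = set()
    for c in clusters:
        for g in annotation.overlapping_genes(c):
            targets.add(g.gene_id)
    return targets
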