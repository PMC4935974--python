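"""k-mer counting, enrichment vs region-matched background, and motif scans.

Enrichment of cluster sequences is measured against random background
clusters drawn from the same genic region classes, as percent enrichment
above background: 100 * (f_real - f_bg) / f_bg per k-mer. The seed-motif
comparison (k-mers containing a 4-mer of interest vs not) is tested with a
two-sample Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, RegionLabel
from .intervals import GenomicInterval
from .sequences import find_motif, motif_regex, sense_sequence, to_rna

RNA_ALPHABET = frozenset("ACGU")


class EmptyKmerTableError(ValueError):
    pass


@dataclass
class KmerTable:
    """Sliding-window k-mer counts (N in the enrichment formulas) and
    frequencies (f = N / total windows)."""

    k: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        t = self.total
        return {w: n / t for w, n in self.counts.items()} if t else {}

    def freq(self, word: str) -> float:
        t = self.total
        return self.counts.get(word, 0) / t if t else 0.0


def count_kmers(sequences: Iterable[str], k: int) -> KmerTable:
    """Count overlapping k-mer windows; windows containing a non-ACGU
    character (N, masked positions) are skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    any_long_enough = False
    for seq in sequences:
        seq = to_rna(seq)
        if len(seq) >= k:
            any_long_enough = True
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if RNA_ALPHABET.issuperset(word):
                counts[word] = counts.get(word, 0) + 1
    if not any_long_enough:
        raise EmptyKmerTableError(f"k={k} exceeds the length of every sequence")
    return KmerTable(k=k, counts=counts)


def sample_background_clusters(
    clusters: Sequence[GenomicInterval],
    labels: Sequence[RegionLabel],
    annotation: GenomeAnnotation,
    seed: int,
) -> list[GenomicInterval]:
    """Random background clusters matched to the real ones.

    One interval per input cluster, of identical length, placed uniformly at
    random over all possible placements within intervals of the same region
    class (any gene, same strand convention as the chosen interval).
    Clusters whose class has no interval long enough are skipped with a
    warning, so the per-class length distribution of the output matches the
    placeable input exactly.
    """
    rng = np.random.default_rng(seed)
    pool = annotation.region_interval_pool()
    out: list[GenomicInterval] = []
    n_skipped = 0
    for cluster, label in zip(clusters, labels):
        length = len(cluster)
        candidates = [iv for iv in pool.get(label, []) if len(iv) >= length]
        if not candidates:
            n_skipped += 1
            continue
        # uniform over placements: weight intervals by number of valid starts
        weights = np.array([len(iv) - length + 1 for iv in candidates], dtype=float)
        idx = rng.choice(len(candidates), p=weights / weights.sum())
        iv = candidates[idx]
        start = iv.start + int(rng.integers(0, len(iv) - length + 1))
        out.append(GenomicInterval(iv.chrom, start, start + length, iv.strand))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} cluster(s) skipped: no region interval long enough",
            stacklevel=2,
        )
    return out


def kmer_enrichment(
    real: KmerTable, background: KmerTable, seed_4mer: str | None = None
) -> pd.DataFrame:
    """Percent enrichment above background per k-mer.

    Returns a DataFrame indexed by k-mer with columns f_real, f_bg,
    percent_enrichment and contains_seed. k-mers absent from the background
    get NaN enrichment and are excluded from downstream distribution tests.
    """
    if real.k != background.k:
        raise ValueError("k-mer tables have different k")
    words = sorted(set(real.counts) | set(background.counts))
    f_real = np.array([real.freq(w) for w in words])
    f_bg = np.array([background.freq(w) for w in words])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(f_bg > 0, 100.0 * (f_real - f_bg) / f_bg, np.nan)
    df = pd.DataFrame(
        {"f_real": f_real, "f_bg": f_bg, "percent_enrichment": pct}, index=words
    )
    if seed_4mer is not None:
        pat = motif_regex(seed_4mer)
        df["contains_seed"] = [pat.search(w) is not None for w in words]
    return df


def compare_distributions(profile: pd.DataFrame) -> tuple[float, float]:
    """Two-sample KS test of percent enrichment, seed-containing k-mers vs
    the rest. Returns (D, two-tailed P)."""
    if "contains_seed" not in profile:
        raise ValueError("profile lacks a contains_seed column")
    valid = profile.dropna(subset=["percent_enrichment"])
    with_seed = valid.loc[valid["contains_seed"], "percent_enrichment"]
    without = valid.loc[~valid["contains_seed"], "percent_enrichment"]
    if len(with_seed) == 0 or len(without) == 0:
        raise ValueError("one of the comparison groups is empty")
    res = stats.ks_2samp(with_seed, without, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PositionalHistogram:
    """Motif occurrences binned by offset from cluster centers."""

    bin_centers: np.ndarray
    counts: np.ndarray
    density: np.ndarray = field(init=False)
    window: int = 1000
    bin_width: int = 10

    def __post_init__(self) -> None:
        total = self.counts.sum()
        self.density = self.counts / total if total > 0 else self.counts.astype(float)


def motif_positional_histogram(
    clusters: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motif: str,
    window: int = 1000,
    bin_width: int = 10,
) -> PositionalHistogram:
    """Histogram of motif-start offsets relative to cluster centers.

    Offsets are measured in the transcript (sense) direction within
    +/- window/2 of each cluster center, floor-divided into bins of
    ``bin_width``; density is normalized to the total number of matches.
    Neighborhoods truncated by a chromosome end are counted over the
    available span.
    """
    half = window // 2
    n_bins = window // bin_width
    edges_lo = -half
    counts = np.zeros(n_bins, dtype=int)
    pad = len(motif) - 1  # so matches starting near the window edge are seen
    for cluster in clusters:
        center = (cluster.start + cluster.end) // 2
        lo = max(0, center - half - pad)
        hi = min(len(genome[cluster.chrom]), center + half + pad)
        if hi <= lo:
            continue
        neighborhood = GenomicInterval(cluster.chrom, lo, hi, cluster.strand)
        seq = sense_sequence(genome, neighborhood)
        if cluster.strand == "+":
            center_idx = center - lo
        else:
            center_idx = hi - 1 - center
        for start in find_motif(seq, motif):
            offset = start - center_idx
            b = (offset - edges_lo) // bin_width
            if 0 <= b < n_bins:
                counts[b] += 1
    centers = np.arange(n_bins) * bin_width + edges_lo + bin_width / 2
    return PositionalHistogram(
        bin_centers=centers, counts=counts, window=window, bin_width=bin_width
    )


def _expand_region_request(
    regions: Iterable[RegionLabel | str],
) -> set[RegionLabel]:
    out: set[RegionLabel] = set()
    for r in regions:
        if isinstance(r, RegionLabel):
            out.add(r)
        elif r == "intron":
            out.update((RegionLabel.PROXIMAL_INTRON, RegionLabel.DISTAL_INTRON))
        else:
            out.add(RegionLabel(r))
    return out


def scan_motif_presence(
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    motif: str,
    regions: Iterable[RegionLabel | str],
) -> dict[str, bool]:
    """Per-gene flag: motif present in any interval of the requested region
    classes, matched exactly on the gene's sense strand. The string
    ``"intron"`` is shorthand for proximal plus distal intron."""
    wanted = _expand_region_request(regions)
    pat = motif_regex(motif)
    result: dict[str, bool] = {}
    for gid, gene in annotation.genes.items():
        found = False
        region_ivs = gene.region_intervals()
        for label in wanted:
            for iv in region_ivs.get(label, []):
                if pat.search(sense_sequence(genome, iv)):
                    found = True
                    break
            if found:
                break
        result[gid] = found
    return result
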