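"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its config and seed and returns a
truth table sufficient to score the downstream stage by parameter recovery:
planted binding sites for the cluster caller, planted motif affinities for
RBNS, true half-lives for the decay fits, and the constructed overlap for
the gene-set statistics.

Study-condition defaults: RBNS uses the assayed concentration series
(0, 5, 20, 80, 320 nM) over randomized 20-mers with the strongest affinity
at 80 nM; CLIP plants 20 sites of 50 nt at a 50x enrichment over a uniform
pre-mRNA background; the decay course has 6 time points spanning about two
median half-lives with sigma = 0.1 multiplicative log-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureRecord, GenomeAnnotation, build_annotation
from .decay import ExpressionTimeCourse
from .intervals import GenomicInterval
from .rbns import RbnsLibrary

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_RNA = np.frombuffer(b"ACGU", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configs


@dataclass
class GenomeConfig:
    n_genes: int = 50
    chrom: str = "chrS"
    utr5_len: tuple[int, int] = (100, 300)
    utr3_len: tuple[int, int] = (200, 800)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (500, 3000)
    n_internal_exons: tuple[int, int] = (2, 5)
    intergenic_len: tuple[int, int] = (500, 2000)
    long_intron_fraction: float = 0.1
    long_intron_len: int = 50_000  # exercises the long-intron analyses
    gc: float = 0.5


@dataclass
class ClipConfig:
    n_reads: int = 10_000
    read_length: int = 40
    n_sites: int = 20
    site_width: int = 50
    enrichment: float = 50.0  # per-nucleotide rate multiplier inside sites
    motif: str = "GGUAAG"


@dataclass
class RbnsConfig:
    n_reads: int = 100_000
    random_len: int = 20
    motif: str = "GGUAAG"
    # affinity a(c) per concentration (nM); pulldown weight = 1 + a * occurrences
    affinities: dict = field(
        default_factory=lambda: {0: 0.0, 5: 2.0, 20: 5.0, 80: 10.0, 320: 7.0}
    )
    pool_oversample: int = 20


@dataclass
class DecayConfig:
    n_genes: int = 500
    halflife_range: tuple[float, float] = (2.0, 6.0)  # hours, log-uniform
    n0_range: tuple[float, float] = (5.0, 500.0)  # RPKM at t=0, log-uniform
    noise_sigma: float = 0.1  # log-normal multiplicative noise
    times: tuple[float, ...] = (0.0, 1.5, 3.0, 4.5, 6.0, 7.5)
    frac_stabilized: float = 0.1
    frac_destabilized: float = 0.1
    stabilized_factor: float = 4.0
    destabilized_factor: float = 0.25


@dataclass
class DeConfig:
    n_background: int = 2000
    n_sig_a: int = 150
    n_sig_b: int = 150
    overlap_fraction: float = 0.3
    effect_sign: int = 1  # +1 correlated, -1 anticorrelated shared effects


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    clip: ClipConfig = field(default_factory=ClipConfig)
    rbns: RbnsConfig = field(default_factory=RbnsConfig)
    decay: DecayConfig = field(default_factory=DecayConfig)
    de: DeConfig = field(default_factory=DeConfig)


# ---------------------------------------------------------------------------
# helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _DNA[codes].tobytes().decode("ascii")


def _uniform_int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# genome


def make_genome(
    config: GenomeConfig, seed: int
) -> tuple[GenomeAnnotation, dict[str, str], pd.DataFrame]:
    """Toy genome: genes with 5'UTR / exon / intron / 3'UTR structure on
    alternating strands, i.i.d. background sequence, and exactly
    ceil(long_intron_fraction * n_genes) genes carrying one intron of
    ``long_intron_len``. Returns (annotation, sequences, gene truth table).
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    n_long = math.ceil(config.long_intron_fraction * config.n_genes)
    long_genes = set(rng.choice(config.n_genes, size=n_long, replace=False).tolist())

    records: list[FeatureRecord] = []
    truth_rows = []
    cursor = _uniform_int(rng, config.intergenic_len)
    for gi in range(config.n_genes):
        gid = f"gene{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_internal = _uniform_int(rng, config.n_internal_exons)
        # left-to-right blocks; for - strand the transcript reads right-to-left
        utr_left = _uniform_int(rng, config.utr5_len if strand == "+" else config.utr3_len)
        utr_right = _uniform_int(rng, config.utr3_len if strand == "+" else config.utr5_len)
        exon_lens = [_uniform_int(rng, config.exon_len) for _ in range(n_internal)]
        intron_lens = [_uniform_int(rng, config.intron_len) for _ in range(n_internal + 1)]
        if gi in long_genes:
            intron_lens[int(rng.integers(0, len(intron_lens)))] = config.long_intron_len

        start = cursor
        blocks: list[tuple[str, int]] = [("utr_left", utr_left)]
        for j in range(n_internal):
            blocks.append(("intron", intron_lens[j]))
            blocks.append(("exon", exon_lens[j]))
        blocks.append(("intron", intron_lens[-1]))
        blocks.append(("utr_right", utr_right))

        pos = start
        for kind, length in blocks:
            iv = (pos, pos + length)
            if kind != "intron":
                records.append(
                    FeatureRecord(config.chrom, iv[0], iv[1], strand, "exon", gid)
                )
            if kind == "utr_left":
                feat = "five_utr" if strand == "+" else "three_utr"
                records.append(FeatureRecord(config.chrom, iv[0], iv[1], strand, feat, gid))
            elif kind == "utr_right":
                feat = "three_utr" if strand == "+" else "five_utr"
                records.append(FeatureRecord(config.chrom, iv[0], iv[1], strand, feat, gid))
            pos += length
        records.append(FeatureRecord(config.chrom, start, pos, strand, "gene", gid))
        truth_rows.append(
            dict(gene=gid, start=start, end=pos, strand=strand,
                 long_intron=gi in long_genes,
                 total_intron_length=sum(intron_lens))
        )
        cursor = pos + _uniform_int(rng, config.intergenic_len)

    seq = _random_dna(rng, cursor + _uniform_int(rng, config.intergenic_len), config.gc)
    annotation = build_annotation(records)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return annotation, {config.chrom: seq}, truth


# ---------------------------------------------------------------------------
# CLIP reads


def simulate_clip_reads(
    annotation: GenomeAnnotation,
    sequences: Mapping[str, str],
    config: ClipConfig,
    seed: int,
) -> tuple[list[GenomicInterval], pd.DataFrame, dict[str, str]]:
    """CLIP reads from a mixture of uniform pre-mRNA background (weight 1
    per nucleotide) and planted sites (weight = enrichment per nucleotide),
    with the binding motif written into each site center of the sequence.

    Returns (reads, truth table of planted sites, motif-edited sequences).
    """
    rng = np.random.default_rng(seed)
    genes = list(annotation.genes.values())
    spans = np.array([len(g.span) for g in genes], dtype=float)
    seqs = {k: list(v) for k, v in sequences.items()}

    eligible = [g for g in genes if len(g.span) >= config.site_width + 2]
    if config.n_sites > len(eligible):
        raise ValueError("more sites than eligible genes")
    site_genes = rng.choice(len(eligible), size=config.n_sites, replace=False)
    sites: list[dict] = []
    motif_dna = rna_to_dna(config.motif)
    for si, gidx in enumerate(site_genes):
        g = eligible[gidx]
        start = int(rng.integers(g.span.start, g.span.end - config.site_width + 1))
        iv = GenomicInterval(g.span.chrom, start, start + config.site_width, g.span.strand)
        center = (iv.start + iv.end) // 2
        planted = motif_dna if iv.strand == "+" else _reverse_complement(motif_dna)
        lo = center - len(planted) // 2
        for j, c in enumerate(planted):
            seqs[iv.chrom][lo + j] = c
        sites.append(dict(site=f"site{si:03d}", chrom=iv.chrom, start=iv.start,
                          end=iv.end, strand=iv.strand, gene=g.gene_id))
    truth = pd.DataFrame(
        sites, columns=["site", "chrom", "start", "end", "strand", "gene"]
    ).set_index("site")

    # mixture weights: every pre-mRNA nucleotide gets 1, site nucleotides
    # get an extra (enrichment - 1)
    components: list[tuple[GenomicInterval, float, str]] = []
    for g in genes:
        components.append((g.span, float(len(g.span)), g.gene_id))
    if config.enrichment > 1:
        for row in truth.itertuples():
            iv = GenomicInterval(row.chrom, row.start, row.end, row.strand)
            components.append((iv, len(iv) * (config.enrichment - 1.0), row.gene))
    weights = np.array([w for _, w, _ in components])
    weights /= weights.sum()
    chosen = rng.choice(len(components), size=config.n_reads, p=weights)
    reads: list[GenomicInterval] = []
    for ci in chosen:
        iv, _, _ = components[ci]
        pos = int(rng.integers(iv.start, iv.end))
        chrom_len = len(sequences[iv.chrom])
        start = min(pos, chrom_len - config.read_length)
        reads.append(
            GenomicInterval(iv.chrom, start, start + config.read_length, iv.strand)
        )
    return reads, truth, {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# RBNS pools


def _random_rna_codes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, length), dtype=np.uint8)


def _codes_to_reads(codes: np.ndarray) -> list[str]:
    flat = _RNA[codes].tobytes().decode("ascii")
    length = codes.shape[1]
    return [flat[i : i + length] for i in range(0, len(flat), length)]


def count_motif_occurrences(codes: np.ndarray, motif: str) -> np.ndarray:
    """Occurrences (overlapping) of an exact RNA motif per encoded read."""
    m = np.frombuffer(motif.upper().replace("T", "U").encode(), dtype=np.uint8)
    mcodes = np.searchsorted(_RNA, m)  # ACGU are sorted in ASCII (A<C<G<U)
    k = len(mcodes)
    n_win = codes.shape[1] - k + 1
    if n_win <= 0:
        return np.zeros(codes.shape[0], dtype=np.int64)
    hits = np.ones((codes.shape[0], n_win), dtype=bool)
    for j in range(k):
        hits &= codes[:, j : j + n_win] == mcodes[j]
    return hits.sum(axis=1)


def simulate_rbns_pool(
    config: RbnsConfig, seed: int
) -> tuple[RbnsLibrary, dict[float, RbnsLibrary], dict]:
    """Input pool plus one pulldown per concentration.

    Input reads are uniform random; each pulldown draws (with replacement)
    from a large candidate pool with per-read weight 1 + a(c) * (occurrences
    of the planted motif), so the expected enrichment of any k-mer is
    analytically derivable. a(0 nM) = 0 by construction.
    """
    rng = np.random.default_rng(seed)
    affinities = dict(config.affinities)
    if 0 in affinities and affinities[0] != 0:
        raise ValueError("the 0 nM library must have zero affinity")
    in_codes = _random_rna_codes(rng, config.n_reads, config.random_len)
    input_library = RbnsLibrary(0.0, _codes_to_reads(in_codes))

    pool_n = config.pool_oversample * config.n_reads
    pool_codes = _random_rna_codes(rng, pool_n, config.random_len)
    occ = count_motif_occurrences(pool_codes, config.motif)
    pulldowns: dict[float, RbnsLibrary] = {}
    for conc in sorted(affinities):
        a = affinities[conc]
        w = 1.0 + a * occ
        idx = rng.choice(pool_n, size=config.n_reads, p=w / w.sum())
        pulldowns[float(conc)] = RbnsLibrary(
            float(conc), _codes_to_reads(pool_codes[idx])
        )
    truth = {"motif": config.motif, "affinities": affinities}
    return input_library, pulldowns, truth


# ---------------------------------------------------------------------------
# decay time courses


def simulate_decay(
    config: DecayConfig, seed: int
) -> tuple[ExpressionTimeCourse, ExpressionTimeCourse, pd.DataFrame]:
    """Paired control/knockdown Actinomycin-D courses with log-normal
    multiplicative noise and planted knockdown half-life factors."""
    rng = np.random.default_rng(seed)
    n = config.n_genes
    genes = [f"gene{i:04d}" for i in range(n)]
    lo, hi = config.halflife_range
    hl_ctrl = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    n0 = np.exp(rng.uniform(*np.log(config.n0_range), size=n))
    factors = np.ones(n)
    n_stab = int(round(config.frac_stabilized * n))
    n_destab = int(round(config.frac_destabilized * n))
    special = rng.choice(n, size=n_stab + n_destab, replace=False)
    factors[special[:n_stab]] = config.stabilized_factor
    factors[special[n_stab:]] = config.destabilized_factor
    hl_kd = hl_ctrl * factors

    times = np.asarray(config.times)

    def course(hl: np.ndarray, label: str) -> ExpressionTimeCourse:
        lam = np.log(2) / hl
        clean = n0[:, None] * np.exp(-lam[:, None] * times[None, :])
        noise = (
            np.exp(rng.normal(0.0, config.noise_sigma, size=clean.shape))
            if config.noise_sigma > 0
            else 1.0
        )
        df = pd.DataFrame(clean * noise, index=genes,
                          columns=[f"t{t:g}" for t in times])
        return ExpressionTimeCourse(rpkm=df, times=tuple(times), condition=label)

    tc_ctrl = course(hl_ctrl, "control")
    tc_kd = course(hl_kd, "knockdown")
    truth = pd.DataFrame(
        dict(gene=genes, half_life_control=hl_ctrl, half_life_knockdown=hl_kd,
             factor=factors, n0=n0)
    ).set_index("gene")
    return tc_ctrl, tc_kd, truth


# ---------------------------------------------------------------------------
# differential-expression tables


def simulate_de_tables(
    config: DeConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired DE tables over a shared background with a controlled number of
    shared significant genes and correlated (or anticorrelated) shared
    effects."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(config.n_background)]
    n_shared = int(round(config.overlap_fraction * min(config.n_sig_a, config.n_sig_b)))
    picks = rng.choice(
        config.n_background,
        size=config.n_sig_a + config.n_sig_b - n_shared,
        replace=False,
    )
    sig_a = set(picks[: config.n_sig_a])
    sig_b = set(picks[: n_shared]) | set(picks[config.n_sig_a :])

    def build(sig: set[int], base_fc: dict[int, float], sign: int) -> pd.DataFrame:
        lfc = rng.normal(0.0, 0.15, size=config.n_background)
        padj = rng.uniform(0.05, 1.0, size=config.n_background)
        for i in sig:
            if i in base_fc:
                lfc[i] = sign * base_fc[i] + rng.normal(0.0, 0.2)
                if abs(lfc[i]) < LFC_MIN:  # keep it significant despite the jitter
                    lfc[i] = math.copysign(LFC_MIN, lfc[i])
            else:
                direction = 1 if rng.random() < 0.5 else -1
                lfc[i] = direction * (LFC_MIN + abs(rng.normal(1.0, 0.5)))
            padj[i] = rng.uniform(1e-6, 0.049)
        return pd.DataFrame(
            {"log2_fold_change": lfc, "padj": padj, "expressed": True}, index=genes
        )

    LFC_MIN = math.log2(1.5) + 0.05
    shared_fc = {
        i: (1 if rng.random() < 0.5 else -1) * (LFC_MIN + abs(rng.normal(1.0, 0.5)))
        for i in (sig_a & sig_b)
    }
    de_a = build(sig_a, shared_fc, sign=1)
    de_b = build(sig_b, shared_fc, sign=config.effect_sign)
    truth = {
        "sig_a": {genes[i] for i in sig_a},
        "sig_b": {genes[i] for i in sig_b},
        "overlap": {genes[i] for i in (sig_a & sig_b)},
        "background": genes,
    }
    return de_a, de_b, truth
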