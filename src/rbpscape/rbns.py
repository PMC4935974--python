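"""RNA Bind-n-Seq enrichment and iterative motif-logo construction.

For each 6-mer, R = frequency in the protein-selected (pulldown) pool over
frequency in the input pool; Z-scores standardize R over all 6-mers
(population mean and s.d.), and R is significant at Z >= 2. Logos are built
by an iterative mask-and-align procedure: the top-R significant 6-mer is
recorded with weight R - 1, all its occurrences are masked in both read
pools, enrichments are recomputed on the masked pools, and the loop stops
when no 6-mer reaches the Z threshold. Accepted 6-mers are aligned to the
seed of an existing logo when they fit with at most 2 mismatches (offsets
-5..+5, overhangs excluded), else they seed a new logo; position weight
matrices and motif proportions come from the weighted aligned 6-mers.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import RNA_ALPHABET, KmerTable, count_kmers
from .sequences import to_rna

MASK_CHAR = "."
DEFAULT_Z_THRESHOLD = 2.0
RNA_LETTERS = "ACGU"


@dataclass
class RbnsLibrary:
    """One sequenced RBNS pool: random-region reads at a protein
    concentration (nM); 0 nM is the no-protein control."""

    concentration: float
    reads: list[str]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        self.reads = [to_rna(r) for r in self.reads]

    def kmer_table(self, k: int = 6) -> KmerTable:
        return count_kmers(self.reads, k)


def extract_random_region(read: str, primer5_len: int, random_len: int = 20) -> str:
    """Strip fixed flanking primers; k-mer counting is restricted to the
    random region so boundary-spanning words are never counted."""
    return read[primer5_len : primer5_len + random_len]


@dataclass
class RbnsEnrichment:
    """Per-k-mer R and Z values plus the k-mers with undefined R."""

    table: pd.DataFrame  # index k-mer; columns f_pulldown, f_input, R, Z, significant
    excluded: list[str]  # pulldown-only k-mers (input frequency zero)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def top_kmer(self) -> str:
        return self.table["R"].idxmax()


def _enrichment_frame(
    pd_counts: dict[str, int],
    in_counts: dict[str, int],
    pd_total: int,
    in_total: int,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> RbnsEnrichment:
    words = sorted(set(pd_counts) | set(in_counts))
    f_pd = np.array([pd_counts.get(w, 0) / pd_total if pd_total else 0.0 for w in words])
    f_in = np.array([in_counts.get(w, 0) / in_total if in_total else 0.0 for w in words])
    defined = f_in > 0
    excluded = [w for w, d, fp in zip(words, defined, f_pd) if not d and fp > 0]
    words = [w for w, d in zip(words, defined) if d]
    f_pd, f_in = f_pd[defined], f_in[defined]
    r = f_pd / f_in
    sd = r.std()  # population s.d. over all defined k-mers
    z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
    df = pd.DataFrame(
        {
            "f_pulldown": f_pd,
            "f_input": f_in,
            "R": r,
            "Z": z,
            "significant": z >= z_threshold,
        },
        index=words,
    )
    return RbnsEnrichment(table=df, excluded=excluded)


def rbns_r_values(
    pulldown: RbnsLibrary,
    input_library: RbnsLibrary,
    k: int = 6,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> RbnsEnrichment:
    """R and Z values of all k-mers, pulldown vs input."""
    pd_t = pulldown.kmer_table(k)
    in_t = input_library.kmer_table(k)
    if in_t.total == 0:
        raise ValueError("input library has no countable k-mer windows")
    return _enrichment_frame(pd_t.counts, in_t.counts, pd_t.total, in_t.total, z_threshold)


def select_concentration(
    libraries: Sequence[RbnsLibrary], input_library: RbnsLibrary, k: int = 6
) -> float:
    """Concentration with the highest overall enrichment, defined as the
    maximum single-k-mer R; ties break toward the lower concentration. The
    0 nM no-protein control is not a candidate unless it is all there is."""
    candidates = [l for l in libraries if l.concentration > 0] or list(libraries)
    if not candidates:
        raise ValueError("no libraries supplied")
    best = None
    for lib in sorted(candidates, key=lambda l: l.concentration):
        max_r = rbns_r_values(lib, input_library, k).table["R"].max()
        if best is None or max_r > best[1]:
            best = (lib.concentration, max_r)
    return best[0]


def _occurrence_starts(seq: str, word: str) -> list[int]:
    starts, i = [], seq.find(word)
    while i != -1:
        starts.append(i)
        i = seq.find(word, i + 1)
    return starts


def mask_word_in_read(read: str, word: str, mask_char: str = MASK_CHAR) -> str:
    """Mask the union of all (overlapping) occurrences of ``word``."""
    starts = _occurrence_starts(read, word)
    if not starts:
        return read
    chars = list(read)
    for s in starts:
        for j in range(s, s + len(word)):
            chars[j] = mask_char
    return "".join(chars)


def mask_occurrences(
    reads: Iterable[str], word: str, mask_char: str = MASK_CHAR
) -> list[str]:
    """Mask every occurrence of ``word`` in every read; masked positions are
    excluded from subsequent k-mer windows."""
    return [mask_word_in_read(r, word, mask_char) for r in reads]


class _MaskableKmerCounts:
    """k-mer counts over a read pool with cheap incremental masking.

    Keeps a word -> read-index map so masking one word only recounts the
    reads that contain it.
    """

    def __init__(self, reads: Iterable[str], k: int):
        self.k = k
        self.reads = [to_rna(r) for r in reads]
        self.counts: dict[str, int] = defaultdict(int)
        self.total = 0
        self._word_reads: dict[str, set[int]] = defaultdict(set)
        self._read_words: list[list[str]] = []
        for idx, read in enumerate(self.reads):
            words = self._window_words(read)
            self._read_words.append(words)
            for w in words:
                self.counts[w] += 1
                self._word_reads[w].add(idx)
            self.total += len(words)

    def _window_words(self, read: str) -> list[str]:
        k = self.k
        return [
            read[i : i + k]
            for i in range(len(read) - k + 1)
            if RNA_ALPHABET.issuperset(read[i : i + k])
        ]

    def mask(self, word: str) -> None:
        for idx in sorted(self._word_reads.get(word, ())):
            for w in self._read_words[idx]:
                self.counts[w] -= 1
                if self.counts[w] == 0:
                    del self.counts[w]
                self.total -= 1
            for w in set(self._read_words[idx]):
                self._word_reads[w].discard(idx)
            self.reads[idx] = mask_word_in_read(self.reads[idx], word)
            words = self._window_words(self.reads[idx])
            self._read_words[idx] = words
            for w in words:
                self.counts[w] += 1
                self._word_reads[w].add(idx)
            self.total += len(words)
        self._word_reads.pop(word, None)


def align_to_seed(
    word: str, seed: str, max_offset: int = 5
) -> tuple[int, int]:
    """Best (mismatches, offset) of ``word`` against ``seed``.

    Offset is the position of the word start relative to the seed start;
    overhanging positions are excluded from the mismatch count. Ties break
    toward the smaller absolute offset, then the smaller offset.
    """
    best: tuple[int, int, int] | None = None
    for o in range(-max_offset, max_offset + 1):
        lo = max(0, -o)
        hi = min(len(word), len(seed) - o)
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if word[i] != seed[i + o])
        key = (mm, abs(o), o)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[0], best[2]


@dataclass
class MotifLogo:
    """One motif: aligned 6-mers with weights (R - 1) and the resulting PWM."""

    seed: str
    members: list[tuple[str, int, float]]  # (k-mer, offset to seed, weight)
    pwm: np.ndarray = field(default=None, repr=False)  # 4 x L, column-stochastic
    positions: tuple[int, int] = (0, 0)  # offset range [lo, hi) relative to seed
    proportion: float = 0.0

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.members)

    def build_pwm(self) -> None:
        lo = min(o for _, o, _ in self.members)
        hi = max(o + len(w) for w, o, _ in self.members)
        pwm = np.zeros((4, hi - lo))
        letter_idx = {c: i for i, c in enumerate(RNA_LETTERS)}
        for word, o, weight in self.members:
            for j, c in enumerate(word):
                pwm[letter_idx[c], o - lo + j] += weight
        col_sums = pwm.sum(axis=0)
        self.pwm = pwm / col_sums[np.newaxis, :]
        self.positions = (lo, hi)


def build_motif_logos(
    pulldown: RbnsLibrary,
    input_library: RbnsLibrary,
    k: int = 6,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    max_mismatch: int = 2,
    max_offset: int = 5,
) -> list[MotifLogo]:
    """Iterative mask-and-align motif construction.

    Terminates because each accepted k-mer is fully masked (its own R
    becomes undefined); a guard errors after 4^k iterations.
    """
    pd_counts = _MaskableKmerCounts(pulldown.reads, k)
    in_counts = _MaskableKmerCounts(input_library.reads, k)
    logos: list[MotifLogo] = []
    max_iter = 4 ** k
    for _ in range(max_iter + 1):
        if in_counts.total == 0 or pd_counts.total == 0:
            break
        enr = _enrichment_frame(
            dict(pd_counts.counts), dict(in_counts.counts),
            pd_counts.total, in_counts.total, z_threshold,
        )
        sig = enr.significant
        if sig.empty:
            break
        word = sig["R"].idxmax()
        weight = float(sig.loc[word, "R"]) - 1.0
        if weight <= 0:
            break
        placed = False
        best: tuple[tuple[int, int, int], MotifLogo, int] | None = None
        for logo in logos:
            mm, off = align_to_seed(word, logo.seed, max_offset)
            key = (mm, abs(off), off)
            if best is None or key < best[0]:
                best = (key, logo, off)
        if best is not None and best[0][0] <= max_mismatch:
            best[1].members.append((word, best[2], weight))
            placed = True
        if not placed:
            logos.append(MotifLogo(seed=word, members=[(word, 0, weight)]))
        pd_counts.mask(word)
        in_counts.mask(word)
    else:
        raise RuntimeError("motif-logo iteration failed to terminate")
    grand_total = sum(l.total_weight for l in logos)
    for logo in logos:
        logo.build_pwm()
        logo.proportion = logo.total_weight / grand_total if grand_total else 0.0
    logos.sort(key=lambda l: l.proportion, reverse=True)
    return logos


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(RNA_LETTERS, repeat=k)]
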