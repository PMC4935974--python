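"""Sequence extraction and IUPAC motif matching on the sense strand.

Genome sequences are stored as DNA (A/C/G/T) keyed by chromosome; all motif
work happens in RNA space: extracted sense-strand sequence is transcribed
(T -> U), and reverse-strand intervals are reverse-complemented first.
"""

from __future__ import annotations

import re
from typing import Mapping

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Degenerate IUPAC codes (RNA); R covers GURAGU-style comparisons.
IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]",
    "B": "[CGU]", "D": "[AGU]", "H": "[ACU]", "V": "[ACG]",
    "N": "[ACGU]",
}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_regex(motif: str) -> re.Pattern[str]:
    motif = to_rna(motif)
    try:
        pattern = "".join(IUPAC_RNA[c] for c in motif)
    except KeyError as exc:
        raise ValueError(f"invalid motif character {exc.args[0]!r}") from exc
    return re.compile(pattern)


def find_motif(seq_rna: str, motif: str) -> list[int]:
    """Start offsets of (possibly overlapping) motif matches."""
    pat = motif_regex(motif)
    hits, pos = [], 0
    while True:
        m = pat.search(seq_rna, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def sense_sequence(
    genome: Mapping[str, str], iv: GenomicInterval, clip: bool = True
) -> str:
    """RNA sequence of an interval read in transcript (sense) orientation."""
    chrom_seq = genome[iv.chrom]
    start, end = iv.start, iv.end
    if clip:
        start, end = max(0, start), min(len(chrom_seq), end)
    sub = chrom_seq[start:end]
    if iv.strand == "-":
        sub = reverse_complement_dna(sub)
    return to_rna(sub)
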