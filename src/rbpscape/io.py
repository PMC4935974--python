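"""Readers and writers for the external formats the pipeline touches.

Dialects: BED6 (0-based half-open, tab-separated); GTF (1-based inclusive,
converted to the internal 0-based half-open convention on read and back on
write); FASTA/FASTQ via Biopython; TSV tables via pandas. Readers reject
malformed records with the offending line number rather than coercing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FeatureRecord, GenomeAnnotation
from .clip import ClipCluster
from .intervals import GenomicInterval
from .rbns import MotifLogo


class FormatError(ValueError):
    pass


@dataclass
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    extra: tuple = ()


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 BED columns "
                    f"(missing {'strand' if len(fields) == 5 else 'columns'})"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            score = float(score_s) if score_s not in (".", "") else 0.0
            records.append(BedRecord(iv, name, score, tuple(fields[6:])))
    return records


def write_bed(records: Iterable[BedRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            score = int(rec.score) if float(rec.score).is_integer() else rec.score
            fields = [iv.chrom, str(iv.start), str(iv.end), rec.name, str(score), iv.strand]
            fields.extend(str(x) for x in rec.extra)
            fh.write("\t".join(fields) + "\n")


def write_clusters_bed(clusters: Sequence[ClipCluster], path: str | os.PathLike) -> None:
    """BED6+ with p_transcriptome, p_gene, region label, gene id."""
    records = [
        BedRecord(
            c.interval,
            name=f"cluster_{i:05d}",
            score=c.read_count,
            extra=(f"{c.p_transcriptome:.6g}", f"{c.p_gene:.6g}", str(c.region), c.gene_id),
        )
        for i, c in enumerate(clusters)
    ]
    write_bed(records, path)


def read_gtf(path: str | os.PathLike) -> list[FeatureRecord]:
    """GTF-like annotation: tab-separated, attribute column with gene_id.
    1-based inclusive coordinates are converted to 0-based half-open."""
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: invalid GTF coordinates")
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            records.append(
                FeatureRecord(chrom, start1 - 1, end1, strand, feature, gene_id)
            )
    return records


def write_gtf(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            rows = [("gene", gene.span)]
            rows += [("exon", iv) for iv in gene.exons]
            rows += [("five_utr", iv) for iv in gene.five_utr]
            rows += [("three_utr", iv) for iv in gene.three_utr]
            for feature, iv in rows:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom, "rbpscape", feature,
                            str(iv.start + 1), str(iv.end),
                            ".", iv.strand, ".", f'gene_id "{gene.gene_id}";',
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[str]:
    """Read sequences from a 4-line-per-record FASTQ; truncated records are
    an error."""
    reads: list[str] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(qual) != len(seq):
            raise FormatError(f"{path}: quality length mismatch at line {i + 1}")
        reads.append(seq.upper())
    return reads


def write_fastq(reads: Iterable[str], path: str | os.PathLike, prefix: str = "read") -> None:
    """Write reads with constant (uninformative) qualities."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """DE table: columns gene, log2_fold_change, padj (extra columns kept)."""
    df = _read_tsv(path)
    required = {"gene", "log2_fold_change", "padj"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicated gene id(s): {list(dupes)[:10]}")
    return df.set_index("gene")


def read_splicing_table(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"event_id", "event_type", "sep_score", "q_value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise FormatError(f"{path}: q values outside [0, 1]")
    return df


def read_timecourse_matrix(path: str | os.PathLike, times: Sequence[float], condition: str):
    """TSV matrix, rows genes, one column per time point."""
    from .decay import ExpressionTimeCourse

    df = _read_tsv(path)
    gene_col = df.columns[0]
    dupes = df[gene_col][df[gene_col].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicated gene id(s): {list(dupes)[:10]}")
    df = df.set_index(gene_col)
    if df.shape[1] != len(times):
        raise FormatError(
            f"{path}: {df.shape[1]} value columns but {len(times)} time points"
        )
    return ExpressionTimeCourse(rpkm=df, times=tuple(times), condition=condition)


def write_meme_pwm(logos: Sequence[MotifLogo], path: str | os.PathLike) -> None:
    """MEME-minimal position frequency matrices, one motif per logo."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for i, logo in enumerate(logos, start=1):
            width = logo.pwm.shape[1]
            fh.write(f"MOTIF motif_{i}_{logo.seed}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {width} "
                f"nsites= {len(logo.members)} E= 0\n"
            )
            for col in range(width):
                fh.write(" ".join(f"{logo.pwm[row, col]:.6f}" for row in range(4)) + "\n")
            fh.write(f"# proportion {logo.proportion:.6f}\n\n")
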