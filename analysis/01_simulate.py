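#!/usr/bin/env python
"""Generate the full synthetic dataset every downstream analysis consumes.

Writes a toy genome (FASTA + GTF), CLIP reads with planted binding sites
(BED + truth table), RBNS input/pulldown pools (FASTQ per concentration),
Actinomycin-D decay time courses (TSV), and paired differential-expression
tables (TSV) under scratch/simdata/. All generators are seeded, so the
dataset is byte-reproducible.
"""

from pathlib import Path

from rbpscape import io
from rbpscape.simulate import (
    ClipConfig,
    DeConfig,
    DecayConfig,
    GenomeConfig,
    RbnsConfig,
    make_genome,
    simulate_clip_reads,
    simulate_de_tables,
    simulate_decay,
    simulate_rbns_pool,
)

SEED = 17
OUT = Path("scratch/simdata")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    annotation, seqs, gene_truth = make_genome(GenomeConfig(), SEED)
    reads, site_truth, seqs = simulate_clip_reads(annotation, seqs, ClipConfig(), SEED + 1)
    io.write_gtf(annotation, OUT / "genes.gtf")
    io.write_fasta(seqs, OUT / "genome.fa")
    io.write_bed([io.BedRecord(r, f"read_{i}", 1) for i, r in enumerate(reads)],
                 OUT / "clip_reads.bed")
    gene_truth.to_csv(OUT / "gene_truth.tsv", sep="\t")
    site_truth.to_csv(OUT / "clip_sites_truth.tsv", sep="\t")
    n_long = int(gene_truth["long_intron"].sum())
    print(f"genome: {len(annotation)} genes ({n_long} with a >=50 kb intron), "
          f"{len(seqs['chrS']):,} nt")
    print(f"CLIP: {len(reads):,} reads, {len(site_truth)} planted 50-nt sites "
          f"at 50x enrichment")

    rbns_cfg = RbnsConfig(n_reads=50_000)
    input_lib, pulldowns, truth = simulate_rbns_pool(rbns_cfg, SEED + 2)
    io.write_fastq(input_lib.reads, OUT / "rbns_input.fastq")
    for conc, lib in pulldowns.items():
        io.write_fastq(lib.reads, OUT / f"rbns_pulldown_{conc:g}nM.fastq")
    print(f"RBNS: {rbns_cfg.n_reads:,} 20-mers per library, planted motif "
          f"{truth['motif']}, affinities {truth['affinities']}")

    tc_ctrl, tc_kd, decay_truth = simulate_decay(DecayConfig(), SEED + 3)
    tc_ctrl.rpkm.to_csv(OUT / "decay_control.tsv", sep="\t", index_label="gene")
    tc_kd.rpkm.to_csv(OUT / "decay_knockdown.tsv", sep="\t", index_label="gene")
    decay_truth.to_csv(OUT / "decay_truth.tsv", sep="\t")
    print(f"decay: {len(tc_ctrl.rpkm)} genes x {len(tc_ctrl.times)} time points "
          f"(hours: {list(tc_ctrl.times)})")

    de_a, de_b, de_truth = simulate_de_tables(DeConfig(), SEED + 4)
    de_a.to_csv(OUT / "de_table_a.tsv", sep="\t", index_label="gene")
    de_b.to_csv(OUT / "de_table_b.tsv", sep="\t", index_label="gene")
    (OUT / "de_overlap_truth.txt").write_text(
        "\n".join(sorted(de_truth["overlap"])) + "\n"
    )
    print(f"DE: paired tables over {len(de_a)} genes, "
          f"{len(de_truth['overlap'])} shared significant genes planted")
    print(f"-> {OUT}/")


if __name__ == "__main__":
    main()
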