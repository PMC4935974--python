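#!/usr/bin/env python
"""RBNS analysis: R values, concentration selection, and motif logos.

Reads the simulated input and pulldown pools, picks the concentration with
the highest overall enrichment (maximum single 6-mer R), computes R and
Z scores for all 6-mers, and runs the iterative mask-and-align logo
builder, writing the PWMs in MEME-minimal format.
"""

from pathlib import Path

import pandas as pd

from rbpscape import io
from rbpscape.rbns import RbnsLibrary, build_motif_logos, rbns_r_values, select_concentration

SIM = Path("scratch/simdata")
OUT = Path("results/rbns")
CONCENTRATIONS = (0, 5, 20, 80, 320)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    input_lib = RbnsLibrary(0.0, io.read_fastq(SIM / "rbns_input.fastq"))
    pulldowns = {
        c: RbnsLibrary(c, io.read_fastq(SIM / f"rbns_pulldown_{c:g}nM.fastq"))
        for c in CONCENTRATIONS
    }
    chosen = select_concentration(list(pulldowns.values()), input_lib)
    print(f"selected concentration: {chosen:g} nM "
          f"(highest overall enrichment across {len(pulldowns)} libraries)")

    enr = rbns_r_values(pulldowns[chosen], input_lib)
    ranked = enr.table.sort_values("R", ascending=False)
    ranked.head(100).to_csv(OUT / "enrichment_top100.tsv", sep="\t", index_label="kmer")
    ranked.to_csv(Path("scratch") / "rbns_enrichment_full.tsv", sep="\t",
                  index_label="kmer")
    n_sig = int(enr.table["significant"].sum())
    print(f"{n_sig} significant 6-mers (Z >= 2); top five:")
    print(ranked.head(5).to_string())

    logos = build_motif_logos(pulldowns[chosen], input_lib)
    io.write_meme_pwm(logos, OUT / "logos.meme")
    pd.DataFrame(
        [dict(seed=l.seed, n_kmers=len(l.members), proportion=l.proportion)
         for l in logos]
    ).to_csv(OUT / "logo_summary.tsv", sep="\t", index=False)
    print(f"{len(logos)} motif logo(s); dominant seed {logos[0].seed} "
          f"({100 * logos[0].proportion:.1f}% of total weight)")


if __name__ == "__main__":
    main()
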