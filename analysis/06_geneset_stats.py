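#!/usr/bin/env python
"""Gene-set statistics connecting binding to regulation.

On the simulated tables: hypergeometric overlap of the two significant
gene sets against the expressed background, Fisher's exact test of
binding vs regulation (CLIP target genes x simulated down-set), OLS
regression of paired log2 fold changes over both-significant genes,
rank-sum comparison of intron lengths (long-intron genes vs the rest),
splicing-event filtering, and GO-style term enrichment of a planted term.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rbpscape import io
from rbpscape.annotation import build_annotation
from rbpscape.genesets import (
    compare_intron_lengths,
    filter_splicing_events,
    fisher_binding_regulation,
    geneset_enrichment,
    hypergeom_overlap,
    regress_log2_changes,
    significant_genes,
)

SIM = Path("scratch/simdata")
OUT = Path("results/genesets")
SEED = 47


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    de_a = io.read_de_table(SIM / "de_table_a.tsv")
    de_b = io.read_de_table(SIM / "de_table_b.tsv")
    background = set(de_a.index)

    up_a, down_a = significant_genes(de_a)
    up_b, down_b = significant_genes(de_b)
    ov = hypergeom_overlap(up_a | down_a, up_b | down_b, background)
    print(f"overlap: |A|={ov.n_a} |B|={ov.n_b} shared={ov.n_overlap} of "
          f"{ov.n_background} expressed genes, hypergeometric P={ov.p_value:.3g}")

    fisher = fisher_binding_regulation(up_a | down_a, up_b | down_b, background)
    print(f"Fisher binding-vs-regulation 2x2 {fisher.table}: "
          f"odds={fisher.odds_ratio:.2f}, two-sided P={fisher.p_value:.3g}")

    reg = regress_log2_changes(de_a, de_b)
    print(f"regression over both-significant genes (n={reg.n}): "
          f"slope={reg.slope:.3f}, R^2={reg.r_squared:.3f}, P={reg.p_value:.3g}")

    annotation = build_annotation(io.read_gtf(SIM / "genes.gtf"))
    gene_truth = pd.read_csv(SIM / "gene_truth.tsv", sep="\t", index_col=0)
    long_set = list(gene_truth.index[gene_truth["long_intron"]])
    rest = list(gene_truth.index[~gene_truth["long_intron"]])
    introns = compare_intron_lengths({"long": long_set, "rest": rest}, annotation)
    introns.to_csv(OUT / "intron_length_comparison.tsv", sep="\t", index=False)
    row = introns.iloc[0]
    print(f"intron length (long-intron genes vs rest): medians "
          f"{row['median_a']:,.0f} vs {row['median_b']:,.0f} nt, "
          f"rank-sum P={row['p_value']:.3g}")

    rng = np.random.default_rng(SEED)
    n_ev, n_true = 200, 25
    sep = rng.normal(0, 0.2, n_ev)
    qv = rng.uniform(0.05, 1.0, n_ev)
    sep[:n_true] = rng.choice([-1, 1], n_true) * rng.uniform(0.6, 2.0, n_true)
    qv[:n_true] = rng.uniform(1e-4, 0.04, n_true)
    events = pd.DataFrame(
        dict(event_id=[f"ev{i:04d}" for i in range(n_ev)], event_type="cassette",
             sep_score=sep, q_value=qv)
    )
    kept = filter_splicing_events(events)
    kept.to_csv(OUT / "splicing_significant.tsv", sep="\t", index=False)
    n_inc = (kept["direction"] == "inclusion").sum()
    print(f"splicing filter: {len(kept)}/{n_ev} events at |Sep|>0.5 & q<0.05 "
          f"({n_inc} inclusion, {len(kept) - n_inc} exclusion; {n_true} planted)")

    genes = sorted(background)
    terms = {f"term{j:02d}": set(genes[40 * j : 40 * j + 40]) for j in range(20)}
    query = set(rng.choice(sorted(terms["term03"]), 25, replace=False))
    enr = geneset_enrichment(query, terms, background)
    enr.to_csv(OUT / "term_enrichment.tsv", sep="\t", index=False)
    print(f"term enrichment: top term {enr.iloc[0]['term']} "
          f"(planted term03), q={enr.iloc[0]['q_value']:.3g}")


if __name__ == "__main__":
    main()
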