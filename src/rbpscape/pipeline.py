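"""End-to-end synthetic pipeline with a reproducible run manifest.

Runs the stages in dependency order on generated data — simulate genome and
CLIP reads, call clusters, annotate and compute region enrichment, k-mer
enrichment against region-matched background, RBNS analysis with motif
logos, decay fits with the shuffled-R^2 null and stability calls, and the
gene-set statistics — writing TSV/BED/FASTA outputs plus a JSON manifest
recording versions, seeds, parameters, input checksums, and per-stage
record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, io
from .annotation import ASSIGNED_LABELS
from .clip import ReadSet, call_clusters
from .decay import classify_stability, fit_timecourse, shuffled_null
from .annotation import region_fold_enrichment, gene_targets
from .genesets import (
    compare_intron_lengths,
    filter_splicing_events,
    fisher_binding_regulation,
    hypergeom_overlap,
    regress_log2_changes,
    significant_genes,
)
from .kmers import (
    compare_distributions,
    count_kmers,
    kmer_enrichment,
    motif_positional_histogram,
    sample_background_clusters,
)
from .rbns import build_motif_logos, rbns_r_values, select_concentration
from .sequences import sense_sequence
from .simulate import (
    SimConfig,
    make_genome,
    simulate_clip_reads,
    simulate_de_tables,
    simulate_decay,
    simulate_rbns_pool,
)

log = logging.getLogger("rbpscape")


@dataclasses.dataclass
class PipelineConfig:
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    alpha: float = 1e-4  # Bonferroni-corrected cluster threshold
    kmer_k: int = 6
    seed_4mer: str = "GGUA"
    hist_window: int = 1000
    hist_bin: int = 10

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (5 <= self.kmer_k <= 9):
            raise ValueError("k must be in 5..9")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages on synthetic data; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.sim.seed
    manifest: dict = {
        "package": "rbpscape",
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name: str, **counts) -> None:
        log.info("stage %s: %s", name, counts)
        manifest["stages"].append({"name": name, **counts})

    # --- simulate genome + CLIP reads
    annotation, seqs, gene_truth = make_genome(config.sim.genome, seed)
    reads, site_truth, seqs = simulate_clip_reads(
        annotation, seqs, config.sim.clip, seed + 1
    )
    io.write_gtf(annotation, outdir / "genes.gtf")
    io.write_fasta(seqs, outdir / "genome.fa")
    io.write_bed(
        [io.BedRecord(r, f"read_{i}", 1) for i, r in enumerate(reads)],
        outdir / "clip_reads.bed",
    )
    site_truth.to_csv(outdir / "clip_sites_truth.tsv", sep="\t")
    stage("simulate", genes=len(annotation), reads=len(reads), sites=len(site_truth))

    # --- cluster calling + annotation + region enrichment
    read_set = ReadSet.from_intervals(reads, annotation)
    clusters = call_clusters(read_set, annotation, alpha=config.alpha)
    io.write_clusters_bed(clusters, outdir / "clusters.bed")
    enr = region_fold_enrichment([c.region for c in clusters], annotation)
    pd.DataFrame(
        {
            "region": [str(l) for l in ASSIGNED_LABELS],
            "f_clip": [enr.f_clip[l] for l in ASSIGNED_LABELS],
            "f_region": [enr.f_region[l] for l in ASSIGNED_LABELS],
            "log2_fold": [enr.log2_fold[l] for l in ASSIGNED_LABELS],
        }
    ).to_csv(outdir / "region_enrichment.tsv", sep="\t", index=False)
    targets = gene_targets([c.interval for c in clusters], annotation)
    stage("call-clusters", candidates_significant=len(clusters), target_genes=len(targets))

    # --- k-mer enrichment of cluster sequences vs region-matched background
    bg = sample_background_clusters(
        [c.interval for c in clusters], [c.region for c in clusters], annotation, seed + 2
    )
    real_tab = count_kmers(
        [sense_sequence(seqs, c.interval) for c in clusters], config.kmer_k
    )
    bg_tab = count_kmers([sense_sequence(seqs, iv) for iv in bg], config.kmer_k)
    profile = kmer_enrichment(real_tab, bg_tab, seed_4mer=config.seed_4mer)
    profile.to_csv(outdir / "kmer_enrichment.tsv", sep="\t")
    ks_d, ks_p = compare_distributions(profile)
    hist = motif_positional_histogram(
        [c.interval for c in clusters], seqs, config.sim.clip.motif,
        window=config.hist_window, bin_width=config.hist_bin,
    )
    pd.DataFrame({"offset": hist.bin_centers, "count": hist.counts,
                  "density": hist.density}).to_csv(
        outdir / "motif_positional_histogram.tsv", sep="\t", index=False
    )
    stage("kmer-enrich", kmers=len(profile), ks_statistic=round(ks_d, 4),
          ks_pvalue=float(ks_p))

    # --- RBNS
    input_lib, pulldowns, rbns_truth = simulate_rbns_pool(config.sim.rbns, seed + 3)
    chosen = select_concentration(list(pulldowns.values()), input_lib, k=config.kmer_k)
    enr_rbns = rbns_r_values(pulldowns[chosen], input_lib, k=config.kmer_k)
    enr_rbns.table.sort_values("R", ascending=False).to_csv(
        outdir / "rbns_enrichment.tsv", sep="\t"
    )
    logos = build_motif_logos(pulldowns[chosen], input_lib, k=config.kmer_k)
    io.write_meme_pwm(logos, outdir / "rbns_logos.meme")
    stage("rbns", concentration_nM=chosen,
          significant_kmers=int(enr_rbns.table["significant"].sum()), logos=len(logos))

    # --- decay
    tc_ctrl, tc_kd, decay_truth = simulate_decay(config.sim.decay, seed + 4)
    tc_ctrl.rpkm.to_csv(outdir / "decay_control.tsv", sep="\t")
    tc_kd.rpkm.to_csv(outdir / "decay_knockdown.tsv", sep="\t")
    fits_ctrl = fit_timecourse(tc_ctrl)
    fits_kd = fit_timecourse(tc_kd)
    fits_ctrl.to_csv(outdir / "decay_fits_control.tsv", sep="\t")
    fits_kd.to_csv(outdir / "decay_fits_knockdown.tsv", sep="\t")
    null = shuffled_null(tc_ctrl, seed + 5)
    calls, unevaluable = classify_stability(fits_kd, fits_ctrl)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        outdir / "stability_calls.tsv", sep="\t", index=False
    )
    n_stab = sum(c.call == "stabilized" for c in calls)
    n_destab = sum(c.call == "destabilized" for c in calls)
    stage("decay", genes=len(tc_ctrl.rpkm),
          included_control=int(fits_ctrl["included"].sum()),
          median_real_r2=round(null["median_real_r2"], 4),
          median_shuffled_r2=round(null["median_shuffled_r2"], 4),
          stabilized=n_stab, destabilized=n_destab, unevaluable=len(unevaluable))

    # --- gene-set statistics
    de_a, de_b, de_truth = simulate_de_tables(config.sim.de, seed + 6)
    de_a.to_csv(outdir / "de_table_a.tsv", sep="\t", index_label="gene")
    de_b.to_csv(outdir / "de_table_b.tsv", sep="\t", index_label="gene")
    up_a, down_a = significant_genes(de_a)
    up_b, down_b = significant_genes(de_b)
    background = set(de_a.index)
    overlap = hypergeom_overlap(up_a | down_a, up_b | down_b, background)
    fisher = fisher_binding_regulation(de_truth["sig_a"], de_truth["sig_b"], background)
    regression = regress_log2_changes(de_a, de_b)
    down_set = {g for g in annotation.genes if g in targets}
    other = set(annotation.genes) - down_set
    intron_cmp = (
        compare_intron_lengths({"targets": down_set, "other": other}, annotation)
        if down_set and other
        else pd.DataFrame()
    )
    intron_cmp.to_csv(outdir / "intron_length_comparison.tsv", sep="\t", index=False)
    rng = np.random.default_rng(seed + 7)
    n_events, n_true = 200, 25
    sep = rng.normal(0, 0.2, n_events)
    qv = rng.uniform(0.05, 1.0, n_events)
    sep[:n_true] = rng.choice([-1, 1], n_true) * rng.uniform(0.6, 2.0, n_true)
    qv[:n_true] = rng.uniform(1e-4, 0.04, n_true)
    events = pd.DataFrame(
        {
            "event_id": [f"ev{i:04d}" for i in range(n_events)],
            "event_type": "cassette",
            "sep_score": sep,
            "q_value": qv,
        }
    )
    kept = filter_splicing_events(events)
    kept.to_csv(outdir / "splicing_significant.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(test="hypergeometric_overlap", statistic=overlap.n_overlap,
                 p_value=overlap.p_value),
            dict(test="fisher_binding_regulation", statistic=fisher.odds_ratio,
                 p_value=fisher.p_value),
            dict(test="regression_slope", statistic=regression.slope,
                 p_value=regression.p_value),
        ]
    ).to_csv(outdir / "geneset_tests.tsv", sep="\t", index=False)
    stage("genesets", sig_a=len(up_a | down_a), sig_b=len(up_b | down_b),
          overlap=overlap.n_overlap, splicing_events_kept=len(kept))

    manifest["input_checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*")) if p.suffix in
        {".gtf", ".fa", ".bed", ".tsv"}
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
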