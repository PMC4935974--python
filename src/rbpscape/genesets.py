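"""Gene-set statistics connecting binding to regulation.

Covers: differential-expression significance filtering, hypergeometric
overlap of gene sets against an expressed background, Fisher's exact test
of binding vs regulation, OLS regression of paired log2 fold changes,
rank-sum comparison of intron lengths between regulated gene classes,
splicing-event filtering on separation scores, and generic (GO-style)
gene-set enrichment with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .intervals import total_length

LFC_THRESHOLD = math.log2(1.5)
PADJ_THRESHOLD = 0.05
SEP_THRESHOLD = 0.5
Q_THRESHOLD = 0.05


def significant_genes(
    de: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated significant genes.

    Significant means |log2FC| >= log2(1.5) and adjusted P < 0.05; genes
    with a missing adjusted P are excluded with a warning.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    missing = de["padj"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} gene(s) lack an adjusted P and were excluded",
            stacklevel=2,
        )
    ok = de[~missing]
    sig = ok[(ok["log2_fold_change"].abs() >= lfc_threshold) & (ok["padj"] < padj_threshold)]
    up = set(sig.index[sig["log2_fold_change"] > 0])
    down = set(sig.index[sig["log2_fold_change"] < 0])
    return up, down


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_background: int
    p_value: float


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], background: Iterable[str]
) -> OverlapResult:
    """Upper-tail hypergeometric P for the overlap of two gene sets drawn
    from a finite background (the expressed genes)."""
    a, b, bg = set(set_a), set(set_b), set(background)
    stray = (a - bg) | (b - bg)
    if stray:
        raise ValueError(f"genes outside the background: {sorted(stray)[:10]}")
    n_ov = len(a & b)
    p = float(stats.hypergeom.sf(n_ov - 1, len(bg), len(a), len(b)))
    return OverlapResult(len(a), len(b), n_ov, len(bg), min(p, 1.0))


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float


def fisher_binding_regulation(
    targets: Iterable[str], regulated: Iterable[str], expressed: Iterable[str]
) -> ContingencyResult:
    """2x2 Fisher's exact test (two-sided) of binding vs regulation over the
    expressed-gene universe: [[target & regulated, target & not],
    [non-target & regulated, non-target & not]]."""
    t, r, e = set(targets), set(regulated), set(expressed)
    if not e:
        raise ValueError("empty expressed-gene universe")
    stray = (t - e) | (r - e)
    if stray:
        raise ValueError(f"genes outside the expressed universe: {sorted(stray)[:10]}")
    a = len(t & r)
    b = len(t - r)
    c = len(r - t)
    d = len(e - t - r)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(((a, b), (c, d)), float(p), float(odds))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_log2_changes(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    restrict: str = "both-significant",
    lfc_threshold: float = LFC_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
) -> RegressionResult:
    """OLS of b's log2 fold change on a's, over shared genes.

    ``restrict="both-significant"`` (the default) keeps only genes
    significant in both tables; ``restrict="all"`` uses every shared gene.
    """
    genes = table_a.index.intersection(table_b.index)
    if restrict == "both-significant":
        up_a, down_a = significant_genes(table_a, lfc_threshold, padj_threshold)
        up_b, down_b = significant_genes(table_b, lfc_threshold, padj_threshold)
        keep = (up_a | down_a) & (up_b | down_b)
        genes = genes.intersection(keep)
    elif restrict != "all":
        raise ValueError("restrict must be 'both-significant' or 'all'")
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} shared genes; need >= 3")
    x = table_a.loc[genes, "log2_fold_change"].values
    y = table_b.loc[genes, "log2_fold_change"].values
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(res.pvalue), len(genes),
    )


def intron_length_table(
    gene_sets: Mapping[str, Iterable[str]], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Summed and maximum intron length per gene, with its set label.
    Intron-less genes get length 0 and are retained."""
    rows = []
    for label, genes in gene_sets.items():
        for gid in genes:
            introns = annotation.genes[gid].introns
            rows.append(
                dict(
                    gene=gid,
                    set=label,
                    total_intron_length=total_length(introns),
                    max_intron_length=max((len(iv) for iv in introns), default=0),
                )
            )
    return pd.DataFrame(rows)


def compare_intron_lengths(
    gene_sets: Mapping[str, Iterable[str]],
    annotation: GenomeAnnotation,
    statistic: str = "total_intron_length",
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of per-gene intron length between every
    pair of gene sets, with medians. Degenerate pairs (all lengths equal)
    are reported with P = NaN."""
    table = intron_length_table(gene_sets, annotation)
    labels = list(gene_sets)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            xa = table.loc[table["set"] == la, statistic].values
            xb = table.loc[table["set"] == lb, statistic].values
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError("gene sets must be non-empty")
            if len(np.unique(np.concatenate([xa, xb]))) == 1:
                stat, p = math.nan, math.nan
            else:
                res = stats.ranksums(xa, xb)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                dict(
                    set_a=la, set_b=lb, statistic=stat, p_value=p,
                    median_a=float(np.median(xa)), median_b=float(np.median(xb)),
                )
            )
    return pd.DataFrame(rows)


def filter_splicing_events(
    events: pd.DataFrame,
    sep_threshold: float = SEP_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Significant splicing events: |Sep| > 0.5 and q < 0.05 (strict), with
    the Sep sign annotated as inclusion (positive) or exclusion."""
    if events.empty:
        raise ValueError("empty splicing-event table")
    kept = events[
        (events["sep_score"].abs() > sep_threshold) & (events["q_value"] < q_threshold)
    ].copy()
    kept["direction"] = np.where(kept["sep_score"] > 0, "inclusion", "exclusion")
    return kept


def geneset_enrichment(
    query: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set in each term.

    Term gene sets are intersected with the background first (empty terms
    are skipped); raw P values are kept and Benjamini-Hochberg q values
    added across terms.
    """
    bg = set(background)
    q = set(query) & bg
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & bg
        if not term_genes:
            continue
        res = hypergeom_overlap(q, term_genes, bg)
        rows.append(
            dict(term=term, n_query=res.n_a, n_term=res.n_b,
                 n_overlap=res.n_overlap, p_value=res.p_value)
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "n_query", "n_term", "n_overlap", "p_value", "q_value"]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df.sort_values("p_value").reset_index(drop=True)
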