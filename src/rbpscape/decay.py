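"""mRNA half-life estimation from transcription-shutoff time courses.

Abundances follow first-order decay N(t) = N(0) exp(-lambda t); a log-linear
ordinary least squares fit of ln(RPKM) on time gives lambda = -slope and
t1/2 = ln(2) / lambda. A gene's fit is included when the decay rate is
positive and the fit's R^2 exceeds 0.6. Quality control compares the real
R^2 distribution with one obtained after shuffling each gene's expression
values across time points (two-sample KS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

R2_THRESHOLD = 0.6
HL_LOG2_THRESHOLD = 1.0
PSEUDOCOUNT_RPKM = 0.01
MIN_T0_RPKM = 1.0


def rpkm(counts, lengths, total_mapped: int):
    """Reads per kilobase of transcript per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return counts * 1e9 / (lengths * total_mapped)


@dataclass
class ExpressionTimeCourse:
    """RPKM matrix (genes x time points) for one Actinomycin-D course."""

    rpkm: pd.DataFrame  # rows genes, columns time points (hours)
    times: tuple[float, ...]
    condition: str = "control"

    def __post_init__(self) -> None:
        self.times = tuple(float(t) for t in self.times)
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("time course must start at t=0")
        if self.rpkm.shape[1] != len(self.times):
            raise ValueError("matrix columns do not match time points")
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be >= 0")


@dataclass
class DecayFit:
    gene: str
    lam: float  # decay rate per hour
    half_life: float  # ln(2)/lambda, hours (inf when lambda <= 0)
    r_squared: float
    included: bool
    reason: str = ""


def fit_decay(
    times: Sequence[float],
    values: Sequence[float],
    gene: str = "",
    pseudocount: float = PSEUDOCOUNT_RPKM,
    max_zeros: int = 1,
    r2_threshold: float = R2_THRESHOLD,
) -> DecayFit:
    """Log-linear OLS decay fit for one gene.

    Zero RPKMs are floored at the pseudocount before the log; genes with
    more than ``max_zeros`` zeros (or fewer than 3 usable points) are marked
    unusable. Inclusion requires lambda > 0 and R^2 > ``r2_threshold``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n_zero = int((values <= 0).sum())
    if n_zero > max_zeros:
        return DecayFit(gene, math.nan, math.nan, math.nan, False, "too many zeros")
    usable = np.isfinite(values)
    if usable.sum() < 3:
        return DecayFit(gene, math.nan, math.nan, math.nan, False, "fewer than 3 points")
    y = np.log(np.maximum(values[usable], pseudocount))
    t = times[usable]
    res = stats.linregress(t, y)
    lam = -res.slope
    r2 = float(res.rvalue**2)
    half_life = math.log(2) / lam if lam > 0 else math.inf
    if lam <= 0:
        return DecayFit(gene, lam, half_life, r2, False, "non-positive decay rate")
    if r2 <= r2_threshold:
        return DecayFit(gene, lam, half_life, r2, False, "poor fit")
    return DecayFit(gene, lam, half_life, r2, True)


def fit_timecourse(
    tc: ExpressionTimeCourse,
    min_t0_rpkm: float = MIN_T0_RPKM,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene decay fits; genes not expressed at t=0 (RPKM <= 1 by
    default) are excluded before fitting."""
    rows = []
    for gene, series in tc.rpkm.iterrows():
        if series.iloc[0] <= min_t0_rpkm:
            rows.append(
                dict(gene=gene, lam=math.nan, half_life=math.nan, r_squared=math.nan,
                     included=False, reason="not expressed at t=0")
            )
            continue
        fit = fit_decay(tc.times, series.values, gene=gene, r2_threshold=r2_threshold)
        rows.append(
            dict(gene=gene, lam=fit.lam, half_life=fit.half_life,
                 r_squared=fit.r_squared, included=fit.included, reason=fit.reason)
        )
    return pd.DataFrame(rows).set_index("gene")


def shuffled_null(
    tc: ExpressionTimeCourse,
    seed: int,
    min_t0_rpkm: float = MIN_T0_RPKM,
) -> dict:
    """Shuffle each gene's expression values across time points (seeded,
    uniform permutation) and compare real vs shuffled R^2 by two-sample KS.

    R^2 values are collected from every fittable gene regardless of the
    inclusion filters, since the comparison is about fit quality itself.
    """
    rng = np.random.default_rng(seed)
    real_r2, shuf_r2 = [], []
    for gene, series in tc.rpkm.iterrows():
        values = series.values
        if values[0] <= min_t0_rpkm:
            continue
        fit = fit_decay(tc.times, values, gene=gene)
        if not math.isfinite(fit.r_squared):
            continue
        shuffled = values[rng.permutation(len(values))]
        sfit = fit_decay(tc.times, shuffled, gene=gene)
        if not math.isfinite(sfit.r_squared):
            continue
        real_r2.append(fit.r_squared)
        shuf_r2.append(sfit.r_squared)
    ks = stats.ks_2samp(real_r2, shuf_r2, alternative="two-sided")
    return {
        "real_r2": np.array(real_r2),
        "shuffled_r2": np.array(shuf_r2),
        "median_real_r2": float(np.median(real_r2)),
        "median_shuffled_r2": float(np.median(shuf_r2)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


@dataclass
class StabilityCall:
    gene: str
    log2_hl_change: float  # log2(t1/2 knockdown / t1/2 control)
    call: str  # stabilized | destabilized | unchanged


def classify_stability(
    fits_kd: pd.DataFrame,
    fits_ctrl: pd.DataFrame,
    threshold: float = HL_LOG2_THRESHOLD,
) -> tuple[list[StabilityCall], list[str]]:
    """Stability calls from paired half-lives.

    A gene is stabilized when log2(kd/ctrl half-life) > threshold,
    destabilized below -threshold, else unchanged; genes failing the
    inclusion filter in either condition are returned as unevaluable.
    """
    calls: list[StabilityCall] = []
    unevaluable: list[str] = []
    for gene in fits_kd.index.union(fits_ctrl.index):
        in_kd = gene in fits_kd.index and bool(fits_kd.loc[gene, "included"])
        in_ctrl = gene in fits_ctrl.index and bool(fits_ctrl.loc[gene, "included"])
        if not (in_kd and in_ctrl):
            unevaluable.append(gene)
            continue
        change = math.log2(
            fits_kd.loc[gene, "half_life"] / fits_ctrl.loc[gene, "half_life"]
        )
        if change > threshold:
            call = "stabilized"
        elif change < -threshold:
            call = "destabilized"
        else:
            call = "unchanged"
        calls.append(StabilityCall(gene, change, call))
    return calls, unevaluable
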