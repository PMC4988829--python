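"""Tail-length / translational-efficiency coupling statistics.

Rank correlations use Spearman's rho with average-rank tie handling; the
binned summary reports per-bin medians of centered log2 TE over fixed-width
tail bins and the linear fold ratio between two named bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, CorrelationError

DEFAULT_BIN_WIDTH = 10
DEFAULT_RATIO_BINS = ((70, 80), (30, 40))


@dataclass(frozen=True)
class BinMedian:
    lo: float
    hi: float
    median_log2_te: float
    n: int
    low_n: bool


@dataclass(frozen=True)
class CouplingResult:
    label: str
    r_s: float
    n_genes: int
    bin_medians: tuple[BinMedian, ...] = ()
    bin_ratio: Optional[float] = None
    dropouts: tuple[str, ...] = ()


def rank_correlation(x, y) -> tuple[float, int]:
    """Spearman rho and the number of paired points used.

    Raises :class:`CorrelationError` for n < 3 or zero variance in either
    argument (undefined correlation).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ConfigError("x and y must be paired over the same genes")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    n = xa.size
    if n < 3:
        raise CorrelationError(f"need >= 3 paired values, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise CorrelationError("zero variance: correlation undefined")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho), int(n)


def binned_median_te(
    tails: pd.Series,
    te: pd.Series,
    bin_width: int = DEFAULT_BIN_WIDTH,
    *,
    min_bin_n: int = 10,
    ratio_bins: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_RATIO_BINS,
    label: str = "",
) -> CouplingResult:
    """Median centered log2 TE within half-open tail bins anchored at 0.

    ``bin_ratio`` is the linear fold ratio 2**(median[hi bin] - median[lo bin])
    between the two ``ratio_bins``; it is None when either named bin is empty.
    """
    genes = tails.index.intersection(te.index)
    t = tails.loc[genes].to_numpy(dtype=float)
    v = te.loc[genes].to_numpy(dtype=float)
    r_s, n = rank_correlation(t, v)
    top = int(np.floor(t.max() / bin_width)) + 1
    medians = []
    named: dict[tuple[int, int], float] = {}
    for i in range(top):
        lo, hi = i * bin_width, (i + 1) * bin_width
        inbin = (t >= lo) & (t < hi)
        k = int(inbin.sum())
        if k == 0:
            continue
        med = float(np.median(v[inbin]))
        medians.append(BinMedian(lo, hi, med, k, k < min_bin_n))
        named[(lo, hi)] = med
    (hi_bin, lo_bin) = ratio_bins
    ratio = None
    if tuple(hi_bin) in named and tuple(lo_bin) in named:
        ratio = float(2.0 ** (named[tuple(hi_bin)] - named[tuple(lo_bin)]))
    return CouplingResult(
        label=label,
        r_s=r_s,
        n_genes=n,
        bin_medians=tuple(medians),
        bin_ratio=ratio,
    )


def change_coupling(
    changes: pd.DataFrame,
    scale: str = "relative",
    *,
    label: str = "",
) -> CouplingResult:
    """Rank correlation of centered TE changes against tail changes.

    ``scale`` selects log2 fold tail changes ('relative') or absolute nt
    differences of mean tails ('absolute').
    """
    if scale == "relative":
        tail_col = "log2_fc_tail"
    elif scale == "absolute":
        tail_col = "delta_tail_nt"
    else:
        raise ConfigError(f"unknown scale {scale!r}")
    r_s, n = rank_correlation(changes[tail_col], changes["log2_fc_te"])
    return CouplingResult(label=label, r_s=r_s, n_genes=n)


def abundance_tail_bias(
    rna_rpm: pd.Series,
    tails: pd.Series,
    *,
    label: str = "",
) -> CouplingResult:
    """Rank correlation between measured RNA abundance and mean tail length.

    A materially positive correlation flags poly(A)-selection bias in the
    RNA-seq measurements.
    """
    genes = rna_rpm.index.intersection(tails.index)
    r_s, n = rank_correlation(
        rna_rpm.loc[genes].to_numpy(), tails.loc[genes].to_numpy()
    )
    return CouplingResult(label=label, r_s=r_s, n_genes=n)
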