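"""Genotype-contrast analyses: dependent-set calling, tail-shortening census,
and gene-set shift tests.

The set-shift test is a Wilcoxon rank-sum of a gene set against its
complement with average-rank ties.  The null is enumerated exactly (dynamic
programming over the rank-sum distribution) when the smaller group has at
most 8 members and the cohort is small enough; otherwise a normal
approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import CouplingResult, rank_correlation
from .errors import ConfigError

EXACT_MIN_GROUP = 8
EXACT_MAX_COHORT = 200


@dataclass(frozen=True)
class RegulatedSets:
    up_ids: frozenset[str]
    down_ids: frozenset[str]
    fold_threshold: float
    comparisons: tuple[str, str]
    dropped: int = 0


@dataclass(frozen=True)
class SetShiftResult:
    set_id: str
    metric: str
    set_median: float
    cohort_median: float
    p_value: float
    sidedness: str
    alternative: str
    n_set: int
    n_rest: int
    method: str


@dataclass(frozen=True)
class ShorteningCensus:
    n_measured: int
    n_shortened: int
    fraction: float
    table: pd.DataFrame


def define_dependent_sets(
    fc_pair_a: pd.Series,
    fc_pair_b: pd.Series,
    threshold_log2: float = 2.0,
    *,
    comparisons: tuple[str, str] = ("pairA", "pairB"),
) -> RegulatedSets:
    """Genes at least ``2**threshold_log2``-fold up or down in both comparisons.

    Inputs are median-centered log2 TE changes; membership requires passing
    the pairwise cutoffs upstream (the inputs only contain passing genes).
    Mismatched gene universes are restricted to the intersection.
    """
    common = fc_pair_a.index.intersection(fc_pair_b.index)
    dropped = (len(fc_pair_a) - len(common)) + (len(fc_pair_b) - len(common))
    a = fc_pair_a.loc[common]
    b = fc_pair_b.loc[common]
    up = frozenset(common[(a >= threshold_log2) & (b >= threshold_log2)])
    down = frozenset(common[(a <= -threshold_log2) & (b <= -threshold_log2)])
    return RegulatedSets(
        up_ids=up,
        down_ids=down,
        fold_threshold=2.0**threshold_log2,
        comparisons=comparisons,
        dropped=dropped,
    )


def fraction_tail_shortened(
    wt_tails: pd.DataFrame,
    mut_tails: pd.DataFrame,
    fraction: float = 0.5,
    *,
    min_tags: int = 100,
) -> ShorteningCensus:
    """Census of genes whose mutant mean tail is >= ``fraction`` shorter.

    The universe is genes with at least ``min_tags`` tags in both samples;
    comparisons use raw (un-floored) means and the boundary is inclusive.
    """
    common = wt_tails.index.intersection(mut_tails.index)
    universe = common[
        (wt_tails.loc[common, "tag_count"] >= min_tags)
        & (mut_tails.loc[common, "tag_count"] >= min_tags)
    ]
    wt = wt_tails.loc[universe, "mean_tail_nt"]
    mut = mut_tails.loc[universe, "mean_tail_nt"]
    shortened = mut <= (1.0 - fraction) * wt
    table = pd.DataFrame(
        {"wt_mean_nt": wt, "mut_mean_nt": mut, "shortened": shortened}
    )
    table.index.name = "gene_id"
    return ShorteningCensus(
        n_measured=int(len(universe)),
        n_shortened=int(shortened.sum()),
        fraction=fraction,
        table=table.sort_index(),
    )


def _exact_ranksum_pvalues(
    values: np.ndarray, in_set: np.ndarray
) -> tuple[float, float]:
    """P(W >= w_obs) and P(W <= w_obs) over all equally likely subsets.

    W is the rank-sum (average ranks) of the set.  Counts are accumulated by
    dynamic programming over doubled ranks (integers even with ties); float64
    holds them exactly for the sizes admitted here.
    """
    ranks = stats.rankdata(values)
    r2 = np.rint(2 * ranks).astype(int)
    k = int(in_set.sum())
    w_obs = int(r2[in_set].sum())
    max_sum = int(np.sort(r2)[-k:].sum())
    # ways[j, s]: subsets of size j with doubled-rank sum s
    ways = np.zeros((k + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in r2:
        for j in range(min(k, 1_000_000), 0, -1):
            ways[j, r:] += ways[j - 1, : max_sum + 1 - r]
    total = ways[k].sum()
    p_ge = float(ways[k, w_obs:].sum() / total)
    p_le = float(ways[k, : w_obs + 1].sum() / total)
    return p_ge, p_le


def _approx_ranksum_pvalues(
    values: np.ndarray, in_set: np.ndarray
) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    ranks = stats.rankdata(values)
    n = len(values)
    k = int(in_set.sum())
    w = float(ranks[in_set].sum())
    mu = k * (n + 1) / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    var = k * (n - k) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0, 1.0
    sd = np.sqrt(var)
    p_ge = float(stats.norm.sf((w - mu - 0.5) / sd))
    p_le = float(stats.norm.cdf((w - mu + 0.5) / sd))
    return p_ge, p_le


def set_shift_test(
    values: pd.Series,
    set_ids: Iterable[str],
    sidedness: str = "one-tailed",
    alternative_direction: str = "greater",
    *,
    set_id: str = "set",
    metric: str = "value",
) -> SetShiftResult:
    """Rank-sum test of a gene set against its complement.

    ``alternative_direction`` ('greater'/'less') states the one-tailed
    alternative for the set's values; the two-tailed p doubles the smaller
    tail and is capped at 1.  Set and cohort medians are reported so shifts
    can be read "relative to the median of all mRNAs".
    """
    if sidedness not in ("one-tailed", "two-tailed"):
        raise ConfigError(f"unknown sidedness {sidedness!r}")
    if alternative_direction not in ("greater", "less"):
        raise ConfigError(f"unknown direction {alternative_direction!r}")
    members = sorted(set(set_ids) & set(values.index))
    if not members:
        raise ConfigError("gene set is empty within the cohort")
    if len(members) == len(values):
        raise ConfigError("gene set equals the whole cohort")
    vals = values.to_numpy(dtype=float)
    in_set = values.index.isin(members)
    k, n = int(in_set.sum()), len(vals)
    if min(k, n - k) <= EXACT_MIN_GROUP and n <= EXACT_MAX_COHORT:
        p_ge, p_le = _exact_ranksum_pvalues(vals, in_set)
        method = "exact"
    else:
        p_ge, p_le = _approx_ranksum_pvalues(vals, in_set)
        method = "normal-approx"
    if sidedness == "one-tailed":
        p = p_ge if alternative_direction == "greater" else p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return SetShiftResult(
        set_id=set_id,
        metric=metric,
        set_median=float(np.median(vals[in_set])),
        cohort_median=float(np.median(vals)),
        p_value=float(p),
        sidedness=sidedness,
        alternative=alternative_direction,
        n_set=k,
        n_rest=n - k,
        method=method,
    )


def geneset_tail_ratio_test(
    wt_tails: pd.DataFrame,
    mut_tails: pd.DataFrame,
    geneset_ids: Iterable[str],
    *,
    min_tags: int = 100,
    set_id: str = "geneset",
) -> SetShiftResult:
    """One-tailed test that a gene set's tails are less shortened than the rest.

    The per-gene metric is log2(mut mean / wt mean) over the >= ``min_tags``
    universe; genes with a zero wild-type mean are excluded (undefined ratio).
    """
    census = fraction_tail_shortened(wt_tails, mut_tails, min_tags=min_tags)
    tab = census.table
    tab = tab[tab["wt_mean_nt"] > 0]
    ratios = pd.Series(
        np.log2(tab["mut_mean_nt"] / tab["wt_mean_nt"]), index=tab.index
    )
    return set_shift_test(
        ratios,
        geneset_ids,
        sidedness="one-tailed",
        alternative_direction="greater",
        set_id=set_id,
        metric="log2_tail_ratio",
    )


def rpf_concordance(
    rpf_rpm_a: pd.Series,
    rpf_rpm_b: pd.Series,
    counts_a: pd.Series,
    counts_b: pd.Series,
    *,
    totals: tuple[float, float],
    pseudocount: float = 1.0,
    min_rpm_either: float = 10.0,
    label: str = "rpf-concordance",
) -> CouplingResult:
    """Footprint agreement between two samples with pseudocounted zeros.

    Over genes with >= ``min_rpm_either`` RPM in either sample, any gene with
    0 reads in a sample gets a ``pseudocount``-read RPM there; genes with 0
    reads in exactly one sample are listed as dropouts.
    """
    common = rpf_rpm_a.index.intersection(rpf_rpm_b.index)
    a = rpf_rpm_a.loc[common].astype(float).copy()
    b = rpf_rpm_b.loc[common].astype(float).copy()
    ca = counts_a.loc[common]
    cb = counts_b.loc[common]
    keep = (a >= min_rpm_either) | (b >= min_rpm_either)
    a, b, ca, cb = a[keep], b[keep], ca[keep], cb[keep]
    a[ca == 0] = pseudocount / totals[0] * 1e6
    b[cb == 0] = pseudocount / totals[1] * 1e6
    dropouts = tuple(sorted(a.index[(ca == 0) != (cb == 0)]))
    r_s, n = rank_correlation(a.to_numpy(), b.to_numpy())
    return CouplingResult(label=label, r_s=r_s, n_genes=n, dropouts=dropouts)
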