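"""Model-profile clustering of short TE time series.

Gene trajectories (centered log2 TE per stage, re-referenced to the first
stage) are assigned to an exhaustively enumerated set of integer model
profiles with bounded per-step change, and per-profile enrichment is scored
against a per-gene stage-permutation null with a binomial tail and a
Bonferroni correction.  The permutation/binomial scheme is this package's
defined surrogate for the significance rule of profile-clustering tools whose
internals are not restated here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

ELIGIBILITY_LOG2 = 0.5
ALPHA = 0.05
EXHAUSTIVE_T_MAX = 6
SAMPLED_PERMUTATIONS = 200


@dataclass(frozen=True)
class ModelProfile:
    id: int
    values: tuple[int, ...]

    @property
    def is_flat(self) -> bool:
        return all(v == self.values[0] for v in self.values)


@dataclass(frozen=True)
class ClusterAssignment:
    gene_id: str
    normalized: tuple[float, ...]
    profile_id: Optional[int]
    correlation: Optional[float]
    eligible: bool


@dataclass(frozen=True)
class ProfileEnrichment:
    profile_id: int
    observed: int
    expected: float
    p_raw: float
    p_adjusted: float
    significant: bool


def enumerate_model_profiles(T: int, c: int = 1) -> list[ModelProfile]:
    """All integer profiles of length T starting at 0 with steps in [-c, c].

    There are (2c+1)**(T-1) of them, ordered lexicographically by step vector.
    """
    if T < 2:
        raise ConfigError(f"T must be >= 2, got {T}")
    if c < 1:
        raise ConfigError(f"c must be >= 1, got {c}")
    steps = range(-c, c + 1)
    profiles = []
    for i, step_vec in enumerate(itertools.product(steps, repeat=T - 1)):
        vals = [0]
        for s in step_vec:
            vals.append(vals[-1] + s)
        profiles.append(ModelProfile(id=i, values=tuple(vals)))
    return profiles


def normalize_trajectories(
    te: pd.DataFrame, reference: Optional[str] = None
) -> pd.DataFrame:
    """Subtract the first-stage value from each gene's trajectory.

    ``te`` holds centered log2 TE with genes as rows and stages as (ordered)
    columns; ``reference`` defaults to the first column.  Genes with any
    missing stage are excluded.
    """
    if te.shape[1] < 2:
        raise ConfigError("need >= 2 stages to normalize trajectories")
    ref = te.columns[0] if reference is None else reference
    complete = te.dropna(axis=0)
    return complete.sub(complete[ref], axis=0)


def _is_eligible(vec: np.ndarray, threshold: float) -> bool:
    return float(vec.max() - vec.min()) >= threshold


def _best_profile(
    vec: np.ndarray, matrix: np.ndarray, ids: np.ndarray
) -> tuple[int, float]:
    """Profile id maximizing Pearson correlation with ``vec``; ties -> lowest id."""
    v = vec - vec.mean()
    sv = np.sqrt((v * v).sum())
    m = matrix - matrix.mean(axis=1, keepdims=True)
    sm = np.sqrt((m * m).sum(axis=1))
    corr = (m @ v) / (sm * sv)
    best = int(np.argmax(corr))  # argmax takes the first (lowest id) on ties
    return int(ids[best]), float(corr[best])


def assign_profiles(
    normalized: pd.DataFrame,
    profiles: Sequence[ModelProfile],
    *,
    eligibility_log2: float = ELIGIBILITY_LOG2,
) -> list[ClusterAssignment]:
    """Assign each eligible gene trajectory to its best-correlated profile.

    Eligibility requires a max-minus-min spread of at least
    ``eligibility_log2`` across stages (so flat trajectories never enter).
    Flat profiles have undefined correlation and are unassignable.
    """
    usable = [p for p in profiles if not p.is_flat]
    if not usable:
        raise ConfigError("no non-flat profiles to assign to")
    matrix = np.array([p.values for p in usable], dtype=float)
    ids = np.array([p.id for p in usable])
    out = []
    for gene_id, row in normalized.iterrows():
        vec = row.to_numpy(dtype=float)
        if not _is_eligible(vec, eligibility_log2):
            out.append(
                ClusterAssignment(str(gene_id), tuple(vec), None, None, False)
            )
            continue
        pid, corr = _best_profile(vec, matrix, ids)
        out.append(ClusterAssignment(str(gene_id), tuple(vec), pid, corr, True))
    return out


def profile_significance(
    assignments: Sequence[ClusterAssignment],
    profiles: Sequence[ModelProfile],
    stage_values: pd.DataFrame,
    *,
    rng: Optional[np.random.Generator] = None,
    eligibility_log2: float = ELIGIBILITY_LOG2,
    alpha: float = ALPHA,
) -> list[ProfileEnrichment]:
    """Per-profile enrichment against a per-gene stage-permutation null.

    For each eligible gene, every ordering of its (pre-normalization) stage
    values is re-referenced to its first entry and re-assigned; the expected
    size of a profile is the summed per-gene assignment fraction.  p_raw is
    the upper binomial tail of observing at least the actual cluster size
    among the eligible genes, Bonferroni-corrected over the assignable
    profiles.  Orderings are exhaustive for T <= 6, else sampled (seeded
    ``rng`` required).
    """
    eligible = [a for a in assignments if a.eligible]
    if not eligible:
        return []
    usable = [p for p in profiles if not p.is_flat]
    matrix = np.array([p.values for p in usable], dtype=float)
    ids = np.array([p.id for p in usable])
    T = matrix.shape[1]
    if T <= EXHAUSTIVE_T_MAX:
        orderings = list(itertools.permutations(range(T)))
    else:
        if rng is None:
            raise ConfigError("rng required for sampled permutations (T > 6)")
        orderings = [tuple(rng.permutation(T)) for _ in range(SAMPLED_PERMUTATIONS)]

    expected = {int(p.id): 0.0 for p in usable}
    for a in eligible:
        vals = stage_values.loc[a.gene_id].to_numpy(dtype=float)
        hits = {int(p.id): 0 for p in usable}
        for order in orderings:
            w = vals[list(order)]
            w = w - w[0]
            if not _is_eligible(w, eligibility_log2):
                continue  # unreachable: the spread is permutation-invariant
            pid, _ = _best_profile(w, matrix, ids)
            hits[pid] += 1
        for pid, k in hits.items():
            expected[pid] += k / len(orderings)

    n = len(eligible)
    observed = {int(p.id): 0 for p in usable}
    for a in eligible:
        observed[int(a.profile_id)] += 1
    n_tests = len(usable)
    out = []
    for p in usable:
        pid = int(p.id)
        prob = min(expected[pid] / n, 1.0)
        p_raw = float(stats.binom.sf(observed[pid] - 1, n, prob)) if observed[
            pid
        ] > 0 else 1.0
        p_adj = min(1.0, p_raw * n_tests)
        out.append(
            ProfileEnrichment(
                profile_id=pid,
                observed=observed[pid],
                expected=expected[pid],
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def cluster_report(
    assignments: Sequence[ClusterAssignment],
    enrichments: Sequence[ProfileEnrichment],
) -> pd.DataFrame:
    """Per-profile membership table ordered by profile id."""
    members: dict[int, list[str]] = {}
    for a in assignments:
        if a.eligible:
            members.setdefault(int(a.profile_id), []).append(a.gene_id)
    rows = []
    for e in sorted(enrichments, key=lambda e: e.profile_id):
        genes = sorted(members.get(e.profile_id, []))
        rows.append(
            {
                "profile_id": e.profile_id,
                "size": e.observed,
                "expected": e.expected,
                "p_raw": e.p_raw,
                "p_adjusted": e.p_adjusted,
                "significant": e.significant,
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "profile_id",
            "size",
            "expected",
            "p_raw",
            "p_adjusted",
            "significant",
            "genes",
        ],
    )
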