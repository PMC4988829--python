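"""Per-gene tail summaries, RPM/RPKM, translational efficiency, and change tables.

All log quantities are base 2.  Even-length medians use the midpoint
convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .gene_models import GeneModel

TAIL_BIN_WIDTH = 5
REPORTED_MEAN_FLOOR = 4.0
LOW_EVIDENCE_RPF = 25
UNRELIABLE_TAIL_NT = 8.0


@dataclass(frozen=True)
class TailSummary:
    """Aggregate of all tail-length measurements assigned to one gene in one sample."""

    gene_id: str
    sample_id: str
    tag_count: int
    mean_tail_nt: float
    histogram: tuple[int, ...]
    bin_width: int = TAIL_BIN_WIDTH

    @property
    def reported_mean_nt(self) -> float:
        return max(self.mean_tail_nt, REPORTED_MEAN_FLOOR)


@dataclass(frozen=True)
class TERecord:
    gene_id: str
    sample_id: str
    log2_te: float
    pseudocount_used: bool
    low_evidence: bool
    centered_log2_te: Optional[float] = None
    sample_median_log2: Optional[float] = None


def assign_tags_to_genes(
    tags: pd.DataFrame,
    models: Sequence[GeneModel],
    tolerance_nt: int = 10,
) -> pd.DataFrame:
    """Assign each tag to the gene owning the nearest isoform end.

    A tag matches a model if it lies on the same chromosome and strand and
    within ``tolerance_nt`` of one of the model's isoform ends (or its final
    3' end when no re-annotated ends exist).  Returns the tag table with a
    ``gene_id`` column; unassignable tags are dropped.
    """
    targets: list[tuple[str, str, int, str]] = []
    for m in models:
        if m.excluded:
            continue
        ends = [e.position for e in m.isoform_ends]
        if not ends and m.final_3p_end is not None:
            ends = [m.final_3p_end]
        for pos in ends:
            targets.append((m.transcript.chrom, m.strand, pos, m.gene_id))
    out_rows = []
    by_key: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for chrom, strand, pos, gid in targets:
        by_key.setdefault((chrom, strand), []).append((pos, gid))
    for key in by_key:
        by_key[key].sort()
    for row in tags.itertuples(index=False):
        cands = by_key.get((row.chrom, row.strand), ())
        best = None
        for pos, gid in cands:
            d = abs(pos - row.site)
            if d <= tolerance_nt and (best is None or d < best[0]):
                best = (d, gid)
        if best is not None:
            out_rows.append(tuple(row) + (best[1],))
    cols = list(tags.columns) + ["gene_id"]
    if "gene_id" in tags.columns:
        raise SchemaError("tag table already carries a gene_id column")
    return pd.DataFrame(out_rows, columns=cols)


def summarize_tails(
    tags: pd.DataFrame,
    sample_id: str,
    *,
    bin_width: int = TAIL_BIN_WIDTH,
) -> list[TailSummary]:
    """Pool tail lengths per gene (across tandem isoform ends) into summaries.

    ``tags`` must carry ``gene_id`` and ``tail_length`` columns.  Genes with
    zero tags yield no record.
    """
    for col in ("gene_id", "tail_length"):
        if col not in tags.columns:
            raise SchemaError(f"tag table missing required column {col!r}")
    out = []
    for gene_id, grp in tags.groupby("gene_id", sort=True):
        tails = grp["tail_length"].to_numpy(dtype=float)
        if tails.size == 0:
            continue
        nbins = int(np.floor(tails.max() / bin_width)) + 1
        hist, _ = np.histogram(
            tails, bins=np.arange(0, (nbins + 1) * bin_width, bin_width)
        )
        out.append(
            TailSummary(
                gene_id=str(gene_id),
                sample_id=sample_id,
                tag_count=int(tails.size),
                mean_tail_nt=float(tails.mean()),
                histogram=tuple(int(h) for h in hist),
                bin_width=bin_width,
            )
        )
    return out


def tail_frame(summaries: Iterable[TailSummary]) -> pd.DataFrame:
    """Tabulate summaries: index gene_id, columns tag_count / mean_tail_nt / reported_mean_nt."""
    rows = {
        s.gene_id: (s.tag_count, s.mean_tail_nt, s.reported_mean_nt)
        for s in summaries
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["tag_count", "mean_tail_nt", "reported_mean_nt"]
    )
    df.index.name = "gene_id"
    return df.sort_index()


def normalize_expression(
    counts: pd.DataFrame,
    totals: Mapping[str, float],
    orf_lengths: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Compute RPM and RPKM from raw counts and mapped-read totals.

    ``counts`` is indexed by gene_id with ``rna_count`` and ``rpf_count``
    columns; ``totals`` maps assay name ('rna', 'rpf') to the mapped-read
    total for the sample (not necessarily the per-gene sum).  ORF lengths are
    in nt with any upstream exclusion already applied.
    """
    for assay in ("rna", "rpf"):
        if assay not in totals:
            raise ConfigError(f"totals missing assay {assay!r}")
        if totals[assay] <= 0:
            raise ConfigError(f"mapped-read total for {assay!r} must be > 0")
    lengths = pd.Series(orf_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:3].tolist()
        raise SchemaError(f"ORF length missing for genes {missing}")
    if (lengths <= 0).any():
        raise ConfigError("orf_lengths must be > 0")
    out = counts.copy()
    out["rna_rpm"] = out["rna_count"] / totals["rna"] * 1e6
    out["rpf_rpm"] = out["rpf_count"] / totals["rpf"] * 1e6
    out["rna_rpkm"] = out["rna_rpm"] * 1e3 / lengths
    out.attrs["totals"] = dict(totals)
    return out


def compute_te(
    rpf_rpm: float,
    rna_rpm: float,
    rpf_count: int,
    *,
    rpf_total: float,
    gene_id: str = "",
    sample_id: str = "",
    low_evidence_threshold: int = LOW_EVIDENCE_RPF,
) -> TERecord:
    """log2(TE) for one gene; a zero RPF count falls back to a 1-read pseudocount."""
    if rna_rpm <= 0:
        raise ConfigError(f"rna_rpm must be > 0 for TE (gene {gene_id!r})")
    pseudo = rpf_count == 0
    if pseudo:
        rpf_rpm = 1.0 / rpf_total * 1e6
    return TERecord(
        gene_id=gene_id,
        sample_id=sample_id,
        log2_te=math.log2(rpf_rpm / rna_rpm),
        pseudocount_used=pseudo,
        low_evidence=rpf_count < low_evidence_threshold,
    )


def te_table(
    expr: pd.DataFrame,
    *,
    rpf_total: float,
    sample_id: str = "",
    rna_rpm: Optional[pd.Series] = None,
    low_evidence_threshold: int = LOW_EVIDENCE_RPF,
) -> pd.DataFrame:
    """Vectorized TE over an expression table.

    ``rna_rpm`` overrides the table's own RNA column; this is the hybrid mode
    in which mutant footprint data is divided by wild-type RNA-seq data.
    Genes with non-positive RNA RPM are dropped.
    """
    rna = expr["rna_rpm"] if rna_rpm is None else rna_rpm.reindex(expr.index)
    rpf_rpm = expr["rpf_rpm"].copy()
    pseudo = expr["rpf_count"] == 0
    rpf_rpm[pseudo] = 1.0 / rpf_total * 1e6
    keep = rna > 0
    df = pd.DataFrame(
        {
            "log2_te": np.log2(rpf_rpm[keep] / rna[keep]),
            "pseudocount_used": pseudo[keep],
            "low_evidence": expr.loc[keep, "rpf_count"] < low_evidence_threshold,
        }
    )
    df.attrs["sample_id"] = sample_id
    return df


def median_center(
    values: pd.Series | Mapping[str, float],
    centering_set: Iterable[str],
) -> tuple[pd.Series, float]:
    """Subtract the median over ``centering_set`` from every value.

    Returns the shifted series and the centering constant.  The median of the
    centered values over the centering set is 0 (midpoint convention for even
    counts).
    """
    series = pd.Series(values, dtype=float)
    ids = [g for g in centering_set if g in series.index]
    if not ids:
        raise ConfigError("centering_set is empty or disjoint from the values")
    constant = float(series.loc[ids].median())
    return series - constant, constant


def apply_cutoffs(
    mode: str,
    rna_rpm: pd.DataFrame,
    rpf_rpm: pd.DataFrame,
    tag_counts: Optional[pd.DataFrame] = None,
    *,
    min_tags: int = 100,
    min_rna_rpm: float = 10.0,
    min_rpf_rpm: float = 10.0,
) -> set[str]:
    """Gene set passing the stage-appropriate quantification cutoffs.

    single (1 sample): >= min_tags tags, >= min_rna_rpm RNA RPM, > 0 RPF RPM.
    pairwise (2 samples): tags and RNA cutoffs in both; RPF >= min_rpf_rpm in
    one of the two and > 0 in the other.
    multistage (>=2 samples): RNA cutoff in all; RPF >= min_rpf_rpm in at
    least one and > 0 in all others.  Tag cutoffs apply only when a tag-count
    table is supplied.
    """
    n = rna_rpm.shape[1]
    if list(rna_rpm.columns) != list(rpf_rpm.columns):
        raise ConfigError("rna_rpm and rpf_rpm must cover the same samples")
    if mode == "single":
        if n != 1:
            raise ConfigError(f"single mode needs exactly 1 sample, got {n}")
        ok = (rna_rpm.iloc[:, 0] >= min_rna_rpm) & (rpf_rpm.iloc[:, 0] > 0)
    elif mode == "pairwise":
        if n != 2:
            raise ConfigError(f"pairwise mode needs exactly 2 samples, got {n}")
        a, b = rpf_rpm.iloc[:, 0], rpf_rpm.iloc[:, 1]
        ok = (rna_rpm >= min_rna_rpm).all(axis=1) & (
            ((a >= min_rpf_rpm) & (b > 0)) | ((b >= min_rpf_rpm) & (a > 0))
        )
    elif mode == "multistage":
        if n < 2:
            raise ConfigError(f"multistage mode needs >= 2 samples, got {n}")
        ok = (
            (rna_rpm >= min_rna_rpm).all(axis=1)
            & (rpf_rpm >= min_rpf_rpm).any(axis=1)
            & (rpf_rpm > 0).all(axis=1)
        )
    else:
        raise ConfigError(f"unknown cutoff mode {mode!r}")
    if tag_counts is not None:
        filled = tag_counts.reindex(ok.index).fillna(0)
        ok &= (filled >= min_tags).all(axis=1)
    return set(ok.index[ok])


def compute_fold_changes(
    te_a: pd.Series,
    te_b: pd.Series,
    tails_a: pd.Series,
    tails_b: pd.Series,
    passing: Iterable[str],
    *,
    stage_pair: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Between-stage change table over the cutoff-passing gene set.

    TE log2 fold changes (B minus A, on uncentered log2 TE) are median
    centered over the passing set; tail log2 fold changes and absolute tail
    differences are reported raw, with the cohort median tail change recorded
    in ``attrs`` alongside the TE centering constant.  Tail changes for genes
    whose raw mean tail is below 8 nt at either stage are flagged unreliable.
    """
    genes = sorted(
        set(passing)
        & set(te_a.index)
        & set(te_b.index)
        & set(tails_a.index)
        & set(tails_b.index)
    )
    if not genes:
        raise ConfigError("no genes pass cutoffs in both stages")
    fc_te_raw = te_b.loc[genes] - te_a.loc[genes]
    fc_te, constant = median_center(fc_te_raw, genes)
    ta, tb = tails_a.loc[genes], tails_b.loc[genes]
    fc_tail = np.log2(tb / ta)
    df = pd.DataFrame(
        {
            "log2_fc_te": fc_te,
            "log2_fc_tail": fc_tail,
            "delta_tail_nt": tb - ta,
            "unreliable_tail": (ta < UNRELIABLE_TAIL_NT) | (tb < UNRELIABLE_TAIL_NT),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df.attrs["stage_pair"] = stage_pair
    df.attrs["te_centering_constant"] = constant
    df.attrs["tail_fc_cohort_median"] = float(np.median(fc_tail))
    return df
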