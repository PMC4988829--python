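"""End-to-end pipeline stages over a fixture directory.

A fixture is the on-disk layout produced by :func:`tailte.io.write_fixture`
(or user-supplied tables in the same dialects): tag tables, a long count
table, gene lengths, library sizes and a manifest giving stage order and
sample naming.  Each stage function is pure given the loaded fixture; the
``run_all`` driver writes every output table plus a run log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import contrasts as contrasts_mod
from . import coupling as coupling_mod
from . import dynamics as dynamics_mod
from . import io as io_mod
from . import quantify as quantify_mod
from .errors import ConfigError
from .gene_models import (
    GeneModel,
    Transcript,
    call_cleavage_sites,
    collapse_tandem_isoforms,
    filter_polya_tags,
    finalize_3p_end,
    select_representative_models,
)
from .synthetic import sample_id_for


@dataclass
class SampleQuant:
    sample: str
    tails: pd.DataFrame  # index gene_id: tag_count, mean_tail_nt, reported_mean_nt
    expr: pd.DataFrame  # index gene_id: counts + rpm/rpkm columns
    totals: dict[str, float]


@dataclass
class Fixture:
    manifest: dict[str, str]
    genes: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.DataFrame
    tags: dict[str, pd.DataFrame]

    @property
    def stages(self) -> list[str]:
        return self.manifest["stages"].split(",")

    @property
    def genotypes(self) -> list[str]:
        return self.manifest["genotypes"].split(",")

    @property
    def samples(self) -> list[str]:
        return self.manifest["samples"].split(",")


def fixture_from_dataset(dataset) -> Fixture:
    """Wrap an in-memory simulated dataset as a Fixture (no disk round trip)."""
    return Fixture(
        manifest=dict(dataset.manifest),
        genes=dataset.genes,
        counts=dataset.counts,
        library_sizes=dataset.library_sizes,
        tags=dataset.tags,
    )


def load_fixture(directory) -> Fixture:
    raw = io_mod.read_fixture(directory)
    return Fixture(
        manifest=raw["manifest"],
        genes=raw["genes"],
        counts=raw["counts"],
        library_sizes=raw["library_sizes"],
        tags=raw["tags"],
    )


def quantify_sample(fix: Fixture, sample: str) -> SampleQuant:
    tag_df = fix.tags[sample]
    if "gene_id" not in tag_df.columns:
        raise ConfigError(
            f"tag table for {sample!r} lacks gene_id; run the annotate step first"
        )
    summaries = quantify_mod.summarize_tails(tag_df, sample)
    tails = quantify_mod.tail_frame(summaries)
    counts = (
        fix.counts[fix.counts["sample"] == sample]
        .set_index("gene_id")[["rna_count", "rpf_count"]]
        .sort_index()
    )
    sizes = fix.library_sizes
    totals = {
        assay: float(
            sizes[(sizes["sample"] == sample) & (sizes["assay"] == assay)][
                "total"
            ].iloc[0]
        )
        for assay in ("rna", "rpf")
    }
    lengths = fix.genes.set_index("gene_id")["orf_length"]
    expr = quantify_mod.normalize_expression(counts, totals, lengths)
    return SampleQuant(sample=sample, tails=tails, expr=expr, totals=totals)


def quantify_all(fix: Fixture) -> dict[str, SampleQuant]:
    return {s: quantify_sample(fix, s) for s in fix.samples}


def _rpm_frames(
    quants: dict[str, SampleQuant], samples: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rna = pd.DataFrame({s: quants[s].expr["rna_rpm"] for s in samples})
    rpf = pd.DataFrame({s: quants[s].expr["rpf_rpm"] for s in samples})
    tag = pd.DataFrame({s: quants[s].tails["tag_count"] for s in samples})
    return rna, rpf, tag


def stage_te(
    quants: dict[str, SampleQuant], sample: str
) -> tuple[pd.DataFrame, set[str], float]:
    """Single-stage centered TE over the cutoff-passing gene set."""
    q = quants[sample]
    rna, rpf, tag = _rpm_frames(quants, [sample])
    passing = quantify_mod.apply_cutoffs("single", rna, rpf, tag)
    te = quantify_mod.te_table(q.expr, rpf_total=q.totals["rpf"], sample_id=sample)
    te = te.loc[sorted(set(te.index) & passing)]
    centered, const = quantify_mod.median_center(te["log2_te"], te.index)
    te = te.assign(centered_log2_te=centered)
    return te, passing, const


def pair_changes(
    quants: dict[str, SampleQuant],
    sample_a: str,
    sample_b: str,
    *,
    require_tags: bool = True,
) -> pd.DataFrame:
    """Pairwise change table between two samples (B relative to A)."""
    rna, rpf, tag = _rpm_frames(quants, [sample_a, sample_b])
    passing = quantify_mod.apply_cutoffs(
        "pairwise", rna, rpf, tag if require_tags else None
    )
    qa, qb = quants[sample_a], quants[sample_b]
    te_a = quantify_mod.te_table(qa.expr, rpf_total=qa.totals["rpf"])["log2_te"]
    te_b = quantify_mod.te_table(qb.expr, rpf_total=qb.totals["rpf"])["log2_te"]
    return quantify_mod.compute_fold_changes(
        te_a,
        te_b,
        qa.tails["mean_tail_nt"],
        qb.tails["mean_tail_nt"],
        passing,
        stage_pair=(sample_a, sample_b),
    )


def genotype_changes(
    quants: dict[str, SampleQuant], sample_ref: str, sample_alt: str
) -> pd.DataFrame:
    """TE change of ``sample_ref`` relative to ``sample_alt`` (no tag cutoff)."""
    return pair_changes(quants, sample_alt, sample_ref, require_tags=False)


def dynamics_analysis(
    fix: Fixture,
    quants: dict[str, SampleQuant],
    *,
    genotype: str = "wt",
    max_step: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list, list, pd.DataFrame]:
    """Profile clustering of TE trajectories across the genotype's stages."""
    samples = [sample_id_for(genotype, s) for s in fix.stages]
    rna, rpf, _ = _rpm_frames(quants, samples)
    passing = sorted(quantify_mod.apply_cutoffs("multistage", rna, rpf))
    te_cols = {}
    for s in samples:
        q = quants[s]
        te = quantify_mod.te_table(q.expr, rpf_total=q.totals["rpf"])["log2_te"]
        te = te.reindex(passing)
        centered, _ = quantify_mod.median_center(te.dropna(), te.dropna().index)
        te_cols[s] = centered
    te_matrix = pd.DataFrame(te_cols).dropna()
    normalized = dynamics_mod.normalize_trajectories(te_matrix)
    profiles = dynamics_mod.enumerate_model_profiles(len(samples), max_step)
    assignments = dynamics_mod.assign_profiles(normalized, profiles)
    enrichments = dynamics_mod.profile_significance(
        assignments, profiles, te_matrix, rng=rng
    )
    return assignments, enrichments, te_matrix


def annotate_genes(
    transcripts: Sequence[Transcript],
    tags,
    *,
    min_tail_nt: int = 20,
    window_nt: int = 60,
    max_utr_nt: int = 4100,
    flag_intervals: Sequence[tuple[str, int, int]] = (),
) -> list[GeneModel]:
    """Full re-annotation pass: representative models, tag-supported 3' ends."""
    models = select_representative_models(transcripts)
    kept_tags = filter_polya_tags(list(tags), min_tail_nt)
    # nearest same-strand downstream TSS per retained model
    retained = [m for m in models if not m.excluded]
    out: list[GeneModel] = []
    for m in models:
        if m.excluded:
            out.append(m)
            continue
        stop = m.stop_codon_position
        if m.strand == "+":
            candidates = [
                o.transcript.tx_start
                for o in retained
                if o.gene_id != m.gene_id
                and o.transcript.chrom == m.transcript.chrom
                and o.strand == "+"
                and o.transcript.tx_start > stop
            ]
            next_tss = min(candidates) if candidates else stop + max_utr_nt + window_nt + 2
        else:
            candidates = [
                o.transcript.tx_end
                for o in retained
                if o.gene_id != m.gene_id
                and o.transcript.chrom == m.transcript.chrom
                and o.strand == "-"
                and o.transcript.tx_end < stop
            ]
            next_tss = max(candidates) if candidates else stop - max_utr_nt - window_nt - 2
        sites = call_cleavage_sites(kept_tags, m, next_tss)
        collapsed = collapse_tandem_isoforms(sites, m, window_nt, max_utr_nt)
        out.append(finalize_3p_end(m, collapsed, flag_intervals=flag_intervals))
    return out


# ---------------------------------------------------------------- run_all

def _coupling_rows(
    fix: Fixture, quants: dict[str, SampleQuant]
) -> tuple[pd.DataFrame, dict[str, float]]:
    rows = []
    constants: dict[str, float] = {}
    for genotype in fix.genotypes:
        for stage in fix.stages:
            sid = sample_id_for(genotype, stage)
            te, passing, const = stage_te(quants, sid)
            constants[sid] = const
            tails = quants[sid].tails["mean_tail_nt"].reindex(te.index).dropna()
            res = coupling_mod.binned_median_te(
                tails, te["centered_log2_te"].loc[tails.index], label=sid
            )
            rows.append(
                {
                    "label": sid,
                    "kind": "stage",
                    "scale": "",
                    "r_s": res.r_s,
                    "n": res.n_genes,
                    "bin_ratio": np.nan if res.bin_ratio is None else res.bin_ratio,
                }
            )
        for a, b in zip(fix.stages, fix.stages[1:]):
            sa, sb = sample_id_for(genotype, a), sample_id_for(genotype, b)
            changes = pair_changes(quants, sa, sb)
            for scale in ("relative", "absolute"):
                res = coupling_mod.change_coupling(
                    changes, scale, label=f"{sb}/{sa}"
                )
                rows.append(
                    {
                        "label": f"{sb}/{sa}",
                        "kind": "change",
                        "scale": scale,
                        "r_s": res.r_s,
                        "n": res.n_genes,
                        "bin_ratio": np.nan,
                    }
                )
    return pd.DataFrame(rows), constants


def _contrast_outputs(
    fix: Fixture, quants: dict[str, SampleQuant], out_dir: Path, prov: dict
) -> None:
    stages = fix.stages
    last_pair = (stages[-2], stages[-1])
    if "wispy" in fix.genotypes:
        rows = []
        for stage in stages:
            wt_q = quants[sample_id_for("wt", stage)]
            mu_q = quants[sample_id_for("wispy", stage)]
            census = contrasts_mod.fraction_tail_shortened(wt_q.tails, mu_q.tails)
            conc = contrasts_mod.rpf_concordance(
                wt_q.expr["rpf_rpm"],
                mu_q.expr["rpf_rpm"],
                wt_q.expr["rpf_count"],
                mu_q.expr["rpf_count"],
                totals=(wt_q.totals["rpf"], mu_q.totals["rpf"]),
                label=f"wispy-{stage}",
            )
            rows.append(
                {
                    "stage": stage,
                    "n_measured": census.n_measured,
                    "n_shortened_50pct": census.n_shortened,
                    "rpf_r_s": conc.r_s,
                    "rpf_n": conc.n_genes,
                    "rpf_dropouts": len(conc.dropouts),
                }
            )
        io_mod.write_tsv(pd.DataFrame(rows), out_dir / "contrasts-wispy.tsv", prov)
    if "png" in fix.genotypes:
        wt_a = sample_id_for("wt", last_pair[0])
        wt_b = sample_id_for("wt", last_pair[1])
        png_b = sample_id_for("png", last_pair[1])
        fc_a = pair_changes(quants, wt_a, wt_b, require_tags=False)
        fc_b = genotype_changes(quants, wt_b, png_b)
        sets = contrasts_mod.define_dependent_sets(
            fc_a["log2_fc_te"],
            fc_b["log2_fc_te"],
            comparisons=(f"{wt_b}/{wt_a}", f"{wt_b}/{png_b}"),
        )
        set_df = pd.DataFrame(
            {
                "gene_id": sorted(sets.up_ids) + sorted(sets.down_ids),
                "direction": ["up"] * len(sets.up_ids) + ["down"] * len(sets.down_ids),
            }
        )
        io_mod.write_tsv(set_df, out_dir / "contrasts-png-sets.tsv", prov)
        shift_rows = []
        comparisons = {"wt": (wt_a, wt_b)}
        for genotype in ("png", "smg"):
            if genotype in fix.genotypes:
                comparisons[genotype] = (
                    sample_id_for(genotype, last_pair[0]),
                    sample_id_for(genotype, last_pair[1]),
                )
        for label, (sa, sb) in comparisons.items():
            changes = pair_changes(quants, sa, sb)
            for set_name, ids, direction in (
                ("png_down", sets.down_ids, "less"),
                ("png_up", sets.up_ids, "greater"),
            ):
                if not ids or not (set(ids) & set(changes.index)):
                    continue
                if len(set(ids) & set(changes.index)) == len(changes):
                    continue
                for metric in ("log2_fc_te", "log2_fc_tail"):
                    res = contrasts_mod.set_shift_test(
                        changes[metric],
                        ids,
                        sidedness="one-tailed",
                        alternative_direction=direction,
                        set_id=f"{set_name}@{label}",
                        metric=metric,
                    )
                    shift_rows.append(dataclasses.asdict(res))
        if shift_rows:
            io_mod.write_tsv(
                pd.DataFrame(shift_rows), out_dir / "contrasts-set-shifts.tsv", prov
            )


def run_all(
    fixture_dir,
    out_dir,
    *,
    steps: Iterable[str] = ("quantify", "coupling", "dynamics", "contrasts"),
    seed: int = 0,
) -> Path:
    """Execute the pipeline stages against a fixture; returns the output dir."""
    steps = set(steps)
    fix = load_fixture(fixture_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quants = quantify_all(fix)
    prov = {
        "tool": f"tailte {__version__}",
        "fixture_config_sha256": fix.manifest.get("config_sha256", ""),
        "seed": seed,
    }
    log_lines = [
        f"tailte {__version__}",
        f"numpy {np.__version__}; pandas {pd.__version__}",
        f"fixture config sha256: {fix.manifest.get('config_sha256', '')}",
        f"fixture seed: {fix.manifest.get('seed', '')}",
        f"pipeline seed: {seed}",
        "cutoffs: tags>=100, rna_rpm>=10.0, rpf_rpm>=10.0/>0 per mode",
    ]
    if "quantify" in steps:
        for sid in fix.samples:
            q = quants[sid]
            tail_out = q.tails.reset_index()
            io_mod.write_tsv(tail_out, out_dir / f"tails-{sid}.tsv", prov)
            te, passing, const = stage_te(quants, sid)
            io_mod.write_tsv(
                te.reset_index().rename(columns={"index": "gene_id"}),
                out_dir / f"te-{sid}.tsv",
                {**prov, "centering_constant": f"{const:.10g}", "mode": "single"},
            )
            log_lines.append(f"centering constant {sid}: {const:.10g}")
        for genotype in fix.genotypes:
            for a, b in zip(fix.stages, fix.stages[1:]):
                sa, sb = sample_id_for(genotype, a), sample_id_for(genotype, b)
                changes = pair_changes(quants, sa, sb)
                io_mod.write_tsv(
                    changes.reset_index(),
                    out_dir / f"changes-{sa}--{sb}.tsv",
                    {
                        **prov,
                        "te_centering_constant": f"{changes.attrs['te_centering_constant']:.10g}",
                        "tail_fc_cohort_median": f"{changes.attrs['tail_fc_cohort_median']:.10g}",
                        "mode": "pairwise",
                    },
                )
                log_lines.append(
                    f"pair centering constant {sb}/{sa}: "
                    f"{changes.attrs['te_centering_constant']:.10g}"
                )
    if "coupling" in steps:
        coupling_df, constants = _coupling_rows(fix, quants)
        io_mod.write_tsv(coupling_df, out_dir / "coupling.tsv", prov)
    if "dynamics" in steps and len(fix.stages) >= 2:
        rng = np.random.default_rng(seed)
        assignments, enrichments, _ = dynamics_analysis(fix, quants, rng=rng)
        assign_df = pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    "eligible": a.eligible,
                    "profile_id": -1 if a.profile_id is None else a.profile_id,
                    "correlation": np.nan if a.correlation is None else a.correlation,
                }
                for a in assignments
            ]
        )
        io_mod.write_tsv(assign_df, out_dir / "dynamics-assignments.tsv", prov)
        report = dynamics_mod.cluster_report(assignments, enrichments)
        io_mod.write_tsv(
            report,
            out_dir / "dynamics-enrichment.tsv",
            {**prov, "significance": "permutation/binomial surrogate"},
        )
    if "contrasts" in steps:
        _contrast_outputs(fix, quants, out_dir, prov)
    (out_dir / "run-log.txt").write_text("\n".join(log_lines) + "\n")
    return out_dir
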