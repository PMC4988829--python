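"""Synthetic multi-stage, multi-genotype cohort generator with ground truth.

The generator emulates the statistical structure the analysis assumes: a
per-stage coupling between log2 mean tail length and log2 TE that can be
switched off stage by stage, unimodal per-molecule tail distributions,
planted temporal TE profiles, and genotype effects (global tail shrinkage
with a spared set, nulled transition changes for planted target sets, and a
partially responsive subset).  All randomness derives from one seed via
named substreams so individual samples are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields as dataclass_fields, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

_STREAMS = ("genes", "profiles", "sets", "noise", "wispy")


@dataclass(frozen=True)
class ProfileClass:
    profile: tuple[int, ...]
    fraction: float
    effect_log2: float


@dataclass(frozen=True)
class WispySpec:
    shrink_min: float = 0.3
    shrink_max: float = 0.7
    spared_fraction: float = 0.05


@dataclass(frozen=True)
class PngSpec:
    n_up: int = 30
    n_down: int = 40
    effect_log2: float = 3.0
    tail_effect_log2: float = 0.8
    transition: Optional[tuple[int, int]] = None  # stage indices; default last pair


@dataclass(frozen=True)
class SmgSpec:
    responsive_fraction: float = 0.6
    multiplier: float = 0.5


GENOTYPE_SPEC_TYPES = {"wispy": WispySpec, "png": PngSpec, "smg": SmgSpec}


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    stages: tuple[str, ...] = ("s1", "s2", "s3", "s4")
    coupling_beta: tuple[float, ...] = (1.2, 1.2, 1.2, 0.0)
    tail_base_mean_nt: float = 55.0
    tail_log2_sd: float = 0.35
    tail_stage_jitter_sd: float = 0.2
    tail_shape: float = 8.0
    noise_sd_log2te: float = 0.5
    alpha_sd: float = 0.5
    abundance_log_sd: float = 0.75
    orf_min_nt: float = 500.0
    orf_max_nt: float = 10_000.0
    depth_rna: int = 2_000_000
    depth_rpf: int = 2_000_000
    depth_tags: int = 600_000
    coupling_scale: str = "relative"
    absolute_scale_nt: float = 30.0
    overdispersion: float = 0.0
    profile_classes: tuple[ProfileClass, ...] = ()
    genotype_specs: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if len(self.stages) != len(set(self.stages)):
            raise ConfigError("stages must be unique")
        if len(self.coupling_beta) != len(self.stages):
            raise ConfigError("coupling_beta must be defined for every stage")
        for name in ("depth_rna", "depth_rpf", "depth_tags"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.tail_base_mean_nt < 1:
            raise ConfigError("tail_base_mean_nt must be >= 1")
        if self.tail_shape <= 0:
            raise ConfigError("tail_shape must be > 0")
        if self.coupling_scale not in ("relative", "absolute"):
            raise ConfigError("coupling_scale must be 'relative' or 'absolute'")
        frac = sum(pc.fraction for pc in self.profile_classes)
        if frac > 1 + 1e-12:
            raise ConfigError("profile_classes fractions must sum to <= 1")
        for pc in self.profile_classes:
            if len(pc.profile) != len(self.stages):
                raise ConfigError(
                    "profile_classes profiles must span every stage"
                )
        for name, spec in self.genotype_specs.items():
            expected = GENOTYPE_SPEC_TYPES.get(name)
            if expected is None:
                raise ConfigError(f"unknown genotype {name!r} in genotype_specs")
            if not isinstance(spec, expected):
                raise ConfigError(
                    f"genotype_specs[{name!r}] must be a {expected.__name__}"
                )

    def digest(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SimTruth:
    """Generator ground truth for one genotype."""

    genotype: str
    gene_ids: list[str]
    stages: tuple[str, ...]
    coupling_beta: np.ndarray  # (T,)
    coupling_scale: str
    absolute_scale_nt: float
    alpha: np.ndarray  # (n,)
    log2_tail: np.ndarray  # (n, T)
    te_extra: np.ndarray  # (n, T)
    te_profile: np.ndarray  # (n, T)
    noise: np.ndarray  # (n, T)
    profile_label: np.ndarray  # (n,) int, -1 = none
    abundance: np.ndarray  # (n,)
    orf_length: np.ndarray  # (n,)
    sets: dict[str, frozenset[str]]
    planted_tail_step: np.ndarray  # (n,)
    planted_te_step: np.ndarray  # (n,)
    transition: Optional[tuple[int, int]] = None

    @property
    def tail_mean_nt(self) -> np.ndarray:
        return 2.0**self.log2_tail

    @property
    def true_log2_te(self) -> np.ndarray:
        if self.coupling_scale == "relative":
            centered = self.log2_tail - self.log2_tail.mean(axis=0, keepdims=True)
        else:
            tails = self.tail_mean_nt
            centered = (
                tails - tails.mean(axis=0, keepdims=True)
            ) / self.absolute_scale_nt
        coupled = self.coupling_beta[None, :] * centered
        return self.alpha[:, None] + coupled + self.te_profile + self.te_extra + self.noise

    def copy(self) -> "SimTruth":
        return SimTruth(
            genotype=self.genotype,
            gene_ids=list(self.gene_ids),
            stages=self.stages,
            coupling_beta=self.coupling_beta.copy(),
            coupling_scale=self.coupling_scale,
            absolute_scale_nt=self.absolute_scale_nt,
            alpha=self.alpha.copy(),
            log2_tail=self.log2_tail.copy(),
            te_extra=self.te_extra.copy(),
            te_profile=self.te_profile.copy(),
            noise=self.noise.copy(),
            profile_label=self.profile_label.copy(),
            abundance=self.abundance.copy(),
            orf_length=self.orf_length.copy(),
            sets=dict(self.sets),
            planted_tail_step=self.planted_tail_step.copy(),
            planted_te_step=self.planted_te_step.copy(),
            transition=self.transition,
        )

    def gene_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array(sorted(lookup[g] for g in ids), dtype=int)


@dataclass
class SimDataset:
    config: SimConfig
    truth: SimTruth  # wild type
    mutant_truths: dict[str, SimTruth]
    genes: pd.DataFrame  # gene_id, orf_length
    tags: dict[str, pd.DataFrame]  # sample_id -> tag table
    counts: pd.DataFrame  # long: gene_id, sample, rna_count, rpf_count
    library_sizes: pd.DataFrame  # sample, assay, total
    manifest: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return sorted(self.tags)


def sample_id_for(genotype: str, stage: str) -> str:
    return f"{genotype}-{stage}"


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    name_idx = _STREAMS.index(stream) if stream in _STREAMS else 90
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(name_idx, index))
    )


def sample_tail_lengths(
    mean_nt: float, shape: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unimodal per-molecule tail lengths: gamma draws rounded and floored at 1."""
    if mean_nt < 1:
        raise ConfigError("mean_nt must be >= 1")
    if shape <= 0:
        raise ConfigError("shape must be > 0")
    if n < 0:
        raise ConfigError("n must be >= 0")
    if n == 0:
        return np.array([], dtype=int)
    draws = rng.gamma(shape, mean_nt / shape, size=n)
    return np.maximum(np.rint(draws).astype(int), 1)


def sample_counts(
    true_abundance: np.ndarray,
    true_te: np.ndarray,
    depth_rna: int,
    depth_rpf: int,
    rng: np.random.Generator,
    *,
    overdispersion: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson RNA and footprint counts with expectations proportional to
    abundance and abundance x TE respectively (gamma-Poisson when
    ``overdispersion`` > 0)."""
    a = np.asarray(true_abundance, dtype=float)
    te = np.asarray(true_te, dtype=float)
    if (a <= 0).any() or a.sum() == 0:
        raise ConfigError("true_abundance must be positive with nonzero total")
    if (te <= 0).any():
        raise ConfigError("true_te must be positive")
    mu_rna = depth_rna * a / a.sum()
    w = a * te
    mu_rpf = depth_rpf * w / w.sum()
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mu_rna = rng.gamma(shape, mu_rna / shape)
        mu_rpf = rng.gamma(shape, mu_rpf / shape)
    return rng.poisson(mu_rna), rng.poisson(mu_rpf)


def _tails_for_genes(
    means: np.ndarray, shape: float, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-gene tail draws: one gamma draw per molecule."""
    per_mol_means = np.repeat(means, counts)
    if per_mol_means.size == 0:
        return np.array([], dtype=int)
    draws = rng.gamma(shape, per_mol_means / shape)
    return np.maximum(np.rint(draws).astype(int), 1)


def _build_wt_truth(config: SimConfig) -> SimTruth:
    n, T = config.n_genes, len(config.stages)
    rng_genes = _rng(config.seed, "genes")
    gene_ids = [f"g{i:05d}" for i in range(n)]
    orf_length = np.exp(
        rng_genes.uniform(
            np.log(config.orf_min_nt), np.log(config.orf_max_nt), size=n
        )
    )
    abundance = np.exp(rng_genes.normal(0.0, config.abundance_log_sd, size=n))
    alpha = rng_genes.normal(0.0, config.alpha_sd, size=n)
    gene_offset = rng_genes.normal(0.0, config.tail_log2_sd, size=n)
    jitter = rng_genes.normal(0.0, config.tail_stage_jitter_sd, size=(n, T))
    log2_tail = np.log2(config.tail_base_mean_nt) + gene_offset[:, None] + jitter

    # planted temporal profiles
    rng_prof = _rng(config.seed, "profiles")
    profile_label = np.full(n, -1, dtype=int)
    te_profile = np.zeros((n, T))
    order = rng_prof.permutation(n)
    cursor = 0
    for k, pc in enumerate(config.profile_classes):
        size = int(round(pc.fraction * n))
        idx = order[cursor : cursor + size]
        cursor += size
        profile_label[idx] = k
        te_profile[idx, :] = np.asarray(pc.profile, dtype=float) * pc.effect_log2

    # genotype target sets and planted transition effects
    rng_sets = _rng(config.seed, "sets")
    sets: dict[str, frozenset[str]] = {}
    planted_tail_step = np.zeros(n)
    planted_te_step = np.zeros(n)
    transition: Optional[tuple[int, int]] = None
    free = np.flatnonzero(profile_label < 0)
    spec = config.genotype_specs.get("png")
    if isinstance(spec, PngSpec):
        transition = spec.transition or (T - 2, T - 1)
        if not (0 <= transition[0] < transition[1] < T):
            raise ConfigError("png transition indices out of range")
        need = spec.n_up + spec.n_down
        if need > len(free):
            raise ConfigError("png target sets larger than available genes")
        chosen = rng_sets.choice(free, size=need, replace=False)
        up_idx, down_idx = chosen[: spec.n_up], chosen[spec.n_up :]
        sets["png_up"] = frozenset(gene_ids[i] for i in up_idx)
        sets["png_down"] = frozenset(gene_ids[i] for i in down_idx)
        b = config.coupling_beta[transition[1]]
        for idx, sign in ((up_idx, 1.0), (down_idx, -1.0)):
            planted_tail_step[idx] = sign * spec.tail_effect_log2
            planted_te_step[idx] = sign * spec.effect_log2 - b * planted_tail_step[idx]
        s = transition[1]
        log2_tail[:, s:] += planted_tail_step[:, None]
        smg = config.genotype_specs.get("smg")
        if isinstance(smg, SmgSpec):
            k = int(round(smg.responsive_fraction * len(down_idx)))
            resp = rng_sets.choice(down_idx, size=k, replace=False)
            sets["smg_responsive"] = frozenset(gene_ids[i] for i in resp)
    wisp = config.genotype_specs.get("wispy")
    if isinstance(wisp, WispySpec):
        k = int(round(wisp.spared_fraction * n))
        spared = rng_sets.choice(n, size=k, replace=False)
        sets["wispy_spared"] = frozenset(gene_ids[i] for i in spared)

    te_extra = np.zeros((n, T))
    if transition is not None:
        te_extra[:, transition[1] :] += planted_te_step[:, None]
    noise = _rng(config.seed, "noise").normal(
        0.0, config.noise_sd_log2te, size=(n, T)
    )
    return SimTruth(
        genotype="wt",
        gene_ids=gene_ids,
        stages=config.stages,
        coupling_beta=np.asarray(config.coupling_beta, dtype=float),
        coupling_scale=config.coupling_scale,
        absolute_scale_nt=config.absolute_scale_nt,
        alpha=alpha,
        log2_tail=log2_tail,
        te_extra=te_extra,
        te_profile=te_profile,
        noise=noise,
        profile_label=profile_label,
        abundance=abundance,
        orf_length=orf_length,
        sets=sets,
        planted_tail_step=planted_tail_step,
        planted_te_step=planted_te_step,
        transition=transition,
    )


def apply_genotype(
    truth: SimTruth,
    spec: WispySpec | PngSpec | SmgSpec,
    rng: Optional[np.random.Generator] = None,
) -> SimTruth:
    """Derive a mutant truth from the wild-type truth.

    wispy: every gene's mean tail is multiplied by a per-gene shrink factor
    drawn from the spec range (spared set keeps factor 1), at every stage, so
    between-stage log2 tail changes are preserved by construction.
    png: for the planted target sets, the transition tail change is replaced
    by the cohort-median change and the tail-independent TE step is nulled.
    smg: the responsive subset of the down set keeps the wild-type planted
    steps scaled by the partial-effect multiplier; everything else behaves as
    if the upstream kinase were intact (wild type).
    """
    out = truth.copy()
    if isinstance(spec, WispySpec):
        if rng is None:
            raise ConfigError("wispy genotype needs an rng for shrink factors")
        n = len(out.gene_ids)
        delta = rng.uniform(spec.shrink_min, spec.shrink_max, size=n)
        spared = out.sets.get("wispy_spared", frozenset())
        if spared:
            delta[out.gene_indices(spared)] = 1.0
        out.log2_tail = out.log2_tail + np.log2(delta)[:, None]
        out.genotype = "wispy"
        return out
    if isinstance(spec, PngSpec):
        out.genotype = "png"
        targets = out.sets.get("png_up", frozenset()) | out.sets.get(
            "png_down", frozenset()
        )
        if not targets or out.transition is None:
            return out
        a, b = out.transition
        wt_delta = truth.log2_tail[:, b] - truth.log2_tail[:, a]
        median_delta = float(np.median(wt_delta))
        idx = out.gene_indices(targets)
        adjust = median_delta - wt_delta[idx]
        out.log2_tail[idx, b:] += adjust[:, None]
        out.te_extra[idx, b:] -= out.planted_te_step[idx, None]
        return out
    if isinstance(spec, SmgSpec):
        out.genotype = "smg"
        resp = out.sets.get("smg_responsive", frozenset())
        if not resp or out.transition is None:
            return out
        b = out.transition[1]
        idx = out.gene_indices(resp)
        scale = spec.multiplier - 1.0
        out.log2_tail[idx, b:] += scale * out.planted_tail_step[idx, None]
        out.te_extra[idx, b:] += scale * out.planted_te_step[idx, None]
        return out
    raise ConfigError(f"unknown genotype spec {type(spec).__name__}")


def _sample_tables(
    config: SimConfig,
    truth: SimTruth,
    stage_index: int,
    sample_index: int,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict[str, int]]:
    rng = _rng(config.seed, "sample", sample_index)
    te_lin = 2.0 ** truth.true_log2_te[:, stage_index]
    rna, rpf = sample_counts(
        truth.abundance,
        te_lin,
        config.depth_rna,
        config.depth_rpf,
        rng,
        overdispersion=config.overdispersion,
    )
    share = truth.abundance / truth.abundance.sum()
    n_tags = rng.poisson(config.depth_tags * share)
    means = truth.tail_mean_nt[:, stage_index]
    tails = _tails_for_genes(means, config.tail_shape, n_tags, rng)
    sid = sample_id_for(truth.genotype, truth.stages[stage_index])
    gene_col = np.repeat(np.asarray(truth.gene_ids), n_tags)
    sites = np.repeat(1000 * (np.arange(len(truth.gene_ids)) + 1), n_tags)
    tag_df = pd.DataFrame(
        {
            "chrom": "chrSim",
            "site": sites,
            "strand": "+",
            "tail_length": tails,
            "sample": sid,
            "gene_id": gene_col,
        }
    )
    sizes = {
        "rna": int(rna.sum()),
        "rpf": int(rpf.sum()),
        "tags": int(n_tags.sum()),
    }
    return tag_df, rna, rpf, sizes


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate tag/count tables for every (genotype, stage) sample plus truth."""
    config.validate()
    wt = _build_wt_truth(config)
    mutants: dict[str, SimTruth] = {}
    for name in sorted(config.genotype_specs):
        spec = config.genotype_specs[name]
        rng = _rng(config.seed, "wispy") if name == "wispy" else None
        mutants[name] = apply_genotype(wt, spec, rng)

    genes = pd.DataFrame(
        {"gene_id": wt.gene_ids, "orf_length": np.rint(wt.orf_length).astype(int)}
    )
    tags: dict[str, pd.DataFrame] = {}
    count_rows = []
    size_rows = []
    genotypes = ["wt"] + sorted(mutants)
    sample_index = 0
    for genotype in genotypes:
        truth = wt if genotype == "wt" else mutants[genotype]
        for s, stage in enumerate(config.stages):
            sid = sample_id_for(genotype, stage)
            tag_df, rna, rpf, sizes = _sample_tables(config, truth, s, sample_index)
            sample_index += 1
            tags[sid] = tag_df
            count_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": wt.gene_ids,
                        "sample": sid,
                        "rna_count": rna,
                        "rpf_count": rpf,
                    }
                )
            )
            for assay in ("rna", "rpf", "tags"):
                size_rows.append({"sample": sid, "assay": assay, "total": sizes[assay]})
    counts = pd.concat(count_rows, ignore_index=True)
    library_sizes = pd.DataFrame(size_rows, columns=["sample", "assay", "total"])
    manifest = {
        "seed": str(config.seed),
        "config_sha256": config.digest(),
        "n_genes": str(config.n_genes),
        "stages": ",".join(config.stages),
        "genotypes": ",".join(genotypes),
        "samples": ",".join(
            sample_id_for(g, s) for g in genotypes for s in config.stages
        ),
        "coupling_beta": ",".join(f"{b:g}" for b in config.coupling_beta),
        "coupling_scale": config.coupling_scale,
    }
    return SimDataset(
        config=config,
        truth=wt,
        mutant_truths=mutants,
        genes=genes,
        tags=tags,
        counts=counts,
        library_sizes=library_sizes,
        manifest=manifest,
    )


def sim_config_from_mapping(mapping: Mapping[str, str]) -> SimConfig:
    """Build a SimConfig from a flat string mapping (the config-file dialect).

    Scalar keys mirror the SimConfig field names.  ``stages`` and
    ``coupling_beta`` are comma-separated.  ``profile_classes`` uses
    ``v0|v1|...:fraction:effect`` items separated by ';'.  Genotypes are
    requested with ``genotypes = wispy,png,smg`` and tuned via dotted keys
    (``png.n_up = 30`` etc.).
    """
    kwargs: dict[str, object] = {}
    mapping = dict(mapping)
    if "stages" in mapping:
        kwargs["stages"] = tuple(s.strip() for s in mapping.pop("stages").split(","))
    if "coupling_beta" in mapping:
        kwargs["coupling_beta"] = tuple(
            float(x) for x in mapping.pop("coupling_beta").split(",")
        )
    if "profile_classes" in mapping:
        classes = []
        for item in mapping.pop("profile_classes").split(";"):
            item = item.strip()
            if not item:
                continue
            try:
                vec, frac, eff = item.split(":")
                classes.append(
                    ProfileClass(
                        profile=tuple(int(v) for v in vec.split("|")),
                        fraction=float(frac),
                        effect_log2=float(eff),
                    )
                )
            except ValueError:
                raise ConfigError(f"malformed profile_classes item {item!r}")
        kwargs["profile_classes"] = tuple(classes)
    genotype_kwargs: dict[str, dict[str, float]] = {}
    requested = []
    if "genotypes" in mapping:
        requested = [g.strip() for g in mapping.pop("genotypes").split(",") if g.strip()]
    for key in list(mapping):
        if "." in key:
            geno, _, attr = key.partition(".")
            if geno not in GENOTYPE_SPEC_TYPES:
                raise ConfigError(f"unknown genotype key {key!r}")
            genotype_kwargs.setdefault(geno, {})[attr] = mapping.pop(key)
            if geno not in requested:
                requested.append(geno)
    specs: dict[str, object] = {}
    for geno in requested:
        cls = GENOTYPE_SPEC_TYPES.get(geno)
        if cls is None:
            raise ConfigError(f"unknown genotype {geno!r}")
        raw = genotype_kwargs.get(geno, {})
        typed: dict[str, object] = {}
        for attr, value in raw.items():
            fields = {f.name: f for f in dataclass_fields(cls)}
            if attr not in fields:
                raise ConfigError(f"unknown field {geno}.{attr}")
            typed[attr] = _coerce(value, fields[attr].type)
        specs[geno] = cls(**typed)
    if specs:
        kwargs["genotype_specs"] = specs
    int_fields = {"n_genes", "depth_rna", "depth_rpf", "depth_tags", "seed"}
    str_fields = {"coupling_scale"}
    for key, value in mapping.items():
        if key in int_fields:
            kwargs[key] = int(value)
        elif key in str_fields:
            kwargs[key] = str(value)
        else:
            try:
                kwargs[key] = float(value)
            except ValueError:
                raise ConfigError(f"cannot parse config value {key} = {value!r}")
    try:
        cfg = SimConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"unknown config field: {exc}")
    cfg.validate()
    return cfg


def _coerce(value: str, annotation: object) -> object:
    text = str(annotation)
    if "int" in text:
        return int(value)
    return float(value)


def write_fixture(dataset: SimDataset, directory) -> str:
    """Write a dataset to a directory of TSVs plus truth and manifest files."""
    from . import io as io_mod  # local import avoids a cycle

    return io_mod.write_fixture(dataset, directory)
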