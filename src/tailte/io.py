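"""Readers and writers: refFlat, tag/count/geneset TSV dialects, flat config
files, and simulation fixtures.

Every writer emits a provenance header of ``# key: value`` lines; every
reader skips ``#`` lines, so round trips are lossless.
"""

from __future__ import annotations

import io as _io
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .gene_models import PolyATag, Transcript

TAG_COLUMNS = ["chrom", "site", "strand", "tail_length", "sample"]
COUNT_COLUMNS = ["gene_id", "sample", "rna_count", "rpf_count"]

_REFFLAT_FIELDS = 11


# ---------------------------------------------------------------- refFlat

def read_refflat(path) -> list[Transcript]:
    """Parse a UCSC refFlat file into transcripts (0-based half-open kept as is)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _REFFLAT_FIELDS:
                raise SchemaError(
                    f"{path}:{lineno}: expected {_REFFLAT_FIELDS} fields, got {len(fields)}"
                )
            (
                gene,
                tx,
                chrom,
                strand,
                tx_start,
                tx_end,
                cds_start,
                cds_end,
                exon_count,
                exon_starts,
                exon_ends,
            ) = fields
            try:
                starts = [int(x) for x in exon_starts.rstrip(",").split(",") if x]
                ends = [int(x) for x in exon_ends.rstrip(",").split(",") if x]
                n_exons = int(exon_count)
                tx_s, tx_e = int(tx_start), int(tx_end)
                cds_s, cds_e = int(cds_start), int(cds_end)
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric field: {exc}")
            if len(starts) != n_exons or len(ends) != n_exons:
                raise SchemaError(
                    f"{path}:{lineno}: exonCount {n_exons} does not match exon lists"
                )
            out.append(
                Transcript(
                    gene_id=gene,
                    tx_id=tx,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_s,
                    tx_end=tx_e,
                    cds_start=cds_s,
                    cds_end=cds_e,
                    exons=tuple(zip(starts, ends)),
                )
            )
    return out


def write_refflat(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.tx_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.cds_start),
                        str(t.cds_end),
                        str(len(t.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- TSV dialects

def write_tsv(df: pd.DataFrame, path, provenance: Optional[Mapping[str, object]] = None) -> None:
    """Write a TSV with an optional ``# key: value`` provenance header."""
    with open(path, "w") as fh:
        for key in sorted(provenance or {}):
            fh.write(f"# {key}: {provenance[key]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tags(path) -> pd.DataFrame:
    """Read a tag table, validating required columns and numeric tails."""
    df = _read_tsv(path)
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: tag table missing column(s) {missing}")
    tails = pd.to_numeric(df["tail_length"], errors="coerce")
    bad = df.index[tails.isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric tail_length at row {bad[0]}")
    if (tails < 0).any():
        raise SchemaError(f"{path}: negative tail_length")
    df["tail_length"] = tails.astype(int)
    df["site"] = pd.to_numeric(df["site"]).astype(int)
    return df


def tags_to_records(df: pd.DataFrame) -> list[PolyATag]:
    return [
        PolyATag(
            chrom=str(r.chrom),
            site=int(r.site),
            strand=str(r.strand),
            tail_length_nt=int(r.tail_length),
            sample_id=str(r.sample),
            gene_id=str(r.gene_id) if "gene_id" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: count table missing column(s) {missing}")
    for col in ("rna_count", "rpf_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} at row {bad[0]}")
        df[col] = vals.astype(int)
    return df


def read_geneset(path) -> list[str]:
    """One gene id per line; a single ``gene_id`` header line is tolerated."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "gene_id":
                continue
            out.append(line.split("\t")[0])
    return out


def write_geneset(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(set(ids)):
            fh.write(gid + "\n")


# ---------------------------------------------------------------- flat config

def read_flat_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (comments with '#')."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_flat_config(mapping: Mapping[str, object], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(mapping):
            fh.write(f"{key} = {mapping[key]}\n")


# ---------------------------------------------------------------- fixtures

def write_fixture(dataset, directory) -> str:
    """Write a simulated dataset as a directory of plain-text tables.

    Layout: ``manifest.txt`` (flat key=value), ``genes.tsv``, ``counts.tsv``,
    ``library_sizes.tsv``, ``tags-<sample>.tsv`` per sample, and
    ``truth-<genotype>.tsv`` per genotype.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prov = {"format": "tailte-fixture-v1", "seed": dataset.manifest["seed"]}
    write_tsv(dataset.genes, directory / "genes.tsv", prov)
    write_tsv(dataset.counts, directory / "counts.tsv", prov)
    write_tsv(dataset.library_sizes, directory / "library_sizes.tsv", prov)
    for sid in sorted(dataset.tags):
        write_tsv(dataset.tags[sid], directory / f"tags-{sid}.tsv", prov)
    truths = {"wt": dataset.truth, **dataset.mutant_truths}
    for name in sorted(truths):
        write_tsv(truth_frame(truths[name]), directory / f"truth-{name}.tsv", prov)
    manifest_path = directory / "manifest.txt"
    write_flat_config(dataset.manifest, manifest_path)
    return str(manifest_path)


def truth_frame(truth) -> pd.DataFrame:
    """Flatten a SimTruth into one row per gene."""
    data: dict[str, object] = {"gene_id": truth.gene_ids}
    data["profile_class"] = truth.profile_label
    for name in sorted(truth.sets):
        members = truth.sets[name]
        data[f"in_{name}"] = [int(g in members) for g in truth.gene_ids]
    tails = truth.tail_mean_nt
    te = truth.true_log2_te
    for s, stage in enumerate(truth.stages):
        data[f"tail_mean_nt.{stage}"] = tails[:, s]
        data[f"log2_te.{stage}"] = te[:, s]
    return pd.DataFrame(data)


def read_fixture(directory) -> dict:
    """Read a fixture directory back into plain tables.

    Returns a dict with keys ``manifest``, ``genes``, ``counts``,
    ``library_sizes``, ``tags`` (sample -> frame), and ``truth``
    (genotype -> frame).
    """
    directory = Path(directory)
    manifest = read_flat_config(directory / "manifest.txt")
    tags = {}
    for sid in manifest["samples"].split(","):
        tags[sid] = read_tags(directory / f"tags-{sid}.tsv")
    truth = {}
    for genotype in manifest["genotypes"].split(","):
        truth[genotype] = _read_tsv(directory / f"truth-{genotype}.tsv")
    return {
        "manifest": manifest,
        "genes": _read_tsv(directory / "genes.tsv"),
        "counts": read_counts(directory / "counts.tsv"),
        "library_sizes": _read_tsv(directory / "library_sizes.tsv"),
        "tags": tags,
        "truth": truth,
    }
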