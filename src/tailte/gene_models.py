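"""Representative gene models and 3'-end re-annotation from poly(A)-anchored tags.

Coordinates are 0-based half-open throughout.  "Distal" is strand-aware:
larger coordinates on the plus strand, smaller coordinates on the minus
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import DegenerateIntervalError

EXCLUDE_NONCODING = "non-coding"
EXCLUDE_OVERLAP = "overlapping-same-strand"
EXCLUDE_SNO = "snoRNA/snRNA overlap"


@dataclass(frozen=True)
class PolyATag:
    """One sequenced mRNA 3' end: genomic cleavage site plus tail length."""

    chrom: str
    site: int
    strand: str
    tail_length_nt: int
    sample_id: str = ""
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tail_length_nt < 0:
            raise ValueError("tail_length_nt must be >= 0")


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    tx_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.tx_id}: tx_start must be < tx_end")

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def stop_codon_position(self) -> int:
        """Genomic coordinate of the CDS 3' boundary (strand-aware)."""
        return self.cds_end if self.strand == "+" else self.cds_start

    @property
    def reference_3p_end(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class IsoformEnd:
    position: int
    tag_support: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcript: Transcript
    isoform_ends: tuple[IsoformEnd, ...] = ()
    final_3p_end: Optional[int] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    excluded_from_figures: bool = False

    @property
    def strand(self) -> str:
        return self.transcript.strand

    @property
    def stop_codon_position(self) -> int:
        return self.transcript.stop_codon_position

    @property
    def reference_3p_end(self) -> int:
        return self.transcript.reference_3p_end


def _distal_key(strand: str, position: int) -> int:
    return position if strand == "+" else -position


def select_representative_models(
    transcripts: Iterable[Transcript],
    *,
    length_measure: str = "span",
) -> list[GeneModel]:
    """Pick one representative transcript per gene and apply gene-level exclusions.

    Per gene, the longest transcript wins (``length_measure`` is ``"span"`` for
    genomic extent or ``"exonic"`` for summed exon length).  Genes whose
    representative is non-coding are excluded.  Pairs of (retained) genes whose
    representative spans overlap on the same strand are both excluded.
    Excluded genes are returned flagged with a reason.
    """
    if length_measure not in ("span", "exonic"):
        raise ValueError(f"unknown length_measure {length_measure!r}")
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    def _length(tx: Transcript) -> int:
        return tx.span if length_measure == "span" else tx.exonic_length

    models: dict[str, GeneModel] = {}
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        # stable winner: longest, tie broken by tx_id
        rep = max(txs, key=lambda t: (_length(t), t.tx_id))
        excluded = not rep.coding
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript=rep,
            excluded=excluded,
            exclusion_reason=EXCLUDE_NONCODING if excluded else None,
        )

    # same-strand span overlap among genes that survived the coding filter
    retained = [m for m in models.values() if not m.excluded]
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in retained:
        by_key.setdefault((m.transcript.chrom, m.strand), []).append(m)
    overlapping: set[str] = set()
    for group in by_key.values():
        group.sort(key=lambda m: m.transcript.tx_start)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.transcript.tx_start >= a.transcript.tx_end:
                    break
                overlapping.add(a.gene_id)
                overlapping.add(b.gene_id)
    for gid in overlapping:
        models[gid] = replace(
            models[gid], excluded=True, exclusion_reason=EXCLUDE_OVERLAP
        )
    return [models[g] for g in sorted(models)]


def filter_polya_tags(
    tags: Sequence[PolyATag], min_tail_nt: int = 20
) -> list[PolyATag]:
    """Keep tags whose tail is at least ``min_tail_nt`` long, preserving order."""
    return [t for t in tags if t.tail_length_nt >= min_tail_nt]


def call_cleavage_sites(
    tags: Sequence[PolyATag],
    model: GeneModel,
    next_tss: int,
    *,
    min_support: int = 2,
) -> list[IsoformEnd]:
    """Call 3'-end sites supported by >= ``min_support`` tags strictly between
    the gene's stop codon and the neighboring same-strand TSS."""
    stop = model.stop_codon_position
    strand = model.strand
    if strand == "+":
        if next_tss <= stop:
            raise DegenerateIntervalError(
                f"{model.gene_id}: next_tss {next_tss} not downstream of stop {stop}"
            )
        lo, hi = stop, next_tss
    else:
        if next_tss >= stop:
            raise DegenerateIntervalError(
                f"{model.gene_id}: next_tss {next_tss} not downstream of stop {stop}"
            )
        lo, hi = next_tss, stop
    support: dict[int, int] = {}
    for tag in tags:
        if tag.chrom != model.transcript.chrom or tag.strand != strand:
            continue
        if lo < tag.site < hi:
            support[tag.site] = support.get(tag.site, 0) + 1
    ends = [
        IsoformEnd(pos, n) for pos, n in support.items() if n >= min_support
    ]
    ends.sort(key=lambda e: _distal_key(strand, e.position))
    return ends


def collapse_tandem_isoforms(
    sites: Sequence[IsoformEnd],
    model: GeneModel,
    window_nt: int = 60,
    max_utr_nt: int = 4100,
) -> list[IsoformEnd]:
    """Collapse nearby sites into one isoform end each, greedily by support.

    Sites implying a 3'-UTR longer than ``max_utr_nt`` are discarded.  Then,
    repeatedly, the unconsumed site with the highest support (ties broken
    toward the distal site) absorbs every site within ``window_nt`` of it,
    accumulating their support.  The result is sorted proximal-to-distal.
    """
    strand = model.strand
    stop = model.stop_codon_position
    sign = 1 if strand == "+" else -1
    pool = [s for s in sites if sign * (s.position - stop) <= max_utr_nt]
    kept: list[IsoformEnd] = []
    while pool:
        best = max(
            pool, key=lambda s: (s.tag_support, _distal_key(strand, s.position))
        )
        absorbed = [s for s in pool if abs(s.position - best.position) <= window_nt]
        kept.append(
            IsoformEnd(best.position, sum(s.tag_support for s in absorbed))
        )
        pool = [s for s in pool if abs(s.position - best.position) > window_nt]
    kept.sort(key=lambda e: _distal_key(strand, e.position))
    return kept


def finalize_3p_end(
    model: GeneModel,
    collapsed: Sequence[IsoformEnd],
    *,
    flag_intervals: Sequence[tuple[str, int, int]] = (),
) -> GeneModel:
    """Extend the model to the distal-most re-annotated end, if any is distal.

    ``flag_intervals`` is an optional list of (chrom, start, end) intervals for
    small structured RNAs (snoRNA/snRNA); a model whose selected end falls in
    one is flagged ``excluded_from_figures`` but retained.
    """
    strand = model.strand
    ref = model.reference_3p_end
    candidates = [ref] + [e.position for e in collapsed]
    final = max(candidates, key=lambda p: _distal_key(strand, p))
    if final == ref and all(
        _distal_key(strand, e.position) <= _distal_key(strand, ref)
        for e in collapsed
    ):
        final = ref
    flagged = any(
        chrom == model.transcript.chrom and start <= final < end
        for chrom, start, end in flag_intervals
    )
    return replace(
        model,
        isoform_ends=tuple(collapsed),
        final_3p_end=final,
        excluded_from_figures=flagged,
    )
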