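"""Genomic interval primitives, locus-domain construction and positional annotation.

All coordinates are 0-based, half-open ``[start, end)``. ``strand`` is one of
``"+"``, ``"-"`` or ``"."`` (unstranded). "Upstream" and "downstream" are
always relative to the transcription direction of the gene in question.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "LocusDomain",
    "PositionalAnnotation",
    "overlaps",
    "define_locus_domain",
    "annotate_position",
    "signed_tss_distance",
    "merge_intervals",
]

Strand = Literal["+", "-", "."]

#: |distance| below this is "proximal" to the TSS.
PROXIMAL_BP = 2_000
#: |distance| above this is "far_distal"; 2 kb..10 kb inclusive is "distal".
DISTAL_BP = 10_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        ``"+"``, ``"-"`` or ``"."``.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff ``pos`` falls inside the half-open interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Strand-blind half-open overlap test.

    True iff the intervals share a chromosome and at least one base;
    bookended intervals (``a.end == b.start``) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body with TSS, poly(A) site and exon structure.

    Invariants: the TSS sits at ``interval.start`` on the + strand and at
    ``interval.end - 1`` on the - strand; exons are sorted, non-overlapping
    and contained in the gene interval.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    polya_site: int
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        iv = self.interval
        if iv.strand == "+" and self.tss != iv.start:
            raise ValueError(f"{self.gene_id}: + strand TSS must equal interval.start")
        if iv.strand == "-" and self.tss != iv.end - 1:
            raise ValueError(f"{self.gene_id}: - strand TSS must equal interval.end - 1")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != iv.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < iv.start or ex.end > iv.end:
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def strand(self) -> Strand:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class LocusDomain:
    """The screened window around one gene: ``upstream_extent`` bp upstream of
    the TSS through ``downstream_extent`` bp downstream of the poly(A) site,
    possibly clamped at chromosome boundaries."""

    gene_id: str
    interval: GenomicInterval
    upstream_extent: int = 70_000
    downstream_extent: int = 20_000


def define_locus_domain(
    gene: GeneModel,
    upstream: int = 70_000,
    downstream: int = 20_000,
    chrom_length: int | None = None,
) -> LocusDomain:
    """Build the locus domain for ``gene``.

    On the + strand the domain is ``[tss - upstream, polya + downstream)``;
    on the - strand it is mirrored to ``[polya - downstream, tss + upstream)``.
    The result is clamped to ``[0, chrom_length)``.

    Raises
    ------
    ValueError
        If extents are negative or clamping empties the domain entirely
        (inconsistent annotation).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("extents must be non-negative")
    if gene.strand == "+":
        start = gene.tss - upstream
        end = gene.polya_site + downstream
    elif gene.strand == "-":
        start = gene.polya_site - downstream
        end = gene.tss + upstream
    else:
        raise ValueError(f"{gene.gene_id}: locus domain requires a stranded gene")

    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(
            f"{gene.gene_id}: domain [{start}, {end}) is empty after clamping"
        )
    return LocusDomain(
        gene_id=gene.gene_id,
        interval=GenomicInterval(gene.chrom, start, end, gene.strand),
        upstream_extent=upstream,
        downstream_extent=downstream,
    )


@dataclass(frozen=True)
class PositionalAnnotation:
    """Genic context and TSS relation of one site against a target gene."""

    genic_context: Literal["intergenic", "intronic", "exonic"]
    tss_relation: Literal["contains_tss", "proximal", "distal", "far_distal"]
    signed_tss_distance: int


def signed_tss_distance(site: GenomicInterval, gene: GeneModel) -> int:
    """Distance from the site edge nearest the TSS, in gene orientation.

    Negative means upstream of the TSS, positive downstream, 0 when the site
    covers the TSS. Measured to the nearest covered base.
    """
    if site.chrom != gene.chrom:
        raise ValueError(
            f"site on {site.chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    tss = gene.tss
    if site.contains(tss):
        return 0
    if tss < site.start:
        raw = site.start - tss
    else:  # tss >= site.end, nearest covered base is end - 1
        raw = (site.end - 1) - tss
    return raw if gene.strand != "-" else -raw


def _tss_relation(site: GenomicInterval, gene: GeneModel) -> tuple[str, int]:
    dist = signed_tss_distance(site, gene)
    if site.contains(gene.tss):
        return "contains_tss", dist
    if abs(dist) < PROXIMAL_BP:
        return "proximal", dist
    if abs(dist) <= DISTAL_BP:
        return "distal", dist
    return "far_distal", dist


def annotate_position(
    site: GenomicInterval,
    gene: GeneModel,
    all_genes: Iterable[GeneModel] = (),
) -> PositionalAnnotation:
    """Annotate ``site`` with its genic context and its TSS relation to ``gene``.

    Genic context is resolved against every gene model overlapping the site
    (the target gene is always considered), with precedence
    exonic > intronic > intergenic. The TSS relation uses the target gene
    only; see :func:`signed_tss_distance` for the distance convention.
    """
    if site.chrom != gene.chrom:
        raise ValueError(
            f"site on {site.chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    genes = list(all_genes)
    if all(g.gene_id != gene.gene_id for g in genes):
        genes.append(gene)

    context = "intergenic"
    for g in genes:
        if not overlaps(site, g.interval):
            continue
        if any(overlaps(site, ex) for ex in g.exons):
            context = "exonic"
            break
        context = "intronic"

    relation, dist = _tss_relation(site, gene)
    return PositionalAnnotation(
        genic_context=context,  # type: ignore[arg-type]
        tss_relation=relation,  # type: ignore[arg-type]
        signed_tss_distance=dist,
    )


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals as maximal connected (overlapping) blocks per
    chromosome, sorted by position. Bookended intervals stay separate,
    consistent with the half-open overlap rule."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
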