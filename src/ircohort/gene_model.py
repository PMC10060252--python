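"""Gene models and constitutive (shared) exonic/intronic region derivation.

Coordinates are 0-based, half-open throughout; GTF input (1-based, closed)
is converted at the reader boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Transcript",
    "ReferenceIntron",
    "GeneModel",
    "GtfFormatError",
    "read_gtf",
    "derive_shared_regions",
    "enumerate_reference_introns",
    "write_bed",
]


class GtfFormatError(ValueError):
    """Raised when a GTF line cannot be parsed into an exon record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """An isoform: ordered, non-overlapping exons on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans multiple "
                "chromosomes or strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} exons unsorted or "
                    f"overlapping at {a} / {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, left to right."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)


@dataclass(frozen=True)
class ReferenceIntron:
    """An intron of the reference isoform with its flanking exons.

    ``ordinal`` is the 1-based index in 5'->3' transcription order;
    ``upstream_exon`` is 5' of the intron in transcription order.
    """

    intron: GenomicInterval
    upstream_exon: GenomicInterval
    downstream_exon: GenomicInterval
    ordinal: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[Transcript, ...]
    shared_exons: tuple[GenomicInterval, ...] | None = None
    shared_introns: tuple[GenomicInterval, ...] | None = None
    reference_introns: tuple[ReferenceIntron, ...] | None = None

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def union_span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def reference_transcript(self) -> Transcript:
        """Designated isoform for per-intron analysis.

        Most exons; ties broken by longest span, then smallest
        transcript_id.
        """
        return min(
            self.transcripts,
            key=lambda t: (-len(t.exons), -t.span.length, t.transcript_id),
        )


# ---------------------------------------------------------------------------
# interval-set arithmetic (sorted, disjoint interval lists)
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> tuple[GenomicInterval, ...]:
    """Merge overlapping/adjacent intervals into maximal disjoint ones."""
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    if not ivs:
        return ()
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = replace(last, end=iv.end)
        else:
            out.append(iv)
    return tuple(out)


def intersect_interval_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[GenomicInterval, ...]:
    """Intersection of two sorted disjoint interval sets (same chrom)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(replace(a[i], start=lo, end=hi))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return tuple(out)


def subtract_from_span(
    span: GenomicInterval, holes: Sequence[GenomicInterval]
) -> tuple[GenomicInterval, ...]:
    """``span`` minus a sorted disjoint set of sub-intervals."""
    out = []
    cursor = span.start
    for h in holes:
        lo = max(h.start, span.start)
        hi = min(h.end, span.end)
        if lo >= hi:
            continue
        if lo > cursor:
            out.append(replace(span, start=cursor, end=lo))
        cursor = max(cursor, hi)
    if cursor < span.end:
        out.append(replace(span, start=cursor, end=span.end))
    return tuple(out)


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[GeneModel]:
    """Parse exon features from a GTF file into one GeneModel per gene.

    Only ``exon`` features are consumed; 1-based closed coordinates are
    converted to 0-based half-open. Genes that appear in the file (any
    feature) but carry no exon records are skipped with a warning.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    seen_genes: set[str] = set()
    genes_with_exons: set[str] = set()
    order: list[tuple[str, str]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            attr_map = dict(_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise GtfFormatError(
                    f"{path}:{lineno}: missing gene_id attribute"
                )
            seen_genes.add(gene_id)
            if feature != "exon":
                continue
            tx_id = attr_map.get("transcript_id")
            if tx_id is None:
                raise GtfFormatError(
                    f"{path}:{lineno}: exon without transcript_id attribute"
                )
            try:
                start = int(start_s) - 1  # GTF is 1-based closed
                end = int(end_s)
            except ValueError as exc:
                raise GtfFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise GtfFormatError(
                    f"{path}:{lineno}: exon end {end_s} <= start {start_s}"
                )
            if strand not in ("+", "-"):
                strand = "."
            key = (gene_id, tx_id)
            if key not in exons:
                exons[key] = []
                order.append(key)
            exons[key].append(GenomicInterval(chrom, start, end, strand))
            genes_with_exons.add(gene_id)

    skipped = seen_genes - genes_with_exons
    for gid in sorted(skipped):
        logger.warning("gene %s has no exon records; skipped", gid)

    by_gene: dict[str, list[Transcript]] = {}
    gene_order: list[str] = []
    for gene_id, tx_id in order:
        ivs = merge_intervals(exons[(gene_id, tx_id)])
        tx = Transcript(tx_id, gene_id, ivs)
        if gene_id not in by_gene:
            by_gene[gene_id] = []
            gene_order.append(gene_id)
        by_gene[gene_id].append(tx)

    return [GeneModel(gid, tuple(by_gene[gid])) for gid in gene_order]


# ---------------------------------------------------------------------------
# shared-region derivation
# ---------------------------------------------------------------------------


def derive_shared_regions(gene: GeneModel) -> GeneModel:
    """Classify bases over the transcript-span union into shared regions.

    A base is shared-exonic iff it is covered by every transcript of the
    gene and exonic in all of them; shared-intronic iff covered by all and
    intronic in all. Mixed bases are ambiguous and excluded from both.
    """
    txs = gene.transcripts
    common_start = max(t.span.start for t in txs)
    common_end = min(t.span.end for t in txs)
    if common_start >= common_end:
        return replace(gene, shared_exons=(), shared_introns=())

    common = GenomicInterval(
        gene.chrom, common_start, common_end, gene.strand
    )
    shared_ex: tuple[GenomicInterval, ...] = (common,)
    shared_in: tuple[GenomicInterval, ...] = (common,)
    for t in txs:
        clipped_ex = intersect_interval_sets(t.exons, (common,))
        shared_ex = intersect_interval_sets(shared_ex, clipped_ex)
        intronic = subtract_from_span(common, t.exons)
        shared_in = intersect_interval_sets(shared_in, intronic)
    return replace(
        gene,
        shared_exons=merge_intervals(shared_ex),
        shared_introns=merge_intervals(shared_in),
    )


def enumerate_reference_introns(gene: GeneModel) -> GeneModel:
    """Attach the ordered intron list (with flanking exons) of the
    reference isoform. Single-exon reference transcripts yield an empty
    list."""
    if gene.shared_exons is None:
        raise ValueError(
            f"gene {gene.gene_id}: derive_shared_regions must run first"
        )
    ref = gene.reference_transcript()
    introns = ref.introns()
    records = []
    n = len(introns)
    for left_idx, intron in enumerate(introns):
        left_exon = ref.exons[left_idx]
        right_exon = ref.exons[left_idx + 1]
        if gene.strand == "-":
            ordinal = n - left_idx
            up, down = right_exon, left_exon
        else:
            ordinal = left_idx + 1
            up, down = left_exon, right_exon
        records.append(ReferenceIntron(intron, up, down, ordinal))
    records.sort(key=lambda r: r.ordinal)
    return replace(gene, reference_introns=tuple(records))


def write_bed(path, intervals: Iterable[tuple[str, GenomicInterval]]) -> None:
    """Write (name, interval) pairs as BED6."""
    with open(path, "w") as fh:
        for name, iv in intervals:
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n"
            )
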