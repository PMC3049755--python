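"""Shared domain types and genomic-interval arithmetic.

All coordinates inside the package are 0-based, half-open, on the forward
strand.  Conversion from the 1-based inclusive conventions of GFF3 and
tabular alignment output happens only at I/O boundaries (see :mod:`.io`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."


class Compartment(str, enum.Enum):
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"
    CHLOROPLAST = "chloroplast"


class ExpressionSupport(str, enum.Enum):
    GENE_MODEL = "gene_model_supported"
    LOCUS = "locus_supported"
    NONE = "none"


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    INVERTED = "inverted"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open ``(start, end)`` pairs.

    Result is sorted and pairwise disjoint.  Order-independent.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if end - start <= 0:
            raise ValidationError(f"non-positive interval ({start}, {end})")
        if start < 0:
            raise ValidationError(f"negative coordinate in ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of half-open intervals."""
    return sum(end - start for start, end in merge_intervals(intervals))


def subtract_intervals(
    minuend: Iterable[tuple[int, int]], subtrahend: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference ``minuend - subtrahend`` on half-open intervals."""
    result: list[tuple[int, int]] = []
    sub = list(subtrahend)
    cuts = merge_intervals(sub) if sub else []
    for start, end in merge_intervals(minuend):
        cursor = start
        for c_start, c_end in cuts:
            if c_end <= cursor or c_start >= end:
                continue
            if c_start > cursor:
                result.append((cursor, c_start))
            cursor = max(cursor, c_end)
            if cursor >= end:
                break
        if cursor < end:
            result.append((cursor, end))
    return result


def intersect_intervals(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two half-open interval sets."""
    out: list[tuple[int, int]] = []
    b_merged = merge_intervals(b)
    for start, end in merge_intervals(a):
        for b_start, b_end in b_merged:
            lo, hi = max(start, b_start), min(end, b_end)
            if lo < hi:
                out.append((lo, hi))
    return out


@dataclass
class GeneModel:
    """A protein-coding gene with its representative model.

    ``exons`` and ``cds_segments`` are sorted by genomic position;
    CDS segments must lie inside the exon union.  ``phases`` holds the
    per-CDS-segment phase in genomic order.
    """

    gene_id: str
    representative_model_id: str
    chrom: str
    strand: Strand
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    compartment: Compartment = Compartment.NUCLEAR
    is_te_gene: bool = False
    expression_support: ExpressionSupport = ExpressionSupport.NONE
    intact: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        if not self.cds_segments:
            raise ValidationError(f"{self.gene_id}: no CDS segments")
        exon_union = merge_intervals(self.exons)
        inside = intersect_intervals(self.cds_segments, exon_union)
        if interval_union_length(inside) != interval_union_length(self.cds_segments):
            raise ValidationError(
                f"{self.representative_model_id}: CDS segment outside any exon"
            )
        for (a_start, a_end), (b_start, b_end) in zip(
            self.cds_segments, self.cds_segments[1:]
        ):
            if b_start < a_end:
                raise ValidationError(
                    f"{self.representative_model_id}: overlapping CDS segments"
                )
        if not self.phases:
            self.phases = self._derive_phases()

    def _derive_phases(self) -> list[int]:
        phases = []
        done = 0
        segments = self.cds_segments
        if self.strand is Strand.MINUS:
            segments = segments[::-1]
        out = {}
        for seg in segments:
            out[seg] = (3 - done % 3) % 3
            done += seg[1] - seg[0]
        return [out[seg] for seg in self.cds_segments]

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_segments)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        ]

    def cds_boundaries(self) -> list[int]:
        """Genomic offsets of internal CDS-segment boundaries (splice sites)."""
        bounds: list[int] = []
        for (_, a_end), (b_start, _) in zip(self.cds_segments, self.cds_segments[1:]):
            bounds.extend([a_end, b_start])
        return bounds

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 0-based CDS offset (5'->3' in transcript order) to genomic."""
        if cds_pos < 0 or cds_pos >= self.cds_length:
            raise ValidationError(
                f"{self.gene_id}: CDS offset {cds_pos} out of range"
            )
        segments = self.cds_segments
        if self.strand is Strand.MINUS:
            remaining = cds_pos
            for start, end in reversed(segments):
                seg_len = end - start
                if remaining < seg_len:
                    return end - 1 - remaining
                remaining -= seg_len
        else:
            remaining = cds_pos
            for start, end in segments:
                seg_len = end - start
                if remaining < seg_len:
                    return start + remaining
                remaining -= seg_len
        raise AssertionError("unreachable")

    def genomic_to_cds(self, pos: int) -> int | None:
        """Inverse of :meth:`cds_to_genomic`; None when outside the CDS."""
        offset = 0
        segments = self.cds_segments
        if self.strand is Strand.MINUS:
            for start, end in reversed(segments):
                if start <= pos < end:
                    return offset + (end - 1 - pos)
                offset += end - start
            return None
        for start, end in segments:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
        return None

    def extract_cds(self, chrom_seq: str) -> str:
        from .seqs import revcomp

        parts = [chrom_seq[start:end] for start, end in self.cds_segments]
        seq = "".join(parts)
        if self.strand is Strand.MINUS:
            seq = revcomp(seq)
        return seq


@dataclass
class TeFragment:
    """One annotated transposable-element fragment."""

    te_id: str
    interval: GenomicInterval
    superfamily: str

    def __post_init__(self) -> None:
        if not self.superfamily:
            raise ValidationError(f"{self.te_id}: empty TE superfamily")


@dataclass
class HSP:
    """One local-alignment segment (high-scoring segment pair).

    Query/subject offsets are 0-based half-open on the forward coordinate
    system of each sequence; ``orientation`` is INVERTED when the subject
    was hit on the minus strand.  ``n_columns`` counts alignment columns
    including gap columns.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: Orientation
    percent_identity: float
    score: float
    e_value: float
    n_columns: int
    frame_offset: int | None = None
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValidationError(
                f"{self.query_id}->{self.subject_id}: bad query range "
                f"({self.q_start}, {self.q_end})"
            )
        if not (0 <= self.s_start < self.s_end):
            raise ValidationError(
                f"{self.query_id}->{self.subject_id}: bad subject range "
                f"({self.s_start}, {self.s_end})"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"{self.query_id}->{self.subject_id}: negative e-value"
            )
        if self.n_columns < max(self.q_end - self.q_start, self.s_end - self.s_start):
            raise ValidationError(
                f"{self.query_id}->{self.subject_id}: n_columns smaller than "
                "the longer aligned span"
            )

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class ThresholdConfig:
    """Every numeric threshold used across the pipeline.

    Defaults follow the study design this package reproduces: a 1e-3
    E-value for lineage-specificity calls, 0.01 for within-genome and
    outgroup searches, a 10% minimum merged query coverage, 5-bp splice
    boundary tolerance, 4-kb scaffold hit chaining, 95% coverage for
    "shared un-annotated ORF" candidates, 100-bp flanks for distant-genome
    segment extraction, adjusted p < 0.01 and |log2FC| > log2(1.5) for
    differential expression, and p < 0.05 for enrichment.
    """

    lsg_evalue_cutoff: float = 1e-3
    within_genome_evalue: float = 0.01
    min_query_coverage_pct: float = 10.0
    boundary_tolerance_bp: int = 5
    scaffold_chain_gap_bp: int = 4000
    intact_orf_coverage_pct: float = 95.0
    distant_flank_bp: int = 100
    de_adj_p: float = 0.01
    de_min_abs_log2fc: float = math.log2(1.5)
    enrichment_p: float = 0.05
    tandem_max_intervening_genes: int = 10

    def __post_init__(self) -> None:
        for name in (
            "lsg_evalue_cutoff",
            "within_genome_evalue",
            "min_query_coverage_pct",
            "boundary_tolerance_bp",
            "scaffold_chain_gap_bp",
            "intact_orf_coverage_pct",
            "distant_flank_bp",
            "de_adj_p",
            "de_min_abs_log2fc",
            "enrichment_p",
            "tandem_max_intervening_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        for name in ("min_query_coverage_pct", "intact_orf_coverage_pct"):
            if not (0 < getattr(self, name) <= 100):
                raise ValidationError(f"threshold {name} must be in (0, 100]")

    def with_overrides(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def round_pct(value: float, ndigits: int = 2) -> float:
    """Round half-away-from-zero, the convention used for printed shares."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def share_pct(numerator: int, denominator: int) -> float | None:
    """Percentage share rounded to 2 decimals; None for an empty group."""
    if denominator == 0:
        return None
    return round_pct(100.0 * numerator / denominator)


def median_siqr(values: Sequence[float]) -> tuple[float, float] | None:
    """Median and semi-interquartile range (Q3 - Q1) / 2; None if empty."""
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float((q3 - q1) / 2.0)
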