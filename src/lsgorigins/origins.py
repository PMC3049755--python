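"""Classification of LSG evolutionary origins from within-genome context.

Evidence streams: CDS-CDS overlap (overprinting), peptide/CDS paralog hits
with frame and orientation analysis (duplication), intron-exon boundary
patterns (retrotransposition vs unequal crossing over), synteny context
(tandem / distal / syntelog), TE-exon overlap (exaptation) and multi-source
chimerism.  A precedence policy rolls everything up into one primary
mechanism per LSG.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .io import GenomeCatalog
from .model import (
    GeneModel,
    HSP,
    Orientation,
    TeFragment,
    ThresholdConfig,
    ValidationError,
    interval_union_length,
    intersect_intervals,
    merge_intervals,
    share_pct,
    subtract_intervals,
)


class Mechanism(str, enum.Enum):
    OVERPRINTING = "overprinting"
    DUPLICATION = "duplication"
    TE_EXAPTATION = "te_exaptation"
    CHIMERIC = "chimeric"
    OUTGROUP_OUT_OF_FRAME = "outgroup_out_of_frame"
    OUTGROUP_INTERGENIC = "outgroup_intergenic"
    UNKNOWN = "unknown"


class MechanismDetail(str, enum.Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    INVERTED = "inverted"
    RETROTRANSPOSITION = "retrotransposition"
    UNEQUAL_CROSSING_OVER = "unequal_crossing_over"
    TANDEM = "tandem"
    DISTAL = "distal"
    SYNTELOG = "syntelog"
    WGD = "wgd"


#: Default precedence, most specific evidence first.
DEFAULT_PRECEDENCE: tuple[Mechanism, ...] = (
    Mechanism.CHIMERIC,
    Mechanism.OVERPRINTING,
    Mechanism.DUPLICATION,
    Mechanism.TE_EXAPTATION,
    Mechanism.OUTGROUP_OUT_OF_FRAME,
    Mechanism.OUTGROUP_INTERGENIC,
)


@dataclass
class Evidence:
    source: str
    feature_id: str
    query_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class OriginAssignment:
    gene_id: str
    primary_mechanism: Mechanism
    mechanism_detail: set[MechanismDetail] = field(default_factory=set)
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mechanism_detail and self.primary_mechanism not in (
            Mechanism.DUPLICATION,
            Mechanism.CHIMERIC,
        ):
            raise ValidationError(
                f"{self.gene_id}: detail set only valid for duplication/chimeric"
            )


# ---------------------------------------------------------------------------
# HSP merging and coverage
# ---------------------------------------------------------------------------


@dataclass
class MergedCoverage:
    """Merged non-overlapping query coverage of one query-subject pair."""

    query_id: str
    subject_id: str
    merged_intervals: list[tuple[int, int]]
    coverage_pct: float
    level: str  # "peptide" | "cds"
    hsps: list[HSP] = field(default_factory=list)


def merge_hsps(
    hits: Sequence[HSP],
    query_length: int,
    thresholds: ThresholdConfig = ThresholdConfig(),
    level: str = "peptide",
) -> MergedCoverage | None:
    """Concatenate overlapping HSPs of one pair; drop low-coverage pairs.

    Coverage counts alignment columns of the merged HSPs over the query
    length: the union of query spans plus any query-gap columns, so a
    gapped alignment can exceed 100%.  Pairs strictly below
    ``min_query_coverage_pct`` are discarded (None).
    """
    if not hits:
        return None
    query_id, subject_id = hits[0].query_id, hits[0].subject_id
    intervals = []
    gap_columns = 0
    for hsp in hits:
        if (hsp.query_id, hsp.subject_id) != (query_id, subject_id):
            raise ValidationError("merge_hsps: hits span several pairs")
        if hsp.q_end > query_length:
            raise ValidationError(
                f"{query_id}: HSP end {hsp.q_end} beyond query length {query_length}"
            )
        intervals.append((hsp.q_start, hsp.q_end))
        gap_columns += max(0, hsp.n_columns - hsp.q_span)
    merged = merge_intervals(intervals)
    columns = interval_union_length(merged) + gap_columns
    coverage = 100.0 * columns / query_length
    if coverage < thresholds.min_query_coverage_pct:
        return None
    return MergedCoverage(
        query_id=query_id,
        subject_id=subject_id,
        merged_intervals=merged,
        coverage_pct=coverage,
        level=level,
        hsps=list(hits),
    )


def merge_hits_by_pair(
    hits: Iterable[HSP],
    query_lengths: Mapping[str, int],
    thresholds: ThresholdConfig = ThresholdConfig(),
    level: str = "peptide",
    max_evalue: float | None = None,
) -> dict[tuple[str, str], MergedCoverage]:
    """Group a hit table by (query, subject) and merge each group."""
    cutoff = (
        max_evalue if max_evalue is not None else thresholds.within_genome_evalue
    )
    grouped: dict[tuple[str, str], list[HSP]] = {}
    for hsp in hits:
        if hsp.e_value < cutoff:
            grouped.setdefault((hsp.query_id, hsp.subject_id), []).append(hsp)
    out: dict[tuple[str, str], MergedCoverage] = {}
    for pair, pair_hits in grouped.items():
        merged = merge_hsps(pair_hits, query_lengths[pair[0]], thresholds, level)
        if merged is not None:
            out[pair] = merged
    return out


# ---------------------------------------------------------------------------
# Overlapping CDS (overprinting)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapPair:
    gene_a: str
    gene_b: str
    overlap_bp: int
    pair_type: str  # "LSG:LSG" | "LSG:nonLSG" | "nonLSG:nonLSG"


def find_overlapping_cds(
    catalog: GenomeCatalog, lsg_ids: set[str]
) -> list[OverlapPair]:
    """All gene pairs whose CDS unions intersect by >= 1 bp (any strand).

    Only CDS intervals count: genes sharing intronic or UTR span only are
    not reported, because lineage specificity is a peptide-level property.
    """
    pairs: list[OverlapPair] = []
    by_chrom = catalog.genes_by_chrom()
    for genes in by_chrom.values():
        for i, gene_a in enumerate(genes):
            for gene_b in genes[i + 1 :]:
                if gene_b.span.start >= gene_a.span.end:
                    break
                overlap = interval_union_length(
                    intersect_intervals(gene_a.cds_segments, gene_b.cds_segments)
                )
                if overlap >= 1:
                    a_lsg = gene_a.gene_id in lsg_ids
                    b_lsg = gene_b.gene_id in lsg_ids
                    pair_type = (
                        "LSG:LSG"
                        if a_lsg and b_lsg
                        else "nonLSG:nonLSG"
                        if not (a_lsg or b_lsg)
                        else "LSG:nonLSG"
                    )
                    pairs.append(
                        OverlapPair(
                            gene_a.gene_id, gene_b.gene_id, overlap, pair_type
                        )
                    )
    return pairs


# ---------------------------------------------------------------------------
# Frame and orientation
# ---------------------------------------------------------------------------


@dataclass
class FrameReport:
    query_id: str
    subject_id: str
    in_frame: bool
    out_of_frame_intervals: list[tuple[int, int]]  # nucleotide (CDS) space


def detect_out_of_frame(
    peptide_cov: MergedCoverage | None, cds_cov: MergedCoverage | None
) -> FrameReport | None:
    """Compare peptide vs CDS coverage of one LSG:subject pair.

    Greater CDS than peptide coverage flags additional out-of-frame
    alignment segments; the out-of-frame nucleotide intervals are the CDS
    merged intervals minus the peptide intervals mapped to nucleotides.
    A missing peptide hit counts as zero coverage.
    """
    if peptide_cov is None and cds_cov is None:
        return None
    pep_pct = peptide_cov.coverage_pct if peptide_cov else 0.0
    if cds_cov is None or cds_cov.coverage_pct <= pep_pct:
        ref = peptide_cov if peptide_cov is not None else cds_cov
        return FrameReport(ref.query_id, ref.subject_id, True, [])
    pep_nt = (
        [(s * 3, e * 3) for s, e in peptide_cov.merged_intervals]
        if peptide_cov
        else []
    )
    extra = subtract_intervals(cds_cov.merged_intervals, pep_nt)
    return FrameReport(cds_cov.query_id, cds_cov.subject_id, False, extra)


def detect_orientation(cds_hsps: Sequence[HSP]) -> Orientation:
    """Orientation of the dominant (most alignment columns) HSP."""
    if not cds_hsps:
        raise ValidationError("detect_orientation: no HSPs")
    dominant = max(cds_hsps, key=lambda h: (h.n_columns, h.score))
    return dominant.orientation


# ---------------------------------------------------------------------------
# Duplication mechanism (retrotransposition vs unequal crossing over)
# ---------------------------------------------------------------------------


class DuplicationMechanism(str, enum.Enum):
    UNEQUAL_CROSSING_OVER = "unequal_crossing_over"
    RETROTRANSPOSITION = "retrotransposition"
    INDETERMINATE = "indeterminate"


def _internal_cds_boundaries_tx(gene: GeneModel) -> list[int]:
    """Internal splice boundaries as CDS (transcript-order) offsets."""
    lengths = [end - start for start, end in gene.cds_segments]
    if gene.strand.value == "-":
        lengths = lengths[::-1]
    bounds = []
    total = 0
    for seg_len in lengths[:-1]:
        total += seg_len
        bounds.append(total)
    return bounds


def classify_duplication_mechanism(
    lsg: GeneModel,
    subject: GeneModel,
    cds_hsps: Sequence[HSP],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> DuplicationMechanism:
    """Distinguish duplication mechanisms via intron-exon boundaries.

    Unequal crossing over: an LSG splice boundary falls within
    ``boundary_tolerance_bp`` (inclusive) of a subject boundary inside the
    aligned region.  Retrotransposition: the alignment crosses >= 1 subject
    boundary while the corresponding LSG region is intron-free.  No
    boundary inside any alignment -> indeterminate.
    """
    tol = thresholds.boundary_tolerance_bp
    lsg_bounds = _internal_cds_boundaries_tx(lsg)
    subject_bounds = _internal_cds_boundaries_tx(subject)
    lsg_len = lsg.cds_length
    subj_len = subject.cds_length

    saw_uxo = False
    saw_retro = False
    for hsp in cds_hsps:
        if hsp.q_end > lsg_len or hsp.s_end > subj_len:
            raise ValidationError(
                f"{hsp.query_id}->{hsp.subject_id}: alignment outside model"
            )
        q_bounds_in = [b for b in lsg_bounds if hsp.q_start < b < hsp.q_end]
        s_bounds_in = [b for b in subject_bounds if hsp.s_start < b < hsp.s_end]
        # subject boundaries mapped to query offsets through the alignment
        mapped = []
        for b in s_bounds_in:
            if hsp.orientation is Orientation.INVERTED:
                mapped.append(hsp.q_start + (hsp.s_end - b))
            else:
                mapped.append(hsp.q_start + (b - hsp.s_start))
        if any(
            abs(qb - mb) <= tol for qb in q_bounds_in for mb in mapped
        ):
            saw_uxo = True
        if s_bounds_in and not q_bounds_in:
            saw_retro = True
    if saw_uxo:
        return DuplicationMechanism.UNEQUAL_CROSSING_OVER
    if saw_retro:
        return DuplicationMechanism.RETROTRANSPOSITION
    return DuplicationMechanism.INDETERMINATE


# ---------------------------------------------------------------------------
# Duplication context (tandem / distal / syntelog)
# ---------------------------------------------------------------------------


class DuplicationContext(str, enum.Enum):
    TANDEM = "tandem"
    DISTAL = "distal"
    SYNTELOG = "syntelog"


def classify_duplication_context(
    pairs: Sequence[tuple[str, str]],
    catalog: GenomeCatalog,
    syntelog_pairs: set[frozenset[str]] | None = None,
    wgd_pairs: set[frozenset[str]] | None = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> dict[tuple[str, str], tuple[DuplicationContext, bool]]:
    """Classify each (LSG, subject) pair; the bool marks WGD membership.

    Syntelog-table membership wins; otherwise a pair on one chromosome
    separated by at most ``tandem_max_intervening_genes`` is tandem, and
    anything else is distal.
    """
    syntelog_pairs = syntelog_pairs or set()
    wgd_pairs = wgd_pairs or set()
    rank: dict[str, tuple[str, int]] = {}
    for chrom, genes in catalog.genes_by_chrom().items():
        for i, gene in enumerate(genes):
            rank[gene.gene_id] = (chrom, i)
    out: dict[tuple[str, str], tuple[DuplicationContext, bool]] = {}
    for lsg_id, subject_id in pairs:
        key = frozenset((lsg_id, subject_id))
        if key in syntelog_pairs:
            out[(lsg_id, subject_id)] = (DuplicationContext.SYNTELOG, key in wgd_pairs)
            continue
        chrom_a, rank_a = rank[lsg_id]
        chrom_b, rank_b = rank[subject_id]
        if (
            chrom_a == chrom_b
            and abs(rank_a - rank_b) - 1 <= thresholds.tandem_max_intervening_genes
        ):
            out[(lsg_id, subject_id)] = (DuplicationContext.TANDEM, False)
        else:
            out[(lsg_id, subject_id)] = (DuplicationContext.DISTAL, False)
    return out


# ---------------------------------------------------------------------------
# TE exaptation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TeOverlap:
    gene_id: str
    te_id: str
    superfamily: str
    overlap_bp: int
    overlap_intervals: tuple[tuple[int, int], ...]  # genomic


def detect_te_exaptation(
    catalog: GenomeCatalog,
    lsg_ids: set[str],
    level: str = "exon",
    te_fragments: Sequence[TeFragment] | None = None,
) -> tuple[list[TeOverlap], pd.DataFrame]:
    """TE-exon (or TE-CDS) overlaps plus per-superfamily tallies.

    A gene is TE-exapted when at least one of its exons (or CDS segments,
    with ``level='cds'``) intersects a TE fragment by >= 1 bp.  The tally
    counts distinct exapted fragments per superfamily split by LSG status;
    a gene exapting several superfamilies contributes one case per
    superfamily.
    """
    if level not in ("exon", "cds"):
        raise ValidationError(f"unknown overlap level {level!r}")
    fragments = list(te_fragments) if te_fragments is not None else catalog.te_fragments
    by_chrom: dict[str, list[TeFragment]] = {}
    for te in fragments:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    overlaps: list[TeOverlap] = []
    for gene in catalog.genes.values():
        intervals = gene.exons if level == "exon" else gene.cds_segments
        for te in by_chrom.get(gene.chrom, []):
            shared = intersect_intervals(
                intervals, [(te.interval.start, te.interval.end)]
            )
            bp = interval_union_length(shared) if shared else 0
            if bp >= 1:
                overlaps.append(
                    TeOverlap(
                        gene.gene_id, te.te_id, te.superfamily, bp, tuple(shared)
                    )
                )
    tally_rows = []
    superfamilies = sorted({o.superfamily for o in overlaps})
    for superfamily in superfamilies:
        lsg_frags = {
            o.te_id for o in overlaps if o.superfamily == superfamily and o.gene_id in lsg_ids
        }
        non_frags = {
            o.te_id
            for o in overlaps
            if o.superfamily == superfamily and o.gene_id not in lsg_ids
        }
        lsg_genes = {
            o.gene_id for o in overlaps if o.superfamily == superfamily and o.gene_id in lsg_ids
        }
        non_genes = {
            o.gene_id
            for o in overlaps
            if o.superfamily == superfamily and o.gene_id not in lsg_ids
        }
        tally_rows.append(
            {
                "superfamily": superfamily,
                "lsg_fragments": len(lsg_frags),
                "nonlsg_fragments": len(non_frags),
                "lsg_genes": len(lsg_genes),
                "nonlsg_genes": len(non_genes),
            }
        )
    tally = pd.DataFrame(
        tally_rows,
        columns=[
            "superfamily",
            "lsg_fragments",
            "nonlsg_fragments",
            "lsg_genes",
            "nonlsg_genes",
        ],
    )
    if len(tally):
        total_lsg = int(tally["lsg_fragments"].sum())
        total_non = int(tally["nonlsg_fragments"].sum())
        tally["lsg_fragment_share_pct"] = [
            share_pct(v, total_lsg) for v in tally["lsg_fragments"]
        ]
        tally["nonlsg_fragment_share_pct"] = [
            share_pct(v, total_non) for v in tally["nonlsg_fragments"]
        ]
    return overlaps, tally


# ---------------------------------------------------------------------------
# Chimerism
# ---------------------------------------------------------------------------


@dataclass
class ChimericReport:
    gene_id: str
    is_chimeric: bool
    parents: list[str]
    composition: str  # multi_parent | parent_te | overlap_parent | overlap_te | none
    evidence: list[Evidence] = field(default_factory=list)


def _mutual_overlap_small(
    a: list[tuple[int, int]], b: list[tuple[int, int]], max_fraction: float
) -> bool:
    shorter = min(interval_union_length(a), interval_union_length(b))
    shared = interval_union_length(intersect_intervals(a, b)) if a and b else 0
    return shared <= max_fraction * shorter


def detect_chimeric(
    gene_id: str,
    parent_hits: Mapping[str, list[tuple[int, int]]],
    te_overlaps: Mapping[str, list[tuple[int, int]]] | None = None,
    cds_overlaps: Mapping[str, list[tuple[int, int]]] | None = None,
    parent_homology: set[frozenset[str]] | None = None,
    max_mutual_overlap_fraction: float = 0.10,
) -> ChimericReport:
    """Decide whether an LSG is assembled from several unrelated sources.

    Evidence items are query-interval sets: merged hits per parent gene,
    TE overlaps mapped to query space, and CDS overlap regions.  Chimeric
    requires >= 2 items occupying query regions that mutually overlap by
    at most ``max_mutual_overlap_fraction`` of the shorter region, with
    every contributing parent pair mutually non-homologous.
    """
    te_overlaps = te_overlaps or {}
    cds_overlaps = cds_overlaps or {}
    parent_homology = parent_homology or set()
    items: list[tuple[str, str, list[tuple[int, int]]]] = []
    for parent, intervals in sorted(parent_hits.items()):
        items.append(("parent", parent, merge_intervals(intervals)))
    for te_id, intervals in sorted(te_overlaps.items()):
        items.append(("te", te_id, merge_intervals(intervals)))
    for other, intervals in sorted(cds_overlaps.items()):
        items.append(("overlap", other, merge_intervals(intervals)))

    best: tuple[str, str, str, str] | None = None
    for i, (kind_a, id_a, ivs_a) in enumerate(items):
        for kind_b, id_b, ivs_b in items[i + 1 :]:
            if kind_a == kind_b == "parent" and (
                frozenset((id_a, id_b)) in parent_homology
            ):
                continue
            if kind_a == "parent" and kind_b == "parent" and id_a == id_b:
                continue
            if not _mutual_overlap_small(ivs_a, ivs_b, max_mutual_overlap_fraction):
                continue
            kinds = frozenset((kind_a, kind_b))
            if kinds == {"parent"}:
                composition = "multi_parent"
            elif kinds == {"parent", "te"}:
                composition = "parent_te"
            elif kinds == {"parent", "overlap"}:
                composition = "overlap_parent"
            elif kinds == {"te", "overlap"}:
                composition = "overlap_te"
            else:
                continue  # te:te or overlap:overlap is not chimeric evidence
            cand = (composition, kind_a, id_a, id_b)
            if best is None or cand[0] == "multi_parent":
                best = cand
    if best is None:
        return ChimericReport(gene_id, False, [], "none")
    composition = best[0]
    parents = sorted(
        {pid for kind, pid, _ in items if kind == "parent"}
    )
    evidence = [
        Evidence(source=kind, feature_id=fid, query_intervals=ivs)
        for kind, fid, ivs in items
    ]
    return ChimericReport(gene_id, True, parents, composition, evidence)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    k: int, K: int, n: int, N: int, tail: str = "upper"
) -> float:
    """Tail probability for X ~ Hypergeometric(N, K, n).

    ``upper`` returns P(X >= k); ``lower`` returns P(X <= k).  Computed in
    log space through scipy's logsf/logcdf for numerical stability.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if tail == "upper":
        if k == 0:
            return 1.0
        log_p = hypergeom.logsf(k - 1, N, K, n)
    elif tail == "lower":
        log_p = hypergeom.logcdf(k, N, K, n)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return float(min(1.0, math.exp(log_p)))


# ---------------------------------------------------------------------------
# Rollup
# ---------------------------------------------------------------------------


@dataclass
class OriginEvidencePack:
    """Everything the rollup needs for one run, keyed by LSG id."""

    overprint: dict[str, list[Evidence]] = field(default_factory=dict)
    duplication: dict[str, list[Evidence]] = field(default_factory=dict)
    duplication_detail: dict[str, set[MechanismDetail]] = field(default_factory=dict)
    te_exaptation: dict[str, list[Evidence]] = field(default_factory=dict)
    chimeric: dict[str, ChimericReport] = field(default_factory=dict)
    outgroup_out_of_frame: dict[str, list[Evidence]] = field(default_factory=dict)
    outgroup_intergenic: dict[str, list[Evidence]] = field(default_factory=dict)


def summarize_origins(
    lsg_ids: Iterable[str],
    pack: OriginEvidencePack,
    precedence: Sequence[Mechanism] = DEFAULT_PRECEDENCE,
) -> tuple[dict[str, OriginAssignment], pd.DataFrame]:
    """One OriginAssignment per LSG plus the category rollup table.

    Precedence decides the primary mechanism when several classifiers
    fired; category counts always sum to the LSG total.
    """
    lsg_ids = sorted(lsg_ids)
    assignments: dict[str, OriginAssignment] = {}
    for gene_id in lsg_ids:
        sources: dict[Mechanism, list[Evidence]] = {}
        if gene_id in pack.chimeric and pack.chimeric[gene_id].is_chimeric:
            sources[Mechanism.CHIMERIC] = pack.chimeric[gene_id].evidence
        if gene_id in pack.overprint:
            sources[Mechanism.OVERPRINTING] = pack.overprint[gene_id]
        if gene_id in pack.duplication:
            sources[Mechanism.DUPLICATION] = pack.duplication[gene_id]
        if gene_id in pack.te_exaptation:
            sources[Mechanism.TE_EXAPTATION] = pack.te_exaptation[gene_id]
        if gene_id in pack.outgroup_out_of_frame:
            sources[Mechanism.OUTGROUP_OUT_OF_FRAME] = pack.outgroup_out_of_frame[
                gene_id
            ]
        if gene_id in pack.outgroup_intergenic:
            sources[Mechanism.OUTGROUP_INTERGENIC] = pack.outgroup_intergenic[gene_id]
        primary = Mechanism.UNKNOWN
        for mechanism in precedence:
            if mechanism in sources:
                primary = mechanism
                break
        detail: set[MechanismDetail] = set()
        if primary is Mechanism.DUPLICATION:
            detail = set(pack.duplication_detail.get(gene_id, set()))
        assignments[gene_id] = OriginAssignment(
            gene_id=gene_id,
            primary_mechanism=primary,
            mechanism_detail=detail,
            evidence=sources.get(primary, []),
        )
    counts = {mechanism: 0 for mechanism in Mechanism}
    for assignment in assignments.values():
        counts[assignment.primary_mechanism] += 1
    total = len(lsg_ids)
    table = pd.DataFrame(
        [
            {
                "mechanism": mechanism.value,
                "count": counts[mechanism],
                "denominator": total,
                "share_pct": share_pct(counts[mechanism], total),
            }
            for mechanism in Mechanism
        ]
    )
    assert int(table["count"].sum()) == total
    return assignments, table


def origin_rollup_from_counts(
    counts: Mapping[str, int], denominator: int
) -> pd.DataFrame:
    """Category table from pre-tabulated counts (printed-figure style)."""
    rows = []
    for name, count in counts.items():
        rows.append(
            {
                "mechanism": name,
                "count": count,
                "denominator": denominator,
                "share_pct": share_pct(count, denominator),
            }
        )
    return pd.DataFrame(rows)
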