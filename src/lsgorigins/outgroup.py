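"""Tracing species-only LSGs into outgroup genomes.

Scaffold hits are chained (transitive 4-kb gap clustering around the
top-scoring hit), the chained region is aligned back to the LSG CDS with a
frameshift-aware global-local alignment, and each projection is classified
into one of four ORF-disruption categories: INTACT, MSC (missing start
codon), ISC_OR_INDEL (internal stop and/or frameshift indel) or BOTH.
Also here: distant (non-family) genome scans with reciprocal checks,
reciprocal best hits and group-wise dN/dS comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .dnds import DndsResult
from .model import (
    HSP,
    Orientation,
    ThresholdConfig,
    ValidationError,
    median_siqr,
    share_pct,
)
from .search import make_aligner, NUCLEOTIDE_SCORING
from .seqs import STOP_CODONS


class OrfCategory(str, enum.Enum):
    INTACT = "INTACT"
    MSC = "MSC"
    ISC_OR_INDEL = "ISC_OR_INDEL"
    BOTH = "BOTH"


@dataclass
class ChainedRegion:
    scaffold: str
    start: int
    end: int
    orientation: Orientation
    hits: list[HSP] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def chain_scaffold_hits(
    hits: Sequence[HSP],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> ChainedRegion | None:
    """Cluster outgroup scaffold hits of one LSG and pick the top cluster.

    Hits below the within-genome E-value cutoff are clustered on the
    top-scoring hit's scaffold by transitive gaps of at most
    ``scaffold_chain_gap_bp``; the selected region spans the extreme
    coordinates of the cluster containing the top hit.  Returns None when
    no hit qualifies (a candidate de novo / differential-loss signal).
    Independent of hit input order.
    """
    qualifying = [h for h in hits if h.e_value < thresholds.within_genome_evalue]
    if not qualifying:
        return None
    top = max(qualifying, key=lambda h: (h.score, -h.e_value, h.subject_id))
    same_scaffold = sorted(
        (h for h in qualifying if h.subject_id == top.subject_id),
        key=lambda h: (h.s_start, h.s_end),
    )
    clusters: list[list[HSP]] = []
    for hsp in same_scaffold:
        if (
            clusters
            and hsp.s_start - max(h.s_end for h in clusters[-1])
            <= thresholds.scaffold_chain_gap_bp
        ):
            clusters[-1].append(hsp)
        else:
            clusters.append([hsp])
    chosen = next(c for c in clusters if top in c)
    dominant = max(chosen, key=lambda h: (h.n_columns, h.score))
    return ChainedRegion(
        scaffold=top.subject_id,
        start=min(h.s_start for h in chosen),
        end=max(h.s_end for h in chosen),
        orientation=dominant.orientation,
        hits=chosen,
    )


@dataclass
class OrfProjection:
    """Result of projecting an LSG CDS onto an outgroup region."""

    lsg_id: str
    scaffold: str
    region_start: int
    region_end: int
    category: OrfCategory
    coverage_pct: float
    start_codon_present: bool
    start_not_covered: bool
    internal_stop_count: int
    frameshift_indel_count: int
    disruption_positions: list[int] = field(default_factory=list)  # CDS offsets
    #: CDS offset -> aligned outgroup base, or None where the outgroup has a
    #: gap; offsets absent from the map were not covered by the alignment.
    aligned_region_base: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        disrupted = self.internal_stop_count + self.frameshift_indel_count > 0
        expected = (
            OrfCategory.INTACT
            if self.start_codon_present and not disrupted
            else OrfCategory.MSC
            if not self.start_codon_present and not disrupted
            else OrfCategory.ISC_OR_INDEL
            if self.start_codon_present
            else OrfCategory.BOTH
        )
        if expected is not self.category:
            raise ValidationError(
                f"{self.lsg_id}: category {self.category} inconsistent with "
                f"disruption inventory"
            )


_projection_aligner = None


def _get_projection_aligner():
    global _projection_aligner
    if _projection_aligner is None:
        aligner = make_aligner(NUCLEOTIDE_SCORING)
        aligner.mode = "global"
        # the region is local: its unaligned overhangs (gap columns in the
        # query row at the alignment ends) are free, the query is global
        aligner.end_deletion_score = 0.0
        _projection_aligner = aligner
    return _projection_aligner


def _gapped_strings(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def project_orf(
    lsg_id: str,
    cds_seq: str,
    region_seq: str,
    thresholds: ThresholdConfig = ThresholdConfig(),
    scaffold: str = "region",
    region_start: int = 0,
) -> OrfProjection | None:
    """Align an LSG CDS onto an outgroup region and inventory disruptions.

    The CDS is aligned globally against a locally anchored region (affine
    gaps; region end gaps free).  Frameshift indels are alignment gap runs
    whose length is not a multiple of 3; internal stops come from
    translating the region's aligned span in the frame anchored at the
    LSG's codon boundaries (the frame therefore shifts through indels, as
    it would in the genome).  The terminal stop codon is not counted.
    Returns None when coverage falls below ``min_query_coverage_pct``.
    """
    cds_seq = cds_seq.upper()
    region_seq = region_seq.upper()
    if len(region_seq) < 3:
        raise ValidationError(f"{lsg_id}: outgroup region shorter than one codon")
    aligner = _get_projection_aligner()
    alignment = aligner.align(region_seq, cds_seq)[0]
    region_gapped, cds_gapped = _gapped_strings(alignment)

    n_cols = len(region_gapped)
    both = [
        i
        for i in range(n_cols)
        if region_gapped[i] != "-" and cds_gapped[i] != "-"
    ]
    if not both:
        return None
    i0, i1 = both[0], both[-1]
    core_region = region_gapped[i0 : i1 + 1]
    core_cds = cds_gapped[i0 : i1 + 1]
    columns = i1 - i0 + 1
    coverage = 100.0 * columns / len(cds_seq)
    if coverage < thresholds.min_query_coverage_pct:
        return None

    # query (CDS) offset at the start of the core and per-column mapping
    q_before = sum(1 for c in cds_gapped[:i0] if c != "-")
    q_offsets: list[int] = []
    q_pos = q_before
    for c in core_cds:
        q_offsets.append(q_pos)
        if c != "-":
            q_pos += 1
    q_end = q_pos  # one past last aligned CDS offset
    start_covered = q_before == 0
    end_covered = q_end == len(cds_seq)

    # frameshift indels: internal gap runs with length != 0 (mod 3)
    frameshifts = 0
    disruption_positions: list[int] = []
    for seq in (core_region, core_cds):
        run = 0
        run_start_col = 0
        for col, char in enumerate(seq + "X"):
            if char == "-":
                if run == 0:
                    run_start_col = col
                run += 1
            else:
                if run and run % 3 != 0:
                    frameshifts += 1
                    disruption_positions.append(q_offsets[run_start_col])
                run = 0

    # internal stops: translate the region's aligned bases in the frame
    # anchored at the first complete CDS codon inside the core
    region_sub = core_region.replace("-", "")
    first_full = ((q_before + 2) // 3) * 3  # first CDS offset on a codon boundary
    offset_bases = 0
    for col, char in enumerate(core_cds):
        if q_offsets[col] >= first_full and char != "-":
            break
        if core_region[col] != "-":
            offset_bases += 1
    projected = region_sub[offset_bases:]
    stop_count = 0
    n_proj_codons = (len(projected)) // 3
    for idx in range(n_proj_codons):
        codon = projected[idx * 3 : idx * 3 + 3]
        if codon not in STOP_CODONS:
            continue
        if idx == 0 and start_covered:
            continue  # the start-codon position is never an internal stop
        if idx == n_proj_codons - 1 and end_covered:
            continue  # terminal stop codon excluded
        stop_count += 1
        disruption_positions.append(first_full + idx * 3)

    if start_covered:
        start_codon = region_sub[:3] if len(region_sub) >= 3 else ""
        start_present = start_codon == "ATG"
        start_not_covered = False
    else:
        start_present = True  # cannot claim a missing start we cannot see
        start_not_covered = True

    aligned_base: dict[int, str | None] = {}
    for col, char in enumerate(core_cds):
        if char != "-":
            region_char = core_region[col]
            aligned_base[q_offsets[col]] = None if region_char == "-" else region_char

    disrupted = stop_count + frameshifts > 0
    category = (
        OrfCategory.INTACT
        if start_present and not disrupted
        else OrfCategory.MSC
        if not start_present and not disrupted
        else OrfCategory.ISC_OR_INDEL
        if start_present
        else OrfCategory.BOTH
    )
    return OrfProjection(
        lsg_id=lsg_id,
        scaffold=scaffold,
        region_start=region_start,
        region_end=region_start + len(region_seq),
        category=category,
        coverage_pct=coverage,
        start_codon_present=start_present,
        start_not_covered=start_not_covered,
        internal_stop_count=stop_count,
        frameshift_indel_count=frameshifts,
        disruption_positions=sorted(disruption_positions),
        aligned_region_base=aligned_base,
    )


def classify_projection_set(
    projections: Sequence[OrfProjection],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Category counts/shares, coverage distributions, high-coverage list.

    The summary row per category carries count, share over the explicit
    projection denominator, and the coverage median with its
    semi-interquartile range.  The second return value lists LSGs with an
    INTACT projection at >= ``intact_orf_coverage_pct`` coverage
    (candidate shared un-annotated ORFs).
    """
    total = len(projections)
    rows = []
    for category in OrfCategory:
        members = [p for p in projections if p.category is category]
        stats = median_siqr([p.coverage_pct for p in members])
        rows.append(
            {
                "category": category.value,
                "count": len(members),
                "denominator": total,
                "share_pct": share_pct(len(members), total),
                "coverage_median": None if stats is None else round(stats[0], 2),
                "coverage_siqr": None if stats is None else round(stats[1], 4),
            }
        )
    high_intact = sorted(
        p.lsg_id
        for p in projections
        if p.category is OrfCategory.INTACT
        and p.coverage_pct >= thresholds.intact_orf_coverage_pct
    )
    return pd.DataFrame(rows), high_intact


# ---------------------------------------------------------------------------
# Distant (non-family) genome scans
# ---------------------------------------------------------------------------


@dataclass
class DistantSpeciesData:
    """Inputs for one distant species: hit tables plus sequence databases."""

    cds_hits: list[HSP] = field(default_factory=list)
    genomic_hits: list[HSP] = field(default_factory=list)
    cds_seqs: dict[str, str] = field(default_factory=dict)
    genome_seqs: dict[str, str] = field(default_factory=dict)


@dataclass
class DistantEvidence:
    lsg_id: str
    species: str
    evidence: str  # distant_cds | distant_intergenic | none
    subject_id: str | None = None
    segment: tuple[int, int] | None = None


def _qualifying_top(
    hits: Iterable[HSP],
    lsg_id: str,
    query_length: int,
    thresholds: ThresholdConfig,
) -> HSP | None:
    from .origins import merge_hits_by_pair
    from .search import top_hit

    mine = [h for h in hits if h.query_id == lsg_id]
    merged = merge_hits_by_pair(
        mine, {lsg_id: query_length}, thresholds, level="cds"
    )
    qualifying = [h for h in mine if (h.query_id, h.subject_id) in merged]
    return top_hit(qualifying)


def scan_distant_genomes(
    lsg_cds: Mapping[str, str],
    species_data: Mapping[str, DistantSpeciesData],
    focal_cds_db: Mapping[str, str],
    thresholds: ThresholdConfig = ThresholdConfig(),
    search_fn: Callable[..., list[HSP]] | None = None,
) -> list[DistantEvidence]:
    """Reciprocal evidence for LSG homology in distant genomes.

    CDS-level evidence: a qualifying transcript hit whose top subject
    reciprocally top-hits the LSG against the focal CDS database.
    Genomic evidence: the top qualifying genomic hit's span plus
    ``distant_flank_bp`` on each side (clamped to the scaffold) extracted
    and reciprocally searched.  Evidence per LSG per species is one of
    distant_cds / distant_intergenic / none.
    """
    import logging

    from .search import top_hit, toy_search

    logger = logging.getLogger(__name__)
    search = search_fn or toy_search
    results: list[DistantEvidence] = []
    for species in sorted(species_data):
        data = species_data[species]
        for lsg_id in sorted(lsg_cds):
            qlen = len(lsg_cds[lsg_id])
            evidence = DistantEvidence(lsg_id, species, "none")
            cds_top = _qualifying_top(data.cds_hits, lsg_id, qlen, thresholds)
            if cds_top is not None and cds_top.subject_id in data.cds_seqs:
                back = search(
                    {cds_top.subject_id: data.cds_seqs[cds_top.subject_id]},
                    dict(focal_cds_db),
                    mode="nucleotide",
                    seed_word_size=11,
                )
                best = top_hit(back)
                if best is not None and best.subject_id == lsg_id:
                    evidence = DistantEvidence(
                        lsg_id, species, "distant_cds", cds_top.subject_id
                    )
            if evidence.evidence == "none":
                gen_top = _qualifying_top(
                    data.genomic_hits, lsg_id, qlen, thresholds
                )
                if gen_top is not None and gen_top.subject_id in data.genome_seqs:
                    scaffold_seq = data.genome_seqs[gen_top.subject_id]
                    lo = gen_top.s_start - thresholds.distant_flank_bp
                    hi = gen_top.s_end + thresholds.distant_flank_bp
                    if lo < 0 or hi > len(scaffold_seq):
                        logger.warning(
                            "%s/%s: segment extraction clamped to scaffold bounds",
                            lsg_id,
                            species,
                        )
                    lo, hi = max(0, lo), min(len(scaffold_seq), hi)
                    segment = scaffold_seq[lo:hi]
                    back = search(
                        {f"{gen_top.subject_id}:{lo}-{hi}": segment},
                        dict(focal_cds_db),
                        mode="nucleotide",
                        seed_word_size=11,
                    )
                    best = top_hit(back)
                    if best is not None and best.subject_id == lsg_id:
                        evidence = DistantEvidence(
                            lsg_id,
                            species,
                            "distant_intergenic",
                            gen_top.subject_id,
                            (lo, hi),
                        )
            results.append(evidence)
    return results


# ---------------------------------------------------------------------------
# Reciprocal best hits and dN/dS comparison
# ---------------------------------------------------------------------------


def _top_hits_per_query(hits: Iterable[HSP]) -> dict[str, str]:
    best: dict[str, HSP] = {}
    for hsp in hits:
        current = best.get(hsp.query_id)
        key = (hsp.e_value, -hsp.score, hsp.subject_id)
        if current is None or key < (
            current.e_value,
            -current.score,
            current.subject_id,
        ):
            best[hsp.query_id] = hsp
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    forward_hits: Sequence[HSP], reverse_hits: Sequence[HSP]
) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's top hit and a is b's top hit.

    Ties are broken by lower E-value, then higher score, then subject id.
    """
    fwd = _top_hits_per_query(forward_hits)
    rev = _top_hits_per_query(reverse_hits)
    return sorted(
        (a, b) for a, b in fwd.items() if rev.get(b) == a
    )


def compare_dnds_groups(
    results: Sequence[DndsResult],
    lsg_labels: Mapping[str, bool],
) -> pd.DataFrame:
    """Median dN/dS with semi-interquartile range per LSG / non-LSG group.

    Pairs with undefined ratios (dS = 0 or saturation) are excluded from
    the distributions; empty groups report missing values.
    """
    groups: dict[str, list[float]] = {"LSG": [], "non-LSG": []}
    for result in results:
        if result.ratio is None:
            continue
        focal = result.pair[0]
        label = "LSG" if lsg_labels.get(focal, False) else "non-LSG"
        groups[label].append(result.ratio)
    rows = []
    for label in ("LSG", "non-LSG"):
        stats = median_siqr(groups[label])
        rows.append(
            {
                "group": label,
                "n": len(groups[label]),
                "median": None if stats is None else round(stats[0], 4),
                "siqr": None if stats is None else round(stats[1], 4),
            }
        )
    return pd.DataFrame(rows)
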