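"""Step-wise homology filtering that calls lineage-specific genes (LSGs).

A gene is lineage specific when no database tier contains a significant
hit to a subject outside the lineage taxon list and no recognized
cross-lineage protein domain is annotated on it.  Species-only status is a
refinement: no qualifying peptide hit in the sister-species outgroup.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import Compartment, HSP, ThresholdConfig, ValidationError, share_pct


class LineageLevel(str, enum.Enum):
    FAMILY = "family_specific"
    SPECIES_ONLY = "species_only"


@dataclass
class FilterStep:
    tier: str
    hits_considered: int
    survived: bool


@dataclass
class LsgRecord:
    gene_id: str
    compartment: Compartment
    lineage_level: LineageLevel = LineageLevel.FAMILY
    filter_trace: list[FilterStep] = field(default_factory=list)

    @property
    def eliminating_tier(self) -> str | None:
        for step in self.filter_trace:
            if not step.survived:
                return step.tier
        return None


def _eliminating_hits(
    hits: Sequence[HSP],
    gene_id: str,
    lineage_taxa: frozenset[str],
    cutoff: float,
) -> int:
    """Count out-of-lineage hits below the cutoff for one gene.

    Self-hits and hits to subjects inside the lineage never eliminate.
    """
    n = 0
    for hsp in hits:
        if hsp.subject_id == gene_id:
            continue
        if hsp.subject_taxon is not None and hsp.subject_taxon in lineage_taxa:
            continue
        if hsp.e_value < cutoff:
            n += 1
    return n


def stepwise_filter(
    gene_ids: Iterable[str],
    compartments: Mapping[str, Compartment],
    tier_hits: Mapping[str, Sequence[HSP]],
    lineage_taxa: Iterable[str],
    domain_annotations: Mapping[str, bool] | None = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
    evalue_cutoff: float | None = None,
) -> tuple[dict[str, LsgRecord], dict[str, str]]:
    """Run the filtering cascade over ordered database tiers.

    ``tier_hits`` maps tier name (iteration order = cascade order) to its
    hit table; ``domain_annotations`` flags genes carrying a recognized
    cross-lineage domain (the final filtering step).  Returns surviving
    LSG records plus a map of eliminated gene -> eliminating tier.
    """
    cutoff = (
        evalue_cutoff if evalue_cutoff is not None else thresholds.lsg_evalue_cutoff
    )
    gene_ids = list(gene_ids)
    known = set(gene_ids)
    taxa = frozenset(lineage_taxa)
    by_gene: dict[str, dict[str, list[HSP]]] = {g: {} for g in gene_ids}
    for tier, hits in tier_hits.items():
        for hsp in hits:
            if hsp.query_id not in known:
                raise ValidationError(
                    f"tier {tier!r}: hit references unknown gene {hsp.query_id!r}"
                )
            by_gene[hsp.query_id].setdefault(tier, []).append(hsp)

    survivors: dict[str, LsgRecord] = {}
    eliminated: dict[str, str] = {}
    for gene_id in gene_ids:
        record = LsgRecord(
            gene_id=gene_id,
            compartment=compartments.get(gene_id, Compartment.NUCLEAR),
        )
        alive = True
        for tier in tier_hits:
            hits = by_gene[gene_id].get(tier, [])
            if alive:
                n_bad = _eliminating_hits(hits, gene_id, taxa, cutoff)
                step_survived = n_bad == 0
                if not step_survived:
                    alive = False
                    eliminated[gene_id] = tier
                record.filter_trace.append(
                    FilterStep(tier, len(hits), step_survived)
                )
            else:
                record.filter_trace.append(FilterStep(tier, len(hits), False))
        if alive and domain_annotations is not None:
            has_domain = bool(domain_annotations.get(gene_id, False))
            record.filter_trace.append(
                FilterStep("domain_scan", int(has_domain), not has_domain)
            )
            if has_domain:
                alive = False
                eliminated[gene_id] = "domain_scan"
        if alive:
            survivors[gene_id] = record
    return survivors, eliminated


def lsg_counts_by_cutoff(
    gene_ids: Iterable[str],
    compartments: Mapping[str, Compartment],
    tier_hits: Mapping[str, Sequence[HSP]],
    lineage_taxa: Iterable[str],
    cutoffs: Sequence[float],
    domain_annotations: Mapping[str, bool] | None = None,
) -> dict[float, int]:
    """Sensitivity of the LSG count to the E-value cutoff.

    The survivor set shrinks (weakly) as the cutoff rises, because any hit
    eliminating a gene at a small cutoff still eliminates it at a larger
    one.
    """
    gene_ids = list(gene_ids)
    out: dict[float, int] = {}
    for cutoff in cutoffs:
        survivors, _ = stepwise_filter(
            gene_ids,
            compartments,
            tier_hits,
            lineage_taxa,
            domain_annotations,
            evalue_cutoff=cutoff,
        )
        out[cutoff] = len(survivors)
    return out


def assign_lineage_level(
    records: dict[str, LsgRecord],
    outgroup_hits: Sequence[HSP],
    query_lengths: Mapping[str, int],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> dict[str, LsgRecord]:
    """Split LSGs into family-level and species-only records.

    A record stays family-level when the outgroup peptide search has a hit
    with ``e < within_genome_evalue`` whose merged query coverage reaches
    ``min_query_coverage_pct``; otherwise it is species-only.  Mutates and
    returns ``records``.
    """
    from .origins import merge_hsps

    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for hsp in outgroup_hits:
        if hsp.query_id not in records:
            continue
        if hsp.e_value >= thresholds.within_genome_evalue:
            continue
        by_pair.setdefault((hsp.query_id, hsp.subject_id), []).append(hsp)

    covered: set[str] = set()
    for (query_id, _subject_id), hits in by_pair.items():
        merged = merge_hsps(hits, query_lengths[query_id], thresholds)
        if merged is not None:
            covered.add(query_id)
    for gene_id, record in records.items():
        record.lineage_level = (
            LineageLevel.FAMILY if gene_id in covered else LineageLevel.SPECIES_ONLY
        )
    return records


def compartment_summary(
    records: Mapping[str, LsgRecord],
    gene_compartments: Mapping[str, Compartment],
    gene_chroms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """LSG share per compartment (and per chromosome when chroms given).

    Shares are LSG count / tested gene-model count; an empty group yields
    a missing (NA) share rather than zero.
    """
    rows = []
    groups: dict[str, tuple[set[str], set[str]]] = {}

    def add(group: str, gene_id: str) -> None:
        tested, lsgs = groups.setdefault(group, (set(), set()))
        tested.add(gene_id)
        if gene_id in records:
            lsgs.add(gene_id)

    for gene_id, compartment in gene_compartments.items():
        add(f"compartment:{compartment.value}", gene_id)
        if gene_chroms is not None:
            add(f"chrom:{gene_chroms[gene_id]}", gene_id)
    for compartment in Compartment:
        groups.setdefault(f"compartment:{compartment.value}", (set(), set()))
    for group in sorted(groups):
        tested, lsgs = groups[group]
        rows.append(
            {
                "group": group,
                "lsg_count": len(lsgs),
                "tested": len(tested),
                "share_pct": share_pct(len(lsgs), len(tested)),
            }
        )
    return pd.DataFrame(rows)
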