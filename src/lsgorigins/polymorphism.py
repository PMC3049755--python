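"""Accession-level ORF-interrupting SNP calls and birth-vs-loss inference.

Substitution SNPs from a natural-accession panel are applied to each LSG
CDS (strand-aware), the polymorphic sequence translated, and internal stop
codons (ISC) or missing start codons (MSC) called per accession.  Each
polymorphic site is then cross-referenced against the outgroup alignment,
and a parsimony rule labels genes as candidate births in the focal lineage
(disruption ancestral) or losses (disruption derived and rare).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import LineageLevel, LsgRecord
from .io import GenomeCatalog
from .model import ExpressionSupport, Strand, ValidationError
from .outgroup import OrfCategory, OrfProjection
from .seqs import internal_stop_positions

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SnpType(str, enum.Enum):
    ISC = "ISC"
    MSC = "MSC"


class OutgroupStatus(str, enum.Enum):
    CONSERVED_SNP = "CONSERVED_SNP"
    DELETION = "DELETION"
    NOT_COVERED = "NOT_COVERED"
    NOT_DISRUPTED = "NOT_DISRUPTED"


@dataclass(frozen=True)
class Snp:
    accession: str
    chrom: str
    pos: int  # 0-based genomic offset
    ref: str
    alt: str


@dataclass
class DisruptionCall:
    gene_id: str
    accession: str
    snp_type: SnpType
    chrom: str
    pos: int
    codon_index: int  # 1-based; MSC => 1, ISC => internal
    outgroup_status: OutgroupStatus | None = None
    outgroup_disruptions: int | None = None
    outgroup_coverage_pct: float | None = None


def read_snp_table(source: str | Path | pd.DataFrame) -> list[Snp]:
    """Read an accession SNP TSV (accession, chrom, pos, ref, alt).

    Printed positions are 1-based; indel alleles (length != 1 or '-')
    are rejected because the call rule is defined for substitutions only.
    """
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t", dtype=str)
    snps = []
    for row in table.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
            raise ValidationError(
                f"SNP at {row.chrom}:{row.pos}: only substitution SNPs supported"
            )
        snps.append(
            Snp(
                accession=str(row.accession),
                chrom=str(row.chrom),
                pos=int(row.pos) - 1,
                ref=ref,
                alt=alt,
            )
        )
    return snps


def apply_snps_and_call(
    catalog: GenomeCatalog,
    lsg_ids: set[str],
    snps: Sequence[Snp],
) -> tuple[list[DisruptionCall], pd.DataFrame]:
    """Apply each accession's SNPs to every LSG CDS and call ISC/MSC.

    Returns the calls plus a genes x accessions matrix with cells in
    {ref, ISC, MSC, ISC+MSC, missing}.  A SNP whose reference allele does
    not match the genome raises; an undetermined alternate allele ('N')
    marks missing data and produces no call.  Only disruptions absent
    from the reference sequence are called (a reference-intact codon that
    becomes a stop, or a reference ATG start that is lost).
    """
    gene_list = sorted(g for g in lsg_ids if g in catalog.genes)
    accessions = sorted({s.accession for s in snps})
    matrix = pd.DataFrame("ref", index=gene_list, columns=accessions)
    calls: list[DisruptionCall] = []

    by_gene_acc: dict[tuple[str, str], list[Snp]] = {}
    for snp in snps:
        chrom_seq = catalog.sequences.get(snp.chrom)
        if chrom_seq is None:
            raise ValidationError(f"SNP references unknown sequence {snp.chrom!r}")
        if chrom_seq[snp.pos] != snp.ref:
            raise ValidationError(
                f"SNP ref mismatch at {snp.chrom}:{snp.pos + 1}: table says "
                f"{snp.ref}, genome has {chrom_seq[snp.pos]}"
            )
        for gene_id in gene_list:
            gene = catalog.genes[gene_id]
            if gene.chrom != snp.chrom:
                continue
            if gene.genomic_to_cds(snp.pos) is not None:
                by_gene_acc.setdefault((gene_id, snp.accession), []).append(snp)

    for (gene_id, accession), gene_snps in sorted(by_gene_acc.items()):
        gene = catalog.genes[gene_id]
        ref_cds = catalog.cds_sequence(gene_id)
        ref_stops = set(internal_stop_positions(ref_cds))
        mutated = list(ref_cds)
        missing = False
        applied: dict[int, Snp] = {}
        for snp in gene_snps:
            cds_pos = gene.genomic_to_cds(snp.pos)
            alt = snp.alt
            if gene.strand is Strand.MINUS:
                alt = _COMPLEMENT[alt]
            if alt == "N":
                missing = True
                continue
            mutated[cds_pos] = alt
            applied[cds_pos] = snp
        mutated_cds = "".join(mutated)
        gene_calls: list[DisruptionCall] = []
        # MSC: reference start intact, polymorphic start broken
        if ref_cds[:3] == "ATG" and mutated_cds[:3] != "ATG":
            snp_here = next(
                (applied[p] for p in (0, 1, 2) if p in applied), None
            )
            if snp_here is not None:
                gene_calls.append(
                    DisruptionCall(
                        gene_id,
                        accession,
                        SnpType.MSC,
                        snp_here.chrom,
                        snp_here.pos,
                        codon_index=1,
                    )
                )
        # ISC: new internal stop codons (terminal codon never counts)
        new_stops = set(internal_stop_positions(mutated_cds)) - ref_stops
        for codon_idx in sorted(new_stops):
            if codon_idx == 0:
                continue
            snp_here = next(
                (
                    applied[p]
                    for p in range(codon_idx * 3, codon_idx * 3 + 3)
                    if p in applied
                ),
                None,
            )
            if snp_here is not None:
                gene_calls.append(
                    DisruptionCall(
                        gene_id,
                        accession,
                        SnpType.ISC,
                        snp_here.chrom,
                        snp_here.pos,
                        codon_index=codon_idx + 1,
                    )
                )
        calls.extend(gene_calls)
        types = {c.snp_type for c in gene_calls}
        if types == {SnpType.ISC, SnpType.MSC}:
            cell = "ISC+MSC"
        elif SnpType.ISC in types:
            cell = "ISC"
        elif SnpType.MSC in types:
            cell = "MSC"
        else:
            cell = "missing" if missing else "ref"
        matrix.loc[gene_id, accession] = cell
    return calls, matrix


def _disrupting_cds_allele(
    catalog: GenomeCatalog, call: DisruptionCall, snps: Sequence[Snp]
) -> str | None:
    gene = catalog.genes[call.gene_id]
    for snp in snps:
        if (
            snp.accession == call.accession
            and snp.chrom == call.chrom
            and snp.pos == call.pos
        ):
            alt = snp.alt
            if gene.strand is Strand.MINUS:
                alt = _COMPLEMENT[alt]
            return alt
    return None


def cross_reference_outgroup(
    calls: Sequence[DisruptionCall],
    catalog: GenomeCatalog,
    snps: Sequence[Snp],
    projections: Mapping[str, OrfProjection],
) -> list[DisruptionCall]:
    """Annotate each call with the outgroup state at the polymorphic site.

    CONSERVED_SNP: the aligned outgroup base equals the disrupting allele
    (the outgroup carries the same ISC/MSC).  DELETION: the outgroup
    alignment has a gap at the site.  NOT_COVERED: no alignment, or the
    alignment does not span the site.  Otherwise NOT_DISRUPTED.  Also
    attaches the outgroup disruption total and alignment coverage.
    """
    for call in calls:
        gene = catalog.genes[call.gene_id]
        cds_pos = gene.genomic_to_cds(call.pos)
        projection = projections.get(call.gene_id)
        if projection is None or cds_pos not in projection.aligned_region_base:
            call.outgroup_status = OutgroupStatus.NOT_COVERED
        else:
            base = projection.aligned_region_base[cds_pos]
            allele = _disrupting_cds_allele(catalog, call, snps)
            if base is None:
                call.outgroup_status = OutgroupStatus.DELETION
            elif allele is not None and base == allele:
                call.outgroup_status = OutgroupStatus.CONSERVED_SNP
            else:
                call.outgroup_status = OutgroupStatus.NOT_DISRUPTED
        if projection is not None:
            call.outgroup_disruptions = (
                projection.internal_stop_count + projection.frameshift_indel_count
            )
            call.outgroup_coverage_pct = round(projection.coverage_pct, 2)
    return list(calls)


class BirthLossScenario(str, enum.Enum):
    BIRTH_IN_FOCAL = "birth_in_focal"
    LOSS_IN_FOCAL = "loss_in_focal"
    AMBIGUOUS = "ambiguous"


def infer_birth_vs_loss(
    calls: Sequence[DisruptionCall],
    n_genotyped_accessions: int,
    projections: Mapping[str, OrfProjection],
    minority_fraction: float = 0.5,
) -> dict[str, BirthLossScenario]:
    """Parsimony label per polymorphic gene.

    A disruption conserved in the outgroup marks a birth in the focal
    lineage (the intact allele is derived).  An intact outgroup ORF with
    the disruption confined to a minority (< ``minority_fraction``) of
    genotyped accessions marks a loss in the focal lineage.  Anything
    else is ambiguous.
    """
    by_gene: dict[str, list[DisruptionCall]] = {}
    for call in calls:
        by_gene.setdefault(call.gene_id, []).append(call)
    scenarios: dict[str, BirthLossScenario] = {}
    for gene_id, gene_calls in sorted(by_gene.items()):
        statuses = {c.outgroup_status for c in gene_calls}
        if OutgroupStatus.CONSERVED_SNP in statuses:
            scenarios[gene_id] = BirthLossScenario.BIRTH_IN_FOCAL
            continue
        projection = projections.get(gene_id)
        disrupted_accessions = {c.accession for c in gene_calls}
        if (
            statuses == {OutgroupStatus.NOT_DISRUPTED}
            and projection is not None
            and projection.category is OrfCategory.INTACT
            and len(disrupted_accessions)
            < minority_fraction * n_genotyped_accessions
        ):
            scenarios[gene_id] = BirthLossScenario.LOSS_IN_FOCAL
        else:
            scenarios[gene_id] = BirthLossScenario.AMBIGUOUS
    return scenarios


def summarize_polymorphic_lsgs(
    calls: Sequence[DisruptionCall],
    records: Mapping[str, LsgRecord],
    expression_support: Mapping[str, ExpressionSupport] | None = None,
) -> pd.DataFrame:
    """Counts of distinct disrupted LSGs per (lineage level, SNP type).

    Columns give the total plus gene-model-support and locus-support
    subtotals; a final row reports the ISC/MSC gene-set overlap.
    """
    expression_support = expression_support or {}
    rows = []
    isc_genes = {c.gene_id for c in calls if c.snp_type is SnpType.ISC}
    msc_genes = {c.gene_id for c in calls if c.snp_type is SnpType.MSC}
    for level in (LineageLevel.FAMILY, LineageLevel.SPECIES_ONLY):
        for snp_type, gene_set in ((SnpType.ISC, isc_genes), (SnpType.MSC, msc_genes)):
            members = {
                g
                for g in gene_set
                if g in records and records[g].lineage_level is level
            }
            model_support = sum(
                1
                for g in members
                if expression_support.get(g) is ExpressionSupport.GENE_MODEL
            )
            locus_support = sum(
                1
                for g in members
                if expression_support.get(g)
                in (ExpressionSupport.GENE_MODEL, ExpressionSupport.LOCUS)
            )
            rows.append(
                {
                    "lineage_level": level.value,
                    "snp_type": snp_type.value,
                    "total": len(members),
                    "gene_model_support": model_support,
                    "locus_support": locus_support,
                }
            )
    rows.append(
        {
            "lineage_level": "all",
            "snp_type": "ISC&MSC overlap",
            "total": len(isc_genes & msc_genes),
            "gene_model_support": None,
            "locus_support": None,
        }
    )
    return pd.DataFrame(rows)
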