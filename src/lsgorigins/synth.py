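"""Synthetic genome pairs with planted, labelled gene-origin events.

The generator emits everything the pipeline consumes — a focal genome
(FASTA + GFF3 + TE GFF3), a diverged outgroup carrying planted ORF
disruptions and gene losses, per-tier homology-hit tables, accession SNP
tables and expression matrices — together with a ground-truth record of
every planted event, so each downstream classifier can be scored against
known labels.

Planted origin classes: overprinting (a reverse-strand ORF engineered
inside a conserved CDS), duplication (in-frame copy, frameshifted copy,
inverted copy, intron-less retrocopy), TE exaptation (exon-TE overlap),
chimerism (fusion of two unrelated donor CDS fragments), de novo /
differential-loss genes (outgroup locus disrupted or deleted), and
accession-level ISC/MSC polymorphisms.

Everything is deterministic under a fixed seed: one root SeedSequence
spawns child generators in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dnds import _codon_sites
from .io import GenomeCatalog
from .model import (
    Compartment,
    ExpressionSupport,
    GeneModel,
    GenomicInterval,
    HSP,
    Orientation,
    Strand,
    TeFragment,
    ValidationError,
)
from .polymorphism import Snp
from .seqs import BASES, STOP_CODONS, codons, is_intact_orf, revcomp, translate

NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)

ORIGIN_CLASSES = (
    "overprint",
    "dup_inframe",
    "dup_frameshift",
    "dup_inverted",
    "retrocopy",
    "te_exapt",
    "chimera",
    "de_novo",
    "differential_loss",
    "accession_isc",
    "accession_msc",
)

TE_SUPERFAMILIES = ("RC/Helitron", "DNA/MuDR", "LTR/Gypsy", "LTR/Copia", "DNA/En-Spm")

OUT_LINEAGE_TAXA = ("Poaceae", "Fabaceae", "Metazoa", "Fungi")
LINEAGE_TAXON = "Brassicaceae"
TIER_NAMES = ("peptide_db", "nucleotide_db", "est_db", "position_specific")


class CapacityError(ValidationError):
    """Requested gene count cannot be placed in the configured genome."""


@dataclass(frozen=True)
class ExpressionConfig:
    """Shape of the synthetic expression study.

    Defaults emulate a developmental atlas of 63 tissue/stage groups with
    3 replicates each, LSG-like genes expressed in a median of ~4 tissues
    against ~51 for conserved genes, LSG expression shifted down by
    ~0.45 log2 units, and stress contrasts in which LSG-like genes are
    up-regulated with 5-fold odds relative to the background rate.
    """

    n_tissues: int = 63
    n_replicates: int = 3
    lsg_breadth_mean: float = 4.0
    nonlsg_breadth_mean: float = 51.0
    base_log2_expression: float = 2.96
    lsg_expr_shift: float = 0.45
    n_stress_contrasts: int = 6
    n_control_contrasts: int = 2
    planted_enrichment_odds: float = 5.0
    base_de_rate: float = 0.05


def _default_planted() -> dict[str, int]:
    return {
        "overprint": 5,
        "dup_inframe": 8,
        "dup_frameshift": 6,
        "dup_inverted": 6,
        "retrocopy": 5,
        "te_exapt": 6,
        "chimera": 5,
        "de_novo": 8,
        "differential_loss": 4,
        "accession_isc": 4,
        "accession_msc": 3,
    }


def _default_te_density() -> dict[str, int]:
    return {
        "RC/Helitron": 28,
        "DNA/MuDR": 16,
        "LTR/Gypsy": 12,
        "LTR/Copia": 8,
        "DNA/En-Spm": 6,
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    The default scenario holds 140 conserved background genes plus 60
    planted origin events (~200 gene models) on a ~1 Mb nuclear
    chromosome with small organellar chromosomes, a 5% diverged outgroup
    and 19 accessions — sized to generate in well under a minute.
    """

    seed: int = 0
    n_background_genes: int = 140
    n_planted: dict[str, int] = field(default_factory=_default_planted)
    intergenic_fraction: float = 0.4
    te_density: dict[str, int] = field(default_factory=_default_te_density)
    outgroup_divergence: float = 0.05
    n_accessions: int = 19
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    n_mito_genes: int = 4
    n_chloro_genes: int = 2
    target_genome_length: int | None = None
    conserved_omega: float = 0.15
    lsg_omega: float = 0.6

    def __post_init__(self) -> None:
        if self.n_background_genes < 0 or self.n_accessions < 0:
            raise ValidationError("counts must be non-negative")
        unknown = set(self.n_planted) - set(ORIGIN_CLASSES)
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in self.n_planted.values()):
            raise ValidationError("planted counts must be non-negative")
        if not (0.0 <= self.outgroup_divergence):
            raise ValidationError("divergence must be non-negative")
        if self.outgroup_divergence >= 0.5:
            raise ValidationError(
                "outgroup divergence >= 0.5 breaks the alignability assumption"
            )
        if not (0.0 <= self.intergenic_fraction < 1.0):
            raise ValidationError("intergenic_fraction must be in [0, 1)")

    def planted(self, name: str) -> int:
        return self.n_planted.get(name, 0)


@dataclass
class AccessionEvent:
    """One planned accession-level ORF disruption."""

    gene_id: str
    snp_type: str  # "ISC" | "MSC"
    accessions: list[str]
    cds_pos: int  # CDS offset of the substituted base
    ref_cds_base: str
    alt_cds_base: str
    conserved_in_outgroup: bool


@dataclass
class GroundTruth:
    """Labels for every planted event, keyed by emitted gene ids."""

    origin: dict[str, str] = field(default_factory=dict)
    lineage: dict[str, str] = field(default_factory=dict)
    outgroup_category: dict[str, str] = field(default_factory=dict)
    donors: dict[str, list[str]] = field(default_factory=dict)
    disruptions: dict[tuple[str, str], str] = field(default_factory=dict)
    expression_class: dict[str, str] = field(default_factory=dict)
    de_truth: dict[str, set[str]] = field(default_factory=dict)
    te_partner: dict[str, str] = field(default_factory=dict)
    accession_events: list[AccessionEvent] = field(default_factory=list)

    def lsg_ids(self) -> set[str]:
        return {
            g
            for g, lvl in self.lineage.items()
            if lvl in ("family_specific", "species_only")
        }

    def reconcile(self, config: ScenarioConfig) -> None:
        counts: dict[str, int] = {}
        for label in self.origin.values():
            counts[label] = counts.get(label, 0) + 1
        for name in ORIGIN_CLASSES:
            if counts.get(name, 0) != config.planted(name):
                raise ValidationError(
                    f"ground truth holds {counts.get(name, 0)} {name} genes, "
                    f"config asked for {config.planted(name)}"
                )


@dataclass
class ExpressionBundle:
    expression: pd.DataFrame  # genes x samples, log2
    calls: pd.DataFrame  # genes x samples, bool
    sample_tissue: dict[str, str]
    de_tables: dict[str, pd.DataFrame]  # contrast -> (gene, log2fc, adj_p)
    contrast_meta: dict[str, dict[str, str]]  # contrast -> tissue/time/kind


@dataclass
class SyntheticScenario:
    """Everything one synthetic run produces."""

    config: ScenarioConfig
    catalog: GenomeCatalog
    truth: GroundTruth
    tier_hits: dict[str, list[HSP]]
    domain_annotations: dict[str, bool]
    outgroup_scaffolds: dict[str, str]
    outgroup_cds: dict[str, str]  # outgroup gene models as CDS sequences
    snps: list[Snp]
    expression: ExpressionBundle
    syntelog_pairs: set[frozenset[str]] = field(default_factory=set)
    wgd_pairs: set[frozenset[str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Sequence-construction helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _make_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(NON_STOP_CODONS, size=max(0, n_codons - 2))
    stop = rng.choice(("TAA", "TAG", "TGA"))
    return "ATG" + "".join(body) + stop


def _mutate_orf_preserving(
    rng: np.random.Generator, cds: str, rate: float
) -> str:
    """Point substitutions that keep the ORF intact (start/stop/no ISC)."""
    seq = list(cds)
    n_codons = len(cds) // 3
    for pos in range(len(cds)):
        if rng.random() >= rate:
            continue
        codon_idx = pos // 3
        alt = rng.choice([b for b in BASES if b != seq[pos]])
        old = seq[pos]
        seq[pos] = alt
        codon = "".join(seq[codon_idx * 3 : codon_idx * 3 + 3])
        bad = (
            (codon_idx == 0 and codon != "ATG")
            or (codon_idx == n_codons - 1 and codon not in STOP_CODONS)
            or (0 < codon_idx < n_codons - 1 and codon in STOP_CODONS)
        )
        if bad:
            seq[pos] = old
    return "".join(seq)


def _repair_orf(rng: np.random.Generator, seq: str) -> str:
    """Coerce a near-coding sequence into a valid ORF with minimal edits."""
    usable = len(seq) - len(seq) % 3
    work = list(seq[:usable])
    work[0:3] = "ATG"
    for idx in range(1, usable // 3 - 1):
        codon = "".join(work[idx * 3 : idx * 3 + 3])
        if codon in STOP_CODONS:
            choices = [
                (p, b)
                for p in range(3)
                for b in BASES
                if b != codon[p]
                and codon[:p] + b + codon[p + 1 :] not in STOP_CODONS
            ]
            p, b = choices[rng.integers(len(choices))]
            work[idx * 3 + p] = b
    work[usable - 3 : usable] = rng.choice(("TAA", "TAG", "TGA"))
    out = "".join(work)
    assert is_intact_orf(out)
    return out


def _gene_region(
    rng: np.random.Generator,
    cds: str,
    n_exons: int,
    strand: Strand = Strand.PLUS,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Lay a CDS into a gene region with UTRs and introns.

    Returns (region sequence, exon intervals, CDS intervals) relative to
    the region start, already flipped for minus-strand genes.
    """
    utr5 = int(rng.integers(10, 30))
    utr3 = int(rng.integers(10, 30))
    n_exons = max(1, min(n_exons, len(cds) // 60))
    cuts = sorted(
        int(c)
        for c in rng.choice(
            np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False
        )
    ) if n_exons > 1 else []
    # enforce a minimum exon piece of 30 bp
    pieces = []
    prev = 0
    for cut in cuts + [len(cds)]:
        if cut - prev < 30:
            continue
        pieces.append((prev, cut))
        prev = cut
    if pieces and pieces[-1][1] != len(cds):
        pieces[-1] = (pieces[-1][0], len(cds))
    if not pieces:
        pieces = [(0, len(cds))]
    region_parts: list[str] = [_random_seq(rng, utr5)]
    exons: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    cursor = utr5
    for i, (lo, hi) in enumerate(pieces):
        seg = cds[lo:hi]
        start = cursor
        region_parts.append(seg)
        cursor += len(seg)
        cds_ivs.append((start, cursor))
        exon_start = 0 if i == 0 else start
        if i == 0:
            exon_start = 0
        exon_end = cursor
        if i == len(pieces) - 1:
            region_parts.append(_random_seq(rng, utr3))
            exon_end = cursor + utr3
            cursor += utr3
        exons.append((exon_start, exon_end))
        if i < len(pieces) - 1:
            intron = _random_seq(rng, int(rng.integers(60, 200)))
            region_parts.append(intron)
            cursor += len(intron)
    region = "".join(region_parts)
    if strand is Strand.MINUS:
        L = len(region)
        region = revcomp(region)
        exons = sorted((L - e, L - s) for s, e in exons)
        cds_ivs = sorted((L - e, L - s) for s, e in cds_ivs)
    return region, exons, cds_ivs


# ---------------------------------------------------------------------------
# Genome builder
# ---------------------------------------------------------------------------


@dataclass
class _Builder:
    seqs: dict[str, str] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    tes: list[TeFragment] = field(default_factory=list)
    truth: GroundTruth = field(default_factory=GroundTruth)
    dual_coding: list[tuple[str, str]] = field(default_factory=list)  # donor, overprint

    def order(self, chrom: str) -> list[str]:
        return [
            g.gene_id
            for g in sorted(
                (g for g in self.genes.values() if g.chrom == chrom),
                key=lambda g: g.span.start,
            )
        ]

    def add_gene(
        self,
        gene_id: str,
        chrom: str,
        offset: int,
        exons: list[tuple[int, int]],
        cds: list[tuple[int, int]],
        strand: Strand,
        support: ExpressionSupport = ExpressionSupport.GENE_MODEL,
    ) -> GeneModel:
        model = GeneModel(
            gene_id=gene_id,
            representative_model_id=f"{gene_id}.1",
            chrom=chrom,
            strand=strand,
            exons=[(s + offset, e + offset) for s, e in exons],
            cds_segments=[(s + offset, e + offset) for s, e in cds],
            compartment=(
                Compartment.MITOCHONDRIAL
                if chrom == "ChrM"
                else Compartment.CHLOROPLAST
                if chrom == "ChrC"
                else Compartment.NUCLEAR
            ),
            expression_support=support,
        )
        self.genes[gene_id] = model
        return model

    def append_gene(
        self,
        rng: np.random.Generator,
        gene_id: str,
        chrom: str,
        cds: str,
        n_exons: int,
        strand: Strand = Strand.PLUS,
        gap: tuple[int, int] = (300, 1500),
    ) -> GeneModel:
        region, exons, cds_ivs = _gene_region(rng, cds, n_exons, strand)
        prefix = _random_seq(rng, int(rng.integers(*gap)))
        seq = self.seqs.get(chrom, "")
        offset = len(seq) + len(prefix)
        self.seqs[chrom] = seq + prefix + region
        return self.add_gene(gene_id, chrom, offset, exons, cds_ivs, strand)

    def insert_gene_after(
        self,
        rng: np.random.Generator,
        gene_id: str,
        anchor_gene: str,
        cds: str,
        n_exons: int,
        strand: Strand = Strand.PLUS,
    ) -> GeneModel:
        """Insert a new gene immediately downstream of ``anchor_gene``."""
        anchor = self.genes[anchor_gene]
        chrom = anchor.chrom
        region, exons, cds_ivs = _gene_region(rng, cds, n_exons, strand)
        pad = _random_seq(rng, int(rng.integers(150, 400)))
        insert_at = anchor.span.end + 20
        block = pad + region
        self._shift(chrom, insert_at, len(block))
        seq = self.seqs[chrom]
        self.seqs[chrom] = seq[:insert_at] + block + seq[insert_at:]
        offset = insert_at + len(pad)
        return self.add_gene(gene_id, chrom, offset, exons, cds_ivs, strand)

    def _shift(self, chrom: str, pos: int, delta: int) -> None:
        for gene in self.genes.values():
            if gene.chrom != chrom or gene.span.start < pos:
                continue
            gene.exons = [(s + delta, e + delta) for s, e in gene.exons]
            gene.cds_segments = [(s + delta, e + delta) for s, e in gene.cds_segments]
        for i, te in enumerate(self.tes):
            iv = te.interval
            if iv.chrom == chrom and iv.start >= pos:
                self.tes[i] = TeFragment(
                    te.te_id,
                    GenomicInterval(chrom, iv.start + delta, iv.end + delta, iv.strand),
                    te.superfamily,
                )

    def to_catalog(self) -> GenomeCatalog:
        return GenomeCatalog(
            genes=dict(self.genes),
            te_fragments=list(self.tes),
            sequences=dict(self.seqs),
        )


# ---------------------------------------------------------------------------
# Stage 1: background genome
# ---------------------------------------------------------------------------


def generate_genome(config: ScenarioConfig, rng: np.random.Generator) -> _Builder:
    """Conserved background genes, organellar chromosomes, TE fragments."""
    builder = _Builder()
    n_nuclear = config.n_background_genes - config.n_mito_genes - config.n_chloro_genes
    if n_nuclear < 0:
        raise ValidationError("organellar gene counts exceed background total")
    for i in range(n_nuclear):
        n_codons = int(rng.integers(60, 200))
        # bias toward single-exon structures so duplication donors exist
        n_exons = 1 if rng.random() < 0.4 else int(rng.integers(2, 7))
        strand = Strand.MINUS if rng.random() < 0.15 else Strand.PLUS
        gene_id = f"G{i:03d}"
        builder.append_gene(
            rng, gene_id, "Chr1", _make_orf(rng, n_codons), n_exons, strand
        )
        builder.truth.origin[gene_id] = "background"
        builder.truth.lineage[gene_id] = "conserved"
        builder.truth.expression_class[gene_id] = "conserved_like"
    for chrom, count, prefix in (
        ("ChrM", config.n_mito_genes, "GM"),
        ("ChrC", config.n_chloro_genes, "GC"),
    ):
        for i in range(count):
            gene_id = f"{prefix}{i:02d}"
            builder.append_gene(
                rng, gene_id, chrom, _make_orf(rng, int(rng.integers(60, 150))), 1
            )
            builder.truth.origin[gene_id] = "background"
            builder.truth.lineage[gene_id] = "conserved"
            builder.truth.expression_class[gene_id] = "conserved_like"
    # tail of intergenic sequence, then background TE fragments in gaps
    builder.seqs["Chr1"] = builder.seqs.get("Chr1", "") + _random_seq(rng, 3000)
    te_idx = 0
    chrom_len = len(builder.seqs["Chr1"])
    gene_spans = [
        (g.span.start, g.span.end)
        for g in builder.genes.values()
        if g.chrom == "Chr1"
    ]
    for superfamily in TE_SUPERFAMILIES:
        for _ in range(config.te_density.get(superfamily, 0)):
            for _attempt in range(50):
                length = int(rng.integers(150, 700))
                start = int(rng.integers(0, max(1, chrom_len - length)))
                if all(
                    start + length <= s or start >= e for s, e in gene_spans
                ):
                    builder.tes.append(
                        TeFragment(
                            f"TE{te_idx:03d}",
                            GenomicInterval("Chr1", start, start + length, Strand.PLUS),
                            superfamily,
                        )
                    )
                    te_idx += 1
                    break
    if (
        config.target_genome_length is not None
        and len(builder.seqs["Chr1"]) > config.target_genome_length
    ):
        raise CapacityError(
            f"placed genome needs {len(builder.seqs['Chr1'])} bp; "
            f"target {config.target_genome_length} bp is too small"
        )
    return builder


# ---------------------------------------------------------------------------
# Stage 2: plant origin events
# ---------------------------------------------------------------------------


def _single_exon_donors(builder: _Builder, rng: np.random.Generator, n: int) -> list[str]:
    pool = sorted(
        g.gene_id
        for g in builder.genes.values()
        if g.chrom == "Chr1"
        and len(g.cds_segments) == 1
        and g.strand is Strand.PLUS
        and builder.truth.origin.get(g.gene_id) == "background"
        and g.gene_id not in builder.truth.donors.get("_used", [])
    )
    used = set(builder.truth.donors.get("_used", []))
    pool = [g for g in pool if g not in used]
    if len(pool) < n:
        raise ValidationError("not enough single-exon donors available")
    chosen = [pool[int(i)] for i in rng.choice(len(pool), size=n, replace=False)]
    builder.truth.donors.setdefault("_used", []).extend(chosen)
    return chosen


def _multi_exon_donors(builder: _Builder, rng: np.random.Generator, n: int) -> list[str]:
    used = set(builder.truth.donors.get("_used", []))
    pool = sorted(
        g.gene_id
        for g in builder.genes.values()
        if g.chrom == "Chr1"
        and len(g.cds_segments) >= 3
        and g.strand is Strand.PLUS
        and builder.truth.origin.get(g.gene_id) == "background"
        and g.gene_id not in used
    )
    if len(pool) < n:
        raise ValidationError("no multi-exon donor available for retrocopy")
    chosen = [pool[int(i)] for i in rng.choice(len(pool), size=n, replace=False)]
    builder.truth.donors.setdefault("_used", []).extend(chosen)
    return chosen


def _distal_anchor(builder: _Builder, rng: np.random.Generator, donor: str) -> str:
    order = builder.order("Chr1")
    idx = order.index(donor)
    far = [
        g
        for i, g in enumerate(order)
        if abs(i - idx) > 15 and builder.truth.origin.get(g) == "background"
    ]
    return far[int(rng.integers(len(far)))]


def _plant_duplications(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    n_in = config.planted("dup_inframe")
    n_fs = config.planted("dup_frameshift")
    n_inv = config.planted("dup_inverted")
    donors = _single_exon_donors(builder, rng, n_in + n_fs + n_inv)
    cursor = 0
    for j in range(n_in):
        donor = donors[cursor]
        cursor += 1
        gene_id = f"LSG_dupin_{j}"
        donor_cds = builder.genes[donor].extract_cds(
            builder.seqs[builder.genes[donor].chrom]
        )
        new_cds = _mutate_orf_preserving(rng, donor_cds, 0.05)
        tandem = j % 2 == 0
        anchor = donor if tandem else _distal_anchor(builder, rng, donor)
        builder.insert_gene_after(rng, gene_id, anchor, new_cds, 1)
        builder.truth.origin[gene_id] = "dup_inframe"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = [donor]
    for j in range(n_fs):
        donor = donors[cursor]
        cursor += 1
        gene_id = f"LSG_dupfs_{j}"
        donor_cds = builder.genes[donor].extract_cds(
            builder.seqs[builder.genes[donor].chrom]
        )
        cut = (len(donor_cds) // 3) // 5 * 2 * 3  # ~40% in, on a codon boundary
        shifted = donor_cds[:cut] + donor_cds[cut + 1 :]  # 1-bp deletion
        new_cds = _repair_orf(rng, shifted)
        new_cds = _mutate_orf_preserving(rng, new_cds, 0.02)
        anchor = _distal_anchor(builder, rng, donor)
        builder.insert_gene_after(rng, gene_id, anchor, new_cds, 1)
        builder.truth.origin[gene_id] = "dup_frameshift"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = [donor]
    for j in range(n_inv):
        donor = donors[cursor]
        cursor += 1
        gene_id = f"LSG_dupinv_{j}"
        donor_cds = builder.genes[donor].extract_cds(
            builder.seqs[builder.genes[donor].chrom]
        )
        new_cds = _repair_orf(rng, revcomp(donor_cds))
        new_cds = _mutate_orf_preserving(rng, new_cds, 0.02)
        anchor = _distal_anchor(builder, rng, donor)
        builder.insert_gene_after(rng, gene_id, anchor, new_cds, 1)
        builder.truth.origin[gene_id] = "dup_inverted"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = [donor]


def _plant_retrocopies(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    donors = _multi_exon_donors(builder, rng, config.planted("retrocopy"))
    for j, donor in enumerate(donors):
        gene_id = f"LSG_retro_{j}"
        donor_cds = builder.genes[donor].extract_cds(
            builder.seqs[builder.genes[donor].chrom]
        )
        new_cds = _mutate_orf_preserving(rng, donor_cds, 0.04)
        anchor = _distal_anchor(builder, rng, donor)
        builder.insert_gene_after(rng, gene_id, anchor, new_cds, 1)
        builder.truth.origin[gene_id] = "retrocopy"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = [donor]


def _plant_chimeras(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    n = config.planted("chimera")
    donors = _single_exon_donors(builder, rng, 2 * n)
    for j in range(n):
        donor_a, donor_b = donors[2 * j], donors[2 * j + 1]
        gene_id = f"LSG_chim_{j}"
        cds_a = builder.genes[donor_a].extract_cds(builder.seqs["Chr1"])
        cds_b = builder.genes[donor_b].extract_cds(builder.seqs["Chr1"])
        take_a = min(len(cds_a) // 3 - 1, int(rng.integers(40, 70))) * 3
        b_codons = len(cds_b) // 3
        take_b = min(b_codons - 2, int(rng.integers(40, 70)))
        b_from = int(rng.integers(1, max(2, b_codons - take_b - 1))) * 3
        fusion = cds_a[:take_a] + cds_b[b_from : b_from + take_b * 3]
        new_cds = _repair_orf(rng, fusion + "TAA")
        new_cds = _mutate_orf_preserving(rng, new_cds, 0.01)
        anchor = _distal_anchor(builder, rng, donor_a)
        builder.insert_gene_after(rng, gene_id, anchor, new_cds, 1)
        builder.truth.origin[gene_id] = "chimera"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = sorted([donor_a, donor_b])


def _engineer_overprint(
    builder: _Builder, rng: np.random.Generator, donor: str, gene_id: str
) -> None:
    """Rewrite a donor CDS so its reverse strand holds a second ORF."""
    donor_model = builder.genes[donor]
    (d_start, d_end) = donor_model.cds_segments[0]
    length = d_end - d_start
    for _attempt in range(200):
        cds = _make_orf(rng, length // 3)
        win_codons = int(rng.integers(30, min(60, length // 3 - 4)))
        win_len = win_codons * 3
        a = int(rng.integers(3, length - win_len - 3))
        b = a + win_len
        work = list(cds)
        # reverse-strand ORF occupies forward interval [a, b): force its
        # start (revcomp ATG = CAT at [b-3, b)) and stop (revcomp TAA = TTA
        # at [a, a+3)), then clear internal stops in the reverse frame
        work[b - 3 : b] = "CAT"
        work[a : a + 3] = "TTA"

        def fwd_ok(seq: list[str]) -> bool:
            s = "".join(seq)
            return is_intact_orf(s)

        if not fwd_ok(work):
            continue
        ok = True
        for _round in range(40):
            window = revcomp("".join(work[a:b]))
            stops = [
                i
                for i, codon in enumerate(codons(window)[1:-1], start=1)
                if codon in STOP_CODONS
            ]
            if not stops:
                break
            idx = stops[0]
            # reverse codon idx occupies forward bases [b - 3*(idx+1), b - 3*idx)
            lo = b - 3 * (idx + 1)
            fixed = False
            options = [(p, base) for p in range(3) for base in BASES]
            rng.shuffle(options)
            for p, base in options:
                if work[lo + p] == base:
                    continue
                trial = work.copy()
                trial[lo + p] = base
                new_window = revcomp("".join(trial[a:b]))
                new_codon = codons(new_window)[idx]
                if new_codon in STOP_CODONS:
                    continue
                if fwd_ok(trial):
                    work = trial
                    fixed = True
                    break
            if not fixed:
                ok = False
                break
        else:
            ok = False
        window = revcomp("".join(work[a:b]))
        if not (ok and is_intact_orf(window) and fwd_ok(work)):
            continue
        chrom_seq = builder.seqs[donor_model.chrom]
        builder.seqs[donor_model.chrom] = (
            chrom_seq[:d_start] + "".join(work) + chrom_seq[d_end:]
        )
        interval = (d_start + a, d_start + b)
        builder.add_gene(
            gene_id,
            donor_model.chrom,
            0,
            [interval],
            [interval],
            Strand.MINUS,
        )
        builder.dual_coding.append((donor, gene_id))
        builder.truth.origin[gene_id] = "overprint"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.donors[gene_id] = [donor]
        return
    raise ValidationError(f"could not engineer overprint ORF inside {donor}")


def _plant_overprints(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    used = set(builder.truth.donors.get("_used", []))
    pool = sorted(
        g.gene_id
        for g in builder.genes.values()
        if g.chrom == "Chr1"
        and len(g.cds_segments) == 1
        and g.strand is Strand.PLUS
        and g.cds_length >= 360
        and builder.truth.origin.get(g.gene_id) == "background"
        and g.gene_id not in used
    )
    n = config.planted("overprint")
    if len(pool) < n:
        raise ValidationError("not enough donors for overprinting")
    chosen = [pool[int(i)] for i in rng.choice(len(pool), size=n, replace=False)]
    builder.truth.donors.setdefault("_used", []).extend(chosen)
    for j, donor in enumerate(chosen):
        _engineer_overprint(builder, rng, donor, f"LSG_over_{j}")



def _background_anchor(builder: _Builder, rng: np.random.Generator) -> str:
    pool = [
        g
        for g in builder.order("Chr1")
        if builder.truth.origin.get(g) == "background"
    ]
    return pool[int(rng.integers(len(pool)))]

def _plant_te_exaptation(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    te_idx = len(builder.tes)
    for j in range(config.planted("te_exapt")):
        gene_id = f"LSG_te_{j}"
        anchor = _background_anchor(builder, rng)
        cds = _make_orf(rng, int(rng.integers(60, 110)))
        model = builder.insert_gene_after(rng, gene_id, anchor, cds, 1)
        exon_start, exon_end = model.exons[0]
        # TE fragment overlapping the exon tail and running past the gene
        overlap = int(rng.integers(60, min(200, exon_end - exon_start - 10)))
        te_start = exon_end - overlap
        te_end = exon_end + int(rng.integers(80, 300))
        superfamily = TE_SUPERFAMILIES[j % len(TE_SUPERFAMILIES)]
        te_id = f"TE{te_idx:03d}"
        te_idx += 1
        builder.tes.append(
            TeFragment(
                te_id,
                GenomicInterval("Chr1", te_start, te_end, Strand.PLUS),
                superfamily,
            )
        )
        builder.truth.origin[gene_id] = "te_exapt"
        builder.truth.lineage[gene_id] = "family_specific"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.te_partner[gene_id] = te_id


_DE_NOVO_CATEGORIES = ("INTACT", "MSC", "ISC_OR_INDEL", "BOTH")


def _plant_species_only(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    for j in range(config.planted("de_novo")):
        gene_id = f"LSG_denovo_{j}"
        anchor = _background_anchor(builder, rng)
        cds = _make_orf(rng, int(rng.integers(60, 110)))
        builder.insert_gene_after(rng, gene_id, anchor, cds, 1)
        builder.truth.origin[gene_id] = "de_novo"
        builder.truth.lineage[gene_id] = "species_only"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.outgroup_category[gene_id] = _DE_NOVO_CATEGORIES[
            j % len(_DE_NOVO_CATEGORIES)
        ]
    for j in range(config.planted("differential_loss")):
        gene_id = f"LSG_loss_{j}"
        anchor = _background_anchor(builder, rng)
        cds = _make_orf(rng, int(rng.integers(60, 110)))
        builder.insert_gene_after(rng, gene_id, anchor, cds, 1)
        builder.truth.origin[gene_id] = "differential_loss"
        builder.truth.lineage[gene_id] = "species_only"
        builder.truth.expression_class[gene_id] = "lsg_like"
        builder.truth.outgroup_category[gene_id] = "NO_HIT"


def _stop_creating_site(
    rng: np.random.Generator, cds: str
) -> tuple[int, str, str] | None:
    """(cds offset, ref base, alt base) turning an internal codon into a stop."""
    n_codons = len(cds) // 3
    candidates = []
    for idx in range(1, n_codons - 1):
        codon = cds[idx * 3 : idx * 3 + 3]
        for p in range(3):
            for base in BASES:
                if base == codon[p]:
                    continue
                if codon[:p] + base + codon[p + 1 :] in STOP_CODONS:
                    candidates.append((idx * 3 + p, codon[p], base))
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def _plant_accession_events(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> None:
    accessions = [f"acc{i:02d}" for i in range(config.n_accessions)]

    def new_gene(gene_id: str, strand: Strand) -> GeneModel:
        anchor = _background_anchor(builder, rng)
        cds = _make_orf(rng, int(rng.integers(60, 110)))
        return builder.insert_gene_after(rng, gene_id, anchor, cds, 1, strand)

    specs = []
    for j in range(config.planted("accession_isc")):
        lineage = "family_specific" if j < 2 else "species_only"
        conserved = lineage == "species_only" and j % 2 == 0
        specs.append(("ISC", j, lineage, conserved))
    for j in range(config.planted("accession_msc")):
        lineage = "family_specific" if j < 1 else "species_only"
        conserved = lineage == "species_only" and j % 2 == 1
        specs.append(("MSC", j, lineage, conserved))

    for snp_type, j, lineage, conserved in specs:
        gene_id = f"LSG_acc{snp_type.lower()}_{j}"
        strand = Strand.MINUS if (snp_type, j) == ("ISC", 3) else Strand.PLUS
        model = new_gene(gene_id, strand)
        cds = model.extract_cds(builder.seqs["Chr1"])
        if snp_type == "ISC":
            site = _stop_creating_site(rng, cds)
            assert site is not None
            cds_pos, ref_base, alt_base = site
        else:
            cds_pos, ref_base, alt_base = 0, "A", "G"  # ATG -> GTG
        n_carriers = int(rng.integers(1, 4))
        carriers = sorted(
            accessions[int(i)]
            for i in rng.choice(len(accessions), size=n_carriers, replace=False)
        )
        builder.truth.origin[gene_id] = f"accession_{snp_type.lower()}"
        builder.truth.lineage[gene_id] = lineage
        builder.truth.expression_class[gene_id] = "lsg_like"
        if lineage == "species_only":
            builder.truth.outgroup_category[gene_id] = (
                ("ISC_OR_INDEL" if snp_type == "ISC" else "MSC")
                if conserved
                else "INTACT"
            )
        for accession in carriers:
            builder.truth.disruptions[(gene_id, accession)] = snp_type
        builder.truth.accession_events.append(
            AccessionEvent(
                gene_id=gene_id,
                snp_type=snp_type,
                accessions=carriers,
                cds_pos=cds_pos,
                ref_cds_base=ref_base,
                alt_cds_base=alt_base,
                conserved_in_outgroup=conserved,
            )
        )


def plant_origin_events(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> _Builder:
    """Insert one labelled gene per planted event into the genome."""
    _plant_overprints(builder, config, rng)
    _plant_duplications(builder, config, rng)
    _plant_retrocopies(builder, config, rng)
    _plant_chimeras(builder, config, rng)
    _plant_te_exaptation(builder, config, rng)
    _plant_species_only(builder, config, rng)
    _plant_accession_events(builder, config, rng)
    builder.truth.donors.pop("_used", None)
    return builder


# ---------------------------------------------------------------------------
# Stage 3: diverged outgroup
# ---------------------------------------------------------------------------

SCAFFOLD_NAMES = {"Chr1": "scaffold_1", "ChrM": "scaffold_M", "ChrC": "scaffold_C"}


def _omega_substitutions(
    rng: np.random.Generator,
    cds: str,
    divergence: float,
    omega: float,
) -> dict[int, str]:
    """Choose CDS substitutions hitting a target dN/dS under NG86 counting.

    Expected N/S sites are computed from the reference codons; synonymous
    and nonsynonymous change counts are solved from ``divergence`` (per-site
    substitution probability) and ``omega``, then placed at random codons
    without ever creating a stop or touching the start/terminal codons.
    """
    n_codons = len(cds) // 3
    if n_codons < 4:
        return {}
    N_sites = S_sites = 0.0
    for idx in range(1, n_codons - 1):
        n, s = _codon_sites(cds[idx * 3 : idx * 3 + 3])
        N_sites += n
        S_sites += s
    total = divergence * 3 * (n_codons - 2)
    if omega * N_sites + S_sites <= 0:
        return {}
    p_syn = total / (omega * N_sites + S_sites)
    want_syn = int(round(p_syn * S_sites))
    want_non = int(round(omega * p_syn * N_sites))
    out: dict[int, str] = {}

    def place(want: int, synonymous: bool) -> None:
        placed = 0
        for _attempt in range(200 * max(1, want)):
            if placed >= want:
                break
            idx = int(rng.integers(1, n_codons - 1))
            codon = list(cds[idx * 3 : idx * 3 + 3])
            for pos in (idx * 3, idx * 3 + 1, idx * 3 + 2):
                if pos in out:
                    codon[pos - idx * 3] = out[pos]
            ref_codon = "".join(codon)
            if ref_codon in STOP_CODONS:
                continue
            p = int(rng.integers(3))
            if idx * 3 + p in out:
                continue
            alt = rng.choice([b for b in BASES if b != codon[p]])
            new_codon = ref_codon[:p] + alt + ref_codon[p + 1 :]
            if new_codon in STOP_CODONS:
                continue
            same_aa = translate(new_codon) == translate(ref_codon)
            if same_aa != synonymous:
                continue
            out[idx * 3 + p] = str(alt)
            placed += 1

    place(want_syn, True)
    place(want_non, False)
    return out


_CDS_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_cds_base(
    seq: list[str], model: GeneModel, cds_pos: int, base: str
) -> None:
    pos = model.cds_to_genomic(cds_pos)
    seq[pos] = _CDS_COMPLEMENT[base] if model.strand is Strand.MINUS else base


def derive_outgroup(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str]]:
    """Outgroup scaffolds plus outgroup gene models (as CDS sequences).

    The outgroup is the focal genome with per-site substitutions at the
    configured divergence: ORF-preserving, dN/dS-targeted substitutions
    inside gene CDS (conserved genes at ``conserved_omega``, LSG-like at
    ``lsg_omega``; overlapping dual-coding loci are mutated site-wise with
    both frames checked), free substitutions elsewhere.  Species-only
    genes then receive their planted disruption (start loss, internal
    stop, frameshift deletion, both, or whole-locus deletion); gene
    models are emitted only for genes with an intact, annotated outgroup
    ortholog (conserved background genes and family-level LSGs).
    """
    d = config.outgroup_divergence
    seqs = {chrom: list(seq) for chrom, seq in builder.seqs.items()}
    truth = builder.truth
    dual_genes = {g for pair in builder.dual_coding for g in pair}

    # masks of CDS positions handled gene-wise (or protected)
    cds_positions: dict[str, set[int]] = {chrom: set() for chrom in seqs}
    for gene in builder.genes.values():
        for start, end in gene.cds_segments:
            cds_positions[gene.chrom].update(range(start, end))

    # 1. gene-wise omega-targeted substitutions
    for gene_id in sorted(builder.genes):
        if gene_id in dual_genes:
            continue
        gene = builder.genes[gene_id]
        lineage = truth.lineage.get(gene_id, "conserved")
        omega = config.conserved_omega if lineage == "conserved" else config.lsg_omega
        cds = gene.extract_cds(builder.seqs[gene.chrom])
        for cds_pos, base in sorted(
            _omega_substitutions(rng, cds, d, omega).items()
        ):
            _write_cds_base(seqs[gene.chrom], gene, cds_pos, base)

    # 2. dual-coding loci: site-wise, both reading frames preserved
    for donor_id, over_id in builder.dual_coding:
        donor = builder.genes[donor_id]
        over = builder.genes[over_id]
        chrom = donor.chrom
        lo, hi = donor.cds_segments[0]
        for pos in range(lo, hi):
            if rng.random() >= d:
                continue
            original = seqs[chrom][pos]
            for alt in rng.permutation([b for b in BASES if b != original]):
                seqs[chrom][pos] = str(alt)
                snippet = "".join(seqs[chrom][lo:hi])
                donor_ok = is_intact_orf(snippet)
                o_lo, o_hi = over.cds_segments[0]
                over_ok = is_intact_orf(revcomp("".join(seqs[chrom][o_lo:o_hi])))
                if donor_ok and over_ok:
                    break
                seqs[chrom][pos] = original

    # 3. free sites (introns, UTRs, intergenic)
    for chrom in sorted(seqs):
        seq = seqs[chrom]
        occupied = cds_positions[chrom]
        n = len(seq)
        hits = np.flatnonzero(rng.random(n) < d)
        for pos in hits:
            pos = int(pos)
            if pos in occupied:
                continue
            seq[pos] = str(rng.choice([b for b in BASES if b != seq[pos]]))

    # 4. planted disruptions on species-only genes
    deletions: dict[str, list[tuple[int, int]]] = {chrom: [] for chrom in seqs}
    isc_indel_toggle = 0
    for gene_id in sorted(truth.outgroup_category):
        category = truth.outgroup_category[gene_id]
        gene = builder.genes[gene_id]
        chrom = gene.chrom
        n_codons = gene.cds_length // 3
        if category == "NO_HIT":
            span = gene.span
            deletions[chrom].append(
                (max(0, span.start - 150), min(len(seqs[chrom]), span.end + 150))
            )
            continue
        if truth.origin[gene_id].startswith("accession_"):
            event = next(
                e for e in truth.accession_events if e.gene_id == gene_id
            )
            # restore the whole event codon to its focal state (divergence
            # may have touched its other bases), then plant the disrupting
            # allele only for conserved events — so the outgroup reads
            # exactly CONSERVED_SNP or NOT_DISRUPTED at the site
            ref_cds = gene.extract_cds(builder.seqs[chrom])
            codon_start = (event.cds_pos // 3) * 3
            for k in range(3):
                _write_cds_base(
                    seqs[chrom], gene, codon_start + k, ref_cds[codon_start + k]
                )
            if event.conserved_in_outgroup:
                _write_cds_base(seqs[chrom], gene, event.cds_pos, event.alt_cds_base)
            continue
        if category in ("MSC", "BOTH"):
            _write_cds_base(seqs[chrom], gene, 0, "G")  # ATG -> GTG
        if category == "BOTH" or (
            category == "ISC_OR_INDEL" and isc_indel_toggle % 2 == 0
        ):
            mid = n_codons // 2
            for k, base in enumerate("TAA"):
                _write_cds_base(seqs[chrom], gene, mid * 3 + k, base)
            if category == "ISC_OR_INDEL":
                isc_indel_toggle += 1
        elif category == "ISC_OR_INDEL":
            pos = gene.cds_to_genomic((n_codons // 2) * 3)
            deletions[chrom].append((pos, pos + 1))
            isc_indel_toggle += 1

    # 5. apply deletions (descending) and name scaffolds
    scaffolds: dict[str, str] = {}
    shift_edits: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(seqs):
        seq = seqs[chrom]
        edits = sorted(deletions[chrom], reverse=True)
        for start, end in edits:
            del seq[start:end]
        shift_edits[chrom] = sorted(deletions[chrom])
        scaffolds[SCAFFOLD_NAMES.get(chrom, f"scaffold_{chrom}")] = "".join(seq)

    def shifted(chrom: str, pos: int) -> int:
        return pos - sum(
            min(end, pos) - start
            for start, end in shift_edits[chrom]
            if start < pos
        )

    outgroup_cds: dict[str, str] = {}
    for gene_id in sorted(builder.genes):
        lineage = truth.lineage.get(gene_id, "conserved")
        if lineage == "species_only":
            continue
        gene = builder.genes[gene_id]
        scaffold = SCAFFOLD_NAMES.get(gene.chrom, f"scaffold_{gene.chrom}")
        seq = scaffolds[scaffold]
        parts = [
            seq[shifted(gene.chrom, start) : shifted(gene.chrom, end)]
            for start, end in gene.cds_segments
        ]
        cds = "".join(parts)
        if gene.strand is Strand.MINUS:
            cds = revcomp(cds)
        outgroup_cds[f"og_{gene_id}"] = cds
    return scaffolds, outgroup_cds


# ---------------------------------------------------------------------------
# Stage 4: accession polymorphisms
# ---------------------------------------------------------------------------


def _synonymous_site(
    rng: np.random.Generator, cds: str
) -> tuple[int, str, str] | None:
    n_codons = len(cds) // 3
    for _attempt in range(200):
        idx = int(rng.integers(1, n_codons - 1))
        codon = cds[idx * 3 : idx * 3 + 3]
        options = []
        for p in range(3):
            for base in BASES:
                if base == codon[p]:
                    continue
                alt_codon = codon[:p] + base + codon[p + 1 :]
                if alt_codon in STOP_CODONS:
                    continue
                if translate(alt_codon) == translate(codon):
                    options.append((idx * 3 + p, codon[p], base))
        if options:
            return options[int(rng.integers(len(options)))]
    return None


def generate_polymorphisms(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> list[Snp]:
    """Accession SNP table: planted ISC/MSC alleles plus neutral noise.

    Background SNPs are synonymous (inside conserved single-frame CDS) or
    intergenic, so only the planted events can disrupt an ORF; a handful
    of undetermined ('N') alleles inside LSG CDS exercise missing-data
    handling.
    """
    accessions = [f"acc{i:02d}" for i in range(config.n_accessions)]
    snps: list[Snp] = []
    truth = builder.truth
    dual = {g for pair in builder.dual_coding for g in pair}

    for event in truth.accession_events:
        gene = builder.genes[event.gene_id]
        pos = gene.cds_to_genomic(event.cds_pos)
        ref = builder.seqs[gene.chrom][pos]
        alt = (
            _CDS_COMPLEMENT[event.alt_cds_base]
            if gene.strand is Strand.MINUS
            else event.alt_cds_base
        )
        for accession in event.accessions:
            snps.append(Snp(accession, gene.chrom, pos, ref, alt))

    conserved = sorted(
        g
        for g, lvl in truth.lineage.items()
        if lvl == "conserved" and g not in dual and builder.genes[g].chrom == "Chr1"
    )
    planted_sites = {
        (builder.genes[e.gene_id].chrom, builder.genes[e.gene_id].cds_to_genomic(e.cds_pos))
        for e in truth.accession_events
    }
    for _ in range(120):
        gene_id = conserved[int(rng.integers(len(conserved)))]
        gene = builder.genes[gene_id]
        cds = gene.extract_cds(builder.seqs[gene.chrom])
        site = _synonymous_site(rng, cds)
        if site is None:
            continue
        cds_pos, ref_base, alt_base = site
        pos = gene.cds_to_genomic(cds_pos)
        if (gene.chrom, pos) in planted_sites:
            continue
        if gene.strand is Strand.MINUS:
            ref_base = _CDS_COMPLEMENT[ref_base]
            alt_base = _CDS_COMPLEMENT[alt_base]
        accession = accessions[int(rng.integers(len(accessions)))]
        snps.append(Snp(accession, gene.chrom, pos, ref_base, alt_base))

    chrom = "Chr1"
    exonic = set()
    for gene in builder.genes.values():
        if gene.chrom != chrom:
            continue
        for start, end in gene.exons:
            exonic.update(range(start, end))
    n = len(builder.seqs[chrom])
    placed = 0
    while placed < 80:
        pos = int(rng.integers(n))
        if pos in exonic:
            continue
        ref = builder.seqs[chrom][pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        accession = accessions[int(rng.integers(len(accessions)))]
        snps.append(Snp(accession, chrom, pos, ref, alt))
        placed += 1

    lsg_pool = sorted(
        g for g in truth.lsg_ids() if not truth.origin[g].startswith("accession_")
    )
    for i in range(5 if lsg_pool else 0):
        gene = builder.genes[lsg_pool[int(rng.integers(len(lsg_pool)))]]
        cds_len = gene.cds_length
        cds_pos = int(rng.integers(3, cds_len - 3))
        pos = gene.cds_to_genomic(cds_pos)
        ref = builder.seqs[gene.chrom][pos]
        accession = accessions[int(rng.integers(len(accessions)))]
        snps.append(Snp(accession, gene.chrom, pos, ref, "N"))

    return sorted(snps, key=lambda s: (s.chrom, s.pos, s.accession, s.alt))


# ---------------------------------------------------------------------------
# Stage 5: per-tier homology hit tables
# ---------------------------------------------------------------------------


def generate_homology_tiers(
    builder: _Builder, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[dict[str, list[HSP]], dict[str, bool]]:
    """Database-tier hit tables emulating a cascade of homology searches.

    Conserved genes carry an out-of-lineage hit in exactly one tier (most
    in the peptide tier, a few only in later tiers, three only flagged by
    the domain scan); planted LSGs carry no out-of-lineage hits, though
    some get within-lineage decoy hits that must not eliminate them.
    """
    tiers: dict[str, list[HSP]] = {name: [] for name in TIER_NAMES}
    domains: dict[str, bool] = {}
    conserved = sorted(
        g for g, lvl in builder.truth.lineage.items() if lvl == "conserved"
    )
    assignments: dict[str, str] = {}
    for i, gene_id in enumerate(conserved):
        if i < 3:
            assignments[gene_id] = "domain_scan"
        elif i < 8:
            assignments[gene_id] = "est_db"
        elif i < 12:
            assignments[gene_id] = "position_specific"
        elif i < 20:
            assignments[gene_id] = "nucleotide_db"
        else:
            assignments[gene_id] = "peptide_db"

    for gene_id in conserved:
        domains[gene_id] = assignments[gene_id] == "domain_scan"
        tier = assignments[gene_id]
        if tier == "domain_scan":
            continue
        gene = builder.genes[gene_id]
        length = (
            gene.cds_length // 3 - 1 if tier == "peptide_db" else gene.cds_length
        )
        length = max(length, 30)
        taxon = OUT_LINEAGE_TAXA[int(rng.integers(len(OUT_LINEAGE_TAXA)))]
        tiers[tier].append(
            HSP(
                query_id=gene_id,
                subject_id=f"OUTSP_{gene_id}",
                q_start=0,
                q_end=length,
                s_start=0,
                s_end=length,
                orientation=Orientation.FORWARD,
                percent_identity=float(rng.uniform(40, 90)),
                score=float(rng.uniform(80, 400)),
                e_value=float(10 ** rng.uniform(-60, -6)),
                n_columns=length,
                subject_taxon=taxon,
            )
        )

    lsgs = sorted(builder.truth.lsg_ids())
    for gene_id in lsgs[:10]:
        gene = builder.genes[gene_id]
        length = max(30, gene.cds_length // 3 - 1)
        tiers["peptide_db"].append(
            HSP(
                query_id=gene_id,
                subject_id=f"BRA_{gene_id}",
                q_start=0,
                q_end=length,
                s_start=0,
                s_end=length,
                orientation=Orientation.FORWARD,
                percent_identity=float(rng.uniform(60, 95)),
                score=float(rng.uniform(80, 400)),
                e_value=float(10 ** rng.uniform(-60, -10)),
                n_columns=length,
                subject_taxon=LINEAGE_TAXON,
            )
        )
        domains.setdefault(gene_id, False)
    for gene_id in lsgs:
        domains.setdefault(gene_id, False)
    return tiers, domains


# ---------------------------------------------------------------------------
# Stage 6: expression
# ---------------------------------------------------------------------------


def generate_expression_tables(
    labels: dict[str, str],
    expr_config: ExpressionConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionBundle, dict[str, set[str]]]:
    """Expression + call matrices and per-contrast DE tables.

    LSG-like genes are present in few tissues (median near
    ``lsg_breadth_mean``), expressed lower by ``lsg_expr_shift`` log2
    units, and up-regulated in stress contrasts with
    ``planted_enrichment_odds`` times the background odds.
    """
    if expr_config.n_replicates < 2:
        raise ValidationError("call rule needs >= 2 replicates per tissue")
    genes = sorted(labels)
    is_lsg = np.array([labels[g] == "lsg_like" for g in genes])
    T, R = expr_config.n_tissues, expr_config.n_replicates
    tissues = [f"tissue_{t:02d}" for t in range(T)]
    samples = [f"{tissue}_rep{r}" for tissue in tissues for r in range(R)]
    sample_tissue = {s: s.rsplit("_rep", 1)[0] for s in samples}

    breadth = np.where(
        is_lsg,
        np.clip(
            np.round(
                rng.exponential(
                    expr_config.lsg_breadth_mean / np.log(2.0), size=len(genes)
                )
            ),
            0,
            T,
        ),
        np.clip(
            np.round(rng.normal(expr_config.nonlsg_breadth_mean, 15, len(genes))),
            0,
            T,
        ),
    ).astype(int)

    present = np.zeros((len(genes), T), dtype=bool)
    for gi in range(len(genes)):
        if breadth[gi] > 0:
            chosen = rng.choice(T, size=breadth[gi], replace=False)
            present[gi, chosen] = True

    calls = np.zeros((len(genes), T * R), dtype=bool)
    for t in range(T):
        block = rng.random((len(genes), R)) < 0.7
        none_on = ~block.any(axis=1)
        block[none_on, 0] = True
        block[~present[:, t]] = False
        calls[:, t * R : (t + 1) * R] = block

    base = rng.normal(expr_config.base_log2_expression, 0.35, len(genes))
    base = base - np.where(is_lsg, expr_config.lsg_expr_shift, 0.0)
    expr = np.empty((len(genes), T * R))
    for t in range(T):
        tissue_level = np.where(
            present[:, t], base, rng.normal(1.2, 0.3, len(genes))
        )
        expr[:, t * R : (t + 1) * R] = (
            tissue_level[:, None] + rng.normal(0, 0.15, (len(genes), R))
        )

    expression = pd.DataFrame(expr, index=genes, columns=samples)
    call_df = pd.DataFrame(calls, index=genes, columns=samples)

    de_tables: dict[str, pd.DataFrame] = {}
    contrast_meta: dict[str, dict[str, str]] = {}
    de_truth: dict[str, set[str]] = {}
    p0 = expr_config.base_de_rate
    odds0 = p0 / (1 - p0)
    odds1 = odds0 * expr_config.planted_enrichment_odds
    p1 = odds1 / (1 + odds1)
    stress_names = [
        f"stress{i}_root_{t}h"
        for i, t in zip(
            range(expr_config.n_stress_contrasts),
            [1, 3, 6, 12, 24, 48] * 10,
        )
    ]
    control_names = [
        f"hormone{i}_shoot_24h" for i in range(expr_config.n_control_contrasts)
    ]
    for name in stress_names + control_names:
        is_stress = name.startswith("stress")
        contrast_meta[name] = {
            "tissue": "root" if is_stress else "shoot",
            "time_point": name.rsplit("_", 1)[1],
            "kind": "stress" if is_stress else "control",
        }
        p_up = np.where(is_lsg & is_stress, p1, p0)
        up = rng.random(len(genes)) < p_up
        down = (~up) & (rng.random(len(genes)) < 0.04)
        log2fc = rng.normal(0, 0.2, len(genes))
        adj_p = rng.uniform(0.02, 1.0, len(genes))
        log2fc[up] = rng.uniform(0.8, 3.0, int(up.sum()))
        adj_p[up] = rng.uniform(1e-6, 0.009, int(up.sum()))
        log2fc[down] = -rng.uniform(0.8, 3.0, int(down.sum()))
        adj_p[down] = rng.uniform(1e-6, 0.009, int(down.sum()))
        de_tables[name] = pd.DataFrame(
            {"gene": genes, "log2fc": log2fc, "adj_p": adj_p}
        )
        de_truth[name] = {g for g, flag in zip(genes, up) if flag}
    bundle = ExpressionBundle(
        expression=expression,
        calls=call_df,
        sample_tissue=sample_tissue,
        de_tables=de_tables,
        contrast_meta=contrast_meta,
    )
    return bundle, de_truth


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Run every generation stage under one deterministic seed tree."""
    root = np.random.SeedSequence(config.seed)
    (
        seed_genome,
        seed_plant,
        seed_outgroup,
        seed_snps,
        seed_tiers,
        seed_expr,
        seed_misc,
    ) = root.spawn(7)
    builder = generate_genome(config, np.random.default_rng(seed_genome))
    plant_origin_events(builder, config, np.random.default_rng(seed_plant))
    builder.truth.reconcile(config)

    # expression-support labels for Table-1 style summaries
    rng_misc = np.random.default_rng(seed_misc)
    for gene_id in sorted(builder.truth.lsg_ids()):
        u = rng_misc.random()
        builder.genes[gene_id].expression_support = (
            ExpressionSupport.GENE_MODEL
            if u < 0.5
            else ExpressionSupport.LOCUS
            if u < 0.8
            else ExpressionSupport.NONE
        )

    scaffolds, outgroup_cds = derive_outgroup(
        builder, config, np.random.default_rng(seed_outgroup)
    )
    snps = generate_polymorphisms(builder, config, np.random.default_rng(seed_snps))
    tier_hits, domains = generate_homology_tiers(
        builder, config, np.random.default_rng(seed_tiers)
    )
    bundle, de_truth = generate_expression_tables(
        builder.truth.expression_class,
        config.expression,
        np.random.default_rng(seed_expr),
    )
    builder.truth.de_truth = de_truth

    syntelogs: set[frozenset[str]] = set()
    wgd: set[frozenset[str]] = set()
    if "LSG_dupin_1" in builder.truth.donors:
        pair = frozenset(
            ("LSG_dupin_1", builder.truth.donors["LSG_dupin_1"][0])
        )
        syntelogs.add(pair)
        wgd.add(pair)

    return SyntheticScenario(
        config=config,
        catalog=builder.to_catalog(),
        truth=builder.truth,
        tier_hits=tier_hits,
        domain_annotations=domains,
        outgroup_scaffolds=scaffolds,
        outgroup_cds=outgroup_cds,
        snps=snps,
        expression=bundle,
        syntelog_pairs=syntelogs,
        wgd_pairs=wgd,
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> None:
    """Write every scenario artifact as plain text (FASTA/GFF3/TSV)."""
    from pathlib import Path

    from .io import write_fasta, write_genome_annotation, write_hit_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        dict(sorted(scenario.catalog.sequences.items())), outdir / "focal.fasta"
    )
    write_genome_annotation(
        scenario.catalog, outdir / "genes.gff3", outdir / "tes.gff3"
    )
    write_fasta(
        dict(sorted(scenario.outgroup_scaffolds.items())), outdir / "outgroup.fasta"
    )
    write_fasta(
        dict(sorted(scenario.outgroup_cds.items())), outdir / "outgroup_cds.fasta"
    )
    for tier, hits in scenario.tier_hits.items():
        write_hit_table(hits, outdir / f"hits_{tier}.tsv")
    with open(outdir / "snps.tsv", "w") as handle:
        handle.write("accession\tchrom\tpos\tref\talt\n")
        for snp in scenario.snps:
            handle.write(
                f"{snp.accession}\t{snp.chrom}\t{snp.pos + 1}\t{snp.ref}\t{snp.alt}\n"
            )
    scenario.expression.expression.round(4).to_csv(
        outdir / "expression.tsv", sep="\t"
    )
    scenario.expression.calls.to_csv(outdir / "calls.tsv", sep="\t")
    for contrast, table in sorted(scenario.expression.de_tables.items()):
        table.round(6).to_csv(outdir / f"de_{contrast}.tsv", sep="\t", index=False)
    with open(outdir / "syntelogs.tsv", "w") as handle:
        handle.write("gene_a\tgene_b\twgd\n")
        for pair in sorted(scenario.syntelog_pairs, key=sorted):
            a, b = sorted(pair)
            flag = "1" if pair in scenario.wgd_pairs else "0"
            handle.write(f"{a}\t{b}\t{flag}\n")
    truth = scenario.truth
    with open(outdir / "truth_genes.tsv", "w") as handle:
        handle.write(
            "gene_id\torigin\tlineage\toutgroup_category\tdonors\texpression_class\n"
        )
        for gene_id in sorted(truth.origin):
            handle.write(
                "\t".join(
                    [
                        gene_id,
                        truth.origin[gene_id],
                        truth.lineage.get(gene_id, ""),
                        truth.outgroup_category.get(gene_id, ""),
                        ",".join(truth.donors.get(gene_id, [])),
                        truth.expression_class.get(gene_id, ""),
                    ]
                )
                + "\n"
            )
    with open(outdir / "truth_disruptions.tsv", "w") as handle:
        handle.write("gene_id\taccession\tsnp_type\n")
        for (gene_id, accession), snp_type in sorted(truth.disruptions.items()):
            handle.write(f"{gene_id}\t{accession}\t{snp_type}\n")
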