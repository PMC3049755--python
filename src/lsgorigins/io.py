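"""Readers and writers for the standard formats the pipeline consumes.

This is the only module that touches raw text: GFF3 and tabular alignment
coordinates are 1-based inclusive on disk and converted to the package's
0-based half-open convention here, once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import gffutils
from Bio import SeqIO

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

logger = logging.getLogger(__name__)

#: GFF3 feature types routed to TeFragment rather than GeneModel.
TE_FEATURE_TYPES = {
    "transposable_element",
    "transposon_fragment",
    "transposable_element_gene",
}

#: Chromosome-name prefixes mapping to organellar compartments.
ORGANELLE_CHROMS = {
    "chrm": Compartment.MITOCHONDRIAL,
    "mt": Compartment.MITOCHONDRIAL,
    "chrc": Compartment.CHLOROPLAST,
    "pt": Compartment.CHLOROPLAST,
}


class MalformedAnnotationError(ValidationError):
    """A gene model in the GFF3 violates structural invariants."""


class MissingSequenceError(ValidationError):
    """The GFF3 references a sequence id absent from the FASTA."""


@dataclass
class GenomeCatalog:
    """Validated genes, TE fragments and chromosome sequences."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    te_fragments: list[TeFragment] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def cds_sequence(self, gene_id: str) -> str:
        gene = self.genes[gene_id]
        return gene.extract_cds(self.sequences[gene.chrom])

    def peptide_sequence(self, gene_id: str) -> str:
        from .seqs import translate

        pep = translate(self.cds_sequence(gene_id))
        return pep[:-1] if pep.endswith("*") else pep

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        """Genes grouped per chromosome, sorted by span start."""
        out: dict[str, list[GeneModel]] = {}
        for gene in self.genes.values():
            out.setdefault(gene.chrom, []).append(gene)
        for models in out.values():
            models.sort(key=lambda g: (g.span.start, g.gene_id))
        return out


def compartment_for_chrom(chrom: str) -> Compartment:
    return ORGANELLE_CHROMS.get(chrom.lower(), Compartment.NUCLEAR)


def read_fasta(source: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _pick_representative(models: list[dict]) -> dict:
    """Longest CDS wins; ties broken by lexicographic model id."""
    return min(
        models,
        key=lambda m: (-sum(e - s for s, e in m["cds"]), m["model_id"]),
    )


def read_genome_annotation(
    gff3_source: str | Path,
    fasta_source: str | Path | dict[str, str],
) -> GenomeCatalog:
    """Parse a gene + TE GFF3 and its genome FASTA into a validated catalog.

    One representative model is retained per gene locus.  Models whose CDS
    length is not a multiple of 3 are kept but flagged non-intact with a
    warning.  TE-typed features become :class:`TeFragment` records.
    """
    sequences = (
        dict(fasta_source)
        if isinstance(fasta_source, dict)
        else read_fasta(fasta_source)
    )
    db = gffutils.create_db(
        str(gff3_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    catalog = GenomeCatalog(sequences=sequences)

    for feat in db.all_features():
        if feat.featuretype in TE_FEATURE_TYPES and feat.featuretype != (
            "transposable_element_gene"
        ):
            if feat.seqid not in sequences:
                raise MissingSequenceError(
                    f"TE {feat.id}: sequence {feat.seqid!r} not in FASTA"
                )
            superfamily = feat.attributes.get(
                "superfamily", feat.attributes.get("Alias", ["unknown"])
            )[0]
            catalog.te_fragments.append(
                TeFragment(
                    te_id=feat.id,
                    interval=GenomicInterval(
                        feat.seqid,
                        feat.start - 1,
                        feat.end,
                        Strand(feat.strand) if feat.strand in "+-" else Strand.UNSTRANDED,
                    ),
                    superfamily=superfamily,
                )
            )

    for gene in db.features_of_type("gene"):
        if gene.seqid not in sequences:
            raise MissingSequenceError(
                f"gene {gene.id}: sequence {gene.seqid!r} not in FASTA"
            )
        models = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [
                (c.start - 1, c.end) for c in db.children(mrna, featuretype="exon")
            ]
            cds = [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            if not exons:
                exons = list(cds)
            models.append({"model_id": mrna.id, "exons": exons, "cds": cds})
        if not models:
            continue
        chosen = _pick_representative(models)
        support = gene.attributes.get("expression_support", ["none"])[0]
        is_te_gene = gene.attributes.get("is_te_gene", ["false"])[0] == "true"
        try:
            model = GeneModel(
                gene_id=gene.id,
                representative_model_id=chosen["model_id"],
                chrom=gene.seqid,
                strand=Strand(gene.strand) if gene.strand in "+-" else Strand.UNSTRANDED,
                exons=chosen["exons"],
                cds_segments=chosen["cds"],
                compartment=compartment_for_chrom(gene.seqid),
                is_te_gene=is_te_gene,
                expression_support=ExpressionSupport(support),
            )
        except ValidationError as exc:
            raise MalformedAnnotationError(str(exc)) from exc
        if model.cds_length % 3 != 0:
            model.intact = False
            logger.warning(
                "model %s: CDS length %d not divisible by 3; flagged non-intact",
                model.representative_model_id,
                model.cds_length,
            )
        catalog.genes[gene.id] = model
    return catalog


def write_genome_annotation(
    catalog: GenomeCatalog,
    gff3_path: str | Path,
    te_gff3_path: str | Path | None = None,
) -> None:
    """Emit genes (and optionally TEs) back to GFF3, 1-based inclusive."""

    def gene_lines(gene: GeneModel) -> Iterable[str]:
        strand = gene.strand.value
        attrs = (
            f"ID={gene.gene_id};expression_support={gene.expression_support.value}"
        )
        if gene.is_te_gene:
            attrs += ";is_te_gene=true"
        span = gene.span
        yield (
            f"{gene.chrom}\tlsgorigins\tgene\t{span.start + 1}\t{span.end}\t.\t"
            f"{strand}\t.\t{attrs}"
        )
        yield (
            f"{gene.chrom}\tlsgorigins\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
            f"{strand}\t.\tID={gene.representative_model_id};Parent={gene.gene_id}"
        )
        for start, end in gene.exons:
            yield (
                f"{gene.chrom}\tlsgorigins\texon\t{start + 1}\t{end}\t.\t{strand}"
                f"\t.\tParent={gene.representative_model_id}"
            )
        for (start, end), phase in zip(gene.cds_segments, gene.phases):
            yield (
                f"{gene.chrom}\tlsgorigins\tCDS\t{start + 1}\t{end}\t.\t{strand}"
                f"\t{phase}\tParent={gene.representative_model_id}"
            )

    with open(gff3_path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in sorted(
            catalog.genes.values(), key=lambda g: (g.chrom, g.span.start, g.gene_id)
        ):
            for line in gene_lines(gene):
                handle.write(line + "\n")

    if te_gff3_path is not None:
        with open(te_gff3_path, "w") as handle:
            handle.write("##gff-version 3\n")
            for te in sorted(
                catalog.te_fragments,
                key=lambda t: (t.interval.chrom, t.interval.start, t.te_id),
            ):
                iv = te.interval
                handle.write(
                    f"{iv.chrom}\tlsgorigins\ttransposable_element\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{iv.strand.value}\t.\t"
                    f"ID={te.te_id};superfamily={te.superfamily}\n"
                )


class HitTableError(ValidationError):
    """A row of a 12-column tabular alignment file failed to parse."""


def _parse_hit_row(line: str, line_no: int, taxon_map: dict[str, str] | None) -> HSP:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise HitTableError(f"line {line_no}: expected 12 columns, got {len(fields)}")
    (
        query_id,
        subject_id,
        pident,
        length,
        _mismatch,
        _gapopen,
        qstart,
        qend,
        sstart,
        send,
        evalue,
        bitscore,
    ) = fields
    try:
        qstart_i, qend_i = int(qstart), int(qend)
        sstart_i, send_i = int(sstart), int(send)
        pident_f = float(pident)
        length_i = int(length)
        evalue_f = float(evalue)
        score_f = float(bitscore)
    except ValueError as exc:
        raise HitTableError(f"line {line_no}: non-numeric field ({exc})") from exc
    if qstart_i > qend_i:
        raise HitTableError(
            f"line {line_no}: reversed query coordinates {qstart_i} > {qend_i}"
        )
    if sstart_i > send_i:
        orientation = Orientation.INVERTED
        s_start, s_end = send_i - 1, sstart_i
    else:
        orientation = Orientation.FORWARD
        s_start, s_end = sstart_i - 1, send_i
    return HSP(
        query_id=query_id,
        subject_id=subject_id,
        q_start=qstart_i - 1,
        q_end=qend_i,
        s_start=s_start,
        s_end=s_end,
        orientation=orientation,
        percent_identity=pident_f,
        score=score_f,
        e_value=evalue_f,
        n_columns=length_i,
        subject_taxon=(taxon_map or {}).get(subject_id),
    )


def read_hit_table(
    source: str | Path | TextIO,
    strict: bool = True,
    taxon_map: dict[str, str] | None = None,
) -> list[HSP]:
    """Read 12-column tabular alignment output into HSPs.

    Printed coordinates are 1-based inclusive; ``sstart > send`` encodes an
    inverted-orientation hit.  In non-strict mode malformed rows are logged
    and skipped instead of raising.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    hits: list[HSP] = []
    try:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                hits.append(_parse_hit_row(line, line_no, taxon_map))
            except (HitTableError, ValidationError) as exc:
                if strict:
                    raise HitTableError(str(exc)) from exc
                logger.warning("skipping hit-table row: %s", exc)
    finally:
        if close:
            handle.close()
    return hits


def write_hit_table(hits: Iterable[HSP], path: str | Path) -> None:
    """Write HSPs back to the 12-column tabular format."""
    with open(path, "w") as handle:
        for hsp in hits:
            if hsp.orientation is Orientation.INVERTED:
                sstart, send = hsp.s_end, hsp.s_start + 1
            else:
                sstart, send = hsp.s_start + 1, hsp.s_end
            mismatches = max(
                0,
                round(
                    min(hsp.q_span, hsp.s_end - hsp.s_start)
                    * (1 - hsp.percent_identity / 100.0)
                ),
            )
            handle.write(
                "\t".join(
                    [
                        hsp.query_id,
                        hsp.subject_id,
                        f"{hsp.percent_identity:.2f}",
                        str(hsp.n_columns),
                        str(mismatches),
                        "0",
                        str(hsp.q_start + 1),
                        str(hsp.q_end),
                        str(sstart),
                        str(send),
                        f"{hsp.e_value:.3g}",
                        f"{hsp.score:.1f}",
                    ]
                )
                + "\n"
            )
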