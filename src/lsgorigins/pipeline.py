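"""End-to-end pipeline: catalog -> origins -> outgroup -> polymorphism ->
expression, with a machine-readable summary and TSV reports.

The synthetic mode generates a scenario (see :mod:`.synth`), runs every
stage on the emitted artifacts exactly as a real study would, and scores
each classifier against the planted ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import catalog as catalog_mod
from . import expression as expr_mod
from . import origins, outgroup, polymorphism
from .catalog import LineageLevel, LsgRecord
from .io import GenomeCatalog
from .model import Orientation, ThresholdConfig, round_pct
from .search import toy_search
from .seqs import revcomp
from .synth import (
    LINEAGE_TAXON,
    ScenarioConfig,
    SyntheticScenario,
    generate_scenario,
    write_scenario,
)

logger = logging.getLogger(__name__)

#: Margin added around a chained scaffold region before ORF projection, so
#: that local-alignment end clipping cannot push the start codon out of the
#: extracted region.
REGION_BUFFER_BP = 60

#: Seed word sizes for the within-run searches (exact SW after seeding).
NUC_WORD = 11
PEP_WORD = 4

EXPECTED_PRIMARY = {
    "overprint": origins.Mechanism.OVERPRINTING,
    "dup_inframe": origins.Mechanism.DUPLICATION,
    "dup_frameshift": origins.Mechanism.DUPLICATION,
    "dup_inverted": origins.Mechanism.DUPLICATION,
    "retrocopy": origins.Mechanism.DUPLICATION,
    "te_exapt": origins.Mechanism.TE_EXAPTATION,
    "chimera": origins.Mechanism.CHIMERIC,
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    scenario: ScenarioConfig | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    outdir: Path | None = None
    write_inputs: bool = False
    overwrite: bool = False


@dataclass
class PipelineResult:
    records: dict[str, LsgRecord]
    eliminated: dict[str, str]
    assignments: dict[str, origins.OriginAssignment]
    rollup: pd.DataFrame
    projections: dict[str, outgroup.OrfProjection]
    outgroup_categories: dict[str, str]
    projection_summary: pd.DataFrame
    calls: list[polymorphism.DisruptionCall]
    call_matrix: pd.DataFrame
    scenarios: dict[str, polymorphism.BirthLossScenario]
    table1: pd.DataFrame
    enrichment: list[expr_mod.EnrichmentResult]
    enrichment_counts: dict[str, int]
    dnds_table: pd.DataFrame
    compartments_table: pd.DataFrame
    responsive_origins: pd.DataFrame
    summary: dict


def _peptides(catalog: GenomeCatalog, gene_ids) -> dict[str, str]:
    return {g: catalog.peptide_sequence(g) for g in sorted(gene_ids)}


def _cds(catalog: GenomeCatalog, gene_ids) -> dict[str, str]:
    return {g: catalog.cds_sequence(g) for g in sorted(gene_ids)}


def _te_overlap_to_cds_space(
    catalog: GenomeCatalog, gene_id: str, intervals
) -> list[tuple[int, int]]:
    """Map genomic overlap intervals into the gene's CDS coordinate space."""
    gene = catalog.genes[gene_id]
    out = []
    from .model import intersect_intervals

    for lo, hi in intersect_intervals(list(intervals), gene.cds_segments):
        a = gene.genomic_to_cds(lo)
        b = gene.genomic_to_cds(hi - 1)
        if a is None or b is None:
            continue
        lo_c, hi_c = min(a, b), max(a, b) + 1
        out.append((lo_c, hi_c))
    return out


def classify_lsg_origins(
    catalog: GenomeCatalog,
    records: Mapping[str, LsgRecord],
    thresholds: ThresholdConfig,
    syntelog_pairs: set[frozenset[str]] | None = None,
    wgd_pairs: set[frozenset[str]] | None = None,
) -> tuple[origins.OriginEvidencePack, dict]:
    """Run every within-genome origin classifier over the called LSGs."""
    lsg_ids = set(records)
    nonlsg_ids = sorted(set(catalog.genes) - lsg_ids)
    pack = origins.OriginEvidencePack()
    extras: dict = {}

    # --- overlapping CDS / overprinting
    overlap_pairs = origins.find_overlapping_cds(catalog, lsg_ids)
    extras["overlap_pairs"] = overlap_pairs
    overlap_partners: dict[str, set[str]] = {}
    overlap_regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for pair in overlap_pairs:
        for a, b in ((pair.gene_a, pair.gene_b), (pair.gene_b, pair.gene_a)):
            overlap_partners.setdefault(a, set()).add(b)
        if pair.pair_type == "LSG:nonLSG":
            lsg = pair.gene_a if pair.gene_a in lsg_ids else pair.gene_b
            other = pair.gene_b if lsg == pair.gene_a else pair.gene_a
            pack.overprint.setdefault(lsg, []).append(
                origins.Evidence("cds_overlap", other)
            )
            lsg_model = catalog.genes[lsg]
            other_model = catalog.genes[other]
            from .model import intersect_intervals

            genomic = intersect_intervals(
                lsg_model.cds_segments, other_model.cds_segments
            )
            overlap_regions.setdefault(lsg, {})[other] = _te_overlap_to_cds_space(
                catalog, lsg, genomic
            )

    # --- within-genome paralog searches (peptide + CDS)
    lsg_peps = _peptides(catalog, lsg_ids)
    lsg_cds = _cds(catalog, lsg_ids)
    nonlsg_peps = _peptides(catalog, nonlsg_ids)
    nonlsg_cds = _cds(catalog, nonlsg_ids)
    pep_hits = toy_search(
        lsg_peps, nonlsg_peps, mode="peptide", seed_word_size=PEP_WORD
    )
    cds_hits = toy_search(
        lsg_cds, nonlsg_cds, mode="nucleotide", seed_word_size=NUC_WORD
    )

    def allowed(hsp) -> bool:
        return hsp.subject_id not in overlap_partners.get(hsp.query_id, set())

    pep_hits = [h for h in pep_hits if allowed(h)]
    cds_hits = [h for h in cds_hits if allowed(h)]
    pep_lengths = {g: len(s) for g, s in lsg_peps.items()}
    cds_lengths = {g: len(s) for g, s in lsg_cds.items()}
    pep_cov = origins.merge_hits_by_pair(
        pep_hits, pep_lengths, thresholds, level="peptide"
    )
    cds_cov = origins.merge_hits_by_pair(
        cds_hits, cds_lengths, thresholds, level="cds"
    )
    extras["pep_cov"], extras["cds_cov"] = pep_cov, cds_cov

    pair_keys = sorted(set(pep_cov) | set(cds_cov))
    frame_reports: dict[tuple[str, str], origins.FrameReport] = {}
    mechanisms: dict[tuple[str, str], origins.DuplicationMechanism] = {}
    for key in pair_keys:
        query_id, subject_id = key
        report = origins.detect_out_of_frame(pep_cov.get(key), cds_cov.get(key))
        frame_reports[key] = report
        detail = pack.duplication_detail.setdefault(query_id, set())
        if key in pep_cov:
            detail.add(origins.MechanismDetail.IN_FRAME)
        if report is not None and not report.in_frame:
            detail.add(origins.MechanismDetail.OUT_OF_FRAME)
            if key in cds_cov:
                orientation = origins.detect_orientation(cds_cov[key].hsps)
                if orientation is Orientation.INVERTED:
                    detail.add(origins.MechanismDetail.INVERTED)
        if key in cds_cov:
            mech = origins.classify_duplication_mechanism(
                catalog.genes[query_id],
                catalog.genes[subject_id],
                cds_cov[key].hsps,
                thresholds,
            )
            mechanisms[key] = mech
            if mech is origins.DuplicationMechanism.RETROTRANSPOSITION:
                detail.add(origins.MechanismDetail.RETROTRANSPOSITION)
            elif mech is origins.DuplicationMechanism.UNEQUAL_CROSSING_OVER:
                detail.add(origins.MechanismDetail.UNEQUAL_CROSSING_OVER)
        pack.duplication.setdefault(query_id, []).append(
            origins.Evidence(
                "paralog_hit",
                subject_id,
                (cds_cov.get(key) or pep_cov.get(key)).merged_intervals,
            )
        )
    extras["frame_reports"] = frame_reports
    extras["mechanisms"] = mechanisms

    contexts = origins.classify_duplication_context(
        pair_keys, catalog, syntelog_pairs, wgd_pairs, thresholds
    )
    extras["contexts"] = contexts
    for (query_id, _subject), (context, wgd_flag) in contexts.items():
        detail = pack.duplication_detail.setdefault(query_id, set())
        detail.add(origins.MechanismDetail(context.value))
        if wgd_flag:
            detail.add(origins.MechanismDetail.WGD)

    # --- TE exaptation
    te_overlaps, te_tally = origins.detect_te_exaptation(
        catalog, lsg_ids, level="exon"
    )
    extras["te_overlaps"], extras["te_tally"] = te_overlaps, te_tally
    te_by_gene: dict[str, list[origins.TeOverlap]] = {}
    for overlap in te_overlaps:
        te_by_gene.setdefault(overlap.gene_id, []).append(overlap)
        if overlap.gene_id in lsg_ids:
            pack.te_exaptation.setdefault(overlap.gene_id, []).append(
                origins.Evidence("te_overlap", overlap.te_id)
            )

    # --- chimerism (needs parent-parent homology)
    parent_ids = sorted(
        {subject for (_q, subject) in pair_keys}
    )
    parent_peps = {g: nonlsg_peps[g] for g in parent_ids if g in nonlsg_peps}
    parent_hits = toy_search(
        parent_peps, parent_peps, mode="peptide", seed_word_size=PEP_WORD
    )
    parent_homology = {
        frozenset((h.query_id, h.subject_id))
        for h in parent_hits
        if h.e_value < thresholds.within_genome_evalue
        and h.query_id != h.subject_id
    }
    extras["parent_homology"] = parent_homology
    for gene_id in sorted(lsg_ids):
        parents: dict[str, list[tuple[int, int]]] = {}
        for (query_id, subject_id) in pair_keys:
            if query_id != gene_id:
                continue
            cov = cds_cov.get((query_id, subject_id))
            if cov is not None:
                parents[subject_id] = cov.merged_intervals
            else:
                pep = pep_cov[(query_id, subject_id)]
                parents[subject_id] = [
                    (s * 3, e * 3) for s, e in pep.merged_intervals
                ]
        te_regions = {
            o.te_id: _te_overlap_to_cds_space(
                catalog, gene_id, o.overlap_intervals
            )
            for o in te_by_gene.get(gene_id, [])
        }
        te_regions = {k: v for k, v in te_regions.items() if v}
        overlap_regs = {
            k: v for k, v in overlap_regions.get(gene_id, {}).items() if v
        }
        if len(parents) + len(te_regions) + len(overlap_regs) < 2:
            continue
        report = origins.detect_chimeric(
            gene_id, parents, te_regions, overlap_regs, parent_homology
        )
        if report.is_chimeric:
            pack.chimeric[gene_id] = report
    return pack, extras


def run_synthetic_pipeline(
    config: RunConfig | None = None,
    scenario: SyntheticScenario | None = None,
) -> PipelineResult:
    """Generate (or accept) a scenario and run every stage on it."""
    config = config or RunConfig()
    if scenario is None:
        scenario = generate_scenario(config.scenario or ScenarioConfig())
    thresholds = config.thresholds
    catalog = scenario.catalog
    truth = scenario.truth

    # --- stage 1: LSG calling
    compartments = {g: m.compartment for g, m in catalog.genes.items()}
    records, eliminated = catalog_mod.stepwise_filter(
        sorted(catalog.genes),
        compartments,
        scenario.tier_hits,
        [LINEAGE_TAXON],
        scenario.domain_annotations,
        thresholds,
    )
    logger.info("stage catalog: %d genes in, %d LSGs", len(catalog.genes), len(records))

    # --- stage 2: lineage level via outgroup peptide search
    outgroup_peps = {}
    for name, cds in scenario.outgroup_cds.items():
        from .seqs import translate

        pep = translate(cds)
        pep = pep[:-1] if pep.endswith("*") else pep
        if pep and "*" not in pep:
            outgroup_peps[name] = pep
    lsg_peps = _peptides(catalog, records)
    outgroup_pep_hits = toy_search(
        lsg_peps, outgroup_peps, mode="peptide", seed_word_size=PEP_WORD
    )
    catalog_mod.assign_lineage_level(
        records,
        outgroup_pep_hits,
        {g: len(p) for g, p in lsg_peps.items()},
        thresholds,
    )

    # --- stage 3: within-genome origin classification
    pack, extras = classify_lsg_origins(
        catalog, records, thresholds, scenario.syntelog_pairs, scenario.wgd_pairs
    )

    # --- stage 4: outgroup tracing for species-only LSGs
    species_only = sorted(
        g
        for g, rec in records.items()
        if rec.lineage_level is LineageLevel.SPECIES_ONLY
    )
    so_cds = _cds(catalog, species_only)
    og_cds_hits = toy_search(
        so_cds, scenario.outgroup_cds, mode="nucleotide", seed_word_size=NUC_WORD
    )
    cds_lengths = {g: len(s) for g, s in so_cds.items()}
    og_cds_cov = origins.merge_hits_by_pair(
        og_cds_hits, cds_lengths, thresholds, level="cds"
    )
    for (query_id, subject_id) in sorted(og_cds_cov):
        pack.outgroup_out_of_frame.setdefault(query_id, []).append(
            origins.Evidence("outgroup_cds_hit", subject_id)
        )

    scaffold_hits = toy_search(
        so_cds,
        scenario.outgroup_scaffolds,
        mode="nucleotide",
        seed_word_size=NUC_WORD,
    )
    hits_by_lsg: dict[str, list] = {}
    for hsp in scaffold_hits:
        hits_by_lsg.setdefault(hsp.query_id, []).append(hsp)
    projections: dict[str, outgroup.OrfProjection] = {}
    categories: dict[str, str] = {}
    for gene_id in species_only:
        region = outgroup.chain_scaffold_hits(
            hits_by_lsg.get(gene_id, []), thresholds
        )
        if region is None:
            categories[gene_id] = "NO_HIT"
            continue
        scaffold_seq = scenario.outgroup_scaffolds[region.scaffold]
        lo = max(0, region.start - REGION_BUFFER_BP)
        hi = min(len(scaffold_seq), region.end + REGION_BUFFER_BP)
        region_seq = scaffold_seq[lo:hi]
        if region.orientation is Orientation.INVERTED:
            region_seq = revcomp(region_seq)
        projection = outgroup.project_orf(
            gene_id,
            so_cds[gene_id],
            region_seq,
            thresholds,
            scaffold=region.scaffold,
            region_start=lo,
        )
        if projection is None:
            categories[gene_id] = "NO_HIT"
            continue
        projections[gene_id] = projection
        categories[gene_id] = projection.category.value
        pack.outgroup_intergenic.setdefault(gene_id, []).append(
            origins.Evidence(
                "scaffold_hit", f"{region.scaffold}:{region.start}-{region.end}"
            )
        )
    projection_summary, high_intact = outgroup.classify_projection_set(
        list(projections.values()), thresholds
    )

    # --- stage 4b: RBH + dN/dS between focal genes and outgroup models
    family_ids = sorted(
        g
        for g in catalog.genes
        if truth.lineage.get(g, "conserved") != "species_only"
    )
    focal_peps = _peptides(catalog, family_ids)
    fwd = toy_search(
        focal_peps, outgroup_peps, mode="peptide", seed_word_size=PEP_WORD
    )
    rev = toy_search(
        outgroup_peps, focal_peps, mode="peptide", seed_word_size=PEP_WORD
    )
    rbh_pairs = outgroup.reciprocal_best_hits(fwd, rev)
    from .dnds import compute_dnds

    dnds_results = []
    for focal_id, og_id in rbh_pairs:
        focal_cds = catalog.cds_sequence(focal_id)
        og_seq = scenario.outgroup_cds[og_id]
        if len(focal_cds) != len(og_seq):
            continue  # paralog mispairing; the NG86 input must be codon-aligned
        dnds_results.append(compute_dnds(focal_cds, og_seq, (focal_id, og_id)))
    lsg_flags = {g: g in records for g in catalog.genes}
    dnds_table = outgroup.compare_dnds_groups(dnds_results, lsg_flags)

    # --- rollup
    assignments, rollup = origins.summarize_origins(sorted(records), pack)

    # --- stage 5: polymorphism
    calls, call_matrix = polymorphism.apply_snps_and_call(
        catalog, set(records), scenario.snps
    )
    polymorphism.cross_reference_outgroup(calls, catalog, scenario.snps, projections)
    n_accessions = len({s.accession for s in scenario.snps})
    scenarios = polymorphism.infer_birth_vs_loss(calls, n_accessions, projections)
    support = {g: catalog.genes[g].expression_support for g in records}
    table1 = polymorphism.summarize_polymorphic_lsgs(calls, records, support)

    # --- stage 6: expression
    bundle = scenario.expression
    presence, breadth = expr_mod.collapse_calls(bundle.calls, bundle.sample_tissue)
    lsg_labels = {g: g in records for g in catalog.genes}
    breadth_table = expr_mod.breadth_comparison(breadth, lsg_labels)
    contrasts = []
    for name in sorted(bundle.de_tables):
        up, down = expr_mod.call_de(bundle.de_tables[name], thresholds=thresholds)
        meta = bundle.contrast_meta[name]
        contrasts.append(
            expr_mod.ContrastSets(
                contrast=name,
                tissue=meta["tissue"],
                time_point=meta["time_point"],
                up=up,
                down=down,
                universe=set(bundle.de_tables[name]["gene"]),
            )
        )
    enrichment, enrichment_counts = expr_mod.lsg_stress_enrichment(
        contrasts, lsg_labels, thresholds
    )

    compartments_table = catalog_mod.compartment_summary(
        records,
        {g: m.compartment for g, m in catalog.genes.items()},
        {g: m.chrom for g, m in catalog.genes.items()},
    )
    responsive_lsgs = set()
    for contrast in contrasts:
        responsive_lsgs |= {
            g for g in (contrast.up | contrast.down) if g in records
        }
    responsive_origins = expr_mod.responsive_origin_breakdown(
        responsive_lsgs, assignments
    )

    # --- summary + recovery metrics
    recovery = _recovery_metrics(
        truth, records, assignments, categories, calls
    )
    summary = {
        "n_genes": len(catalog.genes),
        "n_lsg": len(records),
        "n_species_only": len(species_only),
        "thresholds": {
            k: v for k, v in vars(thresholds).items() if not k.startswith("_")
        },
        "origin_rollup": {
            row["mechanism"]: int(row["count"]) for _, row in rollup.iterrows()
        },
        "origin_total": int(rollup["count"].sum()),
        "outgroup_categories": {
            cat: sum(1 for v in categories.values() if v == cat)
            for cat in sorted(set(categories.values()))
        },
        "high_coverage_intact": high_intact,
        "n_disruption_calls": len(calls),
        "birth_loss": {
            k: v.value for k, v in sorted(scenarios.items())
        },
        "enrichment_counts": enrichment_counts,
        "n_enriched_contrast_directions": sum(
            1 for r in enrichment if r.enriched
        ),
        "dnds": {
            row["group"]: {"n": int(row["n"]), "median": row["median"]}
            for _, row in dnds_table.iterrows()
        },
        "recovery": recovery,
    }
    result = PipelineResult(
        records=records,
        eliminated=eliminated,
        assignments=assignments,
        rollup=rollup,
        projections=projections,
        outgroup_categories=categories,
        projection_summary=projection_summary,
        calls=calls,
        call_matrix=call_matrix,
        scenarios=scenarios,
        table1=table1,
        enrichment=enrichment,
        enrichment_counts=enrichment_counts,
        dnds_table=dnds_table,
        compartments_table=compartments_table,
        responsive_origins=responsive_origins,
        summary=summary,
    )
    if config.outdir is not None:
        render_reports(result, scenario, config)
    return result


def _recovery_metrics(truth, records, assignments, categories, calls) -> dict:
    per_class: dict[str, dict] = {}
    for class_name, expected in EXPECTED_PRIMARY.items():
        planted = sorted(
            g for g, label in truth.origin.items() if label == class_name
        )
        if not planted:
            continue
        correct = sum(
            1
            for g in planted
            if g in assignments
            and assignments[g].primary_mechanism is expected
        )
        per_class[class_name] = {
            "planted": len(planted),
            "recovered": correct,
            "rate": round_pct(100.0 * correct / len(planted)),
        }
    og_truth = truth.outgroup_category
    og_total = len(og_truth)
    og_match = sum(
        1 for g, cat in og_truth.items() if categories.get(g) == cat
    )
    called = {(c.gene_id, c.accession, c.snp_type.value) for c in calls}
    planted_calls = {
        (g, a, t) for (g, a), t in truth.disruptions.items()
    }
    lsg_truth = truth.lsg_ids()
    lsg_called = set(records)
    return {
        "origin_classes": per_class,
        "outgroup_category_matches": og_match,
        "outgroup_category_total": og_total,
        "accession_calls_expected": len(planted_calls),
        "accession_calls_made": len(called),
        "accession_false_calls": len(called - planted_calls),
        "accession_missed_calls": len(planted_calls - called),
        "lsg_false_positives": len(lsg_called - lsg_truth),
        "lsg_false_negatives": len(lsg_truth - lsg_called),
    }


def render_reports(
    result: PipelineResult, scenario: SyntheticScenario, config: RunConfig
) -> None:
    """Write TSV/JSON reports (deterministic column and row order)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_path = outdir / "summary.json"
    if summary_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{summary_path} exists; pass overwrite to replace it"
        )
    if config.write_inputs:
        write_scenario(scenario, outdir / "inputs")

    with open(outdir / "lsg_catalog.tsv", "w") as handle:
        handle.write("gene_id\tlineage_level\tcompartment\teliminating_tier\n")
        for gene_id in sorted(scenario.catalog.genes):
            if gene_id in result.records:
                rec = result.records[gene_id]
                handle.write(
                    f"{gene_id}\t{rec.lineage_level.value}\t"
                    f"{rec.compartment.value}\t-\n"
                )
            else:
                handle.write(
                    f"{gene_id}\tnot_lsg\t"
                    f"{scenario.catalog.genes[gene_id].compartment.value}\t"
                    f"{result.eliminated.get(gene_id, '-')}\n"
                )
    with open(outdir / "origin_assignments.tsv", "w") as handle:
        handle.write("gene_id\tprimary_mechanism\tdetails\tevidence\n")
        for gene_id in sorted(result.assignments):
            a = result.assignments[gene_id]
            details = ",".join(sorted(d.value for d in a.mechanism_detail))
            evidence = ",".join(
                f"{e.source}:{e.feature_id}" for e in a.evidence
            )
            handle.write(
                f"{gene_id}\t{a.primary_mechanism.value}\t{details}\t{evidence}\n"
            )
    result.rollup.to_csv(outdir / "origin_rollup.tsv", sep="\t", index=False)
    result.projection_summary.to_csv(
        outdir / "outgroup_projection_summary.tsv", sep="\t", index=False
    )
    result.call_matrix.to_csv(outdir / "disruption_matrix.tsv", sep="\t")
    result.table1.to_csv(outdir / "polymorphic_lsg_summary.tsv", sep="\t", index=False)
    with open(outdir / "enrichment.tsv", "w") as handle:
        handle.write(
            "contrast\ttissue\ttime_point\tdirection\tk\tK\tn\tN\tp_value\tenriched\n"
        )
        for r in result.enrichment:
            handle.write(
                f"{r.contrast}\t{r.tissue}\t{r.time_point}\t{r.direction}\t"
                f"{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.6g}\t{int(r.enriched)}\n"
            )
    result.dnds_table.to_csv(outdir / "dnds_groups.tsv", sep="\t", index=False)
    result.compartments_table.to_csv(
        outdir / "compartment_summary.tsv", sep="\t", index=False
    )
    result.responsive_origins.to_csv(
        outdir / "responsive_lsg_origins.tsv", sep="\t", index=False
    )
    with open(summary_path, "w") as handle:
        json.dump(result.summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
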