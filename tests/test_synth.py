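"""The synthetic generator: determinism, construction echoes, oracles."""

import numpy as np
import pytest

from lsgorigins.model import ValidationError
from lsgorigins.seqs import internal_stop_positions, is_intact_orf, revcomp
from lsgorigins.synth import (
    ScenarioConfig,
    generate_scenario,
    write_scenario,
)


class TestConfig:
    def test_divergence_limit(self):
        with pytest.raises(ValidationError, match="alignability"):
            ScenarioConfig(outgroup_divergence=0.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(n_planted={"mystery": 3})

    def test_capacity_error(self):
        from lsgorigins.synth import CapacityError, generate_genome

        config = ScenarioConfig(target_genome_length=10_000)
        with pytest.raises(CapacityError):
            generate_genome(config, np.random.default_rng(0))


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        config = ScenarioConfig(seed=5)
        for sub in ("a", "b"):
            write_scenario(generate_scenario(config), tmp_path / sub)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name


class TestConstruction:
    def test_ground_truth_counts_reconcile(self, scenario):
        scenario.truth.reconcile(scenario.config)

    def test_all_cds_are_intact_orfs(self, scenario):
        for gene_id in scenario.catalog.genes:
            cds = scenario.catalog.cds_sequence(gene_id)
            assert is_intact_orf(cds), gene_id
            assert internal_stop_positions(cds) == []

    def test_te_exapt_genes_have_exonic_te_overlap(self, scenario):
        from lsgorigins.model import intersect_intervals, interval_union_length

        planted = [
            g for g, label in scenario.truth.origin.items() if label == "te_exapt"
        ]
        assert len(planted) == scenario.config.planted("te_exapt")
        te_by_id = {t.te_id: t for t in scenario.catalog.te_fragments}
        for gene_id in planted:
            te = te_by_id[scenario.truth.te_partner[gene_id]]
            gene = scenario.catalog.genes[gene_id]
            overlap = interval_union_length(
                intersect_intervals(
                    gene.exons, [(te.interval.start, te.interval.end)]
                )
            )
            assert overlap >= 1

    def test_retrocopy_is_single_exon_from_multi_exon_donor(self, scenario):
        for gene_id, label in scenario.truth.origin.items():
            if label != "retrocopy":
                continue
            gene = scenario.catalog.genes[gene_id]
            (donor_id,) = scenario.truth.donors[gene_id]
            donor = scenario.catalog.genes[donor_id]
            assert len(gene.cds_segments) == 1
            assert len(donor.cds_segments) >= 3

    def test_chimera_has_exact_matches_to_both_donors(self, scenario):
        """Each chimera shares a >= 30 bp exact substring with each donor,
        verified by direct substring search in disjoint query regions."""
        catalog = scenario.catalog
        for gene_id, label in scenario.truth.origin.items():
            if label != "chimera":
                continue
            cds = catalog.cds_sequence(gene_id)
            regions = []
            for donor_id in scenario.truth.donors[gene_id]:
                donor_cds = catalog.cds_sequence(donor_id)
                found = None
                for start in range(0, len(cds) - 30):
                    if cds[start : start + 30] in donor_cds:
                        found = (start, start + 30)
                        break
                assert found is not None, (gene_id, donor_id)
                regions.append(found)
            (a, b) = sorted(regions)
            assert a[1] <= b[0], "donor matches must occupy disjoint regions"

    def test_overprint_cds_overlaps_donor_cds(self, scenario):
        from lsgorigins.model import intersect_intervals, interval_union_length

        for gene_id, label in scenario.truth.origin.items():
            if label != "overprint":
                continue
            (donor_id,) = scenario.truth.donors[gene_id]
            gene = scenario.catalog.genes[gene_id]
            donor = scenario.catalog.genes[donor_id]
            assert (
                interval_union_length(
                    intersect_intervals(gene.cds_segments, donor.cds_segments)
                )
                >= 1
            )
            # and both strands still hold intact ORFs
            assert is_intact_orf(scenario.catalog.cds_sequence(donor_id))

    def test_snp_ref_alleles_match_genome(self, scenario):
        for snp in scenario.snps:
            assert scenario.catalog.sequences[snp.chrom][snp.pos] == snp.ref

    def test_msc_outgroup_locus_lacks_start(self, scenario):
        """Planted MSC genes: the outgroup locus no longer starts with ATG."""
        from lsgorigins.synth import SCAFFOLD_NAMES

        checked = 0
        for gene_id, cat in scenario.truth.outgroup_category.items():
            if cat != "MSC" or scenario.truth.origin[gene_id] != "de_novo":
                continue
            gene = scenario.catalog.genes[gene_id]
            scaffold = scenario.outgroup_scaffolds[SCAFFOLD_NAMES[gene.chrom]]
            start, end = gene.cds_segments[0]
            og_cds = scaffold[start:end]
            if gene.strand.value == "-":
                og_cds = revcomp(og_cds)
            assert og_cds[:3] != "ATG"
            assert internal_stop_positions(og_cds) == []
            checked += 1
        assert checked >= 1

    def test_differential_loss_locus_absent_from_outgroup(self, scenario):
        """No chained hit at >= 10% coverage for deleted loci."""
        from lsgorigins.outgroup import chain_scaffold_hits
        from lsgorigins.search import toy_search

        lost = [
            g
            for g, label in scenario.truth.origin.items()
            if label == "differential_loss"
        ]
        for gene_id in lost:
            cds = scenario.catalog.cds_sequence(gene_id)
            hits = toy_search(
                {gene_id: cds},
                scenario.outgroup_scaffolds,
                mode="nucleotide",
                seed_word_size=11,
            )
            assert chain_scaffold_hits(hits) is None

    def test_zero_divergence_no_disruptions_is_identity(self):
        config = ScenarioConfig(
            seed=3,
            outgroup_divergence=0.0,
            n_planted={},
            n_background_genes=20,
            n_mito_genes=0,
            n_chloro_genes=0,
            te_density={},
            n_accessions=2,
        )
        scenario = generate_scenario(config)
        from lsgorigins.synth import SCAFFOLD_NAMES

        for chrom, seq in scenario.catalog.sequences.items():
            assert scenario.outgroup_scaffolds[SCAFFOLD_NAMES[chrom]] == seq


class TestExpressionGeneration:
    def test_breadth_targets_recovered_at_n500(self):
        from lsgorigins.synth import ExpressionConfig, generate_expression_tables
        from lsgorigins.expression import collapse_calls

        labels = {f"l{i}": "lsg_like" for i in range(250)}
        labels.update({f"n{i}": "conserved_like" for i in range(250)})
        bundle, _ = generate_expression_tables(
            labels, ExpressionConfig(), np.random.default_rng(17)
        )
        _, breadth = collapse_calls(bundle.calls, bundle.sample_tissue)
        lsg_median = breadth[[g for g in breadth.index if g.startswith("l")]].median()
        non_median = breadth[[g for g in breadth.index if g.startswith("n")]].median()
        assert abs(lsg_median - 4) <= 1  # within 25% of 4
        assert abs(non_median - 51) <= 51 * 0.25

    def test_expression_values_finite_and_calls_boolean(self, scenario):
        bundle = scenario.expression
        assert np.isfinite(bundle.expression.to_numpy()).all()
        assert bundle.calls.dtypes.map(lambda d: d == bool).all()

    def test_replicate_requirement(self):
        from lsgorigins.synth import ExpressionConfig, generate_expression_tables

        with pytest.raises(ValidationError):
            generate_expression_tables(
                {"g": "lsg_like"},
                ExpressionConfig(n_replicates=1),
                np.random.default_rng(0),
            )
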