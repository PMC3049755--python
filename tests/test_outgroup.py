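"""Scaffold chaining, ORF projection categories, RBH and distant scans."""

import numpy as np
import pytest

from lsgorigins.model import HSP, Orientation, ValidationError
from lsgorigins.outgroup import (
    DistantSpeciesData,
    OrfCategory,
    chain_scaffold_hits,
    classify_projection_set,
    compare_dnds_groups,
    project_orf,
    reciprocal_best_hits,
    scan_distant_genomes,
)
from lsgorigins.dnds import DndsResult
from lsgorigins.synth import NON_STOP_CODONS


def hit(s_start, s_end, score=100.0, scaffold="sc1", evalue=1e-20,
        orientation=Orientation.FORWARD, q_start=0, q_end=None):
    span = s_end - s_start
    q_end = q_end if q_end is not None else q_start + span
    return HSP(
        query_id="lsg",
        subject_id=scaffold,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        orientation=orientation,
        percent_identity=95.0,
        score=score,
        e_value=evalue,
        n_columns=span,
    )


class TestChaining:
    def test_hits_within_4kb_concatenate(self):
        region = chain_scaffold_hits([hit(1000, 1400), hit(5000, 5300, score=90)])
        assert (region.start, region.end) == (1000, 5300)

    def test_gap_over_4kb_splits_and_top_cluster_wins(self):
        region = chain_scaffold_hits(
            [hit(1000, 1400, score=50), hit(5501, 5800, score=200)]
        )
        assert (region.start, region.end) == (5501, 5800)

    def test_single_hit_region_equals_span(self):
        region = chain_scaffold_hits([hit(700, 950)])
        assert (region.start, region.end) == (700, 950)

    def test_only_top_hit_scaffold_considered(self):
        hits = [hit(0, 300, score=300), hit(100, 400, score=50, scaffold="sc2")]
        region = chain_scaffold_hits(hits)
        assert region.scaffold == "sc1"

    def test_no_qualifying_hits_returns_none(self):
        assert chain_scaffold_hits([]) is None
        assert chain_scaffold_hits([hit(0, 300, evalue=0.5)]) is None

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        hits = [
            hit(int(s), int(s) + 200, score=float(rng.integers(40, 300)))
            for s in rng.integers(0, 30000, 12)
        ]
        baseline = chain_scaffold_hits(hits)
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            region = chain_scaffold_hits(perm)
            assert (region.start, region.end) == (baseline.start, baseline.end)


def random_cds(rng, n_codons=100):
    body = "".join(rng.choice(NON_STOP_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


class TestProjectOrf:
    rng = np.random.default_rng(9)
    cds = random_cds(rng)

    def test_identity_is_intact_full_coverage(self):
        proj = project_orf("lsg", self.cds, self.cds)
        assert proj.category is OrfCategory.INTACT
        assert proj.coverage_pct == pytest.approx(100.0)
        assert proj.internal_stop_count == 0
        assert proj.frameshift_indel_count == 0

    def test_start_codon_mutation_is_msc(self):
        region = "ATA" + self.cds[3:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.category is OrfCategory.MSC
        assert not proj.start_codon_present

    def test_internal_stop_is_isc(self):
        region = self.cds[:150] + "TGA" + self.cds[153:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.category is OrfCategory.ISC_OR_INDEL
        assert proj.internal_stop_count == 1
        assert 150 in proj.disruption_positions

    def test_one_bp_deletion_is_frameshift(self):
        region = self.cds[:150] + self.cds[151:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.category is OrfCategory.ISC_OR_INDEL
        assert proj.frameshift_indel_count == 1

    def test_three_bp_deletion_is_not_frameshift(self):
        region = self.cds[:150] + self.cds[153:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.frameshift_indel_count == 0

    def test_msc_plus_stop_is_both(self):
        region = "ATA" + self.cds[3:150] + "TGA" + self.cds[153:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.category is OrfCategory.BOTH

    def test_insertion_pushes_coverage_over_100(self):
        cds = self.cds[:300]
        insert = "GCA" * 10
        region = cds[:150] + insert + cds[150:]
        proj = project_orf("lsg", cds, region)
        assert proj.coverage_pct == pytest.approx(110.0)

    def test_flanked_region_still_full_coverage(self):
        rng = np.random.default_rng(10)
        flank5 = "".join(rng.choice(list("ACGT"), 80))
        flank3 = "".join(rng.choice(list("ACGT"), 80))
        proj = project_orf("lsg", self.cds, flank5 + self.cds + flank3)
        assert proj.category is OrfCategory.INTACT
        assert proj.coverage_pct == pytest.approx(100.0)

    def test_partial_region_flags_start_not_covered(self):
        region = self.cds[90:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.start_not_covered
        assert proj.category in (OrfCategory.INTACT, OrfCategory.ISC_OR_INDEL)

    def test_low_coverage_discarded_and_tiny_region_rejected(self):
        assert project_orf("lsg", self.cds, self.cds[:20]) is None
        with pytest.raises(ValidationError):
            project_orf("lsg", self.cds, "AT")

    def test_aligned_base_map_reports_outgroup_state(self):
        region = self.cds[:150] + "TGA" + self.cds[153:]
        proj = project_orf("lsg", self.cds, region)
        assert proj.aligned_region_base[150] == "T"
        assert proj.aligned_region_base[0] == self.cds[0]


class TestProjectionSummary:
    def _proj(self, category, coverage):
        kwargs = dict(
            lsg_id="x",
            scaffold="sc",
            region_start=0,
            region_end=100,
            coverage_pct=coverage,
            start_codon_present=category in (OrfCategory.INTACT, OrfCategory.ISC_OR_INDEL),
            start_not_covered=False,
            internal_stop_count=0
            if category in (OrfCategory.INTACT, OrfCategory.MSC)
            else 1,
            frameshift_indel_count=0,
        )
        from lsgorigins.outgroup import OrfProjection

        return OrfProjection(category=category, **kwargs)

    def test_category_shares_and_median(self):
        projections = [
            self._proj(OrfCategory.MSC, 10.0),
            self._proj(OrfCategory.MSC, 41.07),
            self._proj(OrfCategory.MSC, 90.0),
            self._proj(OrfCategory.INTACT, 96.0),
            self._proj(OrfCategory.BOTH, 50.0),
        ]
        table, high = classify_projection_set(projections)
        msc = table.set_index("category").loc["MSC"]
        assert msc["share_pct"] == 60.0
        assert msc["coverage_median"] == pytest.approx(41.07)
        assert high == ["x"]  # the single INTACT projection at >= 95%

    def test_empty_input(self):
        table, high = classify_projection_set([])
        assert high == [] and (table["count"] == 0).all()


def pep_hit(query, subject, evalue, score=100.0):
    return HSP(
        query_id=query,
        subject_id=subject,
        q_start=0,
        q_end=50,
        s_start=0,
        s_end=50,
        orientation=Orientation.FORWARD,
        percent_identity=80.0,
        score=score,
        e_value=evalue,
        n_columns=50,
    )


class TestRbh:
    def test_mutual_top_hits_pair(self):
        fwd = [pep_hit("a", "b", 1e-50), pep_hit("a", "c", 1e-10)]
        rev = [pep_hit("b", "a", 1e-50)]
        assert reciprocal_best_hits(fwd, rev) == [("a", "b")]

    def test_non_mutual_top_hit_excluded(self):
        fwd = [pep_hit("a", "b", 1e-50)]
        rev = [pep_hit("b", "c", 1e-60), pep_hit("b", "a", 1e-10)]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_synthetic_ortholog_recovery(self, scenario):
        """Nearly every conserved gene pairs with its own outgroup model."""
        from lsgorigins.pipeline import _peptides
        from lsgorigins.search import toy_search
        from lsgorigins.seqs import translate

        catalog = scenario.catalog
        conserved = sorted(
            g for g, lvl in scenario.truth.lineage.items() if lvl == "conserved"
        )[:40]
        focal = _peptides(catalog, conserved)
        og_peps = {}
        for name, cds in scenario.outgroup_cds.items():
            pep = translate(cds)
            og_peps[name] = pep[:-1] if pep.endswith("*") else pep
        fwd = toy_search(focal, og_peps, mode="peptide", seed_word_size=4)
        rev = toy_search(og_peps, focal, mode="peptide", seed_word_size=4)
        pairs = reciprocal_best_hits(fwd, rev)
        matched = sum(1 for a, b in pairs if b == f"og_{a}")
        assert matched >= 0.99 * len(conserved)


class TestDistantScan:
    def _setup(self):
        rng = np.random.default_rng(21)
        lsg_cds = random_cds(rng, 120)
        scaffold = (
            "".join(rng.choice(list("ACGT"), 5000))
            + lsg_cds
            + "".join(rng.choice(list("ACGT"), 5000))
        )
        return lsg_cds, scaffold

    def test_genomic_hit_with_reciprocity_is_distant_intergenic(self):
        lsg_cds, scaffold = self._setup()
        genomic_hit = HSP(
            query_id="lsg",
            subject_id="dscaf",
            q_start=0,
            q_end=len(lsg_cds),
            s_start=5000,
            s_end=5000 + len(lsg_cds),
            orientation=Orientation.FORWARD,
            percent_identity=95.0,
            score=400.0,
            e_value=1e-40,
            n_columns=len(lsg_cds),
        )
        data = DistantSpeciesData(
            genomic_hits=[genomic_hit], genome_seqs={"dscaf": scaffold}
        )
        results = scan_distant_genomes(
            {"lsg": lsg_cds}, {"papaya": data}, {"lsg": lsg_cds}
        )
        (res,) = results
        assert res.evidence == "distant_intergenic"
        assert res.segment == (4900, 5460)  # hit span plus 100 bp flanks

    def test_reciprocity_failure_gives_none(self):
        lsg_cds, scaffold = self._setup()
        rng = np.random.default_rng(22)
        other = random_cds(rng, 120)
        genomic_hit = HSP(
            query_id="lsg",
            subject_id="dscaf",
            q_start=0,
            q_end=len(lsg_cds),
            s_start=5000,
            s_end=5000 + len(lsg_cds),
            orientation=Orientation.FORWARD,
            percent_identity=95.0,
            score=400.0,
            e_value=1e-40,
            n_columns=len(lsg_cds),
        )
        data = DistantSpeciesData(
            genomic_hits=[genomic_hit], genome_seqs={"dscaf": scaffold}
        )
        # focal database holds another gene whose sequence IS the segment,
        # so the reciprocal best hit lands elsewhere
        results = scan_distant_genomes(
            {"lsg": other}, {"papaya": data}, {"lsg": other, "decoy": lsg_cds}
        )
        (res,) = results
        assert res.evidence == "none"

    def test_transcript_hit_with_reciprocity_is_distant_cds(self):
        lsg_cds, _ = self._setup()
        cds_hit = HSP(
            query_id="lsg",
            subject_id="dtx1",
            q_start=0,
            q_end=len(lsg_cds),
            s_start=0,
            s_end=len(lsg_cds),
            orientation=Orientation.FORWARD,
            percent_identity=95.0,
            score=400.0,
            e_value=1e-40,
            n_columns=len(lsg_cds),
        )
        data = DistantSpeciesData(
            cds_hits=[cds_hit], cds_seqs={"dtx1": lsg_cds}
        )
        results = scan_distant_genomes(
            {"lsg": lsg_cds}, {"grape": data}, {"lsg": lsg_cds}
        )
        assert results[0].evidence == "distant_cds"


class TestCompareGroups:
    def _result(self, gene, ratio):
        return DndsResult(
            pair=(gene, f"og_{gene}"),
            n_codons=100,
            N_sites=230.0,
            S_sites=70.0,
            Nd=5.0,
            Sd=5.0,
            dN=0.02,
            dS=0.07,
            ratio=ratio,
        )

    def test_group_medians(self):
        results = [
            self._result("l1", 0.2),
            self._result("l2", 0.5598),
            self._result("l3", 0.9),
            self._result("n1", 0.1772),
        ]
        labels = {"l1": True, "l2": True, "l3": True, "n1": False}
        table = compare_dnds_groups(results, labels).set_index("group")
        assert table.loc["LSG", "median"] == pytest.approx(0.5598)
        assert table.loc["non-LSG", "siqr"] == 0.0

    def test_empty_group_is_missing(self):
        table = compare_dnds_groups([], {}).set_index("group")
        assert table.loc["LSG", "median"] is None or np.isnan(
            table.loc["LSG", "median"]
        )
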