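"""Origin classifiers: HSP merging, frame/orientation, mechanisms,
context, TE exaptation, chimerism, enrichment and the rollup."""

import math

import numpy as np
import pytest

from lsgorigins.io import GenomeCatalog
from lsgorigins.model import (
    GeneModel,
    GenomicInterval,
    HSP,
    Orientation,
    Strand,
    TeFragment,
    ThresholdConfig,
    ValidationError,
)
from lsgorigins.origins import (
    DuplicationContext,
    DuplicationMechanism,
    Mechanism,
    MechanismDetail,
    MergedCoverage,
    OriginEvidencePack,
    classify_duplication_context,
    classify_duplication_mechanism,
    detect_chimeric,
    detect_orientation,
    detect_out_of_frame,
    detect_te_exaptation,
    find_overlapping_cds,
    hypergeometric_enrichment,
    merge_hsps,
    origin_rollup_from_counts,
    summarize_origins,
)


def cds_hsp(q_start, q_end, s_start, s_end, orientation=Orientation.FORWARD,
            n_columns=None, query="lsg", subject="parent", evalue=1e-20):
    return HSP(
        query_id=query,
        subject_id=subject,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        orientation=orientation,
        percent_identity=90.0,
        score=100.0,
        e_value=evalue,
        n_columns=n_columns or max(q_end - q_start, s_end - s_start),
    )


class TestMergeHsps:
    def test_overlapping_union(self):
        merged = merge_hsps(
            [cds_hsp(0, 40, 0, 40), cds_hsp(30, 60, 100, 130)], 100
        )
        assert merged.coverage_pct == pytest.approx(60.0)
        assert merged.merged_intervals == [(0, 60)]

    def test_below_ten_percent_discarded(self):
        assert merge_hsps([cds_hsp(0, 9, 0, 9)], 100) is None
        assert merge_hsps([cds_hsp(0, 10, 0, 10)], 100) is not None

    def test_full_length_hit(self):
        merged = merge_hsps([cds_hsp(0, 100, 0, 100)], 100)
        assert merged.coverage_pct == pytest.approx(100.0)

    def test_gap_columns_can_exceed_query_length(self):
        merged = merge_hsps([cds_hsp(0, 100, 0, 130, n_columns=130)], 100)
        assert merged.coverage_pct == pytest.approx(130.0)

    def test_hsp_beyond_query_length_rejected(self):
        with pytest.raises(ValidationError):
            merge_hsps([cds_hsp(0, 120, 0, 120)], 100)

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            qlen = int(rng.integers(50, 400))
            hsps = []
            for _ in range(int(rng.integers(1, 8))):
                start = int(rng.integers(0, qlen - 1))
                end = start + int(rng.integers(1, qlen - start))
                hsps.append(cds_hsp(start, end, start, end))
            covered = set()
            for h in hsps:
                covered.update(range(h.q_start, h.q_end))
            expected = 100.0 * len(covered) / qlen
            merged = merge_hsps(hsps, qlen, ThresholdConfig())
            if expected < 10.0:
                assert merged is None
            else:
                assert merged.coverage_pct == pytest.approx(expected)

    def test_raising_threshold_never_retains_more(self):
        rng = np.random.default_rng(12)
        kept = []
        hsps_sets = []
        for _ in range(100):
            start = int(rng.integers(0, 80))
            end = start + int(rng.integers(5, 60))
            hsps_sets.append([cds_hsp(start, min(end, 100), start, min(end, 100))])
        for pct in (5.0, 20.0, 40.0, 60.0):
            thresholds = ThresholdConfig(min_query_coverage_pct=pct)
            kept.append(
                sum(1 for h in hsps_sets if merge_hsps(h, 100, thresholds))
            )
        assert kept == sorted(kept, reverse=True)


class TestFrameAndOrientation:
    def _cov(self, intervals, pct, level="peptide"):
        return MergedCoverage("lsg", "parent", intervals, pct, level)

    def test_equal_coverage_is_in_frame(self):
        report = detect_out_of_frame(
            self._cov([(0, 74)], 74.40), self._cov([(0, 223)], 74.40, "cds")
        )
        assert report.in_frame and report.out_of_frame_intervals == []

    def test_cds_only_pair_is_fully_out_of_frame(self):
        report = detect_out_of_frame(None, self._cov([(0, 80)], 26.45, "cds"))
        assert not report.in_frame
        assert report.out_of_frame_intervals == [(0, 80)]

    def test_out_of_frame_segments_by_subtraction(self):
        report = detect_out_of_frame(
            self._cov([(0, 30)], 30.0),
            self._cov([(0, 90), (300, 450)], 80.0, "cds"),
        )
        assert report.out_of_frame_intervals == [(300, 450)]

    def test_orientation_dominance(self):
        assert (
            detect_orientation([cds_hsp(0, 40, 0, 40, Orientation.INVERTED)])
            is Orientation.INVERTED
        )
        mixed = [
            cds_hsp(0, 300, 0, 300, Orientation.FORWARD),
            cds_hsp(10, 50, 400, 440, Orientation.INVERTED),
        ]
        assert detect_orientation(mixed) is Orientation.FORWARD


def make_model(gene_id, cds_segments, chrom="c1", strand=Strand.PLUS):
    return GeneModel(
        gene_id=gene_id,
        representative_model_id=f"{gene_id}.1",
        chrom=chrom,
        strand=strand,
        exons=list(cds_segments),
        cds_segments=list(cds_segments),
    )


class TestDuplicationMechanism:
    subject = make_model("parent", [(0, 90), (150, 240)])  # tx boundary at 90

    def test_matching_boundaries_mean_unequal_crossing_over(self):
        lsg = make_model("lsg", [(1000, 1088), (1150, 1242)])  # boundary at 88
        mech = classify_duplication_mechanism(
            lsg, self.subject, [cds_hsp(0, 180, 0, 180)]
        )
        assert mech is DuplicationMechanism.UNEQUAL_CROSSING_OVER

    def test_boundary_tolerance_is_inclusive_at_five(self):
        lsg5 = make_model("lsg", [(1000, 1085), (1150, 1245)])  # boundary at 85
        lsg6 = make_model("lsg", [(1000, 1084), (1150, 1246)])  # boundary at 84
        hsps = [cds_hsp(0, 180, 0, 180)]
        assert (
            classify_duplication_mechanism(lsg5, self.subject, hsps)
            is DuplicationMechanism.UNEQUAL_CROSSING_OVER
        )
        assert (
            classify_duplication_mechanism(lsg6, self.subject, hsps)
            is not DuplicationMechanism.UNEQUAL_CROSSING_OVER
        )

    def test_intronless_lsg_over_subject_boundary_is_retrotransposition(self):
        lsg = make_model("lsg", [(1000, 1180)])
        mech = classify_duplication_mechanism(
            lsg, self.subject, [cds_hsp(0, 180, 0, 180)]
        )
        assert mech is DuplicationMechanism.RETROTRANSPOSITION

    def test_alignment_inside_one_exon_is_indeterminate(self):
        lsg = make_model("lsg", [(1000, 1080)])
        mech = classify_duplication_mechanism(
            lsg, self.subject, [cds_hsp(0, 80, 0, 80)]
        )
        assert mech is DuplicationMechanism.INDETERMINATE


class TestDuplicationContext:
    def _catalog(self):
        genes = {}
        for i in range(30):
            genes[f"a{i:02d}"] = make_model(f"a{i:02d}", [(i * 1000, i * 1000 + 300)])
        genes["b0"] = make_model("b0", [(0, 300)], chrom="c2")
        return GenomeCatalog(genes=genes, sequences={})

    def test_adjacent_pair_is_tandem(self):
        out = classify_duplication_context([("a00", "a01")], self._catalog())
        assert out[("a00", "a01")] == (DuplicationContext.TANDEM, False)

    def test_cross_chromosome_pair_is_distal(self):
        out = classify_duplication_context([("a00", "b0")], self._catalog())
        assert out[("a00", "b0")] == (DuplicationContext.DISTAL, False)

    def test_far_same_chromosome_pair_is_distal(self):
        out = classify_duplication_context([("a00", "a29")], self._catalog())
        assert out[("a00", "a29")][0] is DuplicationContext.DISTAL

    def test_syntelog_table_wins_and_wgd_flag(self):
        pair = frozenset(("a00", "a29"))
        out = classify_duplication_context(
            [("a00", "a29")], self._catalog(), {pair}, {pair}
        )
        assert out[("a00", "a29")] == (DuplicationContext.SYNTELOG, True)


class TestOverlapAndTe:
    def _catalog(self):
        genes = {
            "g1": make_model("g1", [(100, 200)]),
            "g2": make_model("g2", [(150, 260)], strand=Strand.MINUS),
            "g3": make_model("g3", [(1000, 1100)]),
            # exons larger than CDS: intron between CDS pieces
            "g4": GeneModel(
                gene_id="g4",
                representative_model_id="g4.1",
                chrom="c1",
                strand=Strand.PLUS,
                exons=[(2000, 2100), (2400, 2500)],
                cds_segments=[(2000, 2100), (2400, 2500)],
            ),
        }
        tes = [
            TeFragment("te1", GenomicInterval("c1", 150, 250), "RC/Helitron"),
            TeFragment("te2", GenomicInterval("c1", 2150, 2350), "DNA/MuDR"),
        ]
        return GenomeCatalog(genes=genes, te_fragments=tes, sequences={})

    def test_cds_overlap_pair_reported_any_strand(self):
        pairs = find_overlapping_cds(self._catalog(), {"g1"})
        assert len(pairs) == 1
        (pair,) = pairs
        assert {pair.gene_a, pair.gene_b} == {"g1", "g2"}
        assert pair.overlap_bp == 50
        assert pair.pair_type == "LSG:nonLSG"

    def test_exonic_te_overlap_flags_gene(self):
        overlaps, tally = detect_te_exaptation(self._catalog(), {"g1"})
        by_gene = {o.gene_id: o for o in overlaps}
        assert by_gene["g1"].overlap_bp == 50
        assert "g4" not in by_gene  # te2 is wholly intronic
        helitron = tally.set_index("superfamily").loc["RC/Helitron"]
        assert helitron["lsg_fragments"] == 1

    def test_intronic_te_counts_at_no_level_but_flanking_cds_does(self):
        catalog = self._catalog()
        overlaps, _ = detect_te_exaptation(catalog, set(), level="cds")
        assert all(o.gene_id != "g4" for o in overlaps)


class TestChimeric:
    def test_disjoint_unrelated_parents(self):
        report = detect_chimeric(
            "lsg",
            {"A": [(0, 100)], "B": [(150, 300)]},
            parent_homology=set(),
        )
        assert report.is_chimeric
        assert report.parents == ["A", "B"]
        assert report.composition == "multi_parent"

    def test_same_region_not_chimeric(self):
        report = detect_chimeric("lsg", {"A": [(0, 100)], "B": [(0, 100)]})
        assert not report.is_chimeric

    def test_homologous_parents_not_chimeric(self):
        report = detect_chimeric(
            "lsg",
            {"A": [(0, 100)], "B": [(150, 300)]},
            parent_homology={frozenset(("A", "B"))},
        )
        assert not report.is_chimeric

    def test_parent_plus_te(self):
        report = detect_chimeric(
            "lsg", {"A": [(0, 60)]}, te_overlaps={"te9": [(200, 300)]}
        )
        assert report.is_chimeric and report.composition == "parent_te"

    def test_ten_percent_mutual_overlap_boundary(self):
        # shorter region 100 long; overlap 10 == 10% allowed, 11 not
        ok = detect_chimeric("lsg", {"A": [(0, 100)], "B": [(90, 290)]})
        too_much = detect_chimeric("lsg", {"A": [(0, 100)], "B": [(89, 289)]})
        assert ok.is_chimeric and not too_much.is_chimeric


class TestHypergeometric:
    def test_exact_small_case(self):
        assert hypergeometric_enrichment(3, 4, 5, 10) == pytest.approx(66 / 252)

    def test_zero_upper_is_one(self):
        assert hypergeometric_enrichment(0, 4, 5, 10) == 1.0

    def test_te_overlap_counts_are_enriched(self):
        assert hypergeometric_enrichment(171, 1337, 1761, 26995) < 0.01

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(6, 4, 5, 10)

    def test_lower_tail_complements_upper(self):
        for k in range(5):
            lower = hypergeometric_enrichment(k, 4, 5, 10, tail="lower")
            upper = hypergeometric_enrichment(k + 1, 4, 5, 10, tail="upper") if k < 4 else 0.0
            assert lower + upper == pytest.approx(1.0)

    def test_matches_enumeration(self):
        for N, K, n in [(10, 4, 5), (12, 6, 3), (20, 7, 9), (25, 10, 12)]:
            for k in range(min(K, n) + 1):
                expected = sum(
                    math.comb(K, i) * math.comb(N - K, n - i)
                    for i in range(k, min(K, n) + 1)
                ) / math.comb(N, n)
                assert hypergeometric_enrichment(k, K, n, N) == pytest.approx(
                    expected, rel=1e-9
                )


class TestRollup:
    def test_precedence_and_conservation(self):
        pack = OriginEvidencePack()
        pack.chimeric["g1"] = detect_chimeric(
            "g1", {"A": [(0, 50)], "B": [(100, 200)]}
        )
        pack.duplication["g1"] = [None]
        pack.duplication["g2"] = [None]
        pack.duplication_detail["g2"] = {MechanismDetail.IN_FRAME}
        pack.te_exaptation["g2"] = [None]
        assignments, table = summarize_origins(["g1", "g2", "g3"], pack)
        assert assignments["g1"].primary_mechanism is Mechanism.CHIMERIC
        assert assignments["g2"].primary_mechanism is Mechanism.DUPLICATION
        assert assignments["g2"].mechanism_detail == {MechanismDetail.IN_FRAME}
        assert assignments["g3"].primary_mechanism is Mechanism.UNKNOWN
        assert table["count"].sum() == 3

    def test_duplication_share_from_printed_counts(self):
        table = origin_rollup_from_counts({"duplication": 225 + 173}, 1789)
        assert table.loc[0, "share_pct"] == 22.25

    def test_overlap_pair_types_partition_members(self):
        genes = {
            "l1": make_model("l1", [(0, 100)]),
            "n1": make_model("n1", [(50, 160)]),
            "l2": make_model("l2", [(1000, 1100)]),
            "l3": make_model("l3", [(1050, 1150)]),
            "n2": make_model("n2", [(2000, 2100)]),
            "n3": make_model("n3", [(2050, 2150)]),
            "solo": make_model("solo", [(5000, 5100)]),
        }
        catalog = GenomeCatalog(genes=genes, sequences={})
        pairs = find_overlapping_cds(catalog, {"l1", "l2", "l3"})
        by_type = {}
        members = set()
        for p in pairs:
            by_type[p.pair_type] = by_type.get(p.pair_type, 0) + 1
            members |= {p.gene_a, p.gene_b}
        assert by_type == {"LSG:nonLSG": 1, "LSG:LSG": 1, "nonLSG:nonLSG": 1}
        assert len(members) == 6 and "solo" not in members
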