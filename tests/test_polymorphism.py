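"""Accession ISC/MSC calling, outgroup cross-referencing and parsimony."""

import numpy as np
import pandas as pd
import pytest

from lsgorigins.catalog import LineageLevel, LsgRecord
from lsgorigins.io import GenomeCatalog
from lsgorigins.model import (
    Compartment,
    ExpressionSupport,
    GeneModel,
    Strand,
    ValidationError,
)
from lsgorigins.outgroup import project_orf
from lsgorigins.polymorphism import (
    BirthLossScenario,
    OutgroupStatus,
    Snp,
    SnpType,
    apply_snps_and_call,
    cross_reference_outgroup,
    infer_birth_vs_loss,
    read_snp_table,
    summarize_polymorphic_lsgs,
)
from lsgorigins.synth import NON_STOP_CODONS


def build_catalog(strand=Strand.PLUS):
    rng = np.random.default_rng(33)
    body = "".join(rng.choice(NON_STOP_CODONS, size=78))
    cds = "ATG" + body + "TAA"  # 80 codons
    assert cds[117:120] not in ("TAA", "TAG", "TGA")
    # force codon 40 (offset 117..120) to TGG so a G->A SNP creates TGA
    cds = cds[:117] + "TGG" + cds[120:]
    # force codon 10 to AAA so AAA->AAG stays synonymous
    cds = cds[:27] + "AAA" + cds[30:]
    from lsgorigins.seqs import revcomp

    chrom = "chr1"
    flank5, flank3 = "GGTT" * 25, "CCAA" * 25
    if strand is Strand.PLUS:
        seq = flank5 + cds + flank3
        interval = (100, 100 + len(cds))
    else:
        seq = flank5 + revcomp(cds) + flank3
        interval = (100, 100 + len(cds))
    gene = GeneModel(
        gene_id="lsg1",
        representative_model_id="lsg1.1",
        chrom=chrom,
        strand=strand,
        exons=[interval],
        cds_segments=[interval],
    )
    return GenomeCatalog(genes={"lsg1": gene}, sequences={chrom: seq}), cds


class TestApplySnps:
    def test_stop_creating_snp_called_isc(self):
        catalog, cds = build_catalog()
        # codon 40 TGG: genomic offset of its third base = 100 + 119
        snp = Snp("Bur-0", "chr1", 100 + 119, "G", "A")
        calls, matrix = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        (call,) = calls
        assert call.snp_type is SnpType.ISC
        assert call.codon_index == 40
        assert matrix.loc["lsg1", "Bur-0"] == "ISC"

    def test_start_loss_called_msc(self):
        catalog, _ = build_catalog()
        snp = Snp("Cvi-0", "chr1", 100, "A", "G")
        calls, matrix = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        (call,) = calls
        assert call.snp_type is SnpType.MSC and call.codon_index == 1
        assert matrix.loc["lsg1", "Cvi-0"] == "MSC"

    def test_minus_strand_allele_complemented(self):
        catalog, cds = build_catalog(strand=Strand.MINUS)
        # codon 40 third base is at CDS offset 119; on the minus strand that
        # sits at genomic 100 + (len(cds) - 1 - 119), and the disrupting
        # genomic allele is the complement (G->A becomes C->T)
        pos = 100 + (len(cds) - 1 - 119)
        snp = Snp("Bay-0", "chr1", pos, "C", "T")
        calls, _ = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        (call,) = calls
        assert call.snp_type is SnpType.ISC and call.codon_index == 40

    def test_synonymous_snp_no_call(self):
        catalog, _ = build_catalog()
        # codon 10 AAA, third base at offset 29: A->G is Lys->Lys
        snp = Snp("Ler-1", "chr1", 100 + 29, "A", "G")
        calls, matrix = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        assert calls == []
        assert matrix.loc["lsg1", "Ler-1"] == "ref"

    def test_terminal_codon_stop_not_internal(self):
        catalog, cds = build_catalog()
        # mutating within the terminal stop codon never yields an ISC call
        pos = 100 + len(cds) - 2
        ref = catalog.sequences["chr1"][pos]
        alt = "A" if ref != "A" else "G"
        calls, _ = apply_snps_and_call(
            catalog, {"lsg1"}, [Snp("x", "chr1", pos, ref, alt)]
        )
        assert all(c.snp_type is not SnpType.ISC or c.codon_index < 80 for c in calls)

    def test_missing_data_marked_not_called(self):
        catalog, _ = build_catalog()
        snp = Snp("Kas-1", "chr1", 100 + 119, "G", "N")
        calls, matrix = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        assert calls == []
        assert matrix.loc["lsg1", "Kas-1"] == "missing"

    def test_ref_mismatch_rejected(self):
        catalog, _ = build_catalog()
        with pytest.raises(ValidationError, match="ref mismatch"):
            apply_snps_and_call(
                catalog, {"lsg1"}, [Snp("x", "chr1", 100, "C", "T")]
            )

    def test_row_order_invariance(self):
        catalog, _ = build_catalog()
        snps = [
            Snp("a1", "chr1", 100 + 119, "G", "A"),
            Snp("a2", "chr1", 100, "A", "G"),
            Snp("a3", "chr1", 100 + 29, "A", "G"),
        ]
        calls_fwd, _ = apply_snps_and_call(catalog, {"lsg1"}, snps)
        calls_rev, _ = apply_snps_and_call(catalog, {"lsg1"}, snps[::-1])
        key = lambda c: (c.gene_id, c.accession, c.snp_type.value, c.pos)
        assert sorted(map(key, calls_fwd)) == sorted(map(key, calls_rev))

    def test_indel_alleles_rejected_at_read(self):
        table = pd.DataFrame(
            [{"accession": "a", "chrom": "chr1", "pos": 5, "ref": "AT", "alt": "A"}]
        )
        with pytest.raises(ValidationError, match="substitution"):
            read_snp_table(table)


class TestCrossReference:
    def _setup(self, outgroup_base):
        catalog, cds = build_catalog()
        snp = Snp("Bur-0", "chr1", 100 + 119, "G", "A")
        calls, _ = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        region = cds[:119] + outgroup_base + cds[120:]
        projection = project_orf("lsg1", cds, region)
        cross_reference_outgroup(calls, catalog, [snp], {"lsg1": projection})
        return calls[0], projection

    def test_conserved_disrupting_allele(self):
        call, _ = self._setup("A")  # outgroup also carries TGA
        assert call.outgroup_status is OutgroupStatus.CONSERVED_SNP

    def test_not_disrupted(self):
        call, _ = self._setup("G")  # outgroup keeps TGG
        assert call.outgroup_status is OutgroupStatus.NOT_DISRUPTED

    def test_deletion_at_site(self):
        catalog, cds = build_catalog()
        # give the polymorphic codon an unambiguous context (TAC GGG) so a
        # single-base deletion at the site cannot slide in the alignment
        chrom = catalog.sequences["chr1"]
        cds = cds[:117] + "TACGGG" + cds[123:]
        catalog.sequences["chr1"] = chrom[:100] + cds + chrom[100 + len(cds):]
        snp = Snp("Bur-0", "chr1", 100 + 119, "C", "A")  # TAC -> TAA
        calls, _ = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        region = cds[:119] + cds[120:]  # 1-bp deletion at the site
        projection = project_orf("lsg1", cds, region)
        cross_reference_outgroup(calls, catalog, [snp], {"lsg1": projection})
        assert calls[0].outgroup_status is OutgroupStatus.DELETION

    def test_no_alignment_not_covered(self):
        catalog, cds = build_catalog()
        snp = Snp("Bur-0", "chr1", 100 + 119, "G", "A")
        calls, _ = apply_snps_and_call(catalog, {"lsg1"}, [snp])
        cross_reference_outgroup(calls, catalog, [snp], {})
        assert calls[0].outgroup_status is OutgroupStatus.NOT_COVERED


class TestBirthVsLoss:
    def _call(self, status, accession="a1"):
        from lsgorigins.polymorphism import DisruptionCall

        call = DisruptionCall("g", accession, SnpType.ISC, "chr1", 50, 10)
        call.outgroup_status = status
        return call

    def _intact_projection(self):
        rng = np.random.default_rng(40)
        cds = "ATG" + "".join(rng.choice(NON_STOP_CODONS, 60)) + "TAA"
        return project_orf("g", cds, cds)

    def test_conserved_disruption_is_birth(self):
        calls = [self._call(OutgroupStatus.CONSERVED_SNP, f"a{i}") for i in range(18)]
        out = infer_birth_vs_loss(calls, 19, {})
        assert out["g"] is BirthLossScenario.BIRTH_IN_FOCAL

    def test_rare_derived_disruption_with_intact_outgroup_is_loss(self):
        calls = [self._call(OutgroupStatus.NOT_DISRUPTED, f"a{i}") for i in range(4)]
        out = infer_birth_vs_loss(calls, 19, {"g": self._intact_projection()})
        assert out["g"] is BirthLossScenario.LOSS_IN_FOCAL

    def test_majority_disruption_is_ambiguous(self):
        calls = [self._call(OutgroupStatus.NOT_DISRUPTED, f"a{i}") for i in range(12)]
        out = infer_birth_vs_loss(calls, 19, {"g": self._intact_projection()})
        assert out["g"] is BirthLossScenario.AMBIGUOUS

    def test_uncovered_outgroup_is_ambiguous(self):
        calls = [self._call(OutgroupStatus.NOT_COVERED)]
        out = infer_birth_vs_loss(calls, 19, {})
        assert out["g"] is BirthLossScenario.AMBIGUOUS


class TestSummary:
    def test_table_rows_and_overlap(self):
        from lsgorigins.polymorphism import DisruptionCall

        records = {}
        calls = []
        for i in range(32):
            g = f"fam_isc_{i}"
            records[g] = LsgRecord(g, Compartment.NUCLEAR, LineageLevel.FAMILY)
            calls.append(DisruptionCall(g, "a0", SnpType.ISC, "c", 1, 5))
        support = {}
        for i in range(12):
            support[f"fam_isc_{i}"] = ExpressionSupport.GENE_MODEL
        for i in range(12, 22):
            support[f"fam_isc_{i}"] = ExpressionSupport.LOCUS
        # one gene carries both an ISC and an MSC
        records["both"] = LsgRecord("both", Compartment.NUCLEAR, LineageLevel.FAMILY)
        calls.append(DisruptionCall("both", "a1", SnpType.ISC, "c", 9, 7))
        calls.append(DisruptionCall("both", "a1", SnpType.MSC, "c", 3, 1))
        table = summarize_polymorphic_lsgs(calls, records, support)
        row = table[(table.lineage_level == "family_specific") & (table.snp_type == "ISC")]
        assert int(row["total"].iloc[0]) == 33
        assert int(row["gene_model_support"].iloc[0]) == 12
        assert int(row["locus_support"].iloc[0]) == 22
        overlap = table[table.snp_type == "ISC&MSC overlap"]
        assert int(overlap["total"].iloc[0]) == 1

    def test_planted_accession_events_counted(self, scenario, pipeline_result):
        truth = scenario.truth
        planted_isc_genes = {
            g for (g, _a), t in truth.disruptions.items() if t == "ISC"
        }
        called_isc = {
            c.gene_id for c in pipeline_result.calls if c.snp_type is SnpType.ISC
        }
        assert called_isc == planted_isc_genes
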