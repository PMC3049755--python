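"""Shared fixtures: one default synthetic scenario + pipeline run per session."""

from __future__ import annotations

import pytest

from lsgorigins.pipeline import RunConfig, run_synthetic_pipeline
from lsgorigins.synth import ScenarioConfig, generate_scenario

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def scenario():
    return generate_scenario(ScenarioConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    return run_synthetic_pipeline(
        RunConfig(scenario=ScenarioConfig(seed=DEFAULT_SEED)), scenario=scenario
    )


@pytest.fixture()
def mini_gff3(tmp_path):
    """Two genes (one 2-exon, one single-exon) plus one helitron fragment."""
    gff = tmp_path / "mini.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
        "chr1\ttest\texon\t101\t220\t.\t+\t.\tParent=geneA.1\n"
        "chr1\ttest\texon\t301\t400\t.\t+\t.\tParent=geneA.1\n"
        "chr1\ttest\tCDS\t111\t220\t.\t+\t0\tParent=geneA.1\n"
        "chr1\ttest\tCDS\t301\t390\t.\t+\t1\tParent=geneA.1\n"
        "chr1\ttest\tgene\t601\t900\t.\t-\t.\tID=geneB\n"
        "chr1\ttest\tmRNA\t601\t900\t.\t-\t.\tID=geneB.1;Parent=geneB\n"
        "chr1\ttest\texon\t601\t900\t.\t-\t.\tParent=geneB.1\n"
        "chr1\ttest\tCDS\t611\t880\t.\t-\t0\tParent=geneB.1\n"
        "chr1\ttest\ttransposable_element\t1001\t1400\t.\t+\t.\t"
        "ID=TE1;superfamily=RC/Helitron\n"
    )
    fasta = tmp_path / "mini.fasta"
    fasta.write_text(">chr1\n" + "ACGT" * 500 + "\n")
    return gff, fasta
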