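import numpy as np
import pytest

from ibdnet import (
    GeneticMap,
    IBDSegment,
    PedigreeSimConfig,
    PopulationTable,
    simulate_pedigree,
)


def make_segment(
    a="I1",
    b="I2",
    chrom="1",
    start=1_000_000,
    end=9_000_000,
    hap_a=1,
    hap_b=1,
    score=6.0,
    length=8.0,
    n_snps=None,
):
    return IBDSegment(
        sample_a=a,
        hap_a=hap_a,
        sample_b=b,
        hap_b=hap_b,
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        score=score,
        length_cM=length,
        n_snps=n_snps,
    )


@pytest.fixture
def linear_map():
    """1 cM/Mb on three chromosomes (matches the simulator default spans)."""
    return GeneticMap.uniform({"1": (120e6, 120.0), "2": (100e6, 100.0), "3": (80e6, 80.0)})


@pytest.fixture
def toy_table():
    return PopulationTable.from_mapping(
        {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B"}
    )


@pytest.fixture(scope="session")
def pedigree_panel():
    """Small two-population pedigree panel shared across detector/triangulation tests."""
    cfg = PedigreeSimConfig(
        populations={"P1": 8, "P2": 8}, generations=3, markers_per_chrom=2000, seed=11
    )
    return simulate_pedigree(cfg)
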