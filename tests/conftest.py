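import numpy as np
import pytest

import lpsprs as lp


@pytest.fixture(scope="session")
def small_panel():
    """60-haplotype, 100-site panel used across module tests."""
    return lp.simulate_panel(60, 100, region_length=1_000_000, maf_min=0.05, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    return lp.simulate_cohort(small_panel, 12, seed=12)


@pytest.fixture(scope="session")
def deep_gl(small_cohort):
    reads = lp.simulate_reads(small_cohort, 30.0, error_rate=0.001, seed=13)
    return lp.compute_gl(reads)


@pytest.fixture(scope="session")
def lowpass_gl(small_cohort):
    reads = lp.simulate_reads(small_cohort, 0.5, error_rate=0.001, seed=14)
    return lp.compute_gl(reads)


def tiny_panel(alleles, positions=None):
    """Hand-built panel from a 0/1 matrix (haplotypes x sites)."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = 1000 * (np.arange(n_sites) + 1)
    return lp.HaplotypePanel(
        positions=np.asarray(positions),
        alleles=alleles,
        site_ids=np.array([f"s{i}" for i in range(n_sites)], dtype=object),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
    )
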