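import numpy as np
import pytest

from ampliseq import fixtures
from ampliseq.panel import CallerConfig
from ampliseq.primer_trim import mask_all
from ampliseq.simulate import PlantedVariant, SimGenotype, SimProfile, simulate_reads


@pytest.fixture(scope="session")
def panel_and_placements():
    return fixtures.build_reference_and_panel()


@pytest.fixture(scope="session")
def panel(panel_and_placements):
    return panel_and_placements[0]


@pytest.fixture(scope="session")
def placements(panel_and_placements):
    return panel_and_placements[1]


@pytest.fixture(scope="session")
def catalog():
    return fixtures.default_catalog()


@pytest.fixture(scope="session")
def config():
    return CallerConfig()


@pytest.fixture(scope="session")
def sim_sample(panel, placements):
    """One masked heterozygous sample carrying the five fixture variants.

    F508del and L467F sit in cis on haplotype 0; 2143delT on haplotype 1;
    E92K under the A05 forward primer; the (A)7 duplication as carrier.
    """
    genotype = SimGenotype([
        PlantedVariant("F508del", *placements["F508del"], haplotype=0),
        PlantedVariant("L467F", *placements["L467F"], haplotype=0),
        PlantedVariant("2143delT", *placements["2143delT"], haplotype=1),
        PlantedVariant("2184insA", *placements["2184insA"], haplotype=0),
        PlantedVariant("E92K", *placements["E92K"], haplotype=0),
    ])
    profile = SimProfile(reads_per_amplicon=150)
    reads, truth = simulate_reads(panel, genotype, profile, seed=42, sample_id="S1")
    mask_all(reads, panel)
    return reads, truth


@pytest.fixture(scope="session")
def cohort_table():
    return fixtures.build_cohort_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
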