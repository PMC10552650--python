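import pytest

from paleotx.synthetic_data import (
    SimConfig,
    simulate_dna_library,
    simulate_genome_annotation,
    simulate_library,
)

# compact study conditions for unit tests: same structure as the defaults,
# scaled to a 0.5-Mb genome so fixtures build in well under a second
SMALL_CFG = SimConfig(
    seed=11,
    scaffold_lengths=(300_000, 200_000),
    window_size=25_000,
    n_protein_coding=25,
    n_shared_hotspots=6,
    n_private_hotspots=2,
    n_trna=6,
    n_mirna=4,
    n_decoy_mirna=2,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_genome_annotation(SMALL_CFG)


@pytest.fixture(scope="session")
def muscle_lib(small_sim):
    return simulate_library(small_sim, "muscle", 2000, seed=5, pcr_duplication=1.0)


@pytest.fixture(scope="session")
def skin_lib(small_sim):
    return simulate_library(small_sim, "skin", 2000, seed=6, pcr_duplication=1.0)


@pytest.fixture(scope="session")
def dna_lib(small_sim):
    return simulate_dna_library(small_sim, 4000, seed=7)
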