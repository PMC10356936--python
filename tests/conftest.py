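"""Shared fixtures: the published nine-genome screening panel and small configs."""

import pytest
from hypothesis import settings

from diazoscan.nif_screen import NIF_GENES

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from diazoscan.simulate import NifProfile, SimulationConfig, make_genomes

ALL_NIF = frozenset(NIF_GENES)

#: The nine nifH-positive Arctic genomes with their printed nif content:
#: Arc-Gamma-01 lacks nifK but carries nifD at a contig end (truncated
#: operon), Arc-Gamma-04 lacks nifB, Arc-Myxo carries nifH alone.
TABLE1_PROFILES = [
    NifProfile("Arc-UCYN-A2", ALL_NIF),
    NifProfile("Arc-Bactero", ALL_NIF),
    NifProfile("Arc-Campylo", ALL_NIF),
    NifProfile("Arc-Alpha", ALL_NIF),
    NifProfile("Arc-Gamma-01", ALL_NIF - {"nifK"}, fragmented=True),
    NifProfile("Arc-Gamma-02", ALL_NIF),
    NifProfile("Arc-Gamma-03", ALL_NIF),
    NifProfile("Arc-Gamma-04", ALL_NIF - {"nifB"}),
    NifProfile("Arc-Myxo", frozenset({"nifH"})),
]


@pytest.fixture(scope="session")
def table1_genomes():
    cfg = SimulationConfig(seed=11, nif_profiles=TABLE1_PROFILES)
    genomes, _, truth = make_genomes(cfg)
    return genomes, truth


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(seed=7, n_genomes=12, n_samples=54)
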