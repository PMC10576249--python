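from __future__ import annotations

import random

import pytest

from ednascreen.io_formats import ScreeningThresholds
from ednascreen.synthetic_data import (
    CommunityConfig,
    ContaminationScenario,
    LibraryConfig,
    NoiseConfig,
    SampleConfig,
    SimulationConfig,
    generate_dataset,
)

from helpers import make_ref, mutate_at, random_dna


@pytest.fixture(scope="session")
def thresholds() -> ScreeningThresholds:
    return ScreeningThresholds()


@pytest.fixture(scope="session")
def toy_sequences():
    """A 658 bp reference and queries derived from its 145 bp window."""
    rng = random.Random(20170514)
    ref = random_dna(rng, 658)
    amplicon = ref[33:178]
    return {"reference": ref, "amplicon": amplicon, "rng_seed": 20170514}


def small_sim_config(noise: NoiseConfig | None = None,
                     scenarios: list | None = None,
                     depth_mean: float = 6000.0) -> SimulationConfig:
    """A scaled-down simulated study used across tests: 30 samples in
    three categories, 15 local + 6 foreign species."""
    if scenarios is None:
        scenarios = [ContaminationScenario(
            mode="lab_point_source", contaminant_species=3,
            target_window=(0.3, 0.6), rra_level=(1.0, 10.0),
            per_sample_probability=0.8)]
    return SimulationConfig(
        library=LibraryConfig(n_local_species=15, n_foreign_species=6,
                              n_congeneric_pairs=1, haplotype_fraction=0.1),
        samples=SampleConfig(
            category_counts={"great_tit": 10, "willow_tit": 10,
                             "frass_sheet": 10},
            n_negative_controls=1, n_replicate_pairs=1),
        community=CommunityConfig(depth_mean=depth_mean, depth_sd=1500,
                                  depth_min=500, richness_mean=6,
                                  richness_min=3),
        scenarios=scenarios,
        noise=noise or NoiseConfig(sub_rate=0.0, homopolymer_del_prob=0.0,
                                   chimera_rate=0.0),
    )


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Zero-noise lab-contamination simulation with truth labels."""
    out = tmp_path_factory.mktemp("clean_sim")
    return generate_dataset(small_sim_config(), out, seed=11)


@pytest.fixture
def tiny_library():
    """Three species, one congeneric pair, 658 bp references."""
    rng = random.Random(7)
    base = random_dna(rng, 658)
    sibling = mutate_at(base, rng.sample(range(33, 178), 5), rng)
    other = random_dna(rng, 658)
    return [
        make_ref("R1", base, "Lymantria dispar", family="Erebidae"),
        make_ref("R2", sibling, "Lymantria monacha", family="Erebidae"),
        make_ref("R3", other, "Catocala fraxini", family="Erebidae"),
    ]
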