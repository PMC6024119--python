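from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import comprep as cp

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix() -> cp.IncidenceMatrix:
    """Four units, five species, with overlaps exercising the greedy path."""
    records = [
        ("a", "u1"), ("b", "u1"),
        ("b", "u2"), ("c", "u2"),
        ("a", "u3"), ("d", "u3"),
        ("e", "u4"),
    ]
    return cp.IncidenceMatrix(records)


@pytest.fixture(scope="session")
def planted() -> cp.PlantedFixture:
    return cp.simulate_planted_cover(4, extra_units=3, decoys_per_block=2, seed=7)


@pytest.fixture(scope="session")
def sim_dataset() -> cp.SimulatedDataset:
    """Small simulated dataset shared across tests (seeded, read-only)."""
    cfg = cp.SimulationConfig(
        n_units=120,
        n_strata=6,
        species_per_group={
            "woody_plant": 120,
            "fern": 30,
            "amphibian": 10,
            "reptile": 10,
            "bird": 25,
            "mammal": 12,
        },
        seed=11,
    )
    return cp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_cs(sim_dataset) -> cp.ComplementarySet:
    return cp.build_complementary_set(sim_dataset.incidence, sim_dataset.species)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
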