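"""Shared fixtures: one simulated population (sequences, truth, distances,
BGC table) reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panmash.sketch_distance import DistanceMatrix, distance_matrix, sketch
from panmash.synthetic_data import SimulationConfig, simulate_bgc_table, simulate_genomes


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def population(sim_config):
    sequences, truth = simulate_genomes(sim_config)
    return sequences, truth


@pytest.fixture(scope="session")
def truth(population) -> pd.DataFrame:
    return population[1]


@pytest.fixture(scope="session")
def mash_dm(population) -> DistanceMatrix:
    sequences, _ = population
    sketches = [sketch(seq, genome_id=g) for g, seq in sequences.items()]
    return distance_matrix(sketches)


@pytest.fixture(scope="session")
def bgc_tables(sim_config, truth):
    table, gcf_truth = simulate_bgc_table(sim_config, truth)
    return table, gcf_truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
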