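"""Shared fixtures: small deterministic models and one full ladder run."""

import numpy as np
import pytest

from pmrdd.pipeline import run_series
from pmrdd.simulate import SimulationConfig, calc_structure_factors
from pmrdd.symmetry import build_cell, expand_model_p1, get_space_group
from pmrdd.synthetic import make_test_model, make_toy_model

LADDER = (30, 100, 300, 1000, 3000)
LADDER_SEED = 11
LADDER_D_MIN = 1.7


@pytest.fixture(scope="session")
def p1():
    return get_space_group("P1")


@pytest.fixture(scope="session")
def toy_model():
    """Three-atom P1 cell for direct-summation oracles."""
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_fc(toy_model):
    return calc_structure_factors(toy_model, 2.0)


@pytest.fixture(scope="session")
def test_model():
    """The ~300-atom synthetic crystal with designated TRP/TYR targets."""
    return make_test_model(seed=0)


@pytest.fixture(scope="session")
def small_model():
    """A lighter 9-residue crystal for merge-statistics benchmarks."""
    return make_test_model(n_residues=9,
                           cell=build_cell(20.0, 20.0, 20.0, 90, 90, 90),
                           seed=2)


@pytest.fixture(scope="session")
def small_truth(small_model, p1):
    return calc_structure_factors(expand_model_p1(small_model, p1), 2.5)


@pytest.fixture(scope="session")
def default_ladder_report(test_model):
    """One full default-configuration PMRDD ladder, shared across tests.

    TRP 1 is truncated and TYR 2 rotamer-swapped; everything else is the
    simulator/pipeline default.
    """
    config = SimulationConfig(n_crystals=max(LADDER), seed=LADDER_SEED)
    return run_series(test_model, list(LADDER), config=config,
                      d_min=LADDER_D_MIN,
                      delete_residue=("A", 1), move_residue=("A", 2))
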