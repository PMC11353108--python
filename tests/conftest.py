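import dataclasses

import numpy as np
import pytest

import livercond as lc


@pytest.fixture(scope="session")
def default_grid() -> lc.FrequencyGrid:
    return lc.FrequencyGrid.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240808)


@pytest.fixture(scope="session")
def small_cohort() -> lc.SimulatedCohort:
    """A reduced cohort (5 per group) with default parasitics, shared across
    read-only tests."""
    specs = tuple(
        dataclasses.replace(s, n=5) for s in lc.default_group_specs()
    )
    return lc.generate_cohort(lc.SimulationConfig(seed=42, group_specs=specs))


def random_impedance(rng: np.random.Generator, n: int = 32) -> lc.ImpedanceSpectrum:
    """Random passive spectrum with strictly positive R."""
    grid = lc.FrequencyGrid(np.sort(rng.uniform(1e3, 1e6, n)))
    return lc.ImpedanceSpectrum(
        grid=grid,
        resistance=rng.uniform(0.1, 500.0, n),
        reactance=rng.uniform(-200.0, 200.0, n),
    )
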