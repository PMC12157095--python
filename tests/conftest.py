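import numpy as np
import pytest

from covselect import (
    CorrelationStructure,
    SimulationDesign,
    simulate_dataset,
)

MEAN_FORMULA = "time + group + age"


def make_dataset(structure, n_subjects=100, T=6, sigma2=1.0, seed=0,
                 variance_weights=None, times=None):
    design = SimulationDesign(
        n_subjects=n_subjects,
        times=tuple(times) if times is not None else tuple(range(1, T + 1)),
        structure=structure,
        sigma2=sigma2,
        variance_weights=variance_weights,
        seed=seed,
    )
    return simulate_dataset(design)


@pytest.fixture(scope="session")
def ar1_dataset():
    return make_dataset(CorrelationStructure("ar", (0.5,)), n_subjects=100,
                        T=6, seed=11)


@pytest.fixture(scope="session")
def cs_dataset():
    return make_dataset(CorrelationStructure("cs", (0.4,)), n_subjects=100,
                        T=6, seed=12)


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(CorrelationStructure("ar", (0.6,)), n_subjects=6,
                        T=4, seed=13)
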