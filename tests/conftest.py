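import numpy as np
import pytest

from irtval import (BankSpec, GrmFitConfig, ItemBank, SimulationDesign,
                    fit_grm, simulate_dataset)


@pytest.fixture(scope="session")
def toy_bank():
    """Fixed 4-item, 5-category bank with known parameters."""
    return ItemBank(
        ["i1", "i2", "i3", "i4"],
        [2.0, 3.0, 1.5, 2.5],
        [[-1.0, 0.0, 1.0, 2.0],
         [-2.0, -1.0, 0.0, 0.5],
         [-0.5, 0.2, 0.8, 1.5],
         [-1.5, -0.5, 0.5, 1.0]],
    )


@pytest.fixture(scope="session")
def ability_cohort():
    """Synthetic cohort in the strong-slope regime of a participation bank:
    35 five-category items, slopes in [2.4, 4.8], n = 1000."""
    design = SimulationDesign(n_persons=1000, seed=7)
    rm, bank, theta = simulate_dataset(design)
    return rm, bank, theta, design


@pytest.fixture(scope="session")
def recovery_fit():
    """10-item bank, n = 1000 simulated from it, and the MML-EM refit."""
    design = SimulationDesign(
        n_persons=1000,
        bank_spec=BankSpec(n_items=10, slope_range=(2.0, 4.0),
                           threshold_range=(-2.0, 1.0)),
        seed=42)
    rm, bank, theta = simulate_dataset(design)
    est = fit_grm(rm, GrmFitConfig(compute_se=True))
    return rm, bank, theta, est


def rng(seed=0):
    return np.random.default_rng(seed)
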