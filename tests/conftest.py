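import numpy as np
import pytest

import veloscope as v
from veloscope import pipeline as pl


def unit_horizon_config(**overrides):
    """Perturbation/reversion conditions rescaled to a unit horizon.

    Rescaling process time t -> t/T maps all rates by a factor T, leaving the
    dimensionless trajectories (and count laws) unchanged; log-means shift by
    ln(10) for the default T = 10 conditions.
    """
    ln10 = float(np.log(10.0))
    defaults = dict(
        horizon=1.0,
        switch_times=(0.3, 0.7),
        alpha_logmean=ln10,
        beta_logmean=1.0 + ln10,
        gamma_logmean=0.5 + ln10,
    )
    defaults.update(overrides)
    return v.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def aba_dataset():
    """The perturbation/reversion dataset at its study conditions (fixed seed)."""
    return v.simulate_perturbation_reversion(v.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def aba_pipeline(aba_dataset):
    """Full estimation chain on the ABA dataset (no filtering/normalization,
    matching the simulated-data processing conventions)."""
    config = pl.PipelineConfig(do_filter=False, normalize=False)
    processed, fits, field = pl.run_pipeline(
        aba_dataset.spliced, aba_dataset.unspliced, config
    )
    return processed, fits, field


@pytest.fixture(scope="session")
def bursty_dataset():
    """A scaled-down stationary bursty dataset (5 types x 120 cells, 40 genes)."""
    return v.simulate_bursty_steady_state(
        v.BurstySimulationConfig(
            n_genes=40, n_cell_types=5, cells_per_type=120, seed=5
        )
    )
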