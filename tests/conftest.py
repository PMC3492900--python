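import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pubgoodsim as pg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small, fast lattice with the default rates.

    Half dose keeps the small population alive long enough for a
    mutation to arise and the window to hold living cells.
    """
    return pg.SimulationParams(
        lattice=pg.LatticeConfig(width=13, height=13),
        transfer_coefficient=0.5,
        dose=0.5,
        record_window=50,
        max_burn_in=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def full_dose_sweep():
    """The reference experiment at full dose: 10 replicates for each
    transfer coefficient in {0, 0.5, 1} on the default 51x51 lattice.

    Session-scoped because several acceptance checks read the same 30
    runs, exactly as the headline analysis does.
    """
    design = pg.ExperimentDesign(dose_values=(1.0,), replicates=10, base_seed=0)
    return pg.run_experiment(design)
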