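import math

import numpy as np
import pytest

from sgt import GrowthCurve, SimulationParams


def exponential_curve(
    n0: float,
    td: float = 0.5,
    od_per_cell: float = 5e-10,
    dt: float = 0.01,
    duration: float = 12.0,
    background: float = 0.0,
    well_id: str = "A1",
) -> GrowthCurve:
    """Noiseless pure-exponential OD curve, built independently of the simulator."""
    t = np.arange(0.0, duration + dt / 2, dt)
    n = n0 * 2.0 ** (t / td)
    return GrowthCurve(well_id, t, background + od_per_cell * n)


def sgt_closed_form(
    n0: float, td: float, threshold: float = 0.15,
    od_per_cell: float = 5e-10, background: float = 0.0,
) -> float:
    """Independent oracle: time for exponential growth to reach the threshold OD."""
    n_thr = (threshold - background) / od_per_cell
    return td * math.log2(n_thr / n0)


@pytest.fixture
def exp_curve():
    return exponential_curve


@pytest.fixture
def oracle_sgt():
    return sgt_closed_form


@pytest.fixture
def noiseless_params():
    """Noiseless simulator parameters in the exponential regime (huge K)."""
    def make(seed: int = 0, **kw) -> SimulationParams:
        defaults = dict(
            seed=seed,
            n0=1e6,
            doubling_time_hours=0.5,
            carrying_capacity=1e18,
            od_per_cell=5e-10,
            od_background=0.0,
            noise_multiplicative_cv=0.0,
            noise_additive_sd=0.0,
            read_interval_hours=0.01,
            duration_hours=12.0,
        )
        defaults.update(kw)
        return SimulationParams(**defaults)
    return make
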