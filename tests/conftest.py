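import numpy as np
import pytest

from fcskit import FCSSimConfig, multi_tau_correlate, per_lag_spread, simulate_fcs_traces
from fcskit.models import ConfocalCalibration

# shared observation volume: 0.25 µm waist, K = 5 (reference-dye calibrated)
CALIB = ConfocalCalibration.from_K(omega_xy=0.25, K=5.0)

TAU_D_TRUE = 0.25 ** 2 / (4 * 400.0)  # 39.06 µs for D = 400 µm²/s


def make_sim_config(seed, **overrides):
    """Single-species reference scenario: D = 400 µm²/s, 1 s acquisition."""
    kwargs = dict(
        box_side=4.0,
        n_particles=(60,),
        D=(400.0,),
        brightness=((60000.0,),),
        background=(0.0,),
        omega_xy=0.25,
        omega_z=1.25,
        bin_time=2e-6,
        duration=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return FCSSimConfig(**kwargs)


@pytest.fixture(scope="session")
def reference_sims():
    """Five seeded Brownian-dynamics runs of the reference scenario.

    Session-scoped because the simulations dominate suite runtime; each
    entry carries the trace, its weighted multi-tau curve and the ground
    truth record.
    """
    out = []
    for seed in range(5):
        cfg = make_sim_config(seed)
        traces, truth = simulate_fcs_traces(cfg)
        curve = per_lag_spread(traces[0])
        out.append({"config": cfg, "trace": traces[0], "curve": curve, "truth": truth})
    return out


@pytest.fixture(scope="session")
def bright_trace():
    """High-count slow-diffusion trace for estimator cross-validation.

    D = 20 µm²/s at 10 µs bins gives a decay over ~150 bins; ~3 counts/bin
    keeps the single-lag brute-force oracle's shot noise well below 1%.
    """
    cfg = make_sim_config(
        5,
        n_particles=(40,),
        D=(20.0,),
        brightness=((2e6,),),
        bin_time=1e-5,
        duration=2.0,
    )
    traces, _ = simulate_fcs_traces(cfg)
    return traces[0]


@pytest.fixture(scope="session")
def two_channel_sim():
    """One run with identical trajectories feeding both detection channels."""
    cfg = make_sim_config(
        11,
        brightness=((80000.0, 80000.0),),
        background=(0.0, 0.0),
        duration=1.0,
        n_particles=(40,),
    )
    traces, truth = simulate_fcs_traces(cfg)
    return {"config": cfg, "traces": traces, "truth": truth}
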