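import numpy as np
import pandas as pd
import pytest

import kmsens as k


@pytest.fixture
def tiny_table():
    """Three subjects, one arm: events at days 1 and 2, censoring at day 3."""
    return k.make_ipd_table(
        ["a", "b", "c"], ["experimental"] * 3, [1.0, 2.0, 3.0], [1, 1, 0]
    )


@pytest.fixture
def two_arm_table():
    """Small two-arm table with events in both arms."""
    return k.make_ipd_table(
        [f"s{i}" for i in range(10)],
        ["experimental"] * 5 + ["control"] * 5,
        [2.0, 5.0, 7.0, 9.0, 12.0, 1.0, 3.0, 4.0, 6.0, 8.0],
        [1, 1, 0, 1, 0, 1, 1, 1, 0, 1],
    )


@pytest.fixture(scope="session")
def s1801_trial():
    """One simulated trial under the calibrated preset (seed 1)."""
    cfg, design = k.s1801_like(seed=1)
    return k.simulate_trial(cfg, design, seed=1)


def roundtrip_error(ipd: pd.DataFrame, arm: str, grid_step: float, **render_kw) -> float:
    """Max pointwise |S_original - S_reconstructed| for one arm."""
    sub = ipd[ipd["arm"] == arm]
    tmax = float(sub["time_days"].max())
    grid = np.arange(0.0, tmax, grid_step)
    rendered = k.render_km_coordinates(ipd, grid, arm=arm, **render_kw)
    recon = k.reconstruct_ipd(rendered)
    ts = np.linspace(0.0, tmax, 500)
    orig = k.survival_at(k.km_estimate(sub), ts)
    rec = k.survival_at(k.km_estimate(recon), ts)
    return float(np.max(np.abs(orig - rec)))
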