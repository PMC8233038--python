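import numpy as np
import pytest

import cablescale as cs


@pytest.fixture
def wt_params() -> cs.FeedbackParams:
    """Wild-type linear feedback: f0 = 0.36 µm/s, steady state at x = 1."""
    return cs.FeedbackParams.linear(0.36, x_star=1.0)


@pytest.fixture
def wt_cell() -> cs.CellGeometry:
    """A typical haploid mother cell (4.5 µm long)."""
    return cs.CellGeometry(4.5, 3.75, 3.75, strain="haploid")


@pytest.fixture
def quiet_obs() -> cs.ObservationModel:
    """Noise-free acquisition at the default 3 s frame interval."""
    return cs.ObservationModel(rate_noise_cv=0.0, tip_noise_sd_um=0.0, seed=0)


@pytest.fixture
def noisy_obs() -> cs.ObservationModel:
    return cs.ObservationModel(seed=0)


def rk4_lengths(params, cell, times, dt=1e-3):
    """Independent fixed-step RK4 oracle for dL/dt = f(L/L_cell)."""
    times = np.asarray(times, dtype=float)
    t_end = float(times.max())
    n = int(round(t_end / dt))
    grid = np.linspace(0.0, n * dt, n + 1)
    L = np.empty(n + 1)
    L[0] = 0.0
    Lc = cell.length_um
    f = lambda length: cs.feedback_rate(params, max(length, 0.0) / Lc)
    for i in range(n):
        y = L[i]
        k1 = f(y)
        k2 = f(y + dt / 2 * k1)
        k3 = f(y + dt / 2 * k2)
        k4 = f(y + dt * k3)
        L[i + 1] = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.interp(times, grid, L)
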