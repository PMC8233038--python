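"""Synthetic trajectory and cell-population generators.

These generators emulate the two kinds of data the quantification pipeline
consumes:

* live-imaging tip trajectories — a cable emerges from the bud neck at
  t = 0 and its tip is tracked at a fixed frame interval for ~2 min;
* fixed-cell snapshots — each cable is caught at a random stage of growth,
  so snapshot ensembles show a wide range of cable lengths.

The noise model is deliberately simple and explicit: multiplicative
Gaussian noise on per-frame growth increments (polymerisation
stochasticity) plus additive Gaussian localisation noise on the observed
lengths (tip-tracking error).  Real movies additionally contain tracking
drop-outs, cable crossings and photobleaching, none of which is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import IntegrationError, ValidationError
from .feedback import (
    BOUNDARY,
    GRADIENT_EXP,
    _EXACTLY_LINEAR,
    FeedbackParams,
    extension_rate,
    feedback_rate,
    steady_state_length,
)
from .geometry import CellGeometry
from .trajectory import Trajectory


@dataclass(frozen=True)
class ObservationModel:
    """Acquisition and noise settings for simulated live imaging.

    Defaults: 3.0 s frame interval (the middle of the 0.30–0.43 frames/s
    acquisition range) for 120 s (2 min recordings); increment noise CV
    0.3 and 0.05 µm localisation noise, chosen to give confidence-interval
    widths of the same order as measured rate curves.
    """

    frame_interval_s: float = 3.0
    rate_noise_cv: float = 0.3
    tip_noise_sd_um: float = 0.05
    duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s must be > 0")
        if self.rate_noise_cv < 0 or self.tip_noise_sd_um < 0:
            raise ValidationError("noise parameters must be >= 0")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be > 0")


@dataclass(frozen=True)
class StrainPreset:
    """Published morphometrics for one yeast strain.

    mean/range of mother-cell length (µm), mean mother-cell volume (µm³),
    and the measured initial cable extension rate f0 (µm/s).
    """

    name: str
    mean_length_um: float
    length_range_um: tuple[float, float]
    mean_volume_um3: float
    f0_um_per_s: float


def _scaled_range(mean: float) -> tuple[float, float]:
    # haploid relative range (3.7-5.5 around 4.5) rescaled to another mean;
    # ranges for the other strains were not reported.
    return (mean * 3.7 / 4.5, mean * 5.5 / 4.5)


#: Strain presets.  Lengths/volumes are the published means for each strain;
#: length ranges other than haploid are estimated by rescaling the haploid
#: range.  Diploid cell length is estimated from its mean cable length
#: (cables grow to match cell length); smy1Δ cell geometry is wild-type-like.
PRESETS: dict[str, StrainPreset] = {
    "haploid": StrainPreset("haploid", 4.5, (3.7, 5.5), 44.9, 0.36),
    "diploid": StrainPreset("diploid", 6.3, _scaled_range(6.3), 81.8, 0.36),
    "cdc28_uninduced": StrainPreset("cdc28_uninduced", 4.3, _scaled_range(4.3), 40.9, 0.36),
    "cdc28_induced": StrainPreset("cdc28_induced", 8.2, _scaled_range(8.2), 198.3, 0.36),
    "smy1_delta": StrainPreset("smy1_delta", 4.5, (3.7, 5.5), 44.9, 0.42),
}

#: Wild-type initial extension rate measured alongside the smy1Δ strain
#: (µm/s); slightly below the headline haploid rate because it comes from a
#: separate experimental series.  Used for the wt-vs-smy1Δ comparisons.
WT_RATE_SMY1_EXPERIMENTS = 0.35


# ---------------------------------------------------------------------------
# deterministic growth


def integrate_growth(
    params: FeedbackParams, cell: CellGeometry, dt: float, t_end: float
) -> Trajectory:
    """Integrate dL/dt = f(L/L_cell) from L(0)=0 with fixed-step RK4.

    Returns a noise-free :class:`Trajectory` sampled at multiples of
    ``dt``.  The boundary family is handled analytically (the vector field
    is discontinuous).  Raises :class:`IntegrationError` if the length ever
    decreases by more than 1e−9 µm in a step.
    """
    if not dt > 0 or not t_end > dt:
        raise ValidationError("need dt > 0 and t_end > dt")
    times = np.arange(0.0, t_end + dt / 2, dt)
    if params.family == BOUNDARY:
        L_stop = params.L_max_ratio * cell.length_um
        lengths = np.minimum(params.f0 * times, L_stop)
        return Trajectory("sim", times, lengths, cell)
    L_cell = cell.length_um
    lengths = np.empty_like(times)
    L = 0.0
    lengths[0] = 0.0
    for i in range(1, times.size):
        k1 = feedback_rate(params, max(L, 0.0) / L_cell)
        k2 = feedback_rate(params, max(L + dt / 2 * k1, 0.0) / L_cell)
        k3 = feedback_rate(params, max(L + dt / 2 * k2, 0.0) / L_cell)
        k4 = feedback_rate(params, max(L + dt * k3, 0.0) / L_cell)
        L_new = L + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if L_new < L - 1e-9:
            raise IntegrationError(
                f"length decreased at t={times[i]:.3f}s; reduce dt"
            )
        L = L_new
        lengths[i] = L
    return Trajectory("sim", times, lengths, cell)


def length_at(params: FeedbackParams, cell: CellGeometry, t) -> np.ndarray:
    """Noise-free model length at arbitrary time(s) t (s).

    Exact closed forms for families with linear or piecewise-constant
    feedback; fine-step RK4 for ``gradient_exp``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    if params.family == BOUNDARY:
        out = np.minimum(params.f0 * t_arr, params.L_max_ratio * cell.length_um)
    elif params.family == GRADIENT_EXP:
        t_max = float(t_arr.max())
        if t_max == 0.0:
            out = np.zeros_like(t_arr)
        else:
            dt = min(1e-2, t_max / 10.0)
            traj = integrate_growth(params, cell, dt, t_max + 2 * dt)
            out = np.interp(t_arr, traj.times_s, traj.lengths_um)
    else:
        from .feedback import closed_form_length

        out = np.asarray(closed_form_length(params, cell, t_arr))
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# stochastic generators


def _deterministic_increment(
    params: FeedbackParams, L: np.ndarray, dt: float, L_cells: np.ndarray
) -> np.ndarray:
    """Noise-free growth over one frame interval, from current lengths L.

    Exact for the exactly-linear families (geometric relaxation toward L*)
    and for the boundary family; RK4 substeps for gradient_exp.  Keeping
    the latent dynamics consistent with the continuous model means the
    simulated frame interval changes only the sampling, not the kinetics.
    """
    if params.family in _EXACTLY_LINEAR:
        g1 = params.slope_at_zero
        L_star = params.x_star * L_cells
        return (L_star - L) * (1.0 - np.exp(g1 * dt / L_cells))
    if params.family == BOUNDARY:
        L_stop = params.L_max_ratio * L_cells
        return np.minimum(L + params.f0 * dt, np.maximum(L_stop, L)) - L
    # gradient_exp: no closed form; 10 RK4 substeps per frame
    n_sub = 10
    h = dt / n_sub
    Lc = L.copy()
    for _ in range(n_sub):
        k1 = feedback_rate(params, np.maximum(Lc, 0.0) / L_cells)
        k2 = feedback_rate(params, np.maximum(Lc + h / 2 * k1, 0.0) / L_cells)
        k3 = feedback_rate(params, np.maximum(Lc + h / 2 * k2, 0.0) / L_cells)
        k4 = feedback_rate(params, np.maximum(Lc + h * k3, 0.0) / L_cells)
        Lc = Lc + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return Lc - L


def simulate_cohort(
    params: FeedbackParams,
    cells: Sequence[CellGeometry],
    obs: ObservationModel,
    seed: Optional[int] = None,
) -> list[Trajectory]:
    """Simulate one observed trajectory per cell, vectorised across cables.

    Per frame, the latent length of each cable advances by the model's
    noise-free growth over the frame interval, scaled by ``(1 + ε)`` with
    ε ~ N(0, rate_noise_cv) and floored at zero; observed lengths add
    N(0, tip_noise_sd_um) localisation noise and are clipped at zero.
    With both noise terms at zero this reduces exactly to the noise-free
    model sampled at the frame times.
    """
    rng = np.random.default_rng(obs.seed if seed is None else seed)
    n = len(cells)
    L_cells = np.array([c.length_um for c in cells])
    dt = obs.frame_interval_s
    times = np.arange(0.0, obs.duration_s + dt / 2, dt)
    n_frames = times.size
    latent = np.zeros((n, n_frames))
    L = np.zeros(n)
    for i in range(1, n_frames):
        inc_det = _deterministic_increment(params, L, dt, L_cells)
        eps = rng.normal(0.0, obs.rate_noise_cv, size=n) if obs.rate_noise_cv > 0 else 0.0
        inc = np.maximum(inc_det * (1.0 + eps), 0.0)
        L = L + inc
        latent[:, i] = L
    if obs.tip_noise_sd_um > 0:
        observed = latent + rng.normal(0.0, obs.tip_noise_sd_um, size=latent.shape)
        observed = np.maximum(observed, 0.0)
    else:
        observed = latent
    return [
        Trajectory(f"cable{j:04d}", times, observed[j], cells[j])
        for j in range(n)
    ]


def simulate_observed_trajectory(
    params: FeedbackParams, cell: CellGeometry, obs: ObservationModel
) -> Trajectory:
    """Simulate a single noisy tip trajectory (seed taken from ``obs``)."""
    return simulate_cohort(params, [cell], obs)[0]


def simulate_fixed_snapshot(
    params: FeedbackParams,
    cells: Sequence[CellGeometry],
    obs_window_s: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a fixed-cell ensemble: each cable caught mid-growth.

    For each cell an observation time is drawn uniformly on
    [0, obs_window_s] and the noise-free model length at that time is
    reported — the simplest account of why fixed cells show a wider range
    of cable lengths than cell lengths.
    """
    if not obs_window_s > 0:
        raise ValidationError("obs_window_s must be > 0")
    rng = np.random.default_rng(seed)
    t_obs = rng.uniform(0.0, obs_window_s, size=len(cells))
    rows = []
    for i, (cell, t) in enumerate(zip(cells, t_obs)):
        rows.append(
            {
                "cell_index": i,
                "cell_length_um": cell.length_um,
                "time_s": t,
                "cable_length_um": float(length_at(params, cell, float(t))),
            }
        )
    return pd.DataFrame(rows)


def simulate_steady_state_fluctuations(
    params: FeedbackParams,
    cell: CellGeometry,
    sigma: float,
    dt: float,
    t_end: float,
    seed: int = 0,
) -> Trajectory:
    """Euler–Maruyama Langevin dynamics linearised about steady state.

    Near L* the feedback is a restoring force with spring constant
    |f'(x*)|/L_cell, so length fluctuations follow an Ornstein–Uhlenbeck
    process with stationary variance σ² L_cell / (2 |f'(x*)|): because the
    feedback weakens with cell length, longer cells show larger
    steady-state fluctuations.

    ``sigma`` has units µm/√s.  Raises :class:`IntegrationError` when the
    explicit step is unstable (dt·|f'(x*)|/L_cell ≥ 2).
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if not dt > 0 or not t_end > dt:
        raise ValidationError("need dt > 0 and t_end > dt")
    theta = abs(params.slope_at_xstar) / cell.length_um  # 1/s relaxation rate
    if dt * theta >= 2.0:
        raise IntegrationError(
            f"Euler-Maruyama unstable: dt*|f'(x*)|/L_cell = {dt * theta:.3f} >= 2"
        )
    L_star = steady_state_length(params, cell)
    times = np.arange(0.0, t_end + dt / 2, dt)
    n = times.size
    rng = np.random.default_rng(seed)
    if sigma == 0.0:
        lengths = np.full(n, L_star)
    else:
        # the EM recursion delta[k+1] = a*delta[k] + noise is an AR(1);
        # lfilter evaluates it without a Python loop
        a = 1.0 - theta * dt
        noise = sigma * np.sqrt(dt) * rng.standard_normal(n)
        noise[0] = 0.0
        deltas = signal.lfilter([1.0], [1.0, -a], noise)
        lengths = np.maximum(L_star + deltas, 0.0)
    return Trajectory("fluct", times, lengths, cell)


def generate_cell_population(
    preset: StrainPreset | str,
    n: int,
    seed: int = 0,
    aspect_mean: float = 1.2,
    aspect_sd: float = 0.15,
    aspect_min: float = 1.0,
) -> list[CellGeometry]:
    """Draw a population of mother cells for one strain preset.

    Cell lengths follow a normal distribution centred on the preset mean,
    truncated to the published length range; widths come from a truncated
    normal aspect-ratio distribution (cells are at least as long as wide)
    and heights equal widths (prolate-spheroid cells).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = preset.length_range_um
    scale = (hi - lo) / 4.0
    a, b = (lo - preset.mean_length_um) / scale, (hi - preset.mean_length_um) / scale
    lengths = stats.truncnorm.rvs(
        a, b, loc=preset.mean_length_um, scale=scale, size=n, random_state=rng
    )
    a_asp = (aspect_min - aspect_mean) / aspect_sd
    aspects = stats.truncnorm.rvs(
        a_asp, np.inf, loc=aspect_mean, scale=aspect_sd, size=n, random_state=rng
    )
    cells = []
    for L, asp in zip(lengths, aspects):
        w = L / asp
        cells.append(CellGeometry(float(L), float(w), float(w), strain=preset.name))
    return cells
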