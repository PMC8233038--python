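"""Quantification of cable traces and tip trajectories.

Mirrors the measurements made on microscopy data: polyline arc length of
traced cables, per-frame-interval extension rates, the initial rate
(first-interval rate), the initial deceleration (slope of a linear
regression of rate on time over the first ~10 s of extension), binned
mean-rate curves with 95% confidence intervals, and cable/cell
length-ratio statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, ValidationError
from .trajectory import Trajectory

TIME_AXIS = "time_s"
LENGTH_AXIS = "length_um"
NORMALIZED_AXIS = "normalized_length"
_AXES = (TIME_AXIS, LENGTH_AXIS, NORMALIZED_AXIS)


@dataclass
class RateSeries:
    """Extension rates against time, length, or normalized length.

    ``ci95_halfwidth`` is the half-width of the t-based 95% confidence
    interval of the mean rate per point (0 where only one cable
    contributes); ``n_per_point`` counts contributing cables.
    """

    axis: str
    axis_values: np.ndarray
    mean_rate_um_per_s: np.ndarray
    ci95_halfwidth: np.ndarray
    n_per_point: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValidationError(f"axis must be one of {_AXES}, got {self.axis!r}")
        arrays = [
            np.asarray(self.axis_values, dtype=float),
            np.asarray(self.mean_rate_um_per_s, dtype=float),
            np.asarray(self.ci95_halfwidth, dtype=float),
            np.asarray(self.n_per_point, dtype=int),
        ]
        if len({a.size for a in arrays}) != 1:
            raise ValidationError("RateSeries arrays must have equal length")
        self.axis_values, self.mean_rate_um_per_s, self.ci95_halfwidth, self.n_per_point = arrays
        if np.any(self.n_per_point < 1):
            raise ValidationError("n_per_point must be >= 1")
        if np.any(self.ci95_halfwidth < 0):
            raise ValidationError("ci95_halfwidth must be >= 0")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis: self.axis_values,
                "mean_rate_um_per_s": self.mean_rate_um_per_s,
                "ci95_halfwidth": self.ci95_halfwidth,
                "n": self.n_per_point,
            }
        )


@dataclass
class DecelerationEstimate:
    """OLS slope of rate vs time over the early regression window."""

    d0_um_per_s2: float
    ci95_halfwidth: float
    window_s: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValidationError("window_s must be > 0")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")


def polyline_length(coords) -> float:
    """Arc length (µm) of an ordered 2D/3D polyline of trace coordinates."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("need at least 2 ordered points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def interval_rates(traj: Trajectory) -> RateSeries:
    """Per-interval extension rates, timestamped at each interval start.

    The first element is the initial extension rate (rate measured during
    the first time interval).
    """
    if traj.n_frames < 2:
        raise ValidationError("need at least 2 frames to compute rates")
    dt = np.diff(traj.times_s)
    rates = np.diff(traj.lengths_um) / dt
    n = rates.size
    return RateSeries(
        axis=TIME_AXIS,
        axis_values=traj.times_s[:-1],
        mean_rate_um_per_s=rates,
        ci95_halfwidth=np.zeros(n),
        n_per_point=np.ones(n, dtype=int),
    )


def initial_rate(traj: Trajectory) -> float:
    """First-interval extension rate, µm/s."""
    return float(interval_rates(traj).mean_rate_um_per_s[0])


def fit_initial_deceleration(
    series: RateSeries, window_s: float = 10.0
) -> DecelerationEstimate:
    """Initial deceleration d0: OLS slope of rate vs time for t ≤ window_s.

    The 95% CI half-width comes from the slope's standard error with a
    t critical value (inf when only 2 points leave no residual degrees of
    freedom).
    """
    if series.axis != TIME_AXIS:
        raise ValidationError("deceleration fit needs a time-axis RateSeries")
    if not window_s > 0:
        raise ValidationError("window_s must be > 0")
    mask = series.axis_values <= window_s + 1e-12
    t = series.axis_values[mask]
    r = series.mean_rate_um_per_s[mask]
    if t.size < 2:
        raise EstimationError(
            f"only {t.size} rate point(s) within the {window_s}s window"
        )
    # OLS slope + standard error by hand (2 parameters, tiny n)
    tm, rm = t.mean(), r.mean()
    sxx = np.sum((t - tm) ** 2)
    if sxx == 0:
        raise EstimationError("zero time variance in regression window")
    slope = float(np.sum((t - tm) * (r - rm)) / sxx)
    resid = r - (rm + slope * (t - tm))
    df = t.size - 2
    if df > 0:
        se = float(np.sqrt(np.sum(resid**2) / df / sxx))
        ci = float(stats.t.ppf(0.975, df) * se)
    else:
        ci = float("inf")
    return DecelerationEstimate(
        d0_um_per_s2=slope, ci95_halfwidth=ci, window_s=window_s, n_points=int(t.size)
    )


def _interval_table(trajs: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for idx, traj in enumerate(trajs):
        rs = interval_rates(traj)
        rows.append(
            pd.DataFrame(
                {
                    "cable": idx,
                    "time_s": rs.axis_values,
                    "length_um": traj.lengths_um[:-1],
                    "normalized_length": traj.normalized_lengths[:-1],
                    "rate": rs.mean_rate_um_per_s,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def aggregate_rates(
    trajs: Sequence[Trajectory],
    axis: str = TIME_AXIS,
    bin_width: Optional[float] = None,
) -> RateSeries:
    """Mean extension rate across cables, binned along the chosen axis.

    Each interval contributes its rate at the axis value of the interval
    start (time, length, or length normalized by the cable's cell length).
    Within each bin, cables are first averaged individually and the 95% CI
    is the t-interval over those per-cable means — so cables, not frames,
    are the unit of replication.  Cables enter a bin only while still
    tracked; empty bins simply do not appear.  ``bin_width`` is required
    for the length axes and defaults to exact-value grouping on the time
    axis (frames are aligned across cables).
    """
    if not trajs:
        raise ValidationError("need at least one trajectory")
    if axis not in _AXES:
        raise ValidationError(f"axis must be one of {_AXES}")
    tab = _interval_table(trajs)
    if bin_width is None:
        if axis != TIME_AXIS:
            raise ValidationError("bin_width is required for length axes")
        # group by exact frame time (rounded against float jitter)
        tab["bin_key"] = np.round(tab[axis] / 1e-9).astype(np.int64)
        centers = tab.groupby("bin_key")[axis].mean()
    else:
        if not bin_width > 0:
            raise ValidationError("bin_width must be > 0")
        tab["bin_key"] = np.floor(tab[axis] / bin_width).astype(np.int64)
        centers = (tab.groupby("bin_key")[axis].first().index.to_series() + 0.5) * bin_width
    per_cable = tab.groupby(["bin_key", "cable"])["rate"].mean()
    grouped = per_cable.groupby(level="bin_key")
    means = grouped.mean()
    ns = grouped.size()
    sds = grouped.std(ddof=1)
    ci = np.zeros(len(means))
    multi = ns.values > 1
    if multi.any():
        tcrit = stats.t.ppf(0.975, ns.values[multi] - 1)
        ci[multi] = tcrit * sds.values[multi] / np.sqrt(ns.values[multi])
    order = np.argsort(centers.values)
    return RateSeries(
        axis=axis,
        axis_values=centers.values[order],
        mean_rate_um_per_s=means.values[order],
        ci95_halfwidth=ci[order],
        n_per_point=ns.values[order],
    )


def length_ratio_stats(
    cable_lengths_um,
    cell_lengths_um,
    grid: Optional[np.ndarray] = None,
) -> dict:
    """Cable/cell length ratios with summary stats and a kernel density.

    Returns a dict with ``ratios``, ``mean``, ``ci95_halfwidth`` (t-based),
    ``density_grid`` and ``density`` (Gaussian KDE, Silverman bandwidth,
    on a fixed grid).
    """
    cab = np.asarray(cable_lengths_um, dtype=float)
    cel = np.asarray(cell_lengths_um, dtype=float)
    if cab.shape != cel.shape:
        raise ValidationError("paired arrays must have equal length")
    if np.any(cel <= 0):
        raise ValidationError("cell lengths must be > 0")
    ratios = cab / cel
    n = ratios.size
    mean = float(ratios.mean())
    if n > 1 and ratios.std(ddof=1) > 0:
        ci = float(stats.t.ppf(0.975, n - 1) * ratios.std(ddof=1) / np.sqrt(n))
    else:
        ci = 0.0
    if grid is None:
        hi = max(ratios.max() * 1.5, 1e-6)
        grid = np.linspace(0.0, hi, 256)
    if n > 1 and ratios.std(ddof=1) > 0:
        kde = stats.gaussian_kde(ratios, bw_method="silverman")
        density = kde(grid)
    else:
        density = np.zeros_like(grid)
    return {
        "ratios": ratios,
        "mean": mean,
        "ci95_halfwidth": ci,
        "density_grid": grid,
        "density": density,
    }
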