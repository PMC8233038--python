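"""Kinetic parameter estimation and model selection from trajectory sets.

The central objects follow the Model/Results convention: build a
:class:`CableGrowthModel` from a set of trajectories, call :meth:`fit`,
and read estimates, uncertainties and diagnostics off the returned
:class:`CableGrowthResults`.

Estimation targets the early-time solution of the balance-point equation,

    L(t) = L_cell (f0/b) (exp(b t / L_cell) - 1),      b = f'(0) < 0,

by nonlinear least squares over all frames of all cables, with f0 and b
shared across cables and each cable's L_cell fixed to its own cell.
Fitting in length space integrates out frame-level growth noise; a
rate-space fit (per-interval rate regressed on normalized length, linear
family) is available as a cross-check.  Because growth noise accumulates
along a cable, length residuals are correlated within cables; standard
errors therefore use a cable-clustered sandwich covariance with t critical
values on n_cables − 2 degrees of freedom.

:func:`select_model` discriminates the balance-point model (exponentially
decaying extension rate) from the boundary-sensing alternative (constant
rate until the tip reaches the rear of the cell, then zero) by comparing
least-squares fits of the two rate profiles with BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import EstimationError, UnsupportedFamilyError, ValidationError
from .feedback import GRADIENT_LINEAR, LINEAR, FeedbackParams
from .geometry import CellGeometry
from .measure import interval_rates
from .trajectory import Trajectory

BALANCE_POINT = "balance_point"
BOUNDARY_SENSING = "boundary_sensing"


# ---------------------------------------------------------------------------
# data assembly


def _stack_lengths(trajs: Sequence[Trajectory]):
    t, L, Lc, cable = [], [], [], []
    for i, traj in enumerate(trajs):
        t.append(traj.times_s)
        L.append(traj.lengths_um)
        Lc.append(np.full(traj.n_frames, traj.cell.length_um))
        cable.append(np.full(traj.n_frames, i))
    return (
        np.concatenate(t),
        np.concatenate(L),
        np.concatenate(Lc),
        np.concatenate(cable),
    )


def _stack_rates(trajs: Sequence[Trajectory]):
    t, r, x, Lc, cable = [], [], [], [], []
    for i, traj in enumerate(trajs):
        rs = interval_rates(traj)
        t.append(rs.axis_values)
        r.append(rs.mean_rate_um_per_s)
        x.append(traj.normalized_lengths[:-1])
        Lc.append(np.full(rs.axis_values.size, traj.cell.length_um))
        cable.append(np.full(rs.axis_values.size, i))
    return (
        np.concatenate(t),
        np.concatenate(r),
        np.concatenate(x),
        np.concatenate(Lc),
        np.concatenate(cable),
    )


# ---------------------------------------------------------------------------
# results


@dataclass
class CableGrowthResults:
    """Estimates of f(0) and f'(0) with clustered uncertainties.

    Attributes
    ----------
    f0, fprime0 : float
        Point estimates of the initial rate (µm/s) and feedback slope.
    cov : ndarray (2, 2)
        Cable-clustered sandwich covariance of (f0, fprime0).
    """

    f0: float
    fprime0: float
    cov: np.ndarray
    n_obs: int
    n_cables: int
    sse: float
    method: str
    family: str
    resid: np.ndarray = field(repr=False)
    cell_lengths: np.ndarray = field(repr=False)
    cable_index: np.ndarray = field(repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"f0": self.f0, "fprime0": self.fprime0}

    @property
    def bse(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.cov))
        return {"f0": float(se[0]), "fprime0": float(se[1])}

    @property
    def x_star(self) -> float:
        """Implied normalized steady-state length −f0/f'(0)."""
        return -self.f0 / self.fprime0

    @property
    def df_resid(self) -> int:
        return max(self.n_cables - 2, 1)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """t-based confidence intervals (clustered df = n_cables − 2)."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        out = {}
        for name, est in self.params.items():
            half = tcrit * self.bse[name]
            out[name] = (est - half, est + half)
        return out

    def initial_deceleration(self, cell: CellGeometry) -> float:
        """Implied d0 = f0 f'(0) / L_cell for a given cell, µm/s²."""
        return self.f0 * self.fprime0 / cell.length_um

    def steady_state_length(self, cell: CellGeometry) -> float:
        """Implied steady-state cable length x*·L_cell, µm."""
        return self.x_star * cell.length_um

    def feedback_params(self) -> FeedbackParams:
        """Fitted parameters as a :class:`FeedbackParams` of the fit family."""
        if self.family == GRADIENT_LINEAR:
            return FeedbackParams.gradient_linear(self.f0, -self.fprime0)
        return FeedbackParams.linear(self.f0, fprime0=self.fprime0)

    def predict(self, cell: CellGeometry, times_s) -> np.ndarray:
        """Fitted mean length curve for a cable growing in ``cell``."""
        t = np.asarray(times_s, dtype=float)
        L = cell.length_um
        return L * (self.f0 / self.fprime0) * np.expm1(self.fprime0 * t / L)

    def residuals_by_cell(self) -> pd.DataFrame:
        """Per-cable mean residual vs cell length (misfit diagnostic)."""
        df = pd.DataFrame(
            {
                "cable": self.cable_index,
                "cell_length_um": self.cell_lengths,
                "resid": self.resid,
            }
        )
        return (
            df.groupby("cable")
            .agg(cell_length_um=("cell_length_um", "first"), mean_resid=("resid", "mean"))
            .reset_index()
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Cable growth model (balance-point, early-time solution)",
            f"  method: {self.method} space, family: {self.family}",
            f"  cables: {self.n_cables}   observations: {self.n_obs}   SSE: {self.sse:.4g}",
            "",
            f"  {'param':>8} {'estimate':>10} {'std err':>10} {'[0.025':>10} {'0.975]':>10}",
        ]
        for name in ("f0", "fprime0"):
            lo, hi = ci[name]
            lines.append(
                f"  {name:>8} {self.params[name]:>10.4f} {self.bse[name]:>10.4f} "
                f"{lo:>10.4f} {hi:>10.4f}"
            )
        lines.append("")
        lines.append(f"  implied x* = -f0/f'(0) = {self.x_star:.4f}")
        return "\n".join(lines)


def _clustered_cov(J: np.ndarray, resid: np.ndarray, cable: np.ndarray) -> np.ndarray:
    bread = np.linalg.inv(J.T @ J)
    meat = np.zeros((J.shape[1], J.shape[1]))
    groups = np.unique(cable)
    for g in groups:
        m = cable == g
        s = J[m].T @ resid[m]
        meat += np.outer(s, s)
    G = groups.size
    correction = G / max(G - 1, 1)
    return correction * bread @ meat @ bread


# ---------------------------------------------------------------------------
# model


class CableGrowthModel:
    """Balance-point growth model for a set of cable trajectories.

    Parameters
    ----------
    trajectories : sequence of Trajectory
        Each with ≥ 4 frames and a cell of known length.
    family : {"linear", "gradient_linear"}
        Feedback family the fitted (f0, f'(0)) pair is reported as; the
        two are observationally equivalent at early times.  The boundary
        family has no smooth rate decay to fit — use :func:`select_model`.
    """

    def __init__(self, trajectories: Sequence[Trajectory], family: str = LINEAR):
        if family not in (LINEAR, GRADIENT_LINEAR):
            raise UnsupportedFamilyError(
                f"family {family!r} cannot be fit from early-time kinetics; "
                "use select_model for the boundary family"
            )
        trajectories = list(trajectories)
        if not trajectories:
            raise ValidationError("need at least one trajectory")
        if all(t.n_frames < 4 for t in trajectories):
            raise ValidationError("need at least one trajectory with >= 4 frames")
        self.trajectories = trajectories
        self.family = family

    @classmethod
    def from_dataframes(
        cls,
        trajectories: pd.DataFrame,
        cells: pd.DataFrame,
        family: str = LINEAR,
    ) -> "CableGrowthModel":
        """Build from tidy tables (the on-disk CSV dialects).

        ``trajectories`` needs columns cable_id, cell_id, time_s,
        length_um; ``cells`` needs cell_id, length_um, width_um,
        height_um (strain optional).
        """
        from .io import tables_to_trajectories

        return cls(tables_to_trajectories(trajectories, cells), family=family)

    # -- fitting ----------------------------------------------------------

    def _start_values(self) -> tuple[float, float]:
        t, r, x, Lc, cable = _stack_rates(self.trajectories)
        first = [interval_rates(tr).mean_rate_um_per_s[0] for tr in self.trajectories]
        f0 = max(float(np.mean(first)), 1e-3)
        if np.ptp(x) > 0:
            slope = float(np.polyfit(x, r, 1)[0])
        else:
            slope = -f0
        b = slope if slope < -1e-6 else -f0
        return f0, b

    def fit(
        self,
        method: str = "length",
        n_starts: int = 5,
        seed: int = 0,
        start: Optional[tuple[float, float]] = None,
    ) -> CableGrowthResults:
        """Estimate (f0, f'(0)) by least squares.

        method="length" (default) fits observed lengths to the early-time
        length solution; method="rate" regresses per-interval rates on
        normalized length (linear-family cross-check).  Multi-start
        (``n_starts`` seeded perturbations around a data-driven start)
        guards against local minima.
        """
        if method == "rate":
            return self._fit_rate_space()
        if method != "length":
            raise ValidationError("method must be 'length' or 'rate'")
        t, L, Lc, cable = _stack_lengths(self.trajectories)

        def residual(theta):
            f0, b = theta
            return Lc * (f0 / b) * np.expm1(b * t / Lc) - L

        def jac(theta):
            f0, b = theta
            u = b * t / Lc
            d_f0 = (Lc / b) * np.expm1(u)
            d_b = f0 * (t * np.exp(u) / b - (Lc / b**2) * np.expm1(u))
            return np.column_stack([d_f0, d_b])

        theta0 = np.array(start if start is not None else self._start_values())
        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(theta0 * rng.uniform(0.5, 1.5, size=2))
        best = None
        for s in starts:
            s = np.array([max(s[0], 1e-6), min(s[1], -1e-8)])
            try:
                sol = optimize.least_squares(
                    residual,
                    s,
                    jac=jac,
                    bounds=([1e-8, -np.inf], [np.inf, -1e-10]),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:  # singular start; try the next one
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise EstimationError("length-space fit failed to converge")
        f0_hat, b_hat = best.x
        r = residual(best.x)
        J = jac(best.x)
        cov = _clustered_cov(J, r, cable)
        return CableGrowthResults(
            f0=float(f0_hat),
            fprime0=float(b_hat),
            cov=cov,
            n_obs=t.size,
            n_cables=len(self.trajectories),
            sse=float(np.sum(r**2)),
            method="length",
            family=self.family,
            resid=r,
            cell_lengths=Lc,
            cable_index=cable,
        )

    def _fit_rate_space(self) -> CableGrowthResults:
        # regress interval rates on the interval-midpoint normalized length:
        # midpoint attribution cancels the interval-averaging attenuation of
        # the slope almost exactly (to <1% at 3 s frames)
        t, r, x, Lc, cable = [], [], [], [], []
        for i, traj in enumerate(self.trajectories):
            rs = interval_rates(traj)
            xn = traj.normalized_lengths
            t.append(rs.axis_values)
            r.append(rs.mean_rate_um_per_s)
            x.append(0.5 * (xn[:-1] + xn[1:]))
            Lc.append(np.full(rs.axis_values.size, traj.cell.length_um))
            cable.append(np.full(rs.axis_values.size, i))
        t, r, x, Lc, cable = map(np.concatenate, (t, r, x, Lc, cable))
        if np.ptp(x) == 0:
            raise EstimationError("no variation in normalized length")
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
        resid = X @ beta - r
        cov = _clustered_cov(X, resid, cable)
        f0_hat, slope = beta
        if slope >= 0:
            raise EstimationError(
                "rate-space fit found a non-negative feedback slope; "
                "data show no deceleration"
            )
        return CableGrowthResults(
            f0=float(f0_hat),
            fprime0=float(slope),
            cov=cov,
            n_obs=r.size,
            n_cables=len(self.trajectories),
            sse=float(np.sum(resid**2)),
            method="rate",
            family=self.family,
            resid=resid,
            cell_lengths=Lc,
            cable_index=cable,
        )


def fit_feedback(
    trajectories: Sequence[Trajectory],
    family: str = LINEAR,
    method: str = "length",
    **kwargs,
) -> tuple[FeedbackParams, CableGrowthResults]:
    """Convenience wrapper: fit and return (FeedbackParams, results)."""
    res = CableGrowthModel(trajectories, family=family).fit(method=method, **kwargs)
    return res.feedback_params(), res


# ---------------------------------------------------------------------------
# model selection


@dataclass(frozen=True)
class ModelSelectionResult:
    """Outcome of balance-point vs boundary-sensing discrimination.

    ``delta_bic`` is BIC(balance) − BIC(boundary); negative favours the
    balance-point model.  ``tie`` flags degenerate data (all rates equal),
    resolved toward boundary sensing by parsimony.
    """

    chosen: str
    delta_bic: float
    per_model_sse: dict[str, float]
    n_obs: int
    tie: bool = False

    def __post_init__(self) -> None:
        if self.chosen not in (BALANCE_POINT, BOUNDARY_SENSING):
            raise ValidationError(f"unknown model label {self.chosen!r}")
        if self.n_obs < 4:
            raise ValidationError("need at least 4 observations")


def _fit_balance_rates(t, r, Lc) -> tuple[float, np.ndarray]:
    """SSE of rate(t) = g0 exp(g1 t / L_cell) by least squares."""

    def residual(theta):
        g0, g1 = theta
        return g0 * np.exp(g1 * t / Lc) - r

    def jac(theta):
        g0, g1 = theta
        e = np.exp(g1 * t / Lc)
        return np.column_stack([e, g0 * (t / Lc) * e])

    g0_start = max(float(np.mean(r[t == t.min()])), 1e-3)
    sol = optimize.least_squares(
        residual,
        [g0_start, -g0_start],
        jac=jac,
        bounds=([1e-8, -np.inf], [np.inf, -1e-12]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not sol.success:
        raise EstimationError("balance-point rate fit failed")
    return float(2 * sol.cost), sol.x


def _fit_boundary_rates(x, r) -> tuple[float, float]:
    """Constant-then-stop fit: rate = f0 for x < x_max, else 0.

    The changepoint is found by exhaustive search over the sorted
    normalized lengths (prefix sums make this O(n log n)).
    Returns (SSE, fitted x_max).
    """
    order = np.argsort(x)
    xs, rs = x[order], r[order]
    n = rs.size
    c1 = np.cumsum(rs)
    c2 = np.cumsum(rs**2)
    total2 = c2[-1]
    k = np.arange(1, n + 1)
    # first k observations growing at f0 = mean(r[:k]); the rest stopped
    sse = (c2 - c1**2 / k) + (total2 - c2)
    k_best = int(np.argmin(sse))
    if k_best == n - 1:
        x_max = float(xs[-1]) * 1.01 + 1e-9
    else:
        x_max = float(0.5 * (xs[k_best] + xs[k_best + 1]))
    return float(sse[k_best]), x_max


def select_model(
    trajectories: Sequence[Trajectory], criterion: str = "bic"
) -> ModelSelectionResult:
    """Discriminate balance-point vs boundary-sensing rate profiles.

    Both models are fitted to the pooled per-interval rates by least
    squares (each has two shape parameters) and compared with a
    Gaussian-likelihood BIC (AIC with ``criterion="aic"``).
    """
    if criterion not in ("bic", "aic"):
        raise ValidationError("criterion must be 'bic' or 'aic'")
    t, r, x, Lc, cable = _stack_rates(list(trajectories))
    n = r.size
    if n < 4:
        raise ValidationError("need at least 4 interval rates")
    if np.ptp(r) < 1e-12:
        return ModelSelectionResult(
            chosen=BOUNDARY_SENSING,
            delta_bic=0.0,
            per_model_sse={BALANCE_POINT: 0.0, BOUNDARY_SENSING: 0.0},
            n_obs=n,
            tie=True,
        )
    sse_bal, _ = _fit_balance_rates(t, r, Lc)
    sse_bnd, _ = _fit_boundary_rates(x, r)
    k = 2
    penalty = k * np.log(n) if criterion == "bic" else 2 * k
    ic_bal = n * np.log(max(sse_bal, 1e-300) / n) + penalty
    ic_bnd = n * np.log(max(sse_bnd, 1e-300) / n) + penalty
    delta = float(ic_bal - ic_bnd)
    return ModelSelectionResult(
        chosen=BALANCE_POINT if delta < 0 else BOUNDARY_SENSING,
        delta_bic=delta,
        per_model_sse={BALANCE_POINT: sse_bal, BOUNDARY_SENSING: sse_bnd},
        n_obs=n,
    )
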