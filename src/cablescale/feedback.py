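"""Balance-point feedback families and their closed-form kinetics.

The net extension rate of an actin cable is modelled as the difference
between its assembly and disassembly rates, expressed as a *feedback
function* of the normalized cable length ``x = L_cable / L_cell``::

    dL_cable/dt = f(L_cable / L_cell)

Because f depends only on the ratio, the model is scale-invariant: the
steady-state cable length ``L* = x* L_cell`` (where ``f(x*) = 0``) is
proportional to cell length, and the early-time kinetics obey

    L_cable(t) = L_cell * (f(0)/f'(0)) * (exp(f'(0) t / L_cell) - 1)
    dL/dt(t)   = f(0) * exp(f'(0) t / L_cell)

with initial deceleration ``d0 = f(0) f'(0) / L_cell`` — inversely
proportional to cell length and proportional to the initial rate.

Four concrete families are provided:

``linear``
    f(x) = f0 (1 - x/x_star).  Realises the early-time formulas exactly.
``gradient_linear``
    f(x) = f0 - k_dis * x: constant assembly minus a disassembly rate that
    rises linearly toward the rear of the cell.
``gradient_exp``
    f(x) = f0 - A exp((x-1)/lam), A = f0 exp((1-x_star)/lam): constant
    assembly minus an exponential disassembly gradient that is highest at
    the rear (x = 1), normalised so f(x_star) = 0.  Note f(0) < f0 for this
    family; use :attr:`FeedbackParams.rate_at_zero`.
``boundary``
    f(x) = f0 for x < L_max_ratio, else 0: the boundary-sensing
    alternative, in which growth is constant until the tip reaches the
    rear of the cell.

Units are µm and s throughout; rates µm/s, decelerations µm/s².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    ConfigurationError,
    UnsupportedFamilyError,
    ValidationError,
)
from .geometry import CellGeometry

LINEAR = "linear"
GRADIENT_LINEAR = "gradient_linear"
GRADIENT_EXP = "gradient_exp"
BOUNDARY = "boundary"
FAMILIES = (LINEAR, GRADIENT_LINEAR, GRADIENT_EXP, BOUNDARY)

#: Families for which the early-time closed forms are exact (f linear in x).
_EXACTLY_LINEAR = (LINEAR, GRADIENT_LINEAR)


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of one feedback family.

    Prefer the family constructors (:meth:`linear`, :meth:`gradient_linear`,
    :meth:`gradient_exp`, :meth:`boundary`) over direct construction; they
    derive the dependent parameters and validate consistency.

    Attributes
    ----------
    family : str
        One of ``FAMILIES``.
    f0 : float
        Initial/constant net assembly rate, µm/s.  Equals f(0) for all
        families except ``gradient_exp`` (see module docstring).
    x_star : float, optional
        Normalized steady-state length (zero of f).
    fprime0 : float, optional
        Feedback slope f'(0), µm/s, negative.  For the linear family this
        is exactly −f0/x_star.
    k_dis : float, optional
        Disassembly slope for ``gradient_linear``, µm/s per unit x.
    lam : float, optional
        Dimensionless decay length of the ``gradient_exp`` gradient.
    L_max_ratio : float, optional
        Normalized stopping length for the ``boundary`` family.
    """

    family: str
    f0: float
    x_star: Optional[float] = None
    fprime0: Optional[float] = None
    k_dis: Optional[float] = None
    lam: Optional[float] = None
    L_max_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown feedback family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.f0 > 0:
            raise ValidationError(f"f0 must be > 0, got {self.f0}")
        if self.family == LINEAR:
            if self.x_star is None or self.fprime0 is None:
                raise ConfigurationError(
                    "linear family needs x_star and fprime0; use FeedbackParams.linear()"
                )
            if not self.x_star > 0:
                raise ValidationError(f"x_star must be > 0, got {self.x_star}")
            if not self.fprime0 < 0:
                raise ValidationError(f"fprime0 must be < 0, got {self.fprime0}")
            if not math.isclose(self.fprime0, -self.f0 / self.x_star, rel_tol=1e-9):
                raise ConfigurationError(
                    "linear family requires fprime0 == -f0/x_star "
                    f"(got fprime0={self.fprime0}, -f0/x_star={-self.f0 / self.x_star})"
                )
        elif self.family == GRADIENT_LINEAR:
            if self.k_dis is None or not self.k_dis > 0:
                raise ValidationError(f"k_dis must be > 0, got {self.k_dis}")
        elif self.family == GRADIENT_EXP:
            if self.x_star is None or not self.x_star > 0:
                raise ValidationError(f"x_star must be > 0, got {self.x_star}")
            if self.lam is None or not self.lam > 0:
                raise ValidationError(f"lam must be > 0, got {self.lam}")
        elif self.family == BOUNDARY:
            if self.L_max_ratio is None or not self.L_max_ratio >= 0:
                raise ValidationError(
                    f"L_max_ratio must be >= 0, got {self.L_max_ratio}"
                )

    # -- constructors -----------------------------------------------------

    @classmethod
    def linear(
        cls,
        f0: float,
        x_star: Optional[float] = None,
        fprime0: Optional[float] = None,
    ) -> "FeedbackParams":
        """Linear feedback f(x) = f0 (1 − x/x_star).

        Exactly one of ``x_star`` / ``fprime0`` may be omitted; the other is
        derived from f'(0) = −f0/x_star.  Supplying ``fprime0`` lets the
        slope be held fixed while the initial rate varies across strains.
        """
        if x_star is None and fprime0 is None:
            raise ConfigurationError("linear family needs x_star or fprime0")
        if x_star is None:
            x_star = -f0 / fprime0  # type: ignore[operator]
        if fprime0 is None:
            fprime0 = -f0 / x_star
        return cls(family=LINEAR, f0=f0, x_star=x_star, fprime0=fprime0)

    @classmethod
    def gradient_linear(cls, f0: float, k_dis: float) -> "FeedbackParams":
        """Constant assembly minus linear disassembly gradient, x* = f0/k_dis."""
        return cls(
            family=GRADIENT_LINEAR,
            f0=f0,
            k_dis=k_dis,
            x_star=f0 / k_dis,
            fprime0=-k_dis,
        )

    @classmethod
    def gradient_exp(cls, f0: float, x_star: float, lam: float) -> "FeedbackParams":
        """Constant assembly minus exponential disassembly gradient.

        The gradient amplitude is normalised so that f(x_star) = 0.
        """
        return cls(family=GRADIENT_EXP, f0=f0, x_star=x_star, lam=lam)

    @classmethod
    def boundary(cls, f0: float, L_max_ratio: float = 1.0) -> "FeedbackParams":
        """Boundary-sensing family: constant rate f0 until x reaches L_max_ratio."""
        return cls(family=BOUNDARY, f0=f0, L_max_ratio=L_max_ratio)

    # -- derived quantities ----------------------------------------------

    @property
    def rate_at_zero(self) -> float:
        """f(0), the initial extension rate, µm/s."""
        if self.family == GRADIENT_EXP:
            return self.f0 * (1.0 - math.exp(-self.x_star / self.lam))
        return self.f0

    @property
    def slope_at_zero(self) -> float:
        """f'(0), µm/s (negative; 0 for the boundary family pre-contact)."""
        if self.family == LINEAR:
            return self.fprime0
        if self.family == GRADIENT_LINEAR:
            return -self.k_dis
        if self.family == GRADIENT_EXP:
            return -(self.f0 / self.lam) * math.exp(-self.x_star / self.lam)
        return 0.0

    @property
    def slope_at_xstar(self) -> float:
        """f'(x*), the restoring-force slope at steady state, µm/s."""
        if self.family == LINEAR:
            return self.fprime0
        if self.family == GRADIENT_LINEAR:
            return -self.k_dis
        if self.family == GRADIENT_EXP:
            return -self.f0 / self.lam
        raise UnsupportedFamilyError(
            "boundary family has no differentiable steady state"
        )


def feedback_rate(params: FeedbackParams, x):
    """Evaluate the feedback function f(x) at normalized length(s) x.

    Parameters
    ----------
    params : FeedbackParams
    x : float or array_like
        Normalized cable length L_cable/L_cell, ≥ 0.

    Returns
    -------
    float or ndarray, µm/s.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValidationError("normalized length x must be >= 0")
    fam = params.family
    if fam == LINEAR:
        out = params.f0 * (1.0 - x_arr / params.x_star)
    elif fam == GRADIENT_LINEAR:
        out = params.f0 - params.k_dis * x_arr
    elif fam == GRADIENT_EXP:
        amp = params.f0 * math.exp((1.0 - params.x_star) / params.lam)
        out = params.f0 - amp * np.exp((x_arr - 1.0) / params.lam)
    elif fam == BOUNDARY:
        out = np.where(x_arr < params.L_max_ratio, params.f0, 0.0)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"unknown family {fam!r}")
    return out if np.ndim(x) else float(out)


def extension_rate(params: FeedbackParams, L_cable: float, cell: CellGeometry):
    """dL_cable/dt for a cable of length L_cable (µm) in the given cell."""
    L_arr = np.asarray(L_cable, dtype=float)
    if np.any(L_arr < 0):
        raise ValidationError("cable length must be >= 0")
    return feedback_rate(params, L_arr / cell.length_um)


def _early_time_coeffs(params: FeedbackParams) -> tuple[float, float]:
    if params.family == BOUNDARY:
        raise UnsupportedFamilyError(
            "closed-form kinetics are undefined for the boundary family "
            "(rate is piecewise constant)"
        )
    g0, g1 = params.rate_at_zero, params.slope_at_zero
    if not g1 < 0:
        raise ConfigurationError("closed forms require f'(0) < 0")
    return g0, g1


def closed_form_length(params: FeedbackParams, cell: CellGeometry, t):
    """Cable length L(t) from the early-time solution (exact for linear f).

    L(t) = L_cell (f(0)/f'(0)) (exp(f'(0) t / L_cell) − 1), with L(0)=0.
    For the ``linear`` and ``gradient_linear`` families f is exactly linear
    in x, so this is the exact solution for all t; for ``gradient_exp`` it
    is an early-time approximation.
    """
    g0, g1 = _early_time_coeffs(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    L = cell.length_um
    out = L * (g0 / g1) * np.expm1(g1 * t_arr / L)
    return out if np.ndim(t) else float(out)


def closed_form_rate(params: FeedbackParams, cell: CellGeometry, t):
    """Extension rate dL/dt(t) = f(0) exp(f'(0) t / L_cell), µm/s."""
    g0, g1 = _early_time_coeffs(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    out = g0 * np.exp(g1 * t_arr / cell.length_um)
    return out if np.ndim(t) else float(out)


def initial_deceleration(params: FeedbackParams, cell: CellGeometry) -> float:
    """Initial deceleration d0 = f(0) f'(0) / L_cell, µm/s² (negative).

    d0 scales inversely with cell length and proportionally with the
    initial extension rate — the two ratio predictions tested on
    cdc28-13ts (cell length doubled) and smy1Δ (initial rate raised).
    """
    g0, g1 = _early_time_coeffs(params)
    return g0 * g1 / cell.length_um


def steady_state_length(params: FeedbackParams, cell: CellGeometry) -> float:
    """Steady-state cable length L* = x* L_cell, µm.

    Analytic for the linear families; for ``gradient_exp`` the zero of f is
    located by bracketed root-finding (relative tolerance 1e−10) as an
    internal consistency check of the parameterisation.  The boundary
    family stops at L_max_ratio · L_cell.
    """
    L = cell.length_um
    if params.family in (LINEAR, GRADIENT_LINEAR):
        return params.x_star * L
    if params.family == BOUNDARY:
        return params.L_max_ratio * L
    # gradient_exp: bracket (tiny, 10 * x_star]
    lo, hi = 1e-12, 10.0 * params.x_star
    f_lo, f_hi = feedback_rate(params, lo), feedback_rate(params, hi)
    if not (f_lo > 0 and f_hi < 0):
        raise ConfigurationError(
            "feedback has no sign change in (0, 10*x_star]; cannot locate x*"
        )
    x_root = brentq(lambda x: feedback_rate(params, x), lo, hi, rtol=1e-12)
    return x_root * L
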