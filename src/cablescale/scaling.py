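"""Allometric power-law scaling of cable length with cell dimensions.

Scaling relations are modelled as y = A x^a and fitted by ordinary least
squares of log10(y) on log10(x); the exponent a is the slope and the
prefactor A = 10^intercept.  An exponent near 1 against cell length is
isometric scaling; an exponent near 1/3 against cell volume is the
hypoallometric signature of a structure that tracks a linear dimension
rather than volume.

No errors-in-variables correction is applied: noise in x attenuates the
fitted exponent toward zero, as it would in the plain double-log fits this
module reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateFitError, ValidationError
from .geometry import CellGeometry


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log power-law fit y = A x^a."""

    exponent_a: float
    prefactor_A: float
    r_squared: float
    a_ci95_halfwidth: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared must lie in [0,1], got {self.r_squared}")
        if self.n < 3:
            raise ValidationError(f"need n >= 3, got {self.n}")


def power_law_fit(x, y) -> PowerLawFit:
    """Fit y = A x^a by OLS in double-log space.

    Both arrays must be positive with at least 3 points; the 95% CI on the
    exponent comes from the slope standard error and a t critical value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("power-law fit requires strictly positive values")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise DegenerateFitError("zero variance in x: exponent not identifiable")
    res = stats.linregress(lx, ly)
    df = x.size - 2
    ci = float(stats.t.ppf(0.975, df) * res.stderr) if df > 0 else float("inf")
    return PowerLawFit(
        exponent_a=float(res.slope),
        prefactor_A=float(10.0**res.intercept),
        r_squared=float(min(res.rvalue**2, 1.0)),
        a_ci95_halfwidth=ci,
        n=int(x.size),
    )


def aspect_ratio_class(aspect: float) -> float:
    """Aspect ratio rounded to the nearest quarter (midpoints round up)."""
    return math.floor(aspect / 0.25 + 0.5) * 0.25


def scaling_by_shape_class(
    cells: Sequence[CellGeometry], cable_lengths_um
) -> dict[float, dict]:
    """Per-aspect-ratio-class power-law fits of cable vs cell length.

    Cells are binned by aspect ratio rounded to the nearest quarter value.
    Each class reports its n, the mean cable/cell length ratio, and a
    :class:`PowerLawFit` (``None``, flagged, when n < 3).
    """
    cable = np.asarray(cable_lengths_um, dtype=float)
    if len(cells) != cable.size:
        raise ValidationError("cells and cable_lengths must be paired")
    classes: dict[float, list[int]] = {}
    for i, cell in enumerate(cells):
        classes.setdefault(aspect_ratio_class(cell.aspect_ratio), []).append(i)
    out: dict[float, dict] = {}
    for cls in sorted(classes):
        idx = np.array(classes[cls])
        cell_L = np.array([cells[i].length_um for i in idx])
        cab_L = cable[idx]
        entry: dict = {
            "n": int(idx.size),
            "mean_ratio": float(np.mean(cab_L / cell_L)),
            "fit": None,
            "too_few_for_fit": idx.size < 3,
        }
        if idx.size >= 3:
            try:
                entry["fit"] = power_law_fit(cell_L, cab_L)
                entry["too_few_for_fit"] = False
            except DegenerateFitError:
                entry["fit"] = None
        out[cls] = entry
    return out
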