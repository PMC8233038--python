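"""Mother-cell geometry and derived morphometrics.

Cell length is measured from the bud neck to the distal end of the mother
cell, width at the widest point perpendicular to the length axis, and
height axially; the cell is treated as an ellipsoid with those three
extents as diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class CellGeometry:
    """One mother cell: the three measured extents (µm) and a strain label."""

    length_um: float
    width_um: float
    height_um: float
    strain: str = ""

    def __post_init__(self) -> None:
        for name in ("length_um", "width_um", "height_um"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")

    @property
    def volume_um3(self) -> float:
        """Ellipsoid volume (π/6)·L·W·H with the extents as diameters, µm³."""
        return math.pi / 6.0 * self.length_um * self.width_um * self.height_um

    @property
    def aspect_ratio(self) -> float:
        """Cell length / cell width (dimensionless)."""
        return self.length_um / self.width_um

    def cortical_path_length(self) -> float:
        """Neck-to-rear arc along the cortex, µm.

        Cables grow along the cortex of an ellipsoid cell, so their length
        can exceed the straight neck-to-rear distance.  The arc is half the
        perimeter of the meridian ellipse with semi-axes (length/2,
        width/2), computed with Ramanujan's second approximation (error
        below 1e−5 of the perimeter for the relevant eccentricities).
        """
        a = self.length_um / 2.0
        b = self.width_um / 2.0
        h = ((a - b) / (a + b)) ** 2
        perimeter = math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))
        return perimeter / 2.0


def cell_metrics(cell: CellGeometry) -> dict:
    """Volume (µm³) and aspect ratio for one cell, as a small dict."""
    return {"volume_um3": cell.volume_um3, "aspect_ratio": cell.aspect_ratio}


def cortical_path_length(cell: CellGeometry) -> float:
    """Functional alias for :meth:`CellGeometry.cortical_path_length`."""
    return cell.cortical_path_length()
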