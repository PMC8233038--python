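"""Cable tip trajectories: time-stamped lengths for one growing cable."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ValidationError
from .geometry import CellGeometry


@dataclass(frozen=True)
class CableState:
    """Instantaneous state of a cable: length (µm) at elapsed time (s)."""

    length_um: float
    time_s: float

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise ValidationError(f"length_um must be >= 0, got {self.length_um}")
        if self.time_s < 0:
            raise ValidationError(f"time_s must be >= 0, got {self.time_s}")


@dataclass
class Trajectory:
    """Observed (or simulated) lengths of one cable over time.

    times_s must be strictly increasing; lengths_um non-negative and the
    same length.  ``tip_xy_um`` optionally carries per-frame tip
    coordinates (n, 2).  ``cell`` is the mother cell the cable grew in.
    """

    cable_id: str
    times_s: np.ndarray
    lengths_um: np.ndarray
    cell: CellGeometry
    tip_xy_um: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.times_s.shape != self.lengths_um.shape:
            raise ValidationError(
                f"times ({self.times_s.shape}) and lengths ({self.lengths_um.shape}) "
                "must have equal shape"
            )
        if self.times_s.size < 1:
            raise ValidationError("trajectory needs at least one frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.lengths_um < 0):
            raise ValidationError("lengths must be non-negative")
        if self.tip_xy_um is not None:
            self.tip_xy_um = np.asarray(self.tip_xy_um, dtype=float)
            if self.tip_xy_um.shape[0] != self.times_s.size:
                raise ValidationError("tip_xy_um must have one row per frame")

    @property
    def n_frames(self) -> int:
        return self.times_s.size

    @property
    def normalized_lengths(self) -> np.ndarray:
        """L_cable / L_cell per frame (dimensionless)."""
        return self.lengths_um / self.cell.length_um
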