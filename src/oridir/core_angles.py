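"""Angle conventions, angular arithmetic, and trial-response containers.

All angles are in degrees throughout the package. The canonical stimulus
convention is "compass" coordinates: a horizontal bar moving upward is 0°
and angles increase clockwise. Direction space covers [0, 360); orientation
space covers [0, 180) (a bar and the same bar moving the opposite way share
one orientation). Trigonometry happens in radians at call sites only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidArgumentError

#: Valid angle-space flags.
ORIENTATION = "orientation"
DIRECTION = "direction"

_PERIODS = {ORIENTATION: 180.0, DIRECTION: 360.0}

#: Absolute tolerance (degrees) when matching grid angles.
ANGLE_MATCH_TOL = 1e-9


def period_of(space: str) -> float:
    """Angular period of a space: 360° for direction, 180° for orientation."""
    try:
        return _PERIODS[space]
    except KeyError:
        raise InvalidArgumentError(
            f"space must be {ORIENTATION!r} or {DIRECTION!r}, got {space!r}"
        ) from None


def convert_coordinates(angle: float) -> float:
    """Convert between compass and Cartesian angle conventions.

    The mapping is its own inverse: ``theta_cartesian = 90° - theta_compass``
    and vice versa. The result is wrapped to [0, 360).

    Parameters
    ----------
    angle : float
        Angle in degrees, in either convention.

    Returns
    -------
    float
        The same physical angle expressed in the other convention.
    """
    angle = _require_finite(angle)
    return float(np.mod(90.0 - angle, 360.0))


def angular_sum(a, b, space: str = DIRECTION):
    """Add two angles modulo the period of *space*.

    In direction space angles are summed modulo 360° (359° + 2° = 1°);
    in orientation space modulo 180°.
    """
    a = _require_finite(a)
    b = _require_finite(b)
    return np.mod(np.asarray(a, dtype=float) + b, period_of(space))[()]


def ang_diff(x, space: str = DIRECTION):
    """Minimal absolute wrapped angular difference.

    Wraps *x* onto [0, 90°] in orientation space or [0, 180°] in direction
    space: ``min(|x|, |x - P|, |x + P|)`` with P the period of *space*.
    """
    x = _require_finite(x)
    p = period_of(space)
    y = np.mod(np.abs(np.asarray(x, dtype=float)), p)
    return np.minimum(y, p - y)[()]


def _require_finite(x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("angle arguments must be finite")
    return x


@dataclass(frozen=True)
class AngleGrid:
    """Ordered set of stimulus angles with its angle space.

    Attributes
    ----------
    angles : ndarray
        Strictly increasing angles in degrees, all inside [0, period).
    space : str
        ``"orientation"`` or ``"direction"``.
    """

    angles: np.ndarray
    space: str = DIRECTION

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise InvalidArgumentError("grid needs a 1-D, nonempty angle list")
        if not np.all(np.isfinite(angles)):
            raise InvalidArgumentError("grid angles must be finite")
        if np.any(np.diff(angles) <= 0):
            raise InvalidArgumentError("grid angles must be strictly increasing")
        p = period_of(self.space)
        if angles[0] < 0 or angles[-1] >= p:
            raise InvalidArgumentError(
                f"{self.space}-space angles must lie in [0, {p:g})"
            )
        object.__setattr__(self, "angles", angles)

    def __len__(self) -> int:
        return self.angles.size

    @property
    def step_alpha(self) -> float:
        """Angle step α in degrees (minimum spacing for unequal grids).

        For a single-angle grid the full period is returned, the only
        spacing consistent with wrapping.
        """
        if len(self) == 1:
            return period_of(self.space)
        return float(np.min(np.diff(self.angles)))

    @property
    def is_equally_spaced(self) -> bool:
        diffs = np.diff(self.angles)
        return diffs.size == 0 or bool(np.allclose(diffs, diffs[0]))

    def index_of(self, angle: float, tol: float | None = None):
        """Index of the grid angle closest to *angle* (wrapped), or None
        if the nearest angle is further away than *tol* (default α/2)."""
        if tol is None:
            tol = self.step_alpha / 2.0
        d = ang_diff(self.angles - angle, self.space)
        k = int(np.argmin(d))
        return k if d[k] <= tol + ANGLE_MATCH_TOL else None


@dataclass(frozen=True)
class TrialResponses:
    """Trial-by-angle matrix of blank-subtracted responses.

    Rows are trials, columns follow ``grid.angles``. Values are in response
    units (Hz for spike data); negative values are legitimate because the
    blank (background) response has been subtracted.
    """

    values: np.ndarray
    grid: AngleGrid
    blank_mean: float | None = field(default=None)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[0] < 1:
            raise InvalidArgumentError("need at least one trial")
        if values.shape[1] != len(self.grid):
            raise InvalidArgumentError(
                f"response matrix has {values.shape[1]} columns but the grid "
                f"has {len(self.grid)} angles"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("responses must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def mean_responses(self) -> np.ndarray:
        """Trial-averaged response at each grid angle."""
        return self.values.mean(axis=0)


def collapse_to_orientation(tr: TrialResponses) -> TrialResponses:
    """Average opposite-direction responses into orientation space.

    Every direction θ < 180° must have its partner θ + 180° on the grid;
    per trial the orientation response at θ is the mean of the responses at
    θ and θ + 180°. The grid halves and becomes orientation space.
    """
    if tr.grid.space != DIRECTION:
        raise GridMismatchError("collapse_to_orientation needs a direction-space grid")
    angles = tr.grid.angles
    low = angles[angles < 180.0 - ANGLE_MATCH_TOL]
    if 2 * low.size != angles.size:
        raise GridMismatchError("direction grid is not composed of opposite pairs")
    cols_low, cols_high = [], []
    for a in low:
        j = int(np.argmin(np.abs(angles - (a + 180.0))))
        if abs(angles[j] - (a + 180.0)) > ANGLE_MATCH_TOL:
            raise GridMismatchError(f"no opposite-direction partner for {a:g}°")
        cols_low.append(int(np.argmin(np.abs(angles - a))))
        cols_high.append(j)
    values = 0.5 * (tr.values[:, cols_low] + tr.values[:, cols_high])
    grid = AngleGrid(low, ORIENTATION)
    return TrialResponses(values, grid, blank_mean=tr.blank_mean)
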