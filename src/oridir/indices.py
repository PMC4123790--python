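"""Scalar selectivity indices for orientation and direction tuning.

Two families of measures are provided. Peak–trough indices compare the
response at the empirically preferred angle with responses at the
orthogonal and opposite angles:

    OI  = (R_pref + R_null - (R_orth+ + R_orth-)) / (R_pref + R_null)   (direction space)
    OI  = (R_pref_ori - R_orth) / R_pref_ori                            (orientation space)
    DI  = (R_pref - R_null) / R_pref
    OSI = (R_pref_ori - R_orth) / (R_pref_ori + R_orth)
    DSI = (R_pref - R_null) / (R_pref + R_null)
    O/P = R_orth / R_pref_ori = 1 - OI

Vector indices are normalized resultant lengths on the complex plane:

    L_ori = |Σ_k R(θ_k) e^{2iθ_k}| / |Σ_k R(θ_k)|   (= 1 - CirVar)
    L_dir = |Σ_k R(θ_k) e^{iθ_k}|  / |Σ_k R(θ_k)|   (= 1 - DirCirVar)

The direction-space resultant deliberately omits the classical factor of 2
so that maximal selectivity gives 1. Negative (below-background) responses
enter all formulas unmodified, so OI can exceed 1 — that is a feature of
the measure, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_angles import (
    DIRECTION,
    ORIENTATION,
    AngleGrid,
    TrialResponses,
    angular_sum,
    collapse_to_orientation,
)
from .errors import InsufficientDataError, InvalidArgumentError

#: Relative tolerance below which a denominator is treated as degenerate.
DENOM_RTOL = 1e-9


@dataclass
class SelectivityIndices:
    """Bag of scalar selectivity measures for one cell.

    Indices whose denominator was degenerate, or whose required angles are
    absent from the grid, are ``None``; the reason is recorded in ``flags``.
    """

    pref_angle_empirical: float | None = None
    oi_dirspace: float | None = None
    oi_orispace: float | None = None
    di: float | None = None
    osi: float | None = None
    dsi: float | None = None
    orth_over_pref: float | None = None
    one_minus_cirvar: float | None = None
    one_minus_dircirvar: float | None = None
    flags: dict = field(default_factory=dict)

    def update(self, other: "SelectivityIndices") -> "SelectivityIndices":
        for name, value in vars(other).items():
            if name == "flags":
                self.flags.update(value)
            elif value is not None:
                setattr(self, name, value)
        return self


def empirical_preferred_angle(mean_responses, grid: AngleGrid) -> float:
    """Grid angle with the maximum trial-averaged response.

    Ties are broken toward the lowest angle (``argmax`` on an ascending
    grid does exactly that).
    """
    r = np.asarray(mean_responses, dtype=float)
    if r.size == 0:
        raise InvalidArgumentError("empty response vector")
    if r.size != len(grid):
        raise InvalidArgumentError("response vector length must match the grid")
    return float(grid.angles[int(np.argmax(r))])


def _denom_tol(r: np.ndarray) -> float:
    scale = float(np.max(np.abs(r))) if r.size else 0.0
    return DENOM_RTOL * max(scale, 1.0)


def _lookup(r, grid, angle):
    """Response at the grid angle nearest *angle*, or None if further than α/2."""
    k = grid.index_of(angle)
    return None if k is None else float(r[k])


def peak_trough_indices(mean_responses, grid: AngleGrid) -> SelectivityIndices:
    """Peak–trough indices (OI, DI, OSI, DSI, O/P) from trial means.

    On a direction grid, all direction-space measures are computed and the
    orientation-space measures are computed after collapsing opposite
    directions; on an orientation grid only the orientation-space measures
    exist. Required angles (θ_pref ± 90°, θ_pref + 180°) are taken from the
    nearest grid angle within α/2; an index whose angle is missing or whose
    denominator is degenerate comes back ``None`` with a flag.
    """
    r = np.asarray(mean_responses, dtype=float)
    out = SelectivityIndices()
    out.pref_angle_empirical = empirical_preferred_angle(r, grid)
    tol = _denom_tol(r)

    if grid.space == DIRECTION:
        th = out.pref_angle_empirical
        r_pref = _lookup(r, grid, th)
        r_null = _lookup(r, grid, angular_sum(th, 180.0, DIRECTION))
        r_op = _lookup(r, grid, angular_sum(th, 90.0, DIRECTION))
        r_om = _lookup(r, grid, angular_sum(th, -90.0, DIRECTION))
        if None in (r_null, r_op, r_om):
            out.flags["oi_dirspace"] = "required angles missing from grid"
        else:
            denom = r_pref + r_null
            if abs(denom) < tol:
                out.flags["oi_dirspace"] = "degenerate denominator"
            else:
                out.oi_dirspace = (r_pref + r_null - (r_op + r_om)) / denom
        if r_null is None:
            out.flags["di"] = "opposite direction missing from grid"
        else:
            if abs(r_pref) < tol:
                out.flags["di"] = "degenerate denominator"
            else:
                out.di = (r_pref - r_null) / r_pref
            denom = r_pref + r_null
            if abs(denom) < tol:
                out.flags["dsi"] = "degenerate denominator"
            else:
                out.dsi = (r_pref - r_null) / denom
        # Orientation-space measures from the collapsed curve.
        tr = TrialResponses(r[np.newaxis, :], grid)
        try:
            ori = collapse_to_orientation(tr)
        except Exception:
            out.flags["oi_orispace"] = "grid lacks opposite pairs"
            return out
        out.update(_orientation_peak_trough(ori.values[0], ori.grid))
        out.pref_angle_empirical = empirical_preferred_angle(r, grid)
    else:
        out.update(_orientation_peak_trough(r, grid))
    return out


def _orientation_peak_trough(r, grid: AngleGrid) -> SelectivityIndices:
    out = SelectivityIndices()
    out.pref_angle_empirical = empirical_preferred_angle(r, grid)
    tol = _denom_tol(r)
    th = out.pref_angle_empirical
    r_pref = _lookup(r, grid, th)
    r_orth = _lookup(r, grid, angular_sum(th, 90.0, ORIENTATION))
    if r_orth is None:
        out.flags["oi_orispace"] = "orthogonal orientation missing from grid"
        return out
    if abs(r_pref) < tol:
        out.flags["oi_orispace"] = "degenerate denominator"
    else:
        out.oi_orispace = (r_pref - r_orth) / r_pref
        out.orth_over_pref = r_orth / r_pref
    denom = r_pref + r_orth
    if abs(denom) < tol:
        out.flags["osi"] = "degenerate denominator"
    else:
        out.osi = (r_pref - r_orth) / denom
    return out


def circular_variance_indices(mean_responses, grid: AngleGrid) -> SelectivityIndices:
    """Normalized vector-sum lengths L_ori (1-CirVar) and L_dir (1-DirCirVar).

    On a direction grid, L_dir uses the responses as-is and L_ori uses the
    collapsed orientation curve; on an orientation grid only L_ori exists.
    A near-zero net response Σ_k R(θ_k) flags the index invalid.
    """
    r = np.asarray(mean_responses, dtype=float)
    if r.size != len(grid):
        raise InvalidArgumentError("response vector length must match the grid")
    out = SelectivityIndices()
    out.pref_angle_empirical = empirical_preferred_angle(r, grid)
    if grid.space == DIRECTION:
        out.one_minus_dircirvar, flag = _resultant_length(r, grid.angles, m=1)
        if flag:
            out.flags["one_minus_dircirvar"] = flag
        tr = TrialResponses(r[np.newaxis, :], grid)
        try:
            ori = collapse_to_orientation(tr)
        except Exception:
            out.flags["one_minus_cirvar"] = "grid lacks opposite pairs"
            return out
        out.one_minus_cirvar, flag = _resultant_length(
            ori.values[0], ori.grid.angles, m=2
        )
        if flag:
            out.flags["one_minus_cirvar"] = flag
    else:
        out.one_minus_cirvar, flag = _resultant_length(r, grid.angles, m=2)
        if flag:
            out.flags["one_minus_cirvar"] = flag
    return out


def _resultant_length(r, angles_deg, m):
    total = np.sum(r)
    if abs(total) < _denom_tol(np.asarray(r, dtype=float)):
        return None, "near-zero net response"
    z = np.sum(r * np.exp(1j * m * np.deg2rad(angles_deg)))
    return float(np.abs(z) / np.abs(total)), None


def compute_indices(tr: TrialResponses) -> SelectivityIndices:
    """All indices available for this grid, from trial-averaged responses."""
    r = tr.mean_responses
    out = peak_trough_indices(r, tr.grid)
    out.update(circular_variance_indices(r, tr.grid))
    return out


def index_population_comparison(indices_a, indices_b) -> dict:
    """Classical pooled-variance two-sample t-test on per-cell index values.

    Returns ``{"t", "dof", "p"}`` with a two-sided p. Degenerate pooled
    variance resolves to p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray([x for x in indices_a if x is not None and np.isfinite(x)], float)
    b = np.asarray([x for x in indices_b if x is not None and np.isfinite(x)], float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 finite values")
    dof = a.size + b.size - 2
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "dof": dof, "p": 1.0}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf, "dof": dof, "p": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "dof": dof, "p": float(p)}
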