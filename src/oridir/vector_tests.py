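"""Per-trial response vectors and vector-based significance tests.

A "trial" is one measurement at each stimulus angle. The orientation
vector of a trial is the raw (unnormalized) vector sum of that trial's
responses with doubled angles, Σ_k R_t(θ_k)(cos 2θ_k, sin 2θ_k); the
direction vector uses single angles. Under the null hypothesis of no
selectivity these vectors have zero mean, which is what makes them
suitable for significance testing where raw index values are not: any
noise inflates an index, but it does not bias a vector away from zero.

Orientation selectivity is tested with Hotelling's T² (is the 2-D mean
of the orientation vectors different from [0, 0]?). Direction
selectivity uses the direction dot product test: project each trial's
direction vector onto the cell's orientation axis (the halved angle of
the mean orientation vector) and run a one-sample Student's t-test of
the signed projections against mean zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_angles import (
    DIRECTION,
    ORIENTATION,
    TrialResponses,
    collapse_to_orientation,
)
from .errors import DegenerateDataError, InsufficientDataError, InvalidArgumentError

#: Condition number above which a covariance matrix is treated as singular.
SINGULAR_COND = 1e12


@dataclass(frozen=True)
class TrialVectorSet:
    """One 2-D response vector per trial, in orientation or direction space."""

    vectors: np.ndarray  # (n_trials, 2)
    space: str

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2 or not np.all(np.isfinite(v)):
            raise InvalidArgumentError("vectors must be a finite (n, 2) array")
        object.__setattr__(self, "vectors", v)

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]

    @property
    def mean_vector(self) -> np.ndarray:
        return self.vectors.mean(axis=0)


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    dof: tuple
    p: float


@dataclass(frozen=True)
class DotProductTestResult:
    axis_angle: float
    projections: np.ndarray
    t_stat: float
    dof: int
    p: float
    degenerate: bool = False


def per_trial_vectors(tr: TrialResponses, space: str) -> TrialVectorSet:
    """Raw per-trial vector sums in the requested angle space.

    For orientation space, direction-space data is first collapsed so each
    orientation is represented once; angles are doubled (m = 2). Direction
    space uses the angles as-is (m = 1).
    """
    if space == ORIENTATION:
        if tr.grid.space == DIRECTION:
            tr = collapse_to_orientation(tr)
        m = 2
    elif space == DIRECTION:
        if tr.grid.space != DIRECTION:
            raise InvalidArgumentError(
                "direction vectors need direction-space responses"
            )
        m = 1
    else:
        raise InvalidArgumentError(f"unknown space {space!r}")
    theta = np.deg2rad(m * tr.grid.angles)
    basis = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (n_angles, 2)
    return TrialVectorSet(tr.values @ basis, space)


def hotelling_t2_one_sample(vs: TrialVectorSet) -> HotellingResult:
    """Hotelling's T² test of H0: the 2-D mean vector is [0, 0].

    T² = n x̄ᵀ S⁻¹ x̄ with S the unbiased sample covariance;
    F = T² (n − 2) / (2 (n − 1)) is referred to F(2, n − 2).
    """
    n = vs.n_trials
    if n < 3:
        raise InsufficientDataError("one-sample Hotelling test needs >= 3 trials")
    xbar = vs.mean_vector
    s = np.cov(vs.vectors.T, ddof=1)
    _check_nonsingular(s)
    t2 = float(n * xbar @ np.linalg.solve(s, xbar))
    f_stat = t2 * (n - 2) / (2.0 * (n - 1))
    dof = (2, n - 2)
    p = float(stats.f.sf(f_stat, *dof))
    return HotellingResult(t2=t2, f_stat=f_stat, dof=dof, p=p)


def hotelling_t2_two_sample(vs_a: TrialVectorSet, vs_b: TrialVectorSet) -> HotellingResult:
    """Two-sample Hotelling's T² with pooled covariance.

    T² = (n_A n_B)/(n_A + n_B) · dᵀ S_p⁻¹ d, d the mean difference;
    F = T² (n_A + n_B − 3) / (2 (n_A + n_B − 2)) on F(2, n_A + n_B − 3).
    """
    na, nb = vs_a.n_trials, vs_b.n_trials
    if na < 2 or nb < 2:
        raise InsufficientDataError("two-sample Hotelling test needs >= 2 per group")
    d = vs_a.mean_vector - vs_b.mean_vector
    sa = np.cov(vs_a.vectors.T, ddof=1)
    sb = np.cov(vs_b.vectors.T, ddof=1)
    sp = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    _check_nonsingular(sp)
    t2 = float(na * nb / (na + nb) * d @ np.linalg.solve(sp, d))
    f_stat = t2 * (na + nb - 3) / (2.0 * (na + nb - 2))
    dof = (2, na + nb - 3)
    p = float(stats.f.sf(f_stat, *dof))
    return HotellingResult(t2=t2, f_stat=f_stat, dof=dof, p=p)


def _check_nonsingular(s):
    s = np.atleast_2d(s)
    if not np.all(np.isfinite(s)) or np.linalg.cond(s) > SINGULAR_COND:
        raise DegenerateDataError(
            "sample covariance of trial vectors is singular "
            "(identical or collinear vectors)"
        )


def orientation_axis_angle(vs_ori: TrialVectorSet, rtol: float = 1e-12) -> float:
    """Orientation axis: halved angle of the mean orientation vector, mod 180°."""
    mean = vs_ori.mean_vector
    scale = max(float(np.max(np.abs(vs_ori.vectors))), 1.0)
    if np.hypot(*mean) < rtol * scale:
        raise DegenerateDataError(
            "mean orientation vector is (numerically) zero; orientation axis "
            "undefined — establish orientation significance first"
        )
    return float(np.mod(np.degrees(np.arctan2(mean[1], mean[0])) / 2.0, 180.0))


def direction_dot_product_test(vs_dir: TrialVectorSet, axis: float) -> DotProductTestResult:
    """One-sample t-test of signed direction dot products against mean 0.

    Each trial's direction vector is projected onto the orientation axis
    (treated as a direction-space unit vector); the signed projections are
    the "direction dot products". The two-sided p is invariant to
    replacing the axis by axis + 180°.
    """
    if vs_dir.n_trials < 2:
        raise InsufficientDataError("dot product test needs >= 2 trials")
    u = np.array([np.cos(np.deg2rad(axis)), np.sin(np.deg2rad(axis))])
    proj = vs_dir.vectors @ u
    n = proj.size
    if np.std(proj, ddof=1) == 0.0:
        mean = float(proj.mean())
        p = 1.0 if np.isclose(mean, 0.0) else 0.0
        t = 0.0 if p == 1.0 else np.inf * np.sign(mean)
        return DotProductTestResult(
            axis_angle=float(np.mod(axis, 180.0)), projections=proj,
            t_stat=float(t), dof=n - 1, p=p, degenerate=True,
        )
    t, p = stats.ttest_1samp(proj, 0.0)
    return DotProductTestResult(
        axis_angle=float(np.mod(axis, 180.0)), projections=proj,
        t_stat=float(t), dof=n - 1, p=float(p),
    )


@dataclass(frozen=True)
class SelectivityTestReport:
    """Combined orientation + direction significance workflow for one cell."""

    orientation: HotellingResult
    axis_angle: float | None
    direction: DotProductTestResult | None
    orientation_significant: bool
    direction_tested_without_orientation: bool


def selectivity_tests(tr: TrialResponses, alpha: float = 0.05) -> SelectivityTestReport:
    """Run the recommended per-cell significance workflow.

    Orientation: collapse to orientation space, compute per-trial
    orientation vectors, Hotelling one-sample T². Direction (direction
    grids only): direction vectors, orientation axis, dot product test.
    If orientation selectivity is not significant the direction test is
    still reported, with a warning flag, since its axis is then poorly
    defined.
    """
    vs_ori = per_trial_vectors(tr, ORIENTATION)
    hot = hotelling_t2_one_sample(vs_ori)
    ori_sig = hot.p < alpha
    axis = None
    dp = None
    warned = False
    if tr.grid.space == DIRECTION:
        try:
            axis = orientation_axis_angle(vs_ori)
        except DegenerateDataError:
            axis = None
        if axis is not None:
            vs_dir = per_trial_vectors(tr, DIRECTION)
            dp = direction_dot_product_test(vs_dir, axis)
            warned = not ori_sig
    return SelectivityTestReport(
        orientation=hot,
        axis_angle=axis,
        direction=dp,
        orientation_significant=bool(ori_sig),
        direction_tested_without_orientation=warned,
    )
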