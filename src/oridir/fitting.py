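"""Constrained Gaussian fits of orientation and direction tuning curves.

Orientation tuning is fitted with a single wrapped Gaussian,

    R(θ) = C + R_p · exp(-ang_ori(θ - θ_pref)² / (2σ²)),

and direction tuning with a double Gaussian sharing one width,

    R(θ) = C + R_p · exp(-ang_dir(θ - θ_pref)² / (2σ²))
             + R_n · exp(-ang_dir(θ + 180° - θ_pref)² / (2σ²)),

where ang_ori / ang_dir wrap angular differences onto [0, 90°] / [0, 180°].
Unconstrained least squares on these models routinely fails (needle-thin
widths through two points, huge R_p with negative lobes, strongly negative
offsets), so the fit is boxed: σ ≥ α/2 (α the stimulation angle step),
C ∈ [-M, M], R_p, R_n ∈ [0, 3M], with M the largest mean response. The
search is multi-start over σ ∈ {α/2, α, 40°, 60°, 90°} from θ_pref at the
empirical peak, R_p = R_n = M, C = 0; the lowest-SSE solution wins.

The half-width at half-height above offset is σ·√(ln 4) ≈ 1.18 σ.
Tuning width and preferred angle are only reported when the cell shows
significant orientation selectivity (Hotelling T² gate): with no
significant tuning these parameters are noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .core_angles import (
    DIRECTION,
    ORIENTATION,
    TrialResponses,
    ang_diff,
    period_of,
)
from .errors import FitFailedError, InsufficientDataError, InvalidArgumentError
from .vector_tests import hotelling_t2_one_sample, per_trial_vectors

#: hwhh / sigma for a Gaussian lobe.
HWHH_FACTOR = math.sqrt(math.log(4.0))

#: Upper bound on the width parameter; beyond the wrap period a Gaussian
#: lobe is indistinguishable from the offset C.
SIGMA_MAX = 180.0

#: Initial width values explored by the multi-start search (degrees);
#: α/2 and α are prepended at fit time.
SIGMA_STARTS_FIXED = (40.0, 60.0, 90.0)

_FIT_TOL = 1e-10
_MAX_NFEV = 2000


@dataclass(frozen=True)
class TuningCurveModel:
    """Parameters of the (double-)Gaussian tuning model.

    ``r_null`` is ignored by orientation-space evaluation. ``theta_pref``
    is in degrees; ``sigma`` is the Gaussian width parameter in degrees.
    """

    c: float
    r_pref: float
    theta_pref: float
    sigma: float
    r_null: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.c, self.r_pref, self.theta_pref, self.sigma,
                            self.r_null]).all():
            raise InvalidArgumentError("model parameters must be finite")
        if self.sigma <= 0:
            raise InvalidArgumentError("sigma must be positive")

    @property
    def hwhh(self) -> float:
        """Half-width at half-height above offset, σ·√(ln 4)."""
        return self.sigma * HWHH_FACTOR


def evaluate_model(model: TuningCurveModel, angles, space: str) -> np.ndarray:
    """Evaluate the tuning model at *angles* (degrees) in the given space."""
    th = np.asarray(angles, dtype=float)
    if space == ORIENTATION:
        d = ang_diff(th - model.theta_pref, ORIENTATION)
        return model.c + model.r_pref * np.exp(-(d ** 2) / (2.0 * model.sigma ** 2))
    if space == DIRECTION:
        dp = ang_diff(th - model.theta_pref, DIRECTION)
        dn = ang_diff(th + 180.0 - model.theta_pref, DIRECTION)
        return (
            model.c
            + model.r_pref * np.exp(-(dp ** 2) / (2.0 * model.sigma ** 2))
            + model.r_null * np.exp(-(dn ** 2) / (2.0 * model.sigma ** 2))
        )
    raise InvalidArgumentError(f"unknown space {space!r}")


@dataclass(frozen=True)
class FitResult:
    """Best multi-start fit with derived parameters.

    ``hwhh`` and ``pref_angle_fit`` are ``None`` when a gating step masked
    them (see :func:`gated_fit_report`); ``gated`` records whether the cell
    passed the orientation-significance gate (``None`` = not gated).
    """

    model: TuningCurveModel
    space: str
    sse: float
    hwhh: float | None
    fit_oi: float | None
    fit_di: float | None
    pref_angle_fit: float | None
    n_starts_tried: int
    start_sses: tuple
    degenerate: bool = False
    gated: bool | None = None
    orientation_p: float | None = None


def fit_tuning(tr: TrialResponses, space: str | None = None) -> FitResult:
    """Constrained multi-start least-squares fit of trial-mean responses.

    *space* defaults to the grid's space; direction-space data may also be
    fitted in orientation space (it is collapsed first).
    """
    if space is None:
        space = tr.grid.space
    if space == ORIENTATION and tr.grid.space == DIRECTION:
        from .core_angles import collapse_to_orientation

        tr = collapse_to_orientation(tr)
    if len(tr.grid) < 4:
        raise InsufficientDataError("fitting needs at least 4 distinct angles")

    angles = tr.grid.angles
    mean = tr.mean_responses
    alpha = tr.grid.step_alpha
    m = float(np.max(mean))
    if m <= 0.0:
        # No positive response: a Gaussian bump has nothing to fit.
        model = TuningCurveModel(
            c=float(np.mean(mean)), r_pref=0.0, r_null=0.0,
            theta_pref=0.0, sigma=max(alpha / 2.0, 1e-6),
        )
        sse = float(np.sum((evaluate_model(model, angles, space) - mean) ** 2))
        return _finalize(model, space, sse, 0, (), degenerate=True)

    if np.ptp(mean) == 0.0:
        # exactly constant data: the flat model is the unique sensible fit
        model = TuningCurveModel(c=m, r_pref=0.0, r_null=0.0,
                                 theta_pref=0.0, sigma=max(alpha / 2.0, 1e-6))
        return _finalize(model, space, 0.0, 0, ())

    is_dir = space == DIRECTION
    theta0 = float(angles[int(np.argmax(mean))])
    sigma_starts = []
    for s in (alpha / 2.0, alpha, *SIGMA_STARTS_FIXED):
        s = min(max(s, alpha / 2.0), SIGMA_MAX)
        if not any(abs(s - t) < 1e-9 for t in sigma_starts):
            sigma_starts.append(s)

    if is_dir:
        def resid(x):
            mdl = TuningCurveModel(c=x[0], r_pref=x[1], r_null=x[2],
                                   theta_pref=x[3], sigma=x[4])
            return evaluate_model(mdl, angles, DIRECTION) - mean

        lb = [-m, 0.0, 0.0, -np.inf, alpha / 2.0]
        ub = [m, 3.0 * m, 3.0 * m, np.inf, SIGMA_MAX]
        x0s = [[0.0, m, m, theta0, s] for s in sigma_starts]
    else:
        def resid(x):
            mdl = TuningCurveModel(c=x[0], r_pref=x[1], theta_pref=x[2], sigma=x[3])
            return evaluate_model(mdl, angles, ORIENTATION) - mean

        lb = [-m, 0.0, -np.inf, alpha / 2.0]
        ub = [m, 3.0 * m, np.inf, SIGMA_MAX]
        x0s = [[0.0, m, theta0, s] for s in sigma_starts]

    best = None
    sses = []
    diagnostics = []
    for x0 in x0s:
        try:
            sol = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_NFEV,
            )
        except Exception as exc:  # pragma: no cover - optimizer blowup
            diagnostics.append(f"start sigma={x0[-1]:g}: {exc}")
            continue
        sse = float(2.0 * sol.cost)
        sses.append(sse)
        if best is None or sse < best[1]:
            best = (sol.x, sse)
    if best is None:
        raise FitFailedError("all fit starts failed", diagnostics)

    x, sse = best
    if is_dir:
        model = TuningCurveModel(c=float(x[0]), r_pref=float(x[1]),
                                 r_null=float(x[2]),
                                 theta_pref=float(np.mod(x[3], 360.0)),
                                 sigma=float(x[4]))
        # The double Gaussian is invariant under (theta+180, Rp<->Rn);
        # report theta_pref as the actually-preferred direction.
        if model.r_null > model.r_pref:
            model = replace(
                model,
                r_pref=model.r_null, r_null=model.r_pref,
                theta_pref=float(np.mod(model.theta_pref + 180.0, 360.0)),
            )
    else:
        model = TuningCurveModel(c=float(x[0]), r_pref=float(x[1]),
                                 theta_pref=float(np.mod(x[2], 180.0)),
                                 sigma=float(x[3]))
    return _finalize(model, space, sse, len(x0s), tuple(sses))


def derived_parameters(model: TuningCurveModel, space: str) -> dict:
    """HWHH, fit-based OI/DI, and preferred angle from a fitted model.

    Fit OI/DI evaluate the fitted curve at θ_pref, θ_pref ± 90°, and
    θ_pref + 180° and apply the peak–trough formulas.
    """
    th = model.theta_pref
    out = {"hwhh": model.hwhh, "pref_angle_fit": th, "fit_oi": None, "fit_di": None}
    if space == DIRECTION:
        rp, rn, rop, rom = evaluate_model(
            model, [th, th + 180.0, th + 90.0, th - 90.0], DIRECTION
        )
        if abs(rp + rn) > 0:
            out["fit_oi"] = float((rp + rn - (rop + rom)) / (rp + rn))
        if abs(rp) > 0:
            out["fit_di"] = float((rp - rn) / rp)
    else:
        rp, ro = evaluate_model(model, [th, th + 90.0], ORIENTATION)
        if abs(rp) > 0:
            out["fit_oi"] = float((rp - ro) / rp)
    return out


def _finalize(model, space, sse, n_starts, sses, degenerate=False):
    d = derived_parameters(model, space)
    return FitResult(
        model=model, space=space, sse=sse,
        hwhh=d["hwhh"], fit_oi=d["fit_oi"], fit_di=d["fit_di"],
        pref_angle_fit=d["pref_angle_fit"],
        n_starts_tried=n_starts, start_sses=sses, degenerate=degenerate,
    )


def gated_fit_report(tr: TrialResponses, alpha: float = 0.05,
                     space: str | None = None) -> FitResult:
    """Fit with the orientation-significance gate applied.

    Runs the orientation Hotelling T² test; if p ≥ *alpha* the returned
    result masks ``hwhh`` and ``pref_angle_fit`` (``gated = False``) while
    still reporting the SSE and fit-based index values.
    """
    hot = hotelling_t2_one_sample(per_trial_vectors(tr, ORIENTATION))
    fit = fit_tuning(tr, space=space)
    significant = hot.p < alpha
    if significant:
        return replace(fit, gated=True, orientation_p=hot.p)
    return replace(fit, gated=False, orientation_p=hot.p,
                   hwhh=None, pref_angle_fit=None)
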