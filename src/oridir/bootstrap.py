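"""Bootstrap uncertainty of fitted tuning parameters.

Whole trials (rows of the trial-by-angle matrix) are resampled with
replacement, preserving within-trial correlations, and the constrained
double-Gaussian fit is rerun on each resample. The spread of the fitted
preferred direction across resamples gives a direction-significance
p-value: the "uncertainty" is the fraction of resamples whose preferred
direction lies more than 90° (in direction space) from the circular mean
preferred direction, which ranges over [0, 0.5], and 2 × uncertainty is
interpreted as a p-value. The Hessian of the constrained fit is useless
for error bars here — the constraint boxes make the error surface
non-smooth — which is why resampling is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_angles import DIRECTION, TrialResponses, ang_diff
from .errors import FitFailedError, InsufficientDataError, InvalidArgumentError
from .fitting import fit_tuning


@dataclass(frozen=True)
class BootstrapResult:
    theta_pref_samples: np.ndarray
    param_samples: dict  # name -> ndarray, aligned with theta_pref_samples
    mean_direction: float
    uncertainty: float
    p_direction: float
    n_boot: int
    n_failed: int
    seed: int


def preference_uncertainty(samples) -> dict:
    """Circular mean and dispersion-based p-value of preferred directions.

    ``uncertainty`` is the fraction of samples further than 90° (direction
    space) from the circular mean; ``p_direction = 2 × uncertainty``
    clamped to [1/n, 1]. Perfectly dispersed samples (zero resultant) have
    no defined mean: uncertainty is then 0.5 and p = 1.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise InvalidArgumentError("need at least one preferred-direction sample")
    rad = np.deg2rad(s)
    z = np.mean(np.exp(1j * rad))
    if np.abs(z) < 1e-12:
        return {"mean_direction": float("nan"), "uncertainty": 0.5, "p_direction": 1.0}
    mean_dir = float(np.mod(np.degrees(np.angle(z)), 360.0))
    unc = float(np.mean(ang_diff(s - mean_dir, DIRECTION) > 90.0))
    p = float(np.clip(2.0 * unc, 1.0 / s.size, 1.0))
    return {"mean_direction": mean_dir, "uncertainty": unc, "p_direction": p}


def bootstrap_fit(tr: TrialResponses, n_boot: int = 100, seed: int = 0) -> BootstrapResult:
    """Resample trials with replacement and refit the double Gaussian.

    Each of the *n_boot* resamples draws ``n_trials`` whole trials with
    replacement and refits in direction space. Resamples whose fit fails
    are excluded and counted. Deterministic for a fixed seed.
    """
    if tr.n_trials < 2:
        raise InsufficientDataError("bootstrap needs at least 2 trials")
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = []
    params = {"c": [], "r_pref": [], "r_null": [], "sigma": [], "sse": []}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, tr.n_trials, size=tr.n_trials)
        resampled = TrialResponses(tr.values[idx], tr.grid, blank_mean=tr.blank_mean)
        try:
            fit = fit_tuning(resampled, space=DIRECTION)
        except FitFailedError:
            n_failed += 1
            continue
        thetas.append(fit.model.theta_pref)
        params["c"].append(fit.model.c)
        params["r_pref"].append(fit.model.r_pref)
        params["r_null"].append(fit.model.r_null)
        params["sigma"].append(fit.model.sigma)
        params["sse"].append(fit.sse)
    thetas = np.asarray(thetas)
    if thetas.size == 0:
        raise FitFailedError("every bootstrap resample failed to fit")
    unc = preference_uncertainty(thetas)
    return BootstrapResult(
        theta_pref_samples=thetas,
        param_samples={k: np.asarray(v) for k, v in params.items()},
        mean_direction=unc["mean_direction"],
        uncertainty=unc["uncertainty"],
        p_direction=unc["p_direction"],
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )
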