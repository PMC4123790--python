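"""Monte-Carlo generation of tuning curves, noise, and simulated experiments.

The generator reproduces the study conditions used throughout the package's
validation work. Ground-truth cells are double Gaussians with geometry drawn
to match typical V1 neurons: preferred direction θ_pref ~ Uniform[0°, 360°)
and width σ = (Gamma(shape 3, scale 6) + 10°) / 1.18 (so the half-width at
half-height is Gamma-distributed above a 10° floor). Amplitude triples
(C, R_p, R_n) come from two 21-point families sweeping true selectivity:

    OI grid: C = 10 - (i-1)/2,  R_p = (i-1)/2,  R_n = (i-1)/4   (i = 1..21)
    DI grid: C = 0,             R_p = 10,       R_n = 10 - (i-1)/2

Noise is additive Gaussian per trial and angle. The constant-fraction model
(extracellular spikes) uses SD = level × reference_max, with reference_max
defaulting to 10 Hz, so "20% noise" means 2 Hz of noise on every response.
The OGB model (bulk-loaded calcium imaging) uses an affine SD,
base_fraction × reference_max + response_fraction × |expected response|,
e.g. 20% + 10% × response. Simulated responses are never clipped at zero:
blank-subtracted data can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_angles import DIRECTION, AngleGrid, TrialResponses
from .errors import InvalidArgumentError
from .fitting import TuningCurveModel, evaluate_model
from .indices import SelectivityIndices, compute_indices

#: Default maximum response used to scale fractional noise levels (Hz).
REFERENCE_MAX = 10.0

OI_GRID = "oi_grid"
DI_GRID = "di_grid"


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian trial noise.

    ``constant_fraction``: SD = level × reference_max at every angle.
    ``ogb_affine``: SD(θ) = level[0] × reference_max + level[1] × |R(θ)|.
    """

    kind: str
    level: float | tuple
    reference_max: float = REFERENCE_MAX

    def __post_init__(self):
        if self.kind == "constant_fraction":
            if not np.isscalar(self.level) or self.level < 0:
                raise InvalidArgumentError("constant_fraction needs a scalar level >= 0")
        elif self.kind == "ogb_affine":
            base, resp = self.level
            if base < 0 or resp < 0:
                raise InvalidArgumentError("ogb_affine fractions must be >= 0")
            object.__setattr__(self, "level", (float(base), float(resp)))
        else:
            raise InvalidArgumentError(f"unknown noise kind {self.kind!r}")

    def sd(self, expected) -> np.ndarray:
        """Noise SD at each expected response value."""
        expected = np.asarray(expected, dtype=float)
        if self.kind == "constant_fraction":
            return np.full_like(expected, self.level * self.reference_max)
        base, resp = self.level
        return base * self.reference_max + resp * np.abs(expected)


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of one Monte-Carlo experiment family."""

    grid_kind: str = OI_GRID
    n_trials: int = 10
    n_angles: int = 16
    noise: NoiseModel = field(default_factory=lambda: NoiseModel("constant_fraction", 0.5))
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.grid_kind not in (OI_GRID, DI_GRID):
            raise InvalidArgumentError(f"unknown grid kind {self.grid_kind!r}")
        if self.n_angles < 4 or self.n_angles % 2:
            raise InvalidArgumentError(
                "need an even angle count >= 4 (opposite-direction pairs)")


def direction_grid(n_angles: int = 16) -> AngleGrid:
    """Equally spaced direction grid starting at 0° (e.g. 16 × 22.5° steps).

    The count must be even so every direction has its opposite on the grid.
    """
    if n_angles < 4 or n_angles % 2:
        raise InvalidArgumentError(
            "need an even angle count >= 4 (opposite-direction pairs)")
    return AngleGrid(np.arange(n_angles) * (360.0 / n_angles), DIRECTION)


def grid_curve(kind: str, i: int) -> tuple:
    """Amplitude triple (C, R_p, R_n) of grid curve *i* (1..21)."""
    if not (isinstance(i, (int, np.integer)) and 1 <= i <= 21):
        raise InvalidArgumentError("grid index i must be an integer in [1, 21]")
    if kind == OI_GRID:
        return (10.0 - (i - 1) / 2.0, (i - 1) / 2.0, (i - 1) / 4.0)
    if kind == DI_GRID:
        return (0.0, 10.0, 10.0 - (i - 1) / 2.0)
    raise InvalidArgumentError(f"unknown grid kind {kind!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_random_curve_geometry(seed) -> tuple:
    """Random (θ_pref, σ): θ ~ U[0, 360), σ = (Gamma(3, 6) + 10°)/1.18."""
    rng = _as_rng(seed)
    theta = float(rng.uniform(0.0, 360.0))
    sigma = float((rng.gamma(3.0, 6.0) + 10.0) / 1.18)
    return theta, sigma


def simulate_trials(model: TuningCurveModel, grid: AngleGrid, n_trials: int,
                    noise: NoiseModel, seed) -> TrialResponses:
    """Simulate an experiment: model curve plus per-trial Gaussian noise."""
    rng = _as_rng(seed)
    expected = evaluate_model(model, grid.angles, grid.space)
    sd = noise.sd(expected)
    values = expected + rng.standard_normal((n_trials, len(grid))) * sd
    return TrialResponses(values, grid)


def true_indices(model: TuningCurveModel, grid: AngleGrid) -> SelectivityIndices:
    """Indices of the noiseless model curve, sampled with the grid's spacing.

    The curve is evaluated on a grid aligned to θ_pref (same spacing, peak
    on-grid), which makes every true index invariant to rotations of the
    preferred angle — the "true" OI/DI of a curve should not depend on
    where the stimulus grid happens to fall.
    """
    offsets = np.mod(grid.angles - grid.angles[0], 360.0)
    offsets.sort()
    aligned = AngleGrid(offsets, grid.space)
    r = evaluate_model(
        model, model.theta_pref + offsets, grid.space
    )
    tr = TrialResponses(r[np.newaxis, :], aligned)
    return compute_indices(tr)


# ---------------------------------------------------------------------------
# Curves with exactly specified true selectivity (for power simulations)
# ---------------------------------------------------------------------------

def _on_grid_quadrature(grid: AngleGrid) -> bool:
    # peak-aligned grids whose spacing hits 90/180/270 exactly admit
    # closed-form true indices
    return grid.is_equally_spaced and len(grid) % 4 == 0


def curve_with_true_oi(oi: float, theta_pref: float, sigma: float,
                       grid: AngleGrid) -> TuningCurveModel:
    """Member of the OI family (C = 10 - R_p, R_n = R_p/2) with true OI *oi*."""
    if not 0.0 <= oi <= 1.0:
        raise InvalidArgumentError("true OI must lie in [0, 1]")
    if _on_grid_quadrature(grid):
        # true OI = (Rp+Rn)(1+g-2h) / (2C + (Rp+Rn)(1+g)) with g, h the
        # Gaussian tails at 180 and 90 degrees; linear in Rp along this family
        g = np.exp(-(180.0 ** 2) / (2.0 * sigma ** 2))
        h = np.exp(-(90.0 ** 2) / (2.0 * sigma ** 2))
        denom = 1.5 * (1.0 + g - 2.0 * h) + oi * (2.0 - 1.5 * (1.0 + g))
        rp = 10.0 if denom <= 0 else min(20.0 * oi / denom, 10.0)
        return TuningCurveModel(c=10.0 - rp, r_pref=rp, r_null=rp / 2.0,
                                theta_pref=theta_pref, sigma=sigma)

    def f(rp):
        m = TuningCurveModel(c=10.0 - rp, r_pref=rp, r_null=rp / 2.0,
                             theta_pref=theta_pref, sigma=sigma)
        return (true_indices(m, grid).oi_dirspace or 0.0) - oi

    if oi == 0.0:
        rp = 0.0
    elif f(10.0) <= 0.0:
        rp = 10.0
    else:
        rp = brentq(f, 0.0, 10.0, xtol=1e-10)
    return TuningCurveModel(c=10.0 - rp, r_pref=rp, r_null=rp / 2.0,
                            theta_pref=theta_pref, sigma=sigma)


def curve_with_true_di(di: float, theta_pref: float, sigma: float,
                       grid: AngleGrid) -> TuningCurveModel:
    """Member of the DI family (C = 0, R_p = 10) with true DI *di*."""
    if not 0.0 <= di <= 1.0:
        raise InvalidArgumentError("true DI must lie in [0, 1]")
    if _on_grid_quadrature(grid):
        # true DI = (Rp-Rn)(1-g) / (Rp+Rn g), g the 180-degree tail
        g = np.exp(-(180.0 ** 2) / (2.0 * sigma ** 2))
        rn = float(np.clip(10.0 * (1.0 - g - di) / (1.0 - g + di * g), 0.0, 10.0))
        return TuningCurveModel(c=0.0, r_pref=10.0, r_null=rn,
                                theta_pref=theta_pref, sigma=sigma)

    def f(rn):
        m = TuningCurveModel(c=0.0, r_pref=10.0, r_null=rn,
                             theta_pref=theta_pref, sigma=sigma)
        return (true_indices(m, grid).di or 0.0) - di

    if f(0.0) <= 0.0:
        rn = 0.0
    else:
        rn = brentq(f, 0.0, 10.0, xtol=1e-10)
    return TuningCurveModel(c=0.0, r_pref=10.0, r_null=rn,
                            theta_pref=theta_pref, sigma=sigma)


def curve_with_true_oi_di(oi: float, di: float, theta_pref: float, sigma: float,
                          grid: AngleGrid, r_pref: float = 10.0) -> TuningCurveModel:
    """Curve with both true OI and true DI specified (R_p fixed, solve C, R_n)."""
    from scipy.optimize import fsolve

    def eqs(x):
        c, rn = x
        m = TuningCurveModel(c=c, r_pref=r_pref, r_null=max(rn, 0.0),
                             theta_pref=theta_pref, sigma=sigma)
        ti = true_indices(m, grid)
        return [(ti.oi_dirspace or 0.0) - oi, (ti.di or 0.0) - di]

    c0 = r_pref * (1.0 - oi) / (2.0 * oi) if oi > 0 else r_pref
    rn0 = r_pref * (1.0 - di)
    (c, rn), info, ok, msg = fsolve(eqs, [c0, rn0], full_output=True)
    if ok != 1 or rn < -1e-6:
        raise InvalidArgumentError(
            f"no curve with true OI={oi}, DI={di} in this family ({msg})"
        )
    return TuningCurveModel(c=float(c), r_pref=r_pref, r_null=float(max(rn, 0.0)),
                            theta_pref=theta_pref, sigma=sigma)


# ---------------------------------------------------------------------------
# Forward / inverse empirical-index distributions
# ---------------------------------------------------------------------------

PERCENTILES = (5, 25, 50, 75, 95)


def run_grid_simulations(spec: SimulationSpec) -> pd.DataFrame:
    """Simulate the full 21-value grid and record true and empirical indices.

    One row per simulated experiment, with the grid index ``i``, the true
    peak–trough index of that cell's own curve (``true_index``: OI for the
    OI grid, DI for the DI grid), and the empirical readouts ``oi``, ``di``,
    ``cirvar`` (1-CirVar) and ``dircirvar`` (1-DirCirVar).
    """
    rng = _as_rng(spec.seed)
    grid = direction_grid(spec.n_angles)
    rows = []
    for i in range(1, 22):
        c, rp, rn = grid_curve(spec.grid_kind, i)
        for _ in range(spec.n_reps):
            theta, sigma = sample_random_curve_geometry(rng)
            model = TuningCurveModel(c=c, r_pref=rp, r_null=rn,
                                     theta_pref=theta, sigma=sigma)
            ti = true_indices(model, grid)
            tr = simulate_trials(model, grid, spec.n_trials, spec.noise, rng)
            emp = compute_indices(tr)
            rows.append({
                "i": i,
                "true_index": ti.oi_dirspace if spec.grid_kind == OI_GRID else ti.di,
                "oi": emp.oi_dirspace,
                "di": emp.di,
                "cirvar": emp.one_minus_cirvar,
                "dircirvar": emp.one_minus_dircirvar,
            })
    return pd.DataFrame(rows)


_READOUTS = ("oi", "di", "cirvar", "dircirvar")


def forward_index_distribution(sims: pd.DataFrame, readout: str) -> pd.DataFrame:
    """Percentiles of the empirical readout at each true-index grid value."""
    if readout not in _READOUTS:
        raise InvalidArgumentError(f"readout must be one of {_READOUTS}")
    rows = []
    for i, g in sims.groupby("i"):
        vals = g[readout].dropna().to_numpy()
        row = {"i": i, "true_index_median": float(np.median(g["true_index"]))}
        for p in PERCENTILES:
            row[f"p{p}"] = float(np.percentile(vals, p)) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("i")


def inverse_index_distribution(sims: pd.DataFrame, readout: str,
                               bin_width: float = 0.05) -> pd.DataFrame:
    """Distribution of the true index conditional on the binned readout.

    Readout values are binned with *bin_width*-wide bins centered on
    multiples of the width (the bin at 0 covers ±width/2); empty bins are
    simply absent from the table, never interpolated.
    """
    if readout not in _READOUTS:
        raise InvalidArgumentError(f"readout must be one of {_READOUTS}")
    df = sims.dropna(subset=[readout, "true_index"])
    centers = np.round(df[readout] / bin_width) * bin_width
    rows = []
    for center, g in df.groupby(centers):
        t = g["true_index"].to_numpy()
        row = {"bin_center": float(center), "n": int(t.size),
               "min": float(t.min()), "max": float(t.max())}
        for p in PERCENTILES:
            row[f"p{p}"] = float(np.percentile(t, p))
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin_center").sort_index()


def calibration_map(sims: pd.DataFrame, readout: str,
                    bin_width: float = 0.05):
    """Best-guess estimator: readout bin center → median true index."""
    inv = inverse_index_distribution(sims, readout, bin_width)
    centers = inv.index.to_numpy()
    medians = inv["p50"].to_numpy()

    def best_guess(values):
        values = np.asarray(values, dtype=float)
        idx = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
        return medians[idx]

    return best_guess


def estimation_error_surface(factor: str, factor_values, readout: str,
                             spec: SimulationSpec, stat: str = "mean",
                             bin_width: float = 0.05) -> pd.DataFrame:
    """Deviation between the true index and its calibrated best guess.

    For each value of the swept *factor* ("noise", "n_trials" or
    "n_angles"), a calibration run under that condition maps the readout
    to the median conditional true index; an independent evaluation run
    then measures |true − best guess| and reports its mean or median.
    """
    if factor not in ("noise", "n_trials", "n_angles"):
        raise InvalidArgumentError("factor must be noise, n_trials or n_angles")
    if stat not in ("mean", "median"):
        raise InvalidArgumentError("stat must be mean or median")
    rows = []
    for k, v in enumerate(factor_values):
        kw = {}
        if factor == "noise":
            kw["noise"] = NoiseModel("constant_fraction", float(v))
        else:
            kw[factor] = int(v)
        base = SimulationSpec(
            grid_kind=spec.grid_kind, n_trials=spec.n_trials,
            n_angles=spec.n_angles, noise=spec.noise, n_reps=spec.n_reps,
            seed=spec.seed,
        )
        cal_spec = _replace_spec(base, seed=spec.seed + 2 * k + 1, **kw)
        ev_spec = _replace_spec(base, seed=spec.seed + 2 * k + 2, **kw)
        cal = run_grid_simulations(cal_spec)
        guess = calibration_map(cal, readout, bin_width)
        ev = run_grid_simulations(ev_spec).dropna(subset=[readout, "true_index"])
        err = np.abs(ev["true_index"].to_numpy() - guess(ev[readout].to_numpy()))
        rows.append({
            "factor": factor, "value": v,
            "error": float(np.mean(err) if stat == "mean" else np.median(err)),
        })
    return pd.DataFrame(rows)


def _replace_spec(spec: SimulationSpec, **kw) -> SimulationSpec:
    fields = dict(grid_kind=spec.grid_kind, n_trials=spec.n_trials,
                  n_angles=spec.n_angles, noise=spec.noise,
                  n_reps=spec.n_reps, seed=spec.seed)
    fields.update(kw)
    return SimulationSpec(**fields)
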