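"""Monte-Carlo statistical power for tuning experiments.

Three planning questions are answered by simulation:

* how many stimulus trials per cell are needed to detect orientation
  (Hotelling T²) or direction (dot product test) selectivity of a given
  true strength;
* whether the selectivity tests are calibrated — p-values uniform on
  [0, 1] when the simulated cell has no selectivity;
* how many cells per condition are needed to detect a difference in
  selectivity (two-sample t-test on per-cell indices) or in preferred
  orientation (two-sample Hotelling T² on per-cell orientation vectors)
  between two populations.

Throughout, confidence and power are coupled at the same level X: the
minimum sample size is the smallest size at which at least X% of
simulated experiments are significant at α = 1 − X. Candidate sizes are
swept on a geometric-ish grid; a condition no size on the sweep can
satisfy is reported as missing (render with the sweep cap as ">cap").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_angles import DIRECTION, ORIENTATION
from .errors import DegenerateDataError, InvalidArgumentError
from .fitting import TuningCurveModel
from .indices import compute_indices, index_population_comparison
from .simulation import (
    NoiseModel,
    _as_rng,
    curve_with_true_di,
    curve_with_true_oi,
    direction_grid,
    grid_curve,
    sample_random_curve_geometry,
    simulate_trials,
)
from .vector_tests import (
    direction_dot_product_test,
    hotelling_t2_one_sample,
    hotelling_t2_two_sample,
    orientation_axis_angle,
    per_trial_vectors,
    TrialVectorSet,
)

HOTELLING_ORI = "hotelling_ori"
DOTPROD_DIR = "dotprod_dir"

#: Default candidate sample-size sweep (trials or cells).
DEFAULT_SWEEP = (4, 5, 6, 8, 10, 13, 16, 20, 26, 33, 42, 54, 68, 86, 110)

CONFIDENCE_LEVELS = (0.95, 0.99, 0.999)


@dataclass(frozen=True)
class PowerTable:
    """Minimum-sample-size grid with its provenance.

    ``table`` holds NaN where no size up to ``cap`` met the criterion.
    """

    table: pd.DataFrame
    reps: int
    cap: int
    params: dict = field(default_factory=dict)

    def to_display(self) -> pd.DataFrame:
        return self.table.map(
            lambda v: f">{self.cap}" if pd.isna(v) else int(v)
        )


def _selectivity_pvalue(test: str, model: TuningCurveModel, grid, n_trials,
                        noise, rng) -> float:
    tr = simulate_trials(model, grid, n_trials, noise, rng)
    try:
        if test == HOTELLING_ORI:
            return hotelling_t2_one_sample(per_trial_vectors(tr, ORIENTATION)).p
        if test == DOTPROD_DIR:
            vs_ori = per_trial_vectors(tr, ORIENTATION)
            axis = orientation_axis_angle(vs_ori)
            return direction_dot_product_test(
                per_trial_vectors(tr, DIRECTION), axis
            ).p
    except DegenerateDataError:
        return 1.0
    raise InvalidArgumentError(f"unknown test {test!r}")


def _null_model(test: str, theta: float, sigma: float) -> TuningCurveModel:
    if test == HOTELLING_ORI:
        c, rp, rn = grid_curve("oi_grid", 1)  # flat: true OI = 0
    elif test == DOTPROD_DIR:
        c, rp, rn = grid_curve("di_grid", 1)  # true DI = 0, OI = 1
    else:
        raise InvalidArgumentError(f"unknown test {test!r}")
    return TuningCurveModel(c=c, r_pref=rp, r_null=rn,
                            theta_pref=theta, sigma=sigma)


def null_pvalue_distribution(test: str, n_reps: int = 5000, n_trials: int = 7,
                             n_angles: int = 16,
                             noise: NoiseModel | None = None,
                             seed: int = 0) -> dict:
    """Sample the p-value distribution of a selectivity test under its null.

    The orientation null is a flat cell (true OI = 0); the direction null
    is a strongly oriented but direction-indifferent cell (DI = 0, OI = 1).
    Returns the p-values, the fraction below 0.05, and a Kolmogorov–Smirnov
    comparison against the uniform distribution.
    """
    if noise is None:
        noise = NoiseModel("constant_fraction", 0.4)
    rng = _as_rng(seed)
    grid = direction_grid(n_angles)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        theta, sigma = sample_random_curve_geometry(rng)
        model = _null_model(test, theta, sigma)
        pvals[r] = _selectivity_pvalue(test, model, grid, n_trials, noise, rng)
    ks = stats.kstest(pvals, "uniform")
    return {
        "pvalues": pvals,
        "frac_below_05": float(np.mean(pvals < 0.05)),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def detection_rate(test: str, true_index: float, n_trials: int,
                   n_reps: int, alpha: float,
                   noise: NoiseModel | None = None, n_angles: int = 16,
                   seed: int = 0) -> float:
    """Fraction of simulated cells significant at level *alpha*."""
    if noise is None:
        noise = NoiseModel("constant_fraction", 0.4)
    rng = _as_rng(seed)
    grid = direction_grid(n_angles)
    hits = 0
    for _ in range(n_reps):
        theta, sigma = sample_random_curve_geometry(rng)
        if test == HOTELLING_ORI:
            model = curve_with_true_oi(true_index, theta, sigma, grid)
        else:
            model = curve_with_true_di(true_index, theta, sigma, grid)
        if _selectivity_pvalue(test, model, grid, n_trials, noise, rng) < alpha:
            hits += 1
    return hits / n_reps


def min_trials_for_selectivity(test: str, true_index_values,
                               confidence_levels=CONFIDENCE_LEVELS,
                               trial_counts=DEFAULT_SWEEP,
                               n_reps: int = 100,
                               noise: NoiseModel | None = None,
                               n_angles: int = 16, seed: int = 0) -> PowerTable:
    """Minimum trials per cell to detect a given true OI (or DI).

    Defaults follow the package's validation conditions: 16 angles and
    40% constant noise (the direction test is typically run at the same
    4 Hz level, i.e. 0.4 of the 10 Hz reference).
    """
    if noise is None:
        noise = NoiseModel("constant_fraction", 0.4)
    rng = _as_rng(seed)
    rows = {}
    for value in true_index_values:
        mins = {c: np.nan for c in confidence_levels}
        pending = set(confidence_levels)
        for n_trials in sorted(trial_counts):
            if n_trials < 3 or not pending:
                continue
            sub = int(rng.integers(0, 2**31 - 1))
            # one simulation batch per trial count; reuse p-values across levels
            batch = _pvalue_batch(test, value, n_trials, n_reps, noise,
                                  n_angles, sub)
            for conf in sorted(pending):
                frac = float(np.mean(batch < (1.0 - conf)))
                if frac >= conf:
                    mins[conf] = n_trials
                    pending.discard(conf)
        rows[value] = mins
    table = pd.DataFrame(rows).T
    table.index.name = "true_index"
    return PowerTable(table=table, reps=n_reps, cap=max(trial_counts),
                      params={"test": test, "noise": noise, "n_angles": n_angles,
                              "seed": seed})


def _pvalue_batch(test, true_index, n_trials, n_reps, noise, n_angles, seed):
    rng = _as_rng(seed)
    grid = direction_grid(n_angles)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        theta, sigma = sample_random_curve_geometry(rng)
        if test == HOTELLING_ORI:
            model = curve_with_true_oi(true_index, theta, sigma, grid)
        else:
            model = curve_with_true_di(true_index, theta, sigma, grid)
        pvals[r] = _selectivity_pvalue(test, model, grid, n_trials, noise, rng)
    return pvals


def _population_indices(kind: str, true_value: float, n_cells: int, grid,
                        n_trials, noise, rng):
    """Per-cell peak–trough and circular-variance readouts for one population."""
    pt, cv = [], []
    for _ in range(n_cells):
        theta, sigma = sample_random_curve_geometry(rng)
        if kind == "oi":
            model = curve_with_true_oi(true_value, theta, sigma, grid)
        else:
            model = curve_with_true_di(true_value, theta, sigma, grid)
        emp = compute_indices(simulate_trials(model, grid, n_trials, noise, rng))
        pt.append(emp.oi_dirspace if kind == "oi" else emp.di)
        cv.append(emp.one_minus_cirvar if kind == "oi" else emp.one_minus_dircirvar)
    return pt, cv


def min_cells_for_population_difference(kind: str, base: float, delta: float,
                                        noise: NoiseModel | None = None,
                                        confidence_levels=CONFIDENCE_LEVELS,
                                        n_reps: int = 100,
                                        cell_counts=DEFAULT_SWEEP,
                                        n_trials: int = 7, n_angles: int = 16,
                                        seed: int = 0) -> PowerTable:
    """Minimum cells per condition to detect a selectivity difference.

    Two populations are simulated with true index *base* and *base + delta*
    (``kind`` selects OI or DI); per-cell indices are compared with the
    pooled two-sample t-test. Both readouts — the peak–trough index and the
    circular-variance index — are evaluated on the same simulated cells,
    making their comparison paired. Rows of the returned table are
    ``(readout, confidence)``.
    """
    if kind not in ("oi", "di"):
        raise InvalidArgumentError("kind must be 'oi' or 'di'")
    if noise is None:
        noise = NoiseModel("constant_fraction", 0.4)
    rng = _as_rng(seed)
    grid = direction_grid(n_angles)
    readouts = ("peak_trough", "cirvar")
    mins = {(ro, c): np.nan for ro in readouts for c in confidence_levels}
    pending = set(mins)
    for n in sorted(cell_counts):
        if not pending:
            break
        sig = {ro: np.zeros(len(confidence_levels)) for ro in readouts}
        for _ in range(n_reps):
            pt_a, cv_a = _population_indices(kind, base, n, grid, n_trials, noise, rng)
            pt_b, cv_b = _population_indices(kind, base + delta, n, grid,
                                             n_trials, noise, rng)
            for ro, (a, b) in (("peak_trough", (pt_a, pt_b)),
                               ("cirvar", (cv_a, cv_b))):
                p = index_population_comparison(a, b)["p"]
                for j, conf in enumerate(confidence_levels):
                    if p < 1.0 - conf:
                        sig[ro][j] += 1
        for ro in readouts:
            for j, conf in enumerate(confidence_levels):
                key = (ro, conf)
                if key in pending and sig[ro][j] / n_reps >= conf:
                    mins[key] = n
                    pending.discard(key)
    table = pd.DataFrame(
        {c: {ro: mins[(ro, c)] for ro in readouts} for c in confidence_levels}
    )
    table.index.name = "readout"
    return PowerTable(table=table, reps=n_reps, cap=max(cell_counts),
                      params={"kind": kind, "base": base, "delta": delta,
                              "noise": noise, "n_trials": n_trials,
                              "n_angles": n_angles, "seed": seed})


def min_cells_for_angle_difference(delta_theta: float,
                                   noise: NoiseModel | None = None,
                                   confidence_levels=CONFIDENCE_LEVELS,
                                   n_reps: int = 100,
                                   cell_counts=DEFAULT_SWEEP,
                                   n_trials: int = 7, n_angles: int = 16,
                                   seed: int = 0) -> PowerTable:
    """Minimum cells to detect a preferred-orientation shift of *delta_theta*.

    Both populations share one (random) base preference per replicate;
    population B is rotated by *delta_theta* (orientation degrees). Each
    cell contributes its mean orientation vector; the populations are
    compared with the two-sample Hotelling T². Because vectors also carry
    width and amplitude information, this is a broad screen — it detects
    that something differs, not specifically the angle.
    """
    if noise is None:
        noise = NoiseModel("constant_fraction", 0.4)
    rng = _as_rng(seed)
    grid = direction_grid(n_angles)
    c0, rp, rn = grid_curve("oi_grid", 21)  # strongly oriented reference cell
    mins = {c: np.nan for c in confidence_levels}
    pending = set(confidence_levels)
    for n in sorted(cell_counts):
        if not pending:
            break
        sig = np.zeros(len(confidence_levels))
        for _ in range(n_reps):
            theta0 = float(rng.uniform(0.0, 360.0))
            va = _population_vectors(theta0, c0, rp, rn, n, grid, n_trials,
                                     noise, rng)
            vb = _population_vectors(theta0 + delta_theta, c0, rp, rn, n, grid,
                                     n_trials, noise, rng)
            try:
                p = hotelling_t2_two_sample(va, vb).p
            except DegenerateDataError:
                p = 1.0
            for j, conf in enumerate(confidence_levels):
                if p < 1.0 - conf:
                    sig[j] += 1
        for j, conf in enumerate(confidence_levels):
            if conf in pending and sig[j] / n_reps >= conf:
                mins[conf] = n
                pending.discard(conf)
    table = pd.DataFrame([mins])
    table.index = pd.Index([delta_theta], name="delta_theta")
    return PowerTable(table=table, reps=n_reps, cap=max(cell_counts),
                      params={"noise": noise, "n_trials": n_trials,
                              "n_angles": n_angles, "seed": seed})


def _population_vectors(theta_base, c0, rp, rn, n_cells, grid, n_trials,
                        noise, rng) -> TrialVectorSet:
    vecs = np.empty((n_cells, 2))
    for k in range(n_cells):
        _, sigma = sample_random_curve_geometry(rng)
        model = TuningCurveModel(c=c0, r_pref=rp, r_null=rn,
                                 theta_pref=float(np.mod(theta_base, 360.0)),
                                 sigma=sigma)
        tr = simulate_trials(model, grid, n_trials, noise, rng)
        vecs[k] = per_trial_vectors(tr, ORIENTATION).mean_vector
    return TrialVectorSet(vecs, ORIENTATION)
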