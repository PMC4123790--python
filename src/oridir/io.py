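"""File formats and report assembly.

Trial matrices travel as CSV: the header row lists stimulus angles in
degrees (compass convention), each data row is one trial, and an optional
``blank`` column carries blank-screen responses whose mean is subtracted
from every entry on read. Analysis results are serialized as JSON with
sorted keys and floats at 10 significant digits, so a report regenerated
under its recorded seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .core_angles import (
    DIRECTION,
    ORIENTATION,
    AngleGrid,
    TrialResponses,
    convert_coordinates,
)
from .errors import InvalidArgumentError, OridirError
from .fitting import gated_fit_report
from .indices import compute_indices
from .vector_tests import selectivity_tests


class ParseError(OridirError, ValueError):
    """Malformed trial CSV; the message carries the offending location."""


def read_trials_csv(path, space: str | None = None,
                    cartesian: bool = False) -> TrialResponses:
    """Read a trial-by-angle CSV into :class:`TrialResponses`.

    Columns are sorted by angle; if a ``blank`` column is present its mean
    is subtracted from every response. The angle space is inferred when not
    given: any angle ≥ 180° implies direction space. ``cartesian=True``
    converts header angles from Cartesian to compass convention on read.
    """
    try:
        with open(path) as fh:
            header = fh.readline().strip()
        # parse the header ourselves: pandas silently renames duplicate
        # column names, which would hide duplicate angles
        raw_cols = [c.strip() for c in header.split(",")]
        df = pd.read_csv(path, header=None, names=range(len(raw_cols)),
                         skiprows=1, skipinitialspace=True)
        df.columns = raw_cols
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not header:
        raise ParseError(f"{path}: missing header row")
    if df.shape[0] < 1:
        raise ParseError(f"{path}: no trial rows")
    if df.shape[1] != len(raw_cols):
        raise ParseError(f"{path}: ragged rows")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing value at row {r + 2}, column {c + 1}")

    blank_mean = None
    cols = list(df.columns)
    blank_cols = [c for c in cols if str(c).strip().lower() == "blank"]
    if blank_cols:
        blanks = pd.to_numeric(df[blank_cols[0]], errors="coerce")
        if blanks.isna().any():
            raise ParseError(f"{path}: non-numeric value in blank column")
        blank_mean = float(blanks.mean())
        df = df.drop(columns=blank_cols)
        cols = list(df.columns)

    angles = []
    for c in cols:
        try:
            angles.append(float(str(c).strip()))
        except ValueError:
            raise ParseError(f"{path}: header entry {c!r} is not an angle") from None
    if cartesian:
        angles = [convert_coordinates(a) for a in angles]
    angles = np.asarray(angles)
    if len(np.unique(np.round(angles, 9))) != angles.size:
        raise ParseError(f"{path}: duplicate angle column")

    values = np.empty(df.shape)
    for j, c in enumerate(cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            r = int(col.isna().to_numpy().argmax())
            raise ParseError(
                f"{path}: non-numeric cell at row {r + 2}, column {j + 1}"
            )
        values[:, j] = col.to_numpy(dtype=float)

    order = np.argsort(angles)
    angles, values = angles[order], values[:, order]
    if space is None:
        space = DIRECTION if angles.max() >= 180.0 else ORIENTATION
    if blank_mean is not None:
        values = values - blank_mean
    try:
        grid = AngleGrid(angles, space)
        return TrialResponses(values, grid, blank_mean=blank_mean)
    except InvalidArgumentError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trials_csv(tr: TrialResponses, path) -> None:
    """Write a trial matrix as a CSV with angle headers."""
    df = pd.DataFrame(tr.values, columns=[f"{a:g}" for a in tr.grid.angles])
    df.to_csv(path, index=False)


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if not np.isfinite(x) else float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Serialize an analysis report as reproducible JSON."""
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True,
                  allow_nan=False, default=str)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def analyze_trials(tr: TrialResponses, alpha: float = 0.05,
                   config: dict | None = None) -> dict:
    """Assemble the standard per-cell analysis report.

    Indices, the orientation/direction significance tests, and the gated
    fit; masked (gated-out) fields are explicit nulls.
    """
    idx = compute_indices(tr)
    tests = selectivity_tests(tr, alpha=alpha)
    fit = gated_fit_report(tr, alpha=alpha)
    report = {
        "oridir_version": __version__,
        "config": dict(config or {}),
        "alpha": alpha,
        "space": tr.grid.space,
        "angles": tr.grid.angles.tolist(),
        "n_trials": tr.n_trials,
        "blank_mean": tr.blank_mean,
        "indices": {
            "pref_angle_empirical": idx.pref_angle_empirical,
            "oi_dirspace": idx.oi_dirspace,
            "oi_orispace": idx.oi_orispace,
            "di": idx.di,
            "osi": idx.osi,
            "dsi": idx.dsi,
            "orth_over_pref": idx.orth_over_pref,
            "one_minus_cirvar": idx.one_minus_cirvar,
            "one_minus_dircirvar": idx.one_minus_dircirvar,
            "flags": dict(idx.flags),
        },
        "tests": {
            "orientation": asdict(tests.orientation) if tests.orientation else None,
            "axis_angle": tests.axis_angle,
            "direction": None,
            "orientation_significant": tests.orientation_significant,
            "direction_tested_without_orientation":
                tests.direction_tested_without_orientation,
            "direction_test_sidedness": "two-sided",
        },
        "fit": {
            "space": fit.space,
            "model": {
                "c": fit.model.c, "r_pref": fit.model.r_pref,
                "r_null": fit.model.r_null,
                "theta_pref": fit.model.theta_pref, "sigma": fit.model.sigma,
            },
            "sse": fit.sse,
            "hwhh": fit.hwhh,
            "fit_oi": fit.fit_oi,
            "fit_di": fit.fit_di,
            "pref_angle_fit": fit.pref_angle_fit,
            "gated": fit.gated,
            "orientation_p": fit.orientation_p,
            "n_starts_tried": fit.n_starts_tried,
            "degenerate": fit.degenerate,
        },
    }
    if tests.direction is not None:
        d = tests.direction
        report["tests"]["direction"] = {
            "axis_angle": d.axis_angle,
            "projections": d.projections.tolist(),
            "t_stat": d.t_stat, "dof": d.dof, "p": d.p,
            "degenerate": d.degenerate,
        }
    return report


def generate_fixtures(out_dir, seed: int = 0) -> list:
    """Write canonical simulated trial CSVs used for demos and testing.

    ``flat_cell.csv``: an unselective cell; ``tuned_cell.csv``: a cell with
    true OI = 0.9 and DI = 0.5 at 20% noise on a 16-direction grid (the
    configuration used to illustrate the vector tests); ``grid_sweep``:
    one simulation per grid index of the true-OI family. All files are
    synthetic, regenerated deterministically from *seed*.
    """
    import pathlib

    from .fitting import TuningCurveModel
    from .simulation import (
        NoiseModel,
        curve_with_true_oi_di,
        direction_grid,
        grid_curve,
        sample_random_curve_geometry,
        simulate_trials,
    )

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    grid = direction_grid(16)
    noise = NoiseModel("constant_fraction", 0.2)
    written = []

    theta, sigma = sample_random_curve_geometry(rng)
    c, rp, rn = grid_curve("oi_grid", 1)
    flat = TuningCurveModel(c=c, r_pref=rp, r_null=rn, theta_pref=theta,
                            sigma=sigma)
    path = out / "flat_cell.csv"
    write_trials_csv(simulate_trials(flat, grid, 7, noise, rng), path)
    written.append(path)

    theta, sigma = sample_random_curve_geometry(rng)
    tuned = curve_with_true_oi_di(0.9, 0.5, theta, sigma, grid)
    path = out / "tuned_cell.csv"
    write_trials_csv(simulate_trials(tuned, grid, 7, noise, rng), path)
    written.append(path)

    sweep_dir = out / "grid_sweep"
    sweep_dir.mkdir(exist_ok=True)
    for i in range(1, 22):
        c, rp, rn = grid_curve("oi_grid", i)
        theta, sigma = sample_random_curve_geometry(rng)
        model = TuningCurveModel(c=c, r_pref=rp, r_null=rn,
                                 theta_pref=theta, sigma=sigma)
        path = sweep_dir / f"oi_grid_{i:02d}.csv"
        write_trials_csv(simulate_trials(model, grid, 10, noise, rng), path)
        written.append(path)
    return written
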