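# Methods

This note records the models, conventions, numerical choices and known
limitations behind `oridir`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Coordinate conventions and angle spaces

All angles are degrees in "compass" convention: a horizontal bar moving
upward is 0° and angles increase clockwise. `convert_coordinates` maps to and
from Cartesian convention (θ_cart = 90° − θ_compass, an involution modulo
360°) at I/O boundaries only; the library is compass throughout. Direction
space has period 360°, orientation space 180°. The wrapped absolute
difference `ang_diff` returns values in [0°, 90°] (orientation) or
[0°, 180°] (direction); it is deliberately the minimum of *absolute*
offsets, since a signed minimum could be negative and would not live on the
stated intervals. Orientation data is obtained from direction data by
averaging each opposite-direction pair per trial (`collapse_to_orientation`);
this halves the grid and preserves the overall mean response.

## Indices

Peak–trough indices read responses at θ_pref and at θ_pref ± 90°,
θ_pref + 180°, where θ_pref is the empirical argmax of the trial-mean curve
(ties break to the lowest angle). Required angles are looked up on the grid
with a tolerance of half the angle step; an index whose angle is missing or
whose denominator is smaller than 10⁻⁹ × max|R| is reported as undefined
with a reason flag rather than raising — population pipelines must be able
to skip unresponsive cells. Negative (below-blank) responses are **not**
clipped anywhere: OI can legitimately exceed 1 when the orthogonal response
falls below background, and simulated trials are likewise left unclipped.
The direction-space resultant length L_dir omits the classical factor of 2
so that a perfectly direction-selective cell scores 1.

Population comparisons of per-cell indices use the classical pooled-variance
two-sample t-test (not Welch); degenerate zero-variance inputs resolve to
p = 1 (equal means) or p = 0.

## Vector significance tests

A trial's orientation vector is the raw, unnormalized sum
Σ_k R_t(θ_k)(cos 2θ_k, sin 2θ_k); direction vectors use single angles.
Normalizing per-trial vectors would destroy the zero-mean null and is never
done. One-sample Hotelling: T² = n·x̄ᵀS⁻¹x̄ with the unbiased covariance S,
F = T²(n−2)/(2(n−1)) on F(2, n−2), requiring n ≥ 3. Two-sample: pooled
covariance, F = T²(n_A+n_B−3)/(2(n_A+n_B−2)) on F(2, n_A+n_B−3).
Covariances with condition number above 10¹² raise a degenerate-data error.

The direction dot product test projects each direction vector onto the unit
vector of the orientation axis — the halved angle of the *same data's* mean
orientation vector, mapped to [0°, 180°) — and applies a two-sided
one-sample t-test of the signed projections against zero. Projections are
signed: an unsigned magnitude could not have mean zero under the null. The
p-value is invariant to flipping the axis by 180° and to rotating stimuli
and vectors together. Sidedness is not dictated by the underlying
construction; two-sided is used and recorded in report metadata. When
orientation selectivity is absent the axis is noise; a requested direction
test still runs but the report carries a warning flag. Independence of the
two stages comes for free on paired grids: orientation vectors depend only
on opposite-pair sums, direction vectors only on their differences.

## Tuning-curve fits

Orientation: R(θ) = C + R_p·exp(−ang_ori(θ−θ_pref)²/(2σ²)). Direction adds a
null lobe at θ_pref + 180° with amplitude R_n and the same σ (independent
lobe widths are not supported; the shared-σ form is the model family used
throughout). Fits run on trial-mean responses — no per-trial weighting —
via bounded trust-region least squares (SciPy `least_squares`, method
`trf`, tolerances 10⁻¹⁰, ≤ 2000 evaluations per start).

Constraint box, with M the largest mean response and α the angle step:
σ ∈ [α/2, 180°], C ∈ [−M, M], R_p, R_n ∈ [0, 3M]. The σ lower bound blocks
needle-thin interpolation minima; the 180° upper bound is the wrap-period
scale beyond which a lobe is indistinguishable from the offset. θ_pref is
unconstrained during optimization (the wrapped difference makes the model
periodic) and wrapped afterwards, avoiding boundary artifacts at 0°/360°.
Starts: θ_pref at the empirical peak, R_p = R_n = M, C = 0, and
σ ∈ {α/2, α, 40°, 60°, 90°} (clipped into the box, deduplicated); the
lowest-SSE solution wins. The double Gaussian is invariant under swapping
lobes with a 180° shift of θ_pref, so the returned model is canonicalized to
R_p ≥ R_n. Exactly constant data short-circuits to the flat model; data with
no positive response returns a flagged degenerate flat fit. HWHH = σ·√(ln 4)
(≈ 1.177σ; the constant is used exactly, not rounded to 1.18). Fit-based
OI/DI evaluate the fitted curve at θ_pref, θ_pref ± 90°, θ_pref + 180°.

Tuning width and preferred angle are masked (explicit nulls) unless the cell
shows significant orientation selectivity by the Hotelling test at a
configurable threshold (default 0.05): with no significant tuning these
parameters are fits to noise. Hessian-based standard errors are deliberately
absent — the active constraints make the error surface non-smooth, so the
Hessian is meaningless here; uncertainty comes from the bootstrap instead.

## Bootstrap

Resampling draws whole trials (rows) with replacement, preserving
within-trial correlation across angles, and refits the direction-space
model; n_boot defaults to 100. The mean preferred direction is the circular
mean of the resampled θ_pref values (arithmetic means are wrong on circles);
"uncertainty" is the fraction of resamples further than 90° (direction
space) from it, and p = 2 × uncertainty, clamped to [1/n_boot, 1] — a
bootstrap cannot resolve probabilities below one resample. A zero-length
mean resultant (perfectly dispersed resamples) yields uncertainty 0.5,
p = 1. Failed refits are excluded and counted. Fixed seeds give bit-identical
results.

## Synthetic-data generator

The generator defines the study conditions used for validation. Ground
truth is a double Gaussian with θ_pref ~ Uniform[0°, 360°) and
σ = (Gamma(shape 3, scale 6) + 10°)/1.18 — mean σ ≈ 23.7°, hard floor
≈ 8.5°, i.e. typical V1-like widths. Amplitudes come from two 21-point
families: the OI grid (C = 10−(i−1)/2, R_p = (i−1)/2, R_n = (i−1)/4)
sweeping true OI from 0 to 1 at moderate direction selectivity, and the DI
grid (C = 0, R_p = 10, R_n = 10−(i−1)/2) sweeping true DI at high
orientation selectivity. Noise is additive Gaussian per trial and angle:
constant-fraction (SD = level × reference_max, reference_max defaulting to
10 Hz, so 20 % noise means 2 Hz), or OGB-affine
(SD = base × reference_max + resp_frac × |expected response|, default
20 % + 10 % × response) emulating bulk-loaded calcium-indicator imaging.
Responses are not rectified at zero, consistent with blank subtraction.

The generator emulates independent Gaussian trial noise only: no spiking
(Poisson) statistics, no noise correlations across angles or trials, no
adaptation or slow drift, and single-peaked Gaussian tuning only. Passing
tests therefore demonstrate correctness and calibration *under this model*;
on real data with correlated or non-Gaussian noise the absolute power
numbers and p-value calibration can differ, though the orderings (vector
indices more reliable than peak–trough; more trials/angles better) are
structural.

"True" indices of a model curve are computed by sampling the noiseless curve
on a grid aligned to θ_pref (same spacing, peak on-grid), which makes them
rotation-invariant, as a ground-truth property of a curve must be. Curves
with an exactly specified true OI or DI are obtained by solving along the
respective grid family — in closed form on grids whose spacing hits 90°/180°
exactly, by bisection otherwise.

## Forward/inverse distributions and power tables

Forward tables report percentiles (5/25/50/75/95) of an empirical readout at
each true-index value; inverse tables bin the readout (width 0.05, bins
centered on multiples of the width) and report the conditional distribution
of the true index, leaving empty bins absent rather than interpolated. The
"best guess" calibration maps a readout bin to the median conditional true
index; estimation-error surfaces report the mean (or median, by flag)
absolute deviation between truth and best guess, with calibration and
evaluation runs seeded independently.

Power computations couple confidence and power at the same level X: the
minimum sample size is the smallest candidate at which ≥ X % of replicate
experiments are significant at α = 1 − X, for X ∈ {95, 99, 99.9}. Candidate
sizes sweep a geometric-ish grid (4, 5, 6, 8, 10, 13, 16, 20, 26, …); a
condition that no swept size satisfies is reported as ">cap". Minimum-size
estimates inherit the binomial noise of the detection fraction near the
crossing, so orderings between conditions are meaningful only to about one
sweep step at 30–100 replicates. Null-calibration runs (flat cells for the
orientation test; direction-indifferent, fully oriented cells for the
direction test) check p-value uniformity by Kolmogorov–Smirnov and the
fraction below 0.05.

Population-difference power simulates two populations of cells with exactly
specified true indices and randomized geometry, 7 trials and 16 angles per
cell by default (trial count chosen to match the angle-difference
simulations), and evaluates both the peak–trough and circular-variance
readouts on the *same* simulated cells — a paired comparison. For
preferred-angle differences, each replicate draws one common random base
preference, shifts population B by Δθ, and compares per-cell mean
orientation vectors with the two-sample Hotelling test; a per-cell uniform
preference would make any Δθ undetectable, which is why the base preference
is shared within a replicate. This test screens for *any* parameter
difference (angle, width, amplitude), not specifically angle.

## Problem sizes used in validation

The packaged validation runs are sized for a desktop: null calibrations use
5,000 replicates (fraction-below-0.05 checked against a binomial 99 % CI,
uniformity by KS at 1 %); grid simulations use the full 21 × 100 design;
population-power orderings use 30 replicate pairs per size and three
base/Δ conditions; bootstrap checks use 50–100 resamples. Monte-Carlo
assertions carry explicit sampling-error allowances: conditional-IQR
comparisons use a 99 % one-sided bootstrap bound on the IQR difference, and
minimum-sample-size orderings allow one sweep grid step.

## Known limitations

- Peak–trough indices depend on the sampled grid containing the orthogonal
  and opposite angles; on sparse or irregular grids they may be undefined
  (flagged, not raised).
- The DI-family power comparison between the DI and 1-DirCirVar readouts is
  close to a tie under this package's unclipped circular variance and
  default noise; the circular-variance advantage is decisive for OI but
  should not be assumed for DI without a power run at your own noise level.
- The direction dot product test presumes a meaningful orientation axis;
  with no orientation selectivity its p-value is reported with a warning
  but is not interpretable as evidence.
- Bootstrap p-values depend on the fit constraints and starts; the ones
  used here are recorded above and in every report, and results are only
  comparable across identical settings.
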