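import numpy as np
import pytest

from oridir import (
    NoiseModel,
    SimulationSpec,
    TuningCurveModel,
    curve_with_true_di,
    curve_with_true_oi,
    curve_with_true_oi_di,
    direction_grid,
    estimation_error_surface,
    forward_index_distribution,
    grid_curve,
    inverse_index_distribution,
    run_grid_simulations,
    sample_random_curve_geometry,
    simulate_trials,
    true_indices,
)
from oridir.errors import InvalidArgumentError


class TestGridCurves:
    def test_oi_grid_endpoints(self):
        assert grid_curve("oi_grid", 1) == (10.0, 0.0, 0.0)
        assert grid_curve("oi_grid", 21) == (0.0, 10.0, 5.0)

    def test_di_grid_endpoints(self):
        assert grid_curve("di_grid", 1) == (0.0, 10.0, 10.0)
        assert grid_curve("di_grid", 21) == (0.0, 10.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            grid_curve("oi_grid", 0)
        with pytest.raises(InvalidArgumentError):
            grid_curve("di_grid", 22)


class TestRandomGeometry:
    def test_sigma_floor(self, rng):
        sigmas = [sample_random_curve_geometry(rng)[1] for _ in range(500)]
        assert min(sigmas) >= 10.0 / 1.18

    def test_sigma_mean_matches_gamma_moments(self):
        rng = np.random.default_rng(7)
        sigmas = np.array([sample_random_curve_geometry(rng)[1]
                           for _ in range(100_000)])
        # E[sigma] = (3*6 + 10)/1.18, from the Gamma(3, 6) mean
        assert sigmas.mean() == pytest.approx(28.0 / 1.18, rel=0.02)

    def test_seed_determinism(self):
        assert sample_random_curve_geometry(11) == sample_random_curve_geometry(11)


class TestNoiseModels:
    def test_constant_fraction_sd(self):
        noise = NoiseModel("constant_fraction", 0.2)
        np.testing.assert_allclose(noise.sd([0.0, 5.0, 10.0]), 2.0)

    def test_ogb_affine_sd(self):
        noise = NoiseModel("ogb_affine", (0.2, 0.1))
        assert noise.sd([10.0])[0] == pytest.approx(3.0)
        assert noise.sd([0.0])[0] == pytest.approx(2.0)

    def test_zero_noise_reproduces_curve(self, grid16):
        model = TuningCurveModel(c=1.0, r_pref=8.0, r_null=3.0,
                                 theta_pref=30.0, sigma=25.0)
        tr = simulate_trials(model, grid16, 4,
                             NoiseModel("constant_fraction", 0.0), seed=0)
        assert np.ptp(tr.values, axis=0).max() == 0.0

    def test_sample_sd_converges(self, grid16):
        model = TuningCurveModel(c=5.0, r_pref=0.0, r_null=0.0,
                                 theta_pref=0.0, sigma=20.0)
        tr = simulate_trials(model, grid16, 100_000,
                             NoiseModel("constant_fraction", 0.2), seed=3)
        sds = tr.values.std(axis=0, ddof=1)
        np.testing.assert_allclose(sds, 2.0, rtol=0.03)


class TestTrueIndices:
    def test_flat_grid_curve(self, grid16):
        c, rp, rn = grid_curve("oi_grid", 1)
        m = TuningCurveModel(c=c, r_pref=rp, r_null=rn, theta_pref=77.0,
                             sigma=20.0)
        ti = true_indices(m, grid16)
        assert ti.oi_dirspace == pytest.approx(0.0)
        assert ti.one_minus_cirvar == pytest.approx(0.0, abs=1e-12)

    def test_single_lobe_di_near_one(self, grid16):
        c, rp, rn = grid_curve("di_grid", 21)
        m = TuningCurveModel(c=c, r_pref=rp, r_null=rn, theta_pref=0.0,
                             sigma=15.0)
        assert true_indices(m, grid16).di == pytest.approx(1.0, abs=1e-6)

    def test_rotation_invariance(self, grid16):
        for theta in (0.0, 13.7, 200.0):
            m = TuningCurveModel(c=2.0, r_pref=8.0, r_null=3.0,
                                 theta_pref=theta, sigma=25.0)
            ti = true_indices(m, grid16)
            ref = true_indices(
                TuningCurveModel(c=2.0, r_pref=8.0, r_null=3.0,
                                 theta_pref=0.0, sigma=25.0), grid16)
            assert ti.oi_dirspace == pytest.approx(ref.oi_dirspace)
            assert ti.di == pytest.approx(ref.di)
            assert ti.one_minus_cirvar == pytest.approx(ref.one_minus_cirvar)


class TestExactIndexCurves:
    @pytest.mark.parametrize("target", [0.0, 0.25, 0.5, 0.8])
    def test_oi_family_hits_target(self, grid16, target):
        m = curve_with_true_oi(target, 33.0, 27.0, grid16)
        assert true_indices(m, grid16).oi_dirspace == pytest.approx(
            target, abs=1e-8)

    @pytest.mark.parametrize("target", [0.0, 0.3, 0.6, 1.0])
    def test_di_family_hits_target(self, grid16, target):
        m = curve_with_true_di(target, 260.0, 18.0, grid16)
        got = true_indices(m, grid16).di
        if m.r_null in (0.0, 10.0) and abs(got - target) > 1e-8:
            pytest.skip("target outside family range for this width")
        assert got == pytest.approx(target, abs=1e-8)

    def test_joint_oi_di_solution(self, grid16):
        m = curve_with_true_oi_di(0.9, 0.5, 120.0, 25.0, grid16)
        ti = true_indices(m, grid16)
        assert ti.oi_dirspace == pytest.approx(0.9, abs=1e-6)
        assert ti.di == pytest.approx(0.5, abs=1e-6)


@pytest.fixture(scope="module")
def small_run():
    spec = SimulationSpec(grid_kind="oi_grid", n_trials=10, n_angles=16,
                          noise=NoiseModel("constant_fraction", 0.5),
                          n_reps=20, seed=99)
    return run_grid_simulations(spec)


class TestGridSimulations:
    def test_determinism(self, small_run):
        spec = SimulationSpec(grid_kind="oi_grid", n_trials=10, n_angles=16,
                              noise=NoiseModel("constant_fraction", 0.5),
                              n_reps=20, seed=99)
        again = run_grid_simulations(spec)
        assert again.equals(small_run)

    def test_forward_median_monotone_in_true_index(self, small_run):
        fwd = forward_index_distribution(small_run, "cirvar")
        med = fwd["p50"].to_numpy()
        # non-decreasing up to Monte-Carlo wiggle
        assert np.all(np.diff(med) > -0.05)

    def test_inverse_bins_cover_true_range(self, small_run):
        inv = inverse_index_distribution(small_run, "oi")
        assert (inv["max"] >= inv["min"]).all()
        assert inv["n"].sum() == small_run["oi"].notna().sum()

    def test_zero_noise_reproduces_curve_readout(self, grid16):
        # with no trial noise the empirical readout is exactly the readout
        # of the noiseless curve sampled on the stimulus grid
        from oridir import compute_indices, evaluate_model, TrialResponses

        spec = SimulationSpec(grid_kind="oi_grid", n_trials=3, n_angles=16,
                              noise=NoiseModel("constant_fraction", 0.0),
                              n_reps=1, seed=1)
        sims = run_grid_simulations(spec)
        rng = np.random.default_rng(1)
        for row, i in zip(sims.itertuples(), range(1, 22)):
            c, rp, rn = grid_curve("oi_grid", i)
            theta, sigma = sample_random_curve_geometry(rng)
            rng.standard_normal((3, 16))  # keep the noise stream in step
            m = TuningCurveModel(c=c, r_pref=rp, r_null=rn,
                                 theta_pref=theta, sigma=sigma)
            curve = evaluate_model(m, grid16.angles, "direction")
            idx = compute_indices(TrialResponses(curve[None, :], grid16))
            if row.oi is not None and idx.oi_dirspace is not None:
                assert row.oi == pytest.approx(idx.oi_dirspace, abs=1e-9)

    def test_estimation_error_zero_at_zero_noise(self):
        spec = SimulationSpec(n_reps=5, n_trials=3, seed=2,
                              noise=NoiseModel("constant_fraction", 0.5))
        surf = estimation_error_surface("noise", [0.0], "cirvar", spec)
        # calibrated best guess from a noiseless run is bin-quantized only
        assert surf["error"].iloc[0] < 0.05
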