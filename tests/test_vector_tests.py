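import numpy as np
import pytest

from oridir import (
    AngleGrid,
    NoiseModel,
    TrialResponses,
    TrialVectorSet,
    TuningCurveModel,
    direction_dot_product_test,
    direction_grid,
    hotelling_t2_one_sample,
    hotelling_t2_two_sample,
    orientation_axis_angle,
    per_trial_vectors,
    selectivity_tests,
    simulate_trials,
)
from oridir.errors import DegenerateDataError, InsufficientDataError


class TestPerTrialVectors:
    def test_single_direction_response(self, grid4):
        vs = per_trial_vectors(TrialResponses([[10, 0, 0, 0]], grid4), "direction")
        np.testing.assert_allclose(vs.vectors, [[10.0, 0.0]], atol=1e-12)

    def test_flat_trial_cancels(self, grid16):
        vs = per_trial_vectors(
            TrialResponses([np.full(16, 3.0)], grid16), "direction")
        np.testing.assert_allclose(vs.vectors, [[0.0, 0.0]], atol=1e-10)

    def test_orientation_angles_doubled(self):
        grid = AngleGrid([0.0, 45.0], "orientation")
        vs = per_trial_vectors(TrialResponses([[3.0, 4.0]], grid), "orientation")
        np.testing.assert_allclose(vs.vectors, [[3.0, 4.0]], atol=1e-12)

    def test_direction_data_collapsed_for_orientation(self, tuned_cell):
        vs = per_trial_vectors(tuned_cell, "orientation")
        assert vs.space == "orientation"
        assert vs.n_trials == tuned_cell.n_trials


class TestHotellingOneSample:
    def test_symmetric_sample_gives_t2_zero(self):
        v = np.array([[1.0, 2.0], [-1.0, -2.0], [2.0, -1.0], [-2.0, 1.0]])
        res = hotelling_t2_one_sample(TrialVectorSet(v, "orientation"))
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_identical_vectors_are_degenerate(self):
        v = np.tile([1.0, 2.0], (5, 1))
        with pytest.raises(DegenerateDataError):
            hotelling_t2_one_sample(TrialVectorSet(v, "orientation"))

    def test_matches_textbook_formula_on_fixed_sample(self):
        # frozen from an explicit covariance/inverse computation
        v = [[2.0, 1.0], [1.5, -0.5], [3.0, 0.5], [2.5, 1.5],
             [1.0, 0.0], [2.0, -1.0], [2.5, 0.5]]
        res = hotelling_t2_one_sample(TrialVectorSet(v, "orientation"))
        assert res.t2 == pytest.approx(77.0860927152318)
        assert res.f_stat == pytest.approx(32.11920529801325)
        assert res.p == pytest.approx(0.0014013844242172437)
        assert res.dof == (2, 5)

    def test_needs_three_trials(self):
        with pytest.raises(InsufficientDataError):
            hotelling_t2_one_sample(TrialVectorSet([[1, 0], [0, 1]], "orientation"))


class TestHotellingTwoSample:
    def test_identical_samples_shuffled(self):
        a = np.array([[1.0, 0.0], [2.0, 1.0], [0.0, -1.0], [1.5, 1.5]])
        res = hotelling_t2_two_sample(
            TrialVectorSet(a, "orientation"),
            TrialVectorSet(a[::-1], "orientation"))
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_separated_clusters(self, rng):
        a = rng.normal([10, 0], 0.5, (6, 2))
        b = rng.normal([-10, 0], 0.5, (6, 2))
        res = hotelling_t2_two_sample(TrialVectorSet(a, "orientation"),
                                      TrialVectorSet(b, "orientation"))
        assert res.p < 1e-3

    def test_matches_textbook_formula_on_fixed_samples(self):
        a = [[1, 0.5], [2, -0.5], [1.5, 1], [0.5, 0], [1, 1.0]]
        b = [[-0.5, 0], [0, 1], [-1, 0.5], [0.5, -0.5], [-0.5, 1.0]]
        res = hotelling_t2_two_sample(TrialVectorSet(a, "orientation"),
                                      TrialVectorSet(b, "orientation"))
        assert res.t2 == pytest.approx(19.77382875605816)
        assert res.f_stat == pytest.approx(8.651050080775445)
        assert res.p == pytest.approx(0.012825958115518262)
        assert res.dof == (2, 7)


class TestOrientationAxis:
    @pytest.mark.parametrize("mean_dir,expected", [
        ((1.0, 0.0), 0.0), ((0.0, 1.0), 45.0), ((-1.0, 0.0), 90.0),
    ])
    def test_axis_halves_mean_vector_angle(self, mean_dir, expected):
        v = np.array(mean_dir) + np.array([[0.1, 0], [-0.1, 0], [0, 0.1], [0, -0.1]])
        assert orientation_axis_angle(
            TrialVectorSet(v, "orientation")) == pytest.approx(expected)

    def test_zero_mean_vector_degenerate(self):
        v = [[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]
        with pytest.raises(DegenerateDataError):
            orientation_axis_angle(TrialVectorSet(v, "orientation"))


class TestDirectionDotProduct:
    def test_alternating_projections_mean_zero(self):
        v = [[2.0, 0.0], [-2.0, 0.0], [2.0, 0.0], [-2.0, 0.0]]
        res = direction_dot_product_test(TrialVectorSet(v, "direction"), 0.0)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_aligned_vectors_strongly_significant(self, rng):
        v = np.array([5.0, 0.0]) + 0.1 * rng.standard_normal((7, 2))
        res = direction_dot_product_test(TrialVectorSet(v, "direction"), 0.0)
        assert res.p < 0.05

    def test_matches_hand_computed_t(self):
        proj = [2.0, -0.5, 1.5, 3.0, 0.5, -1.0, 2.5]
        v = [[x, 0.0] for x in proj]
        res = direction_dot_product_test(TrialVectorSet(v, "direction"), 0.0)
        assert res.t_stat == pytest.approx(1.9896640134952275)
        assert res.p == pytest.approx(0.09375968514006)
        assert res.dof == 6

    def test_p_invariant_to_axis_flip(self, tuned_cell):
        vs = per_trial_vectors(tuned_cell, "direction")
        axis = orientation_axis_angle(per_trial_vectors(tuned_cell, "orientation"))
        p1 = direction_dot_product_test(vs, axis).p
        p2 = direction_dot_product_test(vs, axis + 180.0).p
        assert p1 == pytest.approx(p2)

    def test_invariant_to_global_rotation(self, grid16):
        model = TuningCurveModel(c=0.0, r_pref=10.0, r_null=4.0,
                                 theta_pref=20.0, sigma=25.0)
        noise = NoiseModel("constant_fraction", 0.2)
        tr = simulate_trials(model, grid16, 7, noise, seed=9)
        rolled = TrialResponses(np.roll(tr.values, 3, axis=1), grid16)
        p = selectivity_tests(tr).direction.p
        p_rot = selectivity_tests(rolled).direction.p
        assert p == pytest.approx(p_rot, rel=1e-9)


class TestCombinedWorkflow:
    def test_tuned_cell_significant(self, tuned_cell):
        rep = selectivity_tests(tuned_cell)
        assert rep.orientation.p < 0.05
        assert rep.orientation_significant
        assert rep.direction is not None
        assert not rep.direction_tested_without_orientation

    def test_flat_cell_flags_direction_warning(self, flat_cell):
        rep = selectivity_tests(flat_cell)
        if not rep.orientation_significant and rep.direction is not None:
            assert rep.direction_tested_without_orientation
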