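"""Shape analysis: finite differences, inflection detection, classification."""

import numpy as np
import pytest

from funcresp import (
    ClassificationThresholds,
    ParameterError,
    PredatorParams,
    ResponseCurve,
    ShapeType,
    classify,
    classify_curve,
    find_inflection,
    finite_differences,
    holling_closed_form,
    offered_grid,
    response_curve,
)
from funcresp.shape import DerivativeProfile


def _curve(x, y):
    return ResponseCurve(offered=np.asarray(x, float), consumed=np.asarray(y, float))


class TestFiniteDifferences:
    def test_exact_on_polynomials(self):
        """Central differences are exact for d1 on quadratics and for d2 on
        cubics."""
        x = np.linspace(0.0, 10.0, 21)
        lin = finite_differences(_curve(x, 2.0 * x))
        np.testing.assert_allclose(lin.d1, 2.0, atol=1e-12)
        np.testing.assert_allclose(lin.d2, 0.0, atol=1e-12)

        quad = finite_differences(_curve(x, x**2))
        np.testing.assert_allclose(quad.d2, 2.0, atol=1e-10)

        cub = finite_differences(_curve(x, x**3))
        i = np.searchsorted(cub.offered_interior, 2.0)
        assert cub.d2[i] == pytest.approx(12.0, rel=1e-10)

    def test_interior_convention(self):
        x = np.linspace(0.0, 1.0, 11)
        prof = finite_differences(_curve(x, x))
        assert prof.offered_interior.size == 9
        np.testing.assert_allclose(prof.offered_interior, x[1:-1])

    def test_normalized_d2_is_scale_free(self):
        """Rescaling both axes of the curve leaves normalized_d2 unchanged."""
        x = np.linspace(1.0, 200.0, 200)
        y = 1.0 / (1.0 + np.exp(-(x - 50.0) / 10.0))
        g1 = finite_differences(_curve(x, y)).normalized_d2
        g2 = finite_differences(_curve(x * 3.0, y * 40.0)).normalized_d2
        # rescaling perturbs the last bits of y, which the second difference
        # amplifies by 1/spacing^2 — hence the loose absolute floor
        np.testing.assert_allclose(g1, g2, rtol=1e-6, atol=1e-9)

    def test_flat_curve_has_zero_normalized_d2(self):
        x = np.linspace(0.0, 1.0, 11)
        prof = finite_differences(_curve(x, np.full_like(x, 2.0)))
        np.testing.assert_allclose(prof.normalized_d2, 0.0)

    def test_smoothing_window_validation(self):
        x = np.linspace(0.0, 1.0, 11)
        with pytest.raises(ParameterError):
            finite_differences(_curve(x, x), smooth_window=4)


class TestFindInflection:
    def test_interpolated_crossing(self):
        prof = DerivativeProfile(
            offered_interior=np.array([1.0, 2.0, 3.0, 4.0]),
            d1=np.zeros(4),
            d2=np.array([1.0, 0.5, -0.2, -0.5]),
            normalized_d2=np.array([1.0, 0.5, -0.2, -0.5]),
        )
        loc = find_inflection(prof, persistence=1)
        assert loc == pytest.approx(2.0 + 0.5 / 0.7, abs=1e-9)  # ~2.714

    def test_all_negative_has_none(self):
        prof = DerivativeProfile(
            offered_interior=np.linspace(1, 10, 10),
            d1=np.zeros(10),
            d2=-np.ones(10),
            normalized_d2=-np.ones(10),
        )
        assert find_inflection(prof) is None

    def test_logistic_midpoint(self):
        """The logistic 1/(1+e^-(x-5)) inflects at its midpoint x=5."""
        x = np.arange(0.0, 10.0 + 1e-9, 0.01)
        y = 1.0 / (1.0 + np.exp(-(x - 5.0)))
        loc = find_inflection(finite_differences(_curve(x, y)))
        assert loc == pytest.approx(5.0, abs=0.01)

    def test_single_point_flip_suppressed(self):
        """A one-point positive blip inside a negative profile is not an
        inflection when persistence > 1."""
        d2 = -np.ones(30)
        d2[10] = 0.5
        prof = DerivativeProfile(
            offered_interior=np.linspace(1, 30, 30),
            d1=np.zeros(30),
            d2=d2,
            normalized_d2=d2,
        )
        assert find_inflection(prof, persistence=5) is None
        assert find_inflection(prof, persistence=1) is not None


class TestClassify:
    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            ClassificationThresholds(eps_lin=0.05, eps_pos=0.02)
        with pytest.raises(ParameterError):
            ClassificationThresholds(eps_lin=-0.01)

    def test_linear_curve_is_type_i(self):
        x = np.linspace(1.0, 200.0, 100)
        res = classify_curve(_curve(x, 0.5 * x))
        assert res.shape is ShapeType.TYPE_I
        assert res.inflection_offered is None

    def test_disk_equation_is_type_ii(self, disk_params, offered_coarse):
        curve = response_curve(disk_params, offered_coarse)
        res = classify_curve(curve)
        assert res.shape is ShapeType.TYPE_II
        assert res.max_d2 <= 1e-12
        assert res.inflection_offered is None

    def test_attack_learning_is_type_iii(self, attack_learner, offered_coarse):
        curve = response_curve(attack_learner, offered_coarse)
        res = classify_curve(curve)
        assert res.shape is ShapeType.TYPE_III
        assert res.inflection_offered is not None
        assert res.max_normalized_d2 > 0

    def test_type_iii_implies_inflection_present(self, attack_learner, offered_coarse):
        res = classify_curve(response_curve(attack_learner, offered_coarse))
        assert (res.shape is ShapeType.TYPE_III) == (
            res.inflection_offered is not None
        )

    def test_attenuated_sigmoid_is_near_type_ii(self):
        """A curve with an inflection but tiny positive curvature: y = x +
        A x^2 (1 - x) on [0,1] has normalized d2 = A(2 - 6x); A = 0.02
        keeps max g = 0.04 below the type-III floor."""
        x = np.linspace(0.0, 1.0, 101)
        a = 0.02
        res = classify_curve(_curve(x, x + a * x**2 * (1 - x)))
        assert res.shape is ShapeType.NEAR_TYPE_II

    def test_late_convexity_is_near_type_i(self):
        """Small curvature that turns positive at high offered values with
        no positive-to-negative crossing: y = x + A x^3."""
        x = np.linspace(0.0, 1.0, 101)
        res = classify_curve(_curve(x, x + 0.01 * x**3))
        assert res.shape is ShapeType.NEAR_TYPE_I

    def test_disk_curves_never_type_i_or_iii(self):
        """Negative control: exact disk-equation curves with strong
        saturation (a h D_max >> 1) classify as type II, never I or III."""
        x = offered_grid(1.0, 200.0, 1.0)
        for a, h in [(0.1, 0.1), (0.5, 0.2), (1.0, 0.1), (0.2, 1.0)]:
            y = np.array([holling_closed_form(a, h, d, 1.0) for d in x])
            res = classify_curve(_curve(x, y))
            assert res.shape not in (ShapeType.TYPE_I, ShapeType.TYPE_III)

    def test_no_learning_d2_negative_and_waning(self, disk_params, offered_coarse):
        """Type II signature: d2 < 0 everywhere with |d2| decreasing toward
        zero as offered prey grows."""
        prof = finite_differences(response_curve(disk_params, offered_coarse))
        assert np.all(prof.d2 < 0)
        assert np.all(np.diff(np.abs(prof.d2)) <= 1e-15)

    @pytest.mark.parametrize("a0,la", [(0.05, 0.3), (0.1, 0.5), (0.2, 0.2), (0.3, 0.8)])
    def test_attack_learning_convex_at_low_density(self, a0, la, offered_coarse):
        """With a large attack-learning amplitude the curve is convex at low
        prey densities: experience gains outpace the handling limitation."""
        p = PredatorParams.from_values(a0, 1.0, la, 0.1, 0.1, 0.0)
        prof = finite_differences(response_curve(p, offered_coarse))
        assert prof.d2[0] > 0

    @pytest.mark.parametrize(
        "params",
        [
            PredatorParams.from_values(0.2, 1.0, 0.2, 0.1, 0.1, 0.0),
            PredatorParams.from_values(0.8, 1.0, 0.05, 0.1, 0.1, 0.0),
            PredatorParams.no_learning(0.1, 0.1),
        ],
    )
    def test_classification_stable_under_grid_refinement(self, params):
        """Halving the offered step does not change the class for parameter
        points away from region boundaries."""
        coarse = classify_curve(response_curve(params, offered_grid(1, 200, 0.5)))
        fine = classify_curve(response_curve(params, offered_grid(1, 200, 0.25)))
        assert coarse.shape is fine.shape

    def test_result_serialization(self, attack_learner, offered_coarse):
        res = classify_curve(response_curve(attack_learner, offered_coarse))
        d = res.to_dict()
        assert d["shape"] == "TYPE_III"
        assert set(d) >= {"shape", "inflection_offered", "max_d2", "max_normalized_d2"}
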