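"""The tracer-free route: C coefficients, meal-invariance objective,
closed-form oracle, and multistart estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egpest.data import DiurnalDataset, MealSegment
from egpest.errors import DegenerateDesignError
from egpest.model import (
    LiverEGPModel,
    MultistartConfig,
    _tracerfree_objective_reduced,
    c_coefficients,
    closed_form_ratio_and_A,
    tracerfree_objective,
)
from egpest.signals import BasalAnchors, SegmentAnchors


def _anchors(b, l, d):
    """Build BasalAnchors from (gp_b, id_b, ipo_b) triples; egp_b is inert."""
    return BasalAnchors(
        breakfast=SegmentAnchors(*b, egp_b=2.0),
        lunch=SegmentAnchors(*l, egp_b=1.9),
        dinner=SegmentAnchors(*d, egp_b=1.8),
    )


theta_box = st.tuples(
    st.floats(0.0009, 0.02), st.floats(0.001, 0.05),
    st.floats(0.01, 0.09), st.floats(0.8, 1.4),
)
anchor_triple = st.tuples(
    st.floats(50.0, 400.0), st.floats(5.0, 200.0), st.floats(0.5, 20.0),
)


class TestCCoefficients:
    def test_lunch_arithmetic(self):
        seg = SegmentAnchors(gp_b=180.0, id_b=50.0, ipo_b=2.0, egp_b=1.9)
        c23, c24, c34 = c_coefficients((0.01, 0.01, 0.05, 1.0), seg, "lunch")
        assert (c23, c24, c34) == pytest.approx((1.3, 1.7, 0.4))

    def test_breakfast_uses_a_times_kp4(self):
        seg = SegmentAnchors(gp_b=180.0, id_b=50.0, ipo_b=2.0, egp_b=2.0)
        c23, c24, c34 = c_coefficients((0.01, 0.01, 0.05, 0.8), seg, "breakfast")
        assert c24 == pytest.approx(1.8 - 0.8 * 0.1)
        assert c34 == pytest.approx(0.5 - 0.08)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(theta=theta_box, tri=anchor_triple,
           label=st.sampled_from(["breakfast", "lunch", "dinner"]))
    def test_c34_identity_is_exact(self, theta, tri, label):
        seg = SegmentAnchors(*tri, egp_b=2.0)
        c23, c24, c34 = c_coefficients(theta, seg, label)
        assert c34 == c24 - c23  # bitwise, not approx


class TestObjective:
    def test_identical_anchors_give_zero_at_a_equal_one(self):
        tri = (180.0, 50.0, 2.0)
        anchors = _anchors(tri, tri, tri)
        assert tracerfree_objective((0.01, 0.02, 0.05, 1.0), anchors) == 0.0

    def test_hand_computed_value(self):
        anchors = _anchors((180.0, 50.0, 2.0), (200.0, 60.0, 2.5), (190.0, 55.0, 2.2))
        obj = tracerfree_objective((0.01, 0.02, 0.05, 1.0), anchors)
        expected = 2 * np.sqrt(0.175**2 + 0.09**2 + 0.085**2)
        assert obj == pytest.approx(expected, rel=1e-9)
        assert obj == pytest.approx(0.42872, abs=5e-6)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(theta=theta_box, b=anchor_triple, l=anchor_triple, d=anchor_triple)
    def test_reduces_to_twice_rms_of_c24_differences(self, theta, b, l, d):
        """Because C34 = C24 - C23, the full pairwise objective collapses to
        2 * sqrt(sum of squared C24 differences)."""
        anchors = _anchors(b, l, d)
        full = tracerfree_objective(theta, anchors)
        reduced = _tracerfree_objective_reduced(theta, anchors)
        assert full == pytest.approx(reduced, rel=1e-12, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(theta=theta_box, b=anchor_triple, l=anchor_triple, d=anchor_triple,
           lam=st.floats(0.1, 10.0))
    def test_homogeneous_of_degree_one_in_the_rate_parameters(self, theta, b, l, d, lam):
        anchors = _anchors(b, l, d)
        kp2, kp3, kp4, a = theta
        scaled = (lam * kp2, lam * kp3, lam * kp4, a)
        assert tracerfree_objective(scaled, anchors) == pytest.approx(
            lam * tracerfree_objective(theta, anchors), rel=1e-9, abs=1e-15)


class TestClosedFormOracle:
    def test_worked_example(self):
        anchors = _anchors((210.0, 50.0, 7.5), (200.0, 48.0, 4.0), (190.0, 46.0, 2.0))
        r, a = closed_form_ratio_and_A(anchors)
        assert r == pytest.approx(0.2)
        assert a == pytest.approx(0.8)
        # any theta with kp2/kp4 = r and this A zeroes the objective
        assert tracerfree_objective((0.01, 0.02, 0.05, a), anchors) < 1e-14

    def test_equal_lunch_dinner_portal_gives_zero_ratio(self):
        anchors = _anchors((210.0, 50.0, 7.5), (200.0, 48.0, 3.0), (190.0, 46.0, 3.0))
        r, _ = closed_form_ratio_and_A(anchors)
        assert r == 0.0

    def test_identical_anchors_are_degenerate(self):
        tri = (200.0, 50.0, 3.0)
        with pytest.raises(DegenerateDesignError):
            closed_form_ratio_and_A(_anchors(tri, tri, tri))


class TestEstimation:
    def test_recovers_ratio_and_a_on_consistency_data(self, consistency_model,
                                                      consistency_synth):
        truth = consistency_synth.truth["theta"]
        res = consistency_model.fit(n_starts=40, seed=3)
        assert res.objective_value < 1e-8
        assert res.ratio_kp2_kp4 == pytest.approx(truth.kp2 / truth.kp4, abs=1e-3)
        assert res.params.A == pytest.approx(truth.A, abs=1e-3)
        r_cf, a_cf = closed_form_ratio_and_A(consistency_model.anchors)
        assert res.ratio_kp2_kp4 == pytest.approx(r_cf, abs=1e-3)
        assert res.params.A == pytest.approx(a_cf, abs=1e-3)
        assert res.bounds.contains(res.theta)

    def test_kp3_does_not_move_a_zero_objective_solution(self, consistency_model):
        """The objective never sees kp3: perturbing it anywhere in bounds
        leaves a zero-objective solution at zero."""
        res = consistency_model.fit(n_starts=40, seed=3)
        theta = res.theta.copy()
        for kp3 in (0.001, 0.01, 0.05):
            theta[1] = kp3
            assert consistency_model.objective(theta) == pytest.approx(
                res.objective_value, abs=1e-12)

    def test_same_seed_reproduces_the_result_exactly(self, consistency_model):
        r1 = consistency_model.fit(n_starts=25, seed=9)
        r2 = consistency_model.fit(n_starts=25, seed=9)
        np.testing.assert_array_equal(r1.theta, r2.theta)
        assert r1.objective_value == r2.objective_value
        assert [(s.index, s.objective) for s in r1.starts] == \
               [(s.index, s.objective) for s in r2.starts]

    def test_identical_meals_push_a_to_one(self, rich_synth):
        """With identical anchors the only breakfast-invariance violation is
        kp4*Ipo_b*(1 - A), so the estimate drives A to 1 and warns about the
        degenerate design."""
        seg = rich_synth.dataset["breakfast"]
        clones = [
            MealSegment(lab, seg.times, seg.glucose, seg.insulin, seg.isr, None)
            for lab in ("breakfast", "lunch", "dinner")
        ]
        ds = DiurnalDataset(tuple(clones),
                            {"breakfast": 2.0, "lunch": 2.0, "dinner": 2.0})
        model = LiverEGPModel(ds)
        with pytest.warns(UserWarning, match="degenerate"):
            res = model.fit(n_starts=25, seed=5)
        assert res.params.A == pytest.approx(1.0, abs=1e-6)

    def test_latin_hypercube_and_uniform_schemes_stay_in_bounds(self, consistency_model):
        for scheme in ("latin_hypercube", "uniform"):
            cfg = MultistartConfig(n_starts=10, seed=2, scheme=scheme)
            res = consistency_model.fit(config=cfg)
            assert res.bounds.contains(res.theta)
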