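"""The synthetic diurnal generator and its ground-truth guarantees."""

import numpy as np
import pytest

from egpest.errors import DegenerateDesignError, InfeasibleConfigError, InvalidInputError
from egpest.model import LiverEGPModel, LiverParams, closed_form_ratio_and_A
from egpest.signals import SegmentAnchors, basal_anchors, derive_signals
from egpest.simulate import (
    SAMPLING_GRID,
    GeneratorConfig,
    generate_dataset,
    make_consistent_anchors,
    meal_bump,
)

MEALS = ("breakfast", "lunch", "dinner")


class TestMealBump:
    def test_normalisation_and_endpoints(self):
        assert meal_bump(45.0, 60.0, 45.0, 2.0) == pytest.approx(60.0)
        assert meal_bump(0.0, 60.0, 45.0, 2.0) == 0.0

    def test_derived_value_at_twice_the_peak(self):
        assert meal_bump(90.0, 60.0, 45.0, 2.0) == pytest.approx(240.0 * np.exp(-2.0))

    def test_decays_towards_zero(self):
        assert meal_bump(2400.0, 60.0, 45.0, 2.0) < 1e-6

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            meal_bump(10.0, 60.0, 0.0, 2.0)
        with pytest.raises(InvalidInputError):
            meal_bump(-1.0, 60.0, 45.0, 2.0)


class TestGeneration:
    def test_uses_the_standard_sampling_grid(self, rich_synth):
        for lab in MEALS:
            np.testing.assert_array_equal(rich_synth.dataset[lab].times,
                                          np.asarray(SAMPLING_GRID))

    def test_egp_satisfies_the_liver_equation_at_every_sample(self, rich_synth):
        """Noise-free EGP is exactly kp1 - kp2 Gp - kp3 Id - kp4* Ipo, with
        the per-segment anchoring making EGP(0) = EGP_basal."""
        p = rich_synth.truth["theta"]
        for lab in MEALS:
            sig = rich_synth.signals[lab]
            kp4s = p.A * p.kp4 if lab == "breakfast" else p.kp4
            kp1 = rich_synth.truth["kp1"][lab]
            manual = kp1 - p.kp2 * sig.gp - p.kp3 * sig.idl - kp4s * sig.ipo
            np.testing.assert_allclose(rich_synth.clean_egp[lab], manual,
                                       rtol=1e-12, atol=1e-12)
            assert rich_synth.clean_egp[lab][0] == pytest.approx(
                rich_synth.truth["egp_basal"][lab], abs=1e-12)

    def test_same_seed_is_bit_identical(self):
        cfg = GeneratorConfig(noise_scale=1.0, seed=42)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for lab in MEALS:
            for attr in ("glucose", "insulin", "isr", "egp"):
                np.testing.assert_array_equal(getattr(a.dataset[lab], attr),
                                              getattr(b.dataset[lab], attr))

    def test_equal_drifts_are_a_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            generate_dataset(GeneratorConfig(drift=(1.0, 1.0, 1.0)))

    def test_subject_class_sets_the_constant_selection(self):
        t2d = generate_dataset(GeneratorConfig(subject_class="t2d",
                                               theta=(0.0042, 0.0073, 0.037, 0.88)))
        assert t2d.truth["constants"].vg == 1.49
        assert t2d.truth["constants"].ki == 0.0066

    def test_noise_scale_zero_reproduces_clean_curves(self, rich_synth):
        for lab in MEALS:
            np.testing.assert_array_equal(rich_synth.dataset[lab].egp,
                                          rich_synth.clean_egp[lab])

    def test_noise_spread_matches_the_sigma_model(self):
        """Across 200 seeded replicates the spread of noisy EGP about the
        clean curve tracks sigma = 0.10 y + 0.05 max(y): the pooled
        sigma-normalised spread per curve is 1, and no single sample
        deviates implausibly."""
        clean = generate_dataset(GeneratorConfig(seed=0))
        reps = [generate_dataset(GeneratorConfig(noise_scale=1.0, seed=s))
                for s in range(200)]
        for lab in MEALS:
            y = clean.clean_egp[lab]
            sigma = 0.10 * y + 0.05 * np.max(y)
            z = np.array([(r.dataset[lab].egp - y) / sigma for r in reps])
            pooled = z.std(ddof=1)
            assert abs(pooled - 1.0) < 0.15
            # per-sample spread estimates carry ~5% sampling noise at n=200
            assert np.all(np.abs(z.std(axis=0, ddof=1) - 1.0) < 4 / np.sqrt(2 * 199))

    def test_realism_soft_check_warns_outside_the_envelope(self):
        """The default preset's nadir depth is physiological but arrives
        late (the slow insulin-action chain), so the soft check warns rather
        than fails."""
        with pytest.warns(UserWarning, match="EGP suppression"):
            synth = generate_dataset(GeneratorConfig())
        egp_b = synth.truth["egp_basal"]["breakfast"]
        frac = synth.clean_egp["breakfast"].min() / egp_b
        assert 0.30 <= frac <= 0.70


class TestConsistencyMode:
    def test_worked_anchor_construction(self):
        """kp2=0.01, kp4=0.05, A=0.8, breakfast (Gp=210, Ipo=7.5), glucose
        drifts to Gp 200 and 190: implied Ipo are 4 and 2."""
        theta = LiverParams(0.01, 0.01, 0.05, 0.8)
        bfast = SegmentAnchors(gp_b=210.0, id_b=50.0, ipo_b=7.5, egp_b=2.0)
        lunch, dinner = make_consistent_anchors(theta, bfast, (200 / 210, 190 / 210))
        assert lunch[0] == pytest.approx(200.0)
        assert lunch[2] == pytest.approx(4.0)
        assert dinner[2] == pytest.approx(2.0)

    def test_unit_drifts_and_a_one_reproduce_breakfast(self):
        theta = LiverParams(0.01, 0.01, 0.05, 1.0)
        bfast = SegmentAnchors(gp_b=210.0, id_b=50.0, ipo_b=7.5, egp_b=2.0)
        lunch, dinner = make_consistent_anchors(theta, bfast, (1.0, 1.0))
        assert lunch == pytest.approx((210.0, 50.0, 7.5))
        assert dinner == pytest.approx((210.0, 50.0, 7.5))

    def test_infeasible_construction_raises(self):
        theta = LiverParams(0.02, 0.001, 0.01, 0.8)  # kp2/kp4 = 2
        bfast = SegmentAnchors(gp_b=200.0, id_b=40.0, ipo_b=1.0, egp_b=2.0)
        with pytest.raises(InfeasibleConfigError):
            make_consistent_anchors(theta, bfast, (0.5, 0.6))

    def test_objective_is_zero_at_the_truth(self, consistency_synth):
        model = LiverEGPModel(consistency_synth.dataset)
        assert model.objective(consistency_synth.truth["theta"].to_array()) < 1e-12

    def test_closed_form_round_trip_recovers_the_truth(self, consistency_synth):
        """The estimator's closed-form oracle inverts the generator's anchor
        construction exactly."""
        truth = consistency_synth.truth["theta"]
        r, a = closed_form_ratio_and_A(consistency_synth.anchors)
        assert r == pytest.approx(truth.kp2 / truth.kp4, rel=1e-9)
        assert a == pytest.approx(truth.A, rel=1e-9)

    def test_derived_anchors_of_the_dataset_match_the_construction(self,
                                                                   consistency_synth):
        """Re-deriving signals from the generated curves lands back on the
        constructed anchor triples."""
        consts = consistency_synth.truth["constants"]
        sig = derive_signals(consistency_synth.dataset, consts)
        anch = basal_anchors(sig, consistency_synth.dataset)
        for lab in MEALS:
            built = consistency_synth.anchors[lab]
            assert anch[lab].gp_b == pytest.approx(built.gp_b, rel=1e-9)
            assert anch[lab].id_b == pytest.approx(built.id_b, rel=1e-9)
            assert anch[lab].ipo_b == pytest.approx(built.ipo_b, rel=1e-9)
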