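"""Synthetic diurnal three-meal datasets with known ground truth.

The generator emulates a triple-meal study: three 240-minute segments
sampled at 0, 15, 30, 45, 60, 90, 120, 150, 180, 210 and 240 minutes after
each meal, with gamma-shaped post-prandial bumps on top of per-segment basal
levels and the EGP curve produced exactly by the liver-subsystem equations
at a known parameter vector.  In *consistency mode* the lunch and dinner
basal levels are constructed so the meal-invariance assumption behind the
tracer-free objective holds exactly, making the generating (kp2/kp4, A)
recoverable in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .data import MEAL_LABELS, DiurnalDataset, MealSegment, select_constants
from .errors import DegenerateDesignError, InfeasibleConfigError, InvalidInputError
from .model import LiverParams, anchors_are_degenerate, egp_timecourse
from .signals import BasalAnchors, SegmentAnchors, basal_anchors, derive_signals

#: the standard post-meal sampling grid (minutes since meal)
SAMPLING_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)

#: meal sizes (g) at 8 a.m. / 12 p.m. / 8 p.m. — metadata only, not modelled
MEAL_METADATA = {"breakfast": (45, "8 a.m."), "lunch": (70, "12 p.m."), "dinner": (70, "8 p.m.")}

_CLASS_GLUCOSE_BASAL = {"healthy": 90.0, "pre_diabetic": 112.0, "t2d": 150.0}


def meal_bump(t, amplitude: float, t_peak: float, shape: float = 2.0):
    """Smooth single-peak meal response: zero at t = 0, peak ``amplitude`` at
    ``t_peak``, decaying back towards zero.

    bump(t) = amplitude * (t/t_peak)^shape * exp(shape * (1 - t/t_peak))
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    if t_peak <= 0 or shape <= 0:
        raise InvalidInputError("t_peak and shape must be > 0")
    x = t / t_peak
    return amplitude * x**shape * np.exp(shape * (1.0 - x))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    The default truth theta is a healthy-subject parameter set
    (kp2 = 0.0025 1/min, kp3 = 0.0109 mg/kg/min per pmol/l,
    kp4 = 0.045 mg/kg/min per pmol/kg, A = 0.90); basal EGP declines mildly
    over the day.  Curve-shape values are generator plumbing, not
    physiological claims.
    """

    theta: Tuple[float, float, float, float] = (0.0025, 0.0109, 0.045, 0.90)
    egp_basal: Tuple[float, float, float] = (2.0, 1.9, 1.8)
    subject_class: str = "healthy"
    glucose_basal: Optional[float] = None   # mg/dl; resolved from subject_class
    insulin_basal: float = 40.0             # pmol/l
    isr_basal: float = 1.5                  # pmol/kg/min
    glucose_amplitude: float = 50.0
    glucose_peak: float = 45.0
    insulin_amplitude: float = 250.0
    insulin_peak: float = 60.0
    isr_amplitude: float = 6.0
    isr_peak: float = 30.0
    shape: float = 2.0
    drift: Tuple[float, float, float] = (1.0, 1.10, 1.05)
    noise_scale: float = 0.0
    seed: int = 0
    consistency_mode: bool = False
    times: Tuple[float, ...] = SAMPLING_GRID

    def __post_init__(self):
        if self.subject_class not in _CLASS_GLUCOSE_BASAL:
            raise InvalidInputError(f"unknown subject class {self.subject_class!r}")
        if self.drift[0] != 1.0:
            raise InvalidInputError("breakfast drift must be 1.0")
        if any(b <= 0 for b in self.egp_basal):
            raise InvalidInputError("egp_basal must be > 0")
        if self.noise_scale < 0:
            raise InvalidInputError("noise_scale must be >= 0")
        LiverParams.from_array(self.theta)  # validates positivity

    @property
    def resolved_glucose_basal(self) -> float:
        if self.glucose_basal is not None:
            return self.glucose_basal
        return _CLASS_GLUCOSE_BASAL[self.subject_class]


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus its generating truth.

    ``dataset`` carries the (possibly noisy) observed curves; ``signals``,
    ``anchors`` and ``clean_egp`` are the noise-free ground truth; ``truth``
    records the generating parameters.
    """

    dataset: DiurnalDataset
    signals: object
    anchors: BasalAnchors
    clean_egp: Dict[str, np.ndarray]
    truth: dict


def make_consistent_anchors(theta, breakfast: SegmentAnchors,
                            glucose_drifts: Tuple[float, float]):
    """Lunch/dinner basal anchors making the C coefficients meal-invariant.

    Given the breakfast anchors and glucose-mass drift factors for lunch and
    dinner, the implied basal delayed-insulin and portal-insulin levels are

        Gp_b^i  = drift_i * Gp_b^b
        Id_b^i  = Id_b^b + (kp2/kp3) * (Gp_b^i - Gp_b^b)
        Ipo_b^i = (kp2/kp4) * (Gp_b^i - Gp_b^b) + A * Ipo_b^b

    so that C23, C24 and C34 agree across the three meals at ``theta``.
    """
    p = theta if isinstance(theta, LiverParams) else LiverParams.from_array(theta)
    dl, dd = glucose_drifts
    if dl <= 0 or dd <= 0:
        raise InvalidInputError("glucose drifts must be positive")
    out = {}
    for lab, drift in (("lunch", dl), ("dinner", dd)):
        gp = drift * breakfast.gp_b
        dgp = gp - breakfast.gp_b
        idb = breakfast.id_b + (p.kp2 / p.kp3) * dgp
        ipo = (p.kp2 / p.kp4) * dgp + p.A * breakfast.ipo_b
        if idb < 0 or ipo < 0:
            raise InfeasibleConfigError(
                f"consistency construction implies negative basal level for {lab}")
        out[lab] = (gp, idb, ipo)
    return out["lunch"], out["dinner"]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a three-meal dataset at the configured study conditions.

    Per segment the observed curves are basal level (drifted for lunch and
    dinner) plus a gamma bump; the liver inputs are derived exactly as the
    estimators derive them, and the EGP curve follows the liver equation at
    the true theta with per-segment basal anchoring.  Optional additive
    Gaussian noise uses sigma = noise_scale * (0.10*y + 0.05*max(y)) per
    curve; glucose/insulin/ISR are clipped to stay physical, EGP is not.
    """
    p = LiverParams.from_array(config.theta)
    t = np.asarray(config.times, dtype=float)
    g0 = config.resolved_glucose_basal
    constants = select_constants(g0)

    # per-segment basal levels
    basals = {}
    if config.consistency_mode:
        bfast = SegmentAnchors(gp_b=g0 * constants.vg, id_b=config.insulin_basal,
                               ipo_b=config.isr_basal / constants.gamma,
                               egp_b=config.egp_basal[0])
        lunch, dinner = make_consistent_anchors(p, bfast,
                                                (config.drift[1], config.drift[2]))
        basals["breakfast"] = (g0, config.insulin_basal, config.isr_basal)
        for lab, (gp, idb, ipo) in (("lunch", lunch), ("dinner", dinner)):
            basals[lab] = (gp / constants.vg, idb, ipo * constants.gamma)
    else:
        for lab, drift in zip(MEAL_LABELS, config.drift):
            basals[lab] = (g0 * drift, config.insulin_basal * drift,
                           config.isr_basal * drift)

    # noise-free observed curves
    clean = {}
    for lab in MEAL_LABELS:
        gb, ib, sb = basals[lab]
        clean[lab] = {
            "glucose": gb + meal_bump(t, config.glucose_amplitude, config.glucose_peak,
                                      config.shape),
            "insulin": ib + meal_bump(t, config.insulin_amplitude, config.insulin_peak,
                                      config.shape),
            "isr": sb + meal_bump(t, config.isr_amplitude, config.isr_peak, config.shape),
        }

    egp_basal = dict(zip(MEAL_LABELS, config.egp_basal))
    clean_segments = [
        MealSegment(label=lab, times=t, glucose=clean[lab]["glucose"],
                    insulin=clean[lab]["insulin"], isr=clean[lab]["isr"])
        for lab in MEAL_LABELS
    ]
    clean_ds = DiurnalDataset(segments=tuple(clean_segments), egp_basal=egp_basal)
    signals = derive_signals(clean_ds, constants)
    anchors = basal_anchors(signals, clean_ds)

    if not config.consistency_mode and anchors_are_degenerate(anchors):
        raise DegenerateDesignError(
            "drift factors produce near-identical basal anchors across meals")

    clean_egp = {
        lab: egp_timecourse(p, signals[lab], anchors[lab], lab) for lab in MEAL_LABELS
    }
    _realism_check(clean_egp["breakfast"], t, egp_basal["breakfast"], config)

    # observed (possibly noisy) dataset
    rng = np.random.default_rng(config.seed)
    segments = []
    for lab in MEAL_LABELS:
        g, ins, isr = (clean[lab][k] for k in ("glucose", "insulin", "isr"))
        egp = clean_egp[lab].copy()
        if config.noise_scale > 0:
            g = np.maximum(_add_noise(g, config.noise_scale, rng), 1.0)
            ins = np.maximum(_add_noise(ins, config.noise_scale, rng), 0.0)
            isr = np.maximum(_add_noise(isr, config.noise_scale, rng), 0.0)
            egp = _add_noise(egp, config.noise_scale, rng)
        segments.append(MealSegment(label=lab, times=t, glucose=g, insulin=ins,
                                    isr=isr, egp=egp))
    observed_basal = {lab: float(seg.egp[0]) for lab, seg in zip(MEAL_LABELS, segments)}
    dataset = DiurnalDataset(segments=tuple(segments), egp_basal=observed_basal)

    kp1 = {
        lab: anchors[lab].egp_b + p.kp2 * anchors[lab].gp_b + p.kp3 * anchors[lab].id_b
        + (p.A * p.kp4 if lab == "breakfast" else p.kp4) * anchors[lab].ipo_b
        for lab in MEAL_LABELS
    }
    truth = {
        "theta": p,
        "kp1": kp1,
        "egp_basal": egp_basal,
        "constants": constants,
        "fasting_glucose": g0,
        "config": config,
    }
    return SyntheticDataset(dataset=dataset, signals=signals, anchors=anchors,
                            clean_egp=clean_egp, truth=truth)


def _add_noise(y: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    sigma = scale * (0.10 * y + 0.05 * np.max(y))
    return y + rng.normal(0.0, np.abs(sigma))


def _realism_check(egp_breakfast, times, egp_b, config: GeneratorConfig) -> None:
    """Soft physiological check: post-breakfast EGP should reach a nadir of
    30-70% of basal within 60-120 min; warn (never fail) otherwise."""
    i = int(np.argmin(egp_breakfast))
    frac = egp_breakfast[i] / egp_b
    t_nadir = times[i]
    if not (0.30 <= frac <= 0.70) or not (60.0 <= t_nadir <= 120.0):
        warnings.warn(
            f"EGP suppression outside the physiological envelope: nadir "
            f"{frac:.0%} of basal at {t_nadir:.0f} min", stacklevel=3)
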