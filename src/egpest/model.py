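"""Liver EGP model: prediction, the tracer-free objective, and fitting.

The model describes endogenous glucose production as an affine function of
the liver inputs,

    EGP(t) = kp1 - kp2 * Gp(t) - kp3 * Id(t) - kp4* * Ipo(t),

with kp4* = A * kp4 during breakfast and kp4 otherwise.  kp1 is not a free
parameter: per segment it is anchored so that EGP(0) equals the measured
basal EGP,

    kp1 = EGP_b + kp2 * Gp_b + kp3 * Id_b + kp4* * Ipo_b.

Two estimation routes are provided.  The *direct fit* minimises the root
total squared misfit between predicted and measured EGP over all meals and
time points — it requires tracer-derived EGP curves and serves as the
reference.  The *tracer-free* route needs no EGP curve beyond the basal
values: it exploits the assumption that the meal-specific coefficients

    C23 = kp2*Gp_b - kp3*Id_b
    C24 = kp2*Gp_b - kp4* * Ipo_b
    C34 = C24 - C23

(weighted differences of kp1-sensitivities to parameter pairs) are invariant
across the three meals of a day, and minimises

    obj(theta) = sqrt( sum over meal pairs (dC23 + dC24 + dC34)^2 ).

Because C34 = C24 - C23 identically, the objective reduces to
2*sqrt(sum dC24^2): it constrains only kp2/kp4 and A.  kp3 and the common
scale of (kp2, kp3, kp4) are structurally unidentified by this objective —
reported as-found, and quantifiable through the profile-likelihood module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .data import MEAL_LABELS, DiurnalDataset, FixedConstants, select_constants
from .errors import DegenerateDesignError, EstimationFailedError, InvalidInputError
from .signals import (
    BasalAnchors,
    DerivedSignals,
    SegmentAnchors,
    basal_anchors,
    derive_signals,
)

PARAM_NAMES = ("kp2", "kp3", "kp4", "A")

#: estimation box for (kp2, kp3, kp4, A)
DEFAULT_LOWER = np.array([0.0009, 0.001, 0.01, 0.8])
DEFAULT_UPPER = np.array([0.02, 0.05, 0.09, 1.4])

_MEAL_PAIRS = tuple(itertools.combinations(MEAL_LABELS, 2))


@dataclass(frozen=True)
class LiverParams:
    """Estimated liver parameters.

    kp2 (1/min): liver glucose effectiveness; kp3 (mg/kg/min per pmol/l):
    amplitude of delayed insulin action; kp4 (mg/kg/min per pmol/kg):
    amplitude of portal insulin action; A (dimensionless): breakfast
    multiplier on kp4.
    """

    kp2: float
    kp3: float
    kp4: float
    A: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_array(cls, theta) -> "LiverParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (4,):
            raise InvalidInputError(f"theta must have shape (4,), got {theta.shape}")
        return cls(*theta)

    def to_array(self) -> np.ndarray:
        return np.array([self.kp2, self.kp3, self.kp4, self.A])


@dataclass(frozen=True)
class ParameterBounds:
    lower: np.ndarray = field(default_factory=lambda: DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: DEFAULT_UPPER.copy())

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (4,) or hi.shape != (4,):
            raise InvalidInputError("bounds must be 4-vectors (kp2, kp3, kp4, A)")
        if np.any(lo >= hi):
            raise InvalidInputError("lower bounds must be < upper bounds elementwise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def contains(self, theta, atol: float = 1e-12) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower - atol) and np.all(theta <= self.upper + atol))


@dataclass(frozen=True)
class MultistartConfig:
    """Multistart settings: 150 Latin-hypercube start points by default."""

    n_starts: int = 150
    seed: int = 0
    scheme: str = "latin_hypercube"  # or "uniform"
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self):
        if self.n_starts < 1:
            raise InvalidInputError("n_starts must be >= 1")
        if self.scheme not in ("latin_hypercube", "uniform"):
            raise InvalidInputError(f"unknown start-point scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# model algebra


def _kp4_star(kp4: float, A: float, label: str) -> float:
    return A * kp4 if label == "breakfast" else kp4


def kp1_from_basal(kp2: float, kp3: float, kp4: float, A: float,
                   is_breakfast: bool, anchors: SegmentAnchors) -> float:
    """Anchor kp1 so predicted EGP(0) equals the basal EGP of the segment.

    During breakfast the portal term uses A*kp4, consistently with the EGP
    equation itself, so the anchoring identity holds for every segment.
    """
    for v in (anchors.gp_b, anchors.id_b, anchors.ipo_b, anchors.egp_b):
        if not np.isfinite(v):
            raise InvalidInputError("anchors must be finite")
    kp4s = A * kp4 if is_breakfast else kp4
    return anchors.egp_b + kp2 * anchors.gp_b + kp3 * anchors.id_b + kp4s * anchors.ipo_b


def egp_timecourse(params: LiverParams, signals, anchors: SegmentAnchors,
                   label: str) -> np.ndarray:
    """Predicted EGP series for one segment (mg/kg/min), unclamped.

    EGP(0) equals the segment's basal EGP exactly, by the kp1 anchoring.
    Negative values are physiologically suspect but returned as-is with a
    warning: the model is affine and clamping would bias the fits.
    """
    gp, idl, ipo = np.asarray(signals.gp), np.asarray(signals.idl), np.asarray(signals.ipo)
    if not (gp.shape == idl.shape == ipo.shape):
        raise InvalidInputError("signal series must share one grid")
    for v in (anchors.gp_b, anchors.id_b, anchors.ipo_b, anchors.egp_b):
        if not np.isfinite(v):
            raise InvalidInputError("anchors must be finite")
    kp4s = _kp4_star(params.kp4, params.A, label)
    # deviation form of (kp1 - kp2 Gp - kp3 Id - kp4* Ipo) with kp1 anchored:
    # all deviations vanish at t = 0, so EGP(0) = EGP_b bitwise
    egp = (anchors.egp_b + params.kp2 * (anchors.gp_b - gp)
           + params.kp3 * (anchors.id_b - idl) + kp4s * (anchors.ipo_b - ipo))
    if np.any(egp < 0):
        warnings.warn(f"segment {label}: predicted EGP goes negative", stacklevel=2)
    return egp


def c_coefficients(theta, anchors: SegmentAnchors, label: str):
    """Meal-specific coefficients (C23, C24, C34), mg/kg/min each.

    C34 is computed as C24 - C23, which is algebraically identical to
    kp3*Id_b - kp4* * Ipo_b and makes the identity exact in floating point.
    """
    kp2, kp3, kp4, A = np.asarray(theta, dtype=float)
    kp4s = _kp4_star(kp4, A, label)
    c23 = kp2 * anchors.gp_b - kp3 * anchors.id_b
    c24 = kp2 * anchors.gp_b - kp4s * anchors.ipo_b
    c34 = c24 - c23
    return c23, c24, c34


def tracerfree_residuals(theta, anchors: BasalAnchors) -> np.ndarray:
    """Residual vector over unordered meal pairs; its 2-norm is the
    tracer-free objective."""
    cs = {lab: c_coefficients(theta, anchors[lab], lab) for lab in MEAL_LABELS}
    res = []
    for i, j in _MEAL_PAIRS:
        d = [cs[i][k] - cs[j][k] for k in range(3)]
        res.append(d[0] + d[1] + d[2])
    return np.array(res)


def tracerfree_objective(theta, anchors: BasalAnchors) -> float:
    """Meal-invariance objective: root sum over meal pairs of the squared
    summed C-coefficient differences.  Zero iff C24 is equal across meals."""
    return float(np.linalg.norm(tracerfree_residuals(theta, anchors)))


def _tracerfree_objective_reduced(theta, anchors: BasalAnchors) -> float:
    """Equivalent reduced form 2*sqrt(sum dC24^2); cross-check only."""
    c24 = {lab: c_coefficients(theta, anchors[lab], lab)[1] for lab in MEAL_LABELS}
    s = sum((c24[i] - c24[j]) ** 2 for i, j in _MEAL_PAIRS)
    return 2.0 * float(np.sqrt(s))


def closed_form_ratio_and_A(anchors: BasalAnchors):
    """Closed-form solution (r = kp2/kp4, A) of the meal-invariance system.

    Setting C24 equal across meals gives two equations in (kp2/kp4, A); any
    theta with that ratio and A (any kp3, any common scale) has objective 0.
    Requires lunch/dinner basal glucose masses to differ and breakfast basal
    portal insulin to be positive.
    """
    b, l, d = (anchors[lab] for lab in MEAL_LABELS)
    dgp = l.gp_b - d.gp_b
    if dgp == 0:
        raise DegenerateDesignError("equal lunch/dinner basal glucose mass: ratio undefined")
    if b.ipo_b <= 0:
        raise DegenerateDesignError("zero breakfast basal portal insulin: A undefined")
    r = (l.ipo_b - d.ipo_b) / dgp
    A = (r * (b.gp_b - l.gp_b) + l.ipo_b) / b.ipo_b
    return r, A


def anchors_are_degenerate(anchors: BasalAnchors, rtol: float = 1e-2) -> bool:
    """True when some pair of segments has basal (Gp, Id, Ipo) all within
    ``rtol`` relative difference — the tracer-free design is then singular."""
    triples = {lab: np.array([anchors[lab].gp_b, anchors[lab].id_b, anchors[lab].ipo_b])
               for lab in MEAL_LABELS}
    for i, j in _MEAL_PAIRS:
        a, b = triples[i], triples[j]
        scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-12)
        if np.all(np.abs(a - b) / scale < rtol):
            return True
    return False


# ---------------------------------------------------------------------------
# multistart machinery


@dataclass(frozen=True)
class StartRecord:
    index: int
    x0: np.ndarray
    x: np.ndarray
    objective: float
    converged: bool
    message: str = ""


def start_points(bounds: ParameterBounds, config: MultistartConfig) -> np.ndarray:
    """Seeded start points in the box: Latin hypercube (default) or uniform."""
    rng = np.random.default_rng(config.seed)
    if config.scheme == "latin_hypercube":
        sampler = qmc.LatinHypercube(d=4, seed=rng)
        unit = sampler.random(config.n_starts)
    else:
        unit = rng.random((config.n_starts, 4))
    return qmc.scale(unit, bounds.lower, bounds.upper)


def multistart_least_squares(residual_fn: Callable[[np.ndarray], np.ndarray],
                             bounds: ParameterBounds,
                             config: MultistartConfig):
    """Bounded least squares from each start point; returns (records, best).

    The reported solution minimises the objective (2-norm of residuals) over
    converged starts; ties within 1e-10 absolute break deterministically by
    start index.  Raises EstimationFailedError when no start converges.
    """
    records = []
    for idx, x0 in enumerate(start_points(bounds, config)):
        try:
            sol = least_squares(
                residual_fn, x0, bounds=(bounds.lower, bounds.upper), method="trf",
                ftol=config.ftol, xtol=config.xtol, gtol=config.gtol,
            )
            obj = float(np.linalg.norm(sol.fun))
            records.append(StartRecord(idx, x0, sol.x, obj, bool(sol.success), sol.message))
        except Exception as exc:  # optimizer blow-up on one start is survivable
            records.append(StartRecord(idx, x0, np.full(4, np.nan), np.inf, False, str(exc)))
    converged = [r for r in records if r.converged]
    pool = converged
    if not pool:
        # on structurally flat directions trf exhausts its evaluation budget
        # without tripping ftol/xtol/gtol even though the informative
        # directions are converged; fall back to the best terminated solution
        pool = [r for r in records if np.isfinite(r.objective) and np.all(np.isfinite(r.x))]
        if pool:
            warnings.warn(
                "no start met the convergence tolerances (flat objective "
                "direction?); reporting the best terminated solution",
                stacklevel=2,
            )
    if not pool:
        raise EstimationFailedError("no multistart run converged", starts=records)
    best_obj = min(r.objective for r in pool)
    best = next(r for r in pool if r.objective <= best_obj + 1e-10)
    return records, best


# ---------------------------------------------------------------------------
# the model façade


class LiverEGPModel:
    """Liver EGP model bound to one subject's diurnal dataset.

    Parameters
    ----------
    dataset : DiurnalDataset
        Three-meal curves plus per-segment basal EGP.
    constants : FixedConstants, optional
        Vg/ki/gamma; selected from the fasting glucose when omitted.
    bounds : ParameterBounds, optional
        Estimation box for (kp2, kp3, kp4, A).

    Examples
    --------
    >>> from egpest.simulate import GeneratorConfig, generate_dataset
    >>> synth = generate_dataset(GeneratorConfig(consistency_mode=True))
    >>> model = LiverEGPModel(synth.dataset)
    >>> res = model.fit(seed=1)
    >>> round(res.ratio_kp2_kp4 / synth.truth["theta"].kp2 * synth.truth["theta"].kp4, 3)
    1.0
    """

    def __init__(self, dataset: DiurnalDataset,
                 constants: Optional[FixedConstants] = None,
                 bounds: Optional[ParameterBounds] = None):
        self.dataset = dataset
        self.constants = constants if constants is not None else select_constants(
            dataset.fasting_glucose)
        self.bounds = bounds if bounds is not None else ParameterBounds()
        self.signals: DerivedSignals = derive_signals(dataset, self.constants)
        self.anchors: BasalAnchors = basal_anchors(self.signals, dataset)

    @classmethod
    def from_csv(cls, path, egp_basal=None, constants=None, bounds=None) -> "LiverEGPModel":
        from .data import read_dataset

        return cls(read_dataset(path, egp_basal=egp_basal), constants=constants, bounds=bounds)

    # -- prediction ---------------------------------------------------------

    def predict_egp(self, params) -> dict:
        """Predicted EGP per segment (dict label -> array, mg/kg/min)."""
        if not isinstance(params, LiverParams):
            params = LiverParams.from_array(params)
        return {
            lab: egp_timecourse(params, self.signals[lab], self.anchors[lab], lab)
            for lab in MEAL_LABELS
        }

    def objective(self, theta) -> float:
        """Tracer-free meal-invariance objective at theta."""
        return tracerfree_objective(np.asarray(theta, dtype=float), self.anchors)

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 150, seed: int = 0,
            config: Optional[MultistartConfig] = None):
        """Tracer-free estimation of (kp2, kp3, kp4, A) by bounded multistart
        least squares on the meal-invariance residuals.

        Returns a :class:`~egpest.results.TracerFreeResults`.
        """
        from .results import TracerFreeResults

        cfg = config if config is not None else MultistartConfig(n_starts=n_starts, seed=seed)
        if anchors_are_degenerate(self.anchors):
            warnings.warn(
                "basal anchors are near-identical across meals: the tracer-free "
                "design is degenerate and only A is constrained (towards 1)",
                stacklevel=2,
            )
        records, best = multistart_least_squares(
            lambda th: tracerfree_residuals(th, self.anchors), self.bounds, cfg)
        return TracerFreeResults(model=self, params=LiverParams.from_array(best.x),
                                 objective_value=best.objective, starts=records,
                                 config=cfg, bounds=self.bounds)

    def fit_direct(self, n_starts: int = 150, seed: int = 0,
                   config: Optional[MultistartConfig] = None):
        """Direct fit of measured EGP curves (the tracer-based reference).

        Minimises V = sqrt(sum over segments and time points of
        (EGP_calc - EGP_exp)^2) over the same box with the same multistart
        machinery.  Returns a :class:`~egpest.results.DirectFitResults`.
        """
        from .results import DirectFitResults

        if not self.dataset.has_egp:
            raise InvalidInputError("direct fit requires an EGP curve in every segment")
        cfg = config if config is not None else MultistartConfig(n_starts=n_starts, seed=seed)
        records, best = multistart_least_squares(self._direct_residuals, self.bounds, cfg)
        params = LiverParams.from_array(best.x)
        kp1 = {
            lab: kp1_from_basal(params.kp2, params.kp3, params.kp4, params.A,
                                lab == "breakfast", self.anchors[lab])
            for lab in MEAL_LABELS
        }
        return DirectFitResults(model=self, params=params, cost=best.objective,
                                starts=records, config=cfg, bounds=self.bounds, kp1=kp1)

    def _direct_residuals(self, theta) -> np.ndarray:
        params = LiverParams.from_array(np.asarray(theta, dtype=float))
        res = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative-EGP warnings during search
            for lab in MEAL_LABELS:
                pred = egp_timecourse(params, self.signals[lab], self.anchors[lab], lab)
                res.append(pred - self.dataset[lab].egp)
        return np.concatenate(res)

    def direct_cost(self, theta) -> float:
        """Root total squared EGP misfit V at theta."""
        return float(np.linalg.norm(self._direct_residuals(theta)))

    # -- identifiability ----------------------------------------------------

    def chi2(self, theta, noise_model=None) -> float:
        """Weighted chi-square misfit of measured EGP (profile-likelihood
        objective); see :mod:`egpest.identifiability`."""
        from .identifiability import NoiseModel, chi2_objective

        nm = noise_model if noise_model is not None else NoiseModel()
        return chi2_objective(np.asarray(theta, dtype=float), self, nm)

    def profile(self, parameter=None, profile_config=None, noise_model=None,
                n_starts: int = 150, seed: int = 0):
        """Profile-likelihood analysis of one parameter (by name or index) or,
        when ``parameter`` is None, of all four; see
        :func:`egpest.identifiability.profile_parameter`."""
        from .identifiability import profile_all, profile_parameter

        if parameter is None:
            return profile_all(self, config=profile_config, noise_model=noise_model,
                               n_starts=n_starts, seed=seed)
        if isinstance(parameter, str):
            parameter = PARAM_NAMES.index(parameter)
        return profile_parameter(self, parameter, config=profile_config,
                                 noise_model=noise_model, n_starts=n_starts, seed=seed)
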