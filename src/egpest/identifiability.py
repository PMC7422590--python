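"""Profile-likelihood identifiability analysis against measured EGP.

The agreement objective is the weighted sum of squared residuals

    chi2(theta) = sum_kl ((y_exp_kl - y_calc_kl(theta)) / sigma_kl)^2

over time points k and meal segments l, with the measurement error modelled
as sigma_kl = 0.10 * y_kl + 0.05 * max_l(y_kl) (the max taken within each
segment's own EGP curve).  One parameter at a time is stepped away from the
chi-square optimum in multiplicative 2% steps while the others are
re-optimised; the likelihood-based confidence interval at level alpha is
the region where the chi-square increase stays below the chi-square
quantile Delta_alpha = Q_chi2(alpha, df), df = 1 for point-wise and df = 4
for simultaneous intervals.  A parameter whose interval is finite on both
sides is identifiable; infinite on at least one side with a curved profile,
practically non-identifiable; flat over the whole explored range,
structurally non-identifiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist

from .data import MEAL_LABELS
from .errors import InvalidInputError, InvalidNoiseError
from .model import PARAM_NAMES, LiverParams, MultistartConfig, egp_timecourse, multistart_least_squares

IDENTIFIABLE = "identifiable"
PRACTICALLY_NON_IDENTIFIABLE = "practically_non_identifiable"
STRUCTURALLY_NON_IDENTIFIABLE = "structurally_non_identifiable"

_FLATNESS_TOL = 1e-6


@dataclass(frozen=True)
class NoiseModel:
    """sigma = relative * y + max_fraction * max(y), per segment curve."""

    relative: float = 0.10
    max_fraction: float = 0.05

    def __post_init__(self):
        if self.relative < 0 or self.max_fraction < 0:
            raise InvalidNoiseError("noise coefficients must be >= 0")
        if self.relative == 0 and self.max_fraction == 0:
            raise InvalidNoiseError("noise model cannot be identically zero")

    def sigma(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        s = self.relative * y + self.max_fraction * np.max(y)
        if np.any(s <= 0):
            raise InvalidNoiseError("noise model produced non-positive sigma")
        return s


@dataclass(frozen=True)
class ProfileConfig:
    """Profiling controls: confidence level, threshold df, step geometry."""

    alpha: float = 0.68
    df: int = 1
    rel_step: float = 0.02
    max_steps: int = 200
    range_extension: float = 10.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.df not in (1, 4):
            raise InvalidInputError("df must be 1 (point-wise) or 4 (simultaneous)")
        if self.rel_step <= 0:
            raise InvalidInputError("rel_step must be > 0")


def delta_alpha(alpha: float = 0.68, df: int = 1) -> float:
    """Chi-square threshold Delta_alpha = Q_chi2(alpha, df)."""
    return float(chi2_dist.ppf(alpha, df))


def chi2_objective(theta, model, noise_model: Optional[NoiseModel] = None) -> float:
    """Weighted sum of squared EGP residuals at theta."""
    nm = noise_model if noise_model is not None else NoiseModel()
    return float(np.sum(_chi_residuals(theta, model, nm) ** 2))


def _chi_residuals(theta, model, nm: NoiseModel) -> np.ndarray:
    if not model.dataset.has_egp:
        raise InvalidInputError("chi-square objective requires measured EGP curves")
    params = LiverParams.from_array(np.asarray(theta, dtype=float))
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lab in MEAL_LABELS:
            y = model.dataset[lab].egp
            pred = egp_timecourse(params, model.signals[lab], model.anchors[lab], lab)
            out.append((y - pred) / nm.sigma(y))
    return np.concatenate(out)


@dataclass
class ProfileResult:
    """Profile-likelihood trace for one parameter."""

    name: str
    values: np.ndarray          # profiled parameter values, ascending
    chi2: np.ndarray            # profiled chi-square at each value
    theta_hat: float            # optimum of the profiled parameter
    chi2_min: float             # global chi-square minimum
    delta: float                # threshold used for the stored CI
    alpha: float
    df: int
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    lower_open: bool
    upper_open: bool
    classification: str = ""
    failed_steps: int = 0

    def confidence_interval(self, df: Optional[int] = None):
        """(lower, upper, lower_open, upper_open) from the stored trace at a
        possibly different df; larger df thresholds widen the interval."""
        if df is None:
            return self.ci_lower, self.ci_upper, self.lower_open, self.upper_open
        thr = delta_alpha(self.alpha, df)
        return _ci_from_trace(self.values, self.chi2, self.chi2_min, self.theta_hat, thr)

    def contains(self, value: float, df: Optional[int] = None) -> bool:
        """Whether ``value`` lies inside the (possibly one-side-open) CI."""
        lo, hi, lo_open, hi_open = self.confidence_interval(df)
        ok_lo = lo_open or (lo is not None and value >= lo)
        ok_hi = hi_open or (hi is not None and value <= hi)
        return bool(ok_lo and ok_hi)

    def to_dict(self) -> dict:
        return {
            "parameter": self.name,
            "theta_hat": self.theta_hat,
            "chi2_min": self.chi2_min,
            "alpha": self.alpha,
            "df": self.df,
            "delta_alpha": self.delta,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "lower_open": self.lower_open,
            "upper_open": self.upper_open,
            "classification": self.classification,
            "values": self.values.tolist(),
            "chi2": self.chi2.tolist(),
        }

    def plot(self, ax=None):
        """Profile trace with the Delta_alpha threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.values, self.chi2, "k-")
        ax.axhline(self.chi2_min + self.delta, ls="--", color="gray")
        ax.axvline(self.theta_hat, ls=":", color="gray")
        ax.set_xlabel(self.name)
        ax.set_ylabel(r"$\chi^2$")
        ax.set_title(f"{self.name}: {self.classification}")
        return ax


def _ci_from_trace(values, chi2_vals, chi2_min, theta_hat, thr):
    """Interpolated crossing points of chi2_min + thr on each side."""
    values = np.asarray(values)
    chi2_vals = np.asarray(chi2_vals)
    target = chi2_min + thr

    def crossing(idx_order):
        prev_v, prev_c = None, None
        for i in idx_order:
            v, c = values[i], chi2_vals[i]
            if c > target:
                if prev_v is None:
                    return v, False
                # linear interpolation in log(parameter)
                f = (target - prev_c) / (c - prev_c)
                return float(np.exp(np.log(prev_v) + f * (np.log(v) - np.log(prev_v)))), False
            prev_v, prev_c = v, c
        return None, True

    left = np.flatnonzero(values <= theta_hat)[::-1]
    right = np.flatnonzero(values >= theta_hat)
    lo, lo_open = crossing(left)
    hi, hi_open = crossing(right)
    return lo, hi, lo_open, hi_open


def classify(result: ProfileResult) -> str:
    """Identifiability class from a completed profile.

    Flat profile (variation below 1e-6 of the chi-square scale) ->
    structurally non-identifiable; both CI sides closed -> identifiable;
    otherwise practically non-identifiable (curved but open on >= 1 side).
    """
    scale = max(1.0, result.chi2_min)
    if result.chi2.size and (result.chi2.max() - result.chi2.min()) < _FLATNESS_TOL * scale:
        return STRUCTURALLY_NON_IDENTIFIABLE
    if not result.lower_open and not result.upper_open:
        return IDENTIFIABLE
    return PRACTICALLY_NON_IDENTIFIABLE


def profile_parameter(model, index: int, config: Optional[ProfileConfig] = None,
                      noise_model: Optional[NoiseModel] = None,
                      n_starts: int = 150, seed: int = 0,
                      fit_theta: Optional[np.ndarray] = None) -> ProfileResult:
    """Profile one parameter of the chi-square EGP fit.

    A global chi-square fit (same bounded multistart machinery as the direct
    fit) supplies the optimum unless ``fit_theta`` is given.  The parameter
    is then walked in multiplicative steps both ways, the other three
    re-optimised (warm-started from the neighbouring grid point) at each
    step, until the chi-square increase exceeds Delta_alpha or the range
    (bounds extended by ``range_extension``) is exhausted.
    """
    cfg = config if config is not None else ProfileConfig()
    nm = noise_model if noise_model is not None else NoiseModel()
    if not 0 <= index < 4:
        raise InvalidInputError("parameter index must be 0..3")
    name = PARAM_NAMES[index]

    if fit_theta is None:
        records, best = multistart_least_squares(
            lambda th: _chi_residuals(th, model, nm), model.bounds,
            MultistartConfig(n_starts=n_starts, seed=seed))
        theta_hat = best.x.copy()
    else:
        theta_hat = np.asarray(fit_theta, dtype=float).copy()
    chi2_min = chi2_objective(theta_hat, model, nm)

    thr = delta_alpha(cfg.alpha, cfg.df)
    lo_lim = model.bounds.lower[index] / cfg.range_extension
    hi_lim = model.bounds.upper[index] * cfg.range_extension
    factor = 1.0 + cfg.rel_step

    other = [i for i in range(4) if i != index]
    lb, ub = model.bounds.lower[other], model.bounds.upper[other]

    def inner(value, warm):
        """Re-optimise the other three at fixed profiled value."""
        def res(x):
            th = np.empty(4)
            th[other] = x
            th[index] = value
            return _chi_residuals(th, model, nm)

        x0 = np.clip(warm, lb, ub)
        try:
            sol = least_squares(res, x0, bounds=(lb, ub), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12)
            return float(np.sum(sol.fun ** 2)), sol.x, True
        except Exception:
            return math.inf, warm, False

    grid = [(float(theta_hat[index]), chi2_min)]
    failed = 0
    for direction in (-1, +1):
        value = float(theta_hat[index])
        warm = theta_hat[other].copy()
        for _ in range(cfg.max_steps):
            value = value / factor if direction < 0 else value * factor
            if value < lo_lim or value > hi_lim:
                break
            c2, warm, ok = inner(value, warm)
            if not ok:
                failed += 1
                warnings.warn(f"profile {name}: inner fit failed at {value:.4g}",
                              stacklevel=2)
                continue
            grid.append((value, c2))
            if c2 - chi2_min > thr:
                break

    grid.sort(key=lambda p: p[0])
    values = np.array([p[0] for p in grid])
    chi2_vals = np.array([p[1] for p in grid])
    lo, hi, lo_open, hi_open = _ci_from_trace(values, chi2_vals, chi2_min,
                                              float(theta_hat[index]), thr)
    result = ProfileResult(
        name=name, values=values, chi2=chi2_vals,
        theta_hat=float(theta_hat[index]), chi2_min=chi2_min, delta=thr,
        alpha=cfg.alpha, df=cfg.df, ci_lower=lo, ci_upper=hi,
        lower_open=lo_open, upper_open=hi_open, failed_steps=failed,
    )
    result.classification = classify(result)
    return result


def profile_all(model, config: Optional[ProfileConfig] = None,
                noise_model: Optional[NoiseModel] = None,
                n_starts: int = 150, seed: int = 0) -> Dict[str, ProfileResult]:
    """Profile all four parameters, sharing one global chi-square fit."""
    nm = noise_model if noise_model is not None else NoiseModel()
    records, best = multistart_least_squares(
        lambda th: _chi_residuals(th, model, nm), model.bounds,
        MultistartConfig(n_starts=n_starts, seed=seed))
    return {
        PARAM_NAMES[i]: profile_parameter(model, i, config=config, noise_model=nm,
                                          fit_theta=best.x)
        for i in range(4)
    }


def tracerfree_within_ci(profiles: Dict[str, ProfileResult], params) -> Dict[str, bool]:
    """Per-parameter flag: does the tracer-free estimate lie inside the
    point-wise (df = 1) likelihood-based CI of the direct chi-square fit?"""
    if isinstance(params, LiverParams):
        values = {n: getattr(params, n) for n in PARAM_NAMES}
    else:
        values = dict(zip(PARAM_NAMES, np.asarray(params, dtype=float)))
    return {name: prof.contains(values[name], df=1) for name, prof in profiles.items()}


def summary_table(profiles: Dict[str, ProfileResult],
                  tracerfree_params=None) -> str:
    """Plain-text profile summary (parameter, optimum, CI, class)."""
    inside = (tracerfree_within_ci(profiles, tracerfree_params)
              if tracerfree_params is not None else None)
    lines = [f"{'parameter':<10}{'optimum':>12}{'ci_lower':>12}{'ci_upper':>12}"
             f"  {'class':<32}" + ("tracerfree_in_ci" if inside else "")]
    for name, p in profiles.items():
        lo = "open" if p.lower_open else f"{p.ci_lower:.4g}"
        hi = "open" if p.upper_open else f"{p.ci_upper:.4g}"
        tail = f"{str(inside[name]):<5}" if inside else ""
        lines.append(f"{name:<10}{p.theta_hat:>12.4g}{lo:>12}{hi:>12}"
                     f"  {p.classification:<32}{tail}")
    return "\n".join(lines)
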