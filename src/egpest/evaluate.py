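"""Goodness-of-fit reporting: per-meal R^2 and residual series."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .data import MEAL_LABELS, DiurnalDataset, FixedConstants, select_constants
from .errors import InvalidInputError, UndefinedRSquaredError
from .model import LiverParams, egp_timecourse
from .signals import basal_anchors, derive_signals


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the sampled grid.

    Can be negative for fits worse than the observed mean; reported as-is.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 3:
        raise InvalidInputError("observed/predicted must share a length >= 3")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedRSquaredError("observed series is constant; R^2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def residuals(observed, predicted) -> np.ndarray:
    """Residual series observed - predicted (overprediction -> negative)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise InvalidInputError("observed/predicted length mismatch")
    return o - p


@dataclass(frozen=True)
class EvaluationReport:
    r2: Dict[str, float]
    mean_r2: float
    residuals: Dict[str, np.ndarray]
    max_abs_residual: float

    def to_dict(self) -> dict:
        return {
            "r2": dict(self.r2),
            "mean_r2": self.mean_r2,
            "max_abs_residual": self.max_abs_residual,
            "residuals": {k: v.tolist() for k, v in self.residuals.items()},
        }


def evaluate(dataset: DiurnalDataset, params,
             constants: Optional[FixedConstants] = None) -> EvaluationReport:
    """Predict EGP at ``params`` and report per-meal R^2 and residuals."""
    if not dataset.has_egp:
        raise InvalidInputError("evaluation requires measured EGP curves")
    if not isinstance(params, LiverParams):
        params = LiverParams.from_array(params)
    consts = constants if constants is not None else select_constants(dataset.fasting_glucose)
    signals = derive_signals(dataset, consts)
    anchors = basal_anchors(signals, dataset)
    r2, res = {}, {}
    for lab in MEAL_LABELS:
        pred = egp_timecourse(params, signals[lab], anchors[lab], lab)
        obs = dataset[lab].egp
        r2[lab] = r_squared(obs, pred)
        res[lab] = residuals(obs, pred)
    return EvaluationReport(
        r2=r2,
        mean_r2=float(np.mean([r2[lab] for lab in MEAL_LABELS])),
        residuals=res,
        max_abs_residual=float(max(np.max(np.abs(res[lab])) for lab in MEAL_LABELS)),
    )
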