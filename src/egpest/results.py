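"""Results containers for the two estimation routes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .data import MEAL_LABELS
from .model import (
    PARAM_NAMES,
    LiverParams,
    MultistartConfig,
    ParameterBounds,
    StartRecord,
)


def _starts_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"start": r.index, "objective": r.objective, "converged": r.converged}
        for k, name in enumerate(PARAM_NAMES):
            row[f"x0_{name}"] = r.x0[k]
            row[name] = r.x[k]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class _BaseResults:
    model: object
    params: LiverParams
    starts: List[StartRecord]
    config: MultistartConfig
    bounds: ParameterBounds

    @property
    def theta(self) -> np.ndarray:
        return self.params.to_array()

    @property
    def starts_frame(self) -> pd.DataFrame:
        """Per-start trace: start point, solution, objective, convergence."""
        return _starts_frame(self.starts)

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.starts)

    def to_dict(self) -> dict:
        return {
            "params": {name: getattr(self.params, name) for name in PARAM_NAMES},
            "seed": self.config.seed,
            "n_starts": self.config.n_starts,
            "n_converged": self.n_converged,
            "bounds": {"lower": self.bounds.lower.tolist(),
                       "upper": self.bounds.upper.tolist()},
        }


@dataclass
class TracerFreeResults(_BaseResults):
    """Tracer-free estimate of (kp2, kp3, kp4, A).

    Only kp2/kp4 and A are identified by the meal-invariance objective; kp3
    and the common scale of (kp2, kp3, kp4) are reported as found by the
    optimiser and should be read together with a profile-likelihood
    analysis.
    """

    objective_value: float = np.nan

    @property
    def ratio_kp2_kp4(self) -> float:
        """kp2/kp4 — the quantity the objective actually pins down."""
        return self.params.kp2 / self.params.kp4

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(objective=self.objective_value, ratio_kp2_kp4=self.ratio_kp2_kp4,
                 method="tracerfree")
        return d

    def summary(self) -> str:
        lines = [
            "Tracer-free liver EGP parameter estimation",
            "=" * 58,
            f"{'n starts':<28}{self.config.n_starts:>10d}   converged {self.n_converged}",
            f"{'seed':<28}{self.config.seed:>10d}",
            f"{'objective (mg/kg/min)':<28}{self.objective_value:>14.3e}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>14}  {'identified?':<20}",
        ]
        ident = {"kp2": "ratio kp2/kp4 only", "kp3": "no (structural)",
                 "kp4": "ratio kp2/kp4 only", "A": "yes"}
        for name in PARAM_NAMES:
            lines.append(f"{name:<12}{getattr(self.params, name):>14.5g}  {ident[name]:<20}")
        lines.append(f"{'kp2/kp4':<12}{self.ratio_kp2_kp4:>14.5g}  {'yes':<20}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_objective_starts(self, ax=None):
        """Scatter of per-start final objectives (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.starts_frame
        ax.semilogy(df["start"], np.maximum(df["objective"], 1e-300), ".")
        ax.set_xlabel("start index")
        ax.set_ylabel("objective (mg/kg/min)")
        return ax


@dataclass
class DirectFitResults(_BaseResults):
    """Direct fit of the liver model against measured EGP curves."""

    cost: float = np.nan
    kp1: Dict[str, float] = field(default_factory=dict)

    @property
    def nonunique(self) -> bool:
        """True when >= 2 converged starts reach the minimal cost (within
        1e-10) with solutions differing by more than 1e-3 relative — the
        design does not pin down a unique parameter vector."""
        conv = [r for r in self.starts if r.converged]
        best = min(r.objective for r in conv)
        tied = [r.x for r in conv if r.objective <= best + 1e-10]
        for x in tied[1:]:
            scale = np.maximum(np.abs(tied[0]), 1e-12)
            if np.any(np.abs(x - tied[0]) / scale > 1e-3):
                return True
        return False

    def predicted_egp(self) -> dict:
        return self.model.predict_egp(self.params)

    def evaluate(self):
        """Goodness-of-fit report (per-meal R^2, residuals)."""
        from .evaluate import evaluate

        return evaluate(self.model.dataset, self.params, constants=self.model.constants)

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(cost=self.cost, kp1=dict(self.kp1), nonunique=self.nonunique,
                 method="direct")
        return d

    def summary(self) -> str:
        lines = [
            "Direct fit of measured EGP (reference)",
            "=" * 58,
            f"{'n starts':<28}{self.config.n_starts:>10d}   converged {self.n_converged}",
            f"{'seed':<28}{self.config.seed:>10d}",
            f"{'cost V (mg/kg/min)':<28}{self.cost:>14.3e}",
            f"{'unique solution':<28}{str(not self.nonunique):>14}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>14}",
        ]
        for name in PARAM_NAMES:
            lines.append(f"{name:<12}{getattr(self.params, name):>14.5g}")
        for lab in MEAL_LABELS:
            lines.append(f"{'kp1 ' + lab:<12}{self.kp1[lab]:>14.5g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_fit(self, axes=None):
        """Measured vs predicted EGP per meal segment."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
        pred = self.predicted_egp()
        for ax, lab in zip(axes, MEAL_LABELS):
            seg = self.model.dataset[lab]
            ax.plot(seg.times, seg.egp, "o", label="measured")
            ax.plot(seg.times, pred[lab], "-", label="model")
            ax.set_title(lab)
            ax.set_xlabel("min since meal")
        axes[0].set_ylabel("EGP (mg/kg/min)")
        axes[0].legend()
        return axes
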