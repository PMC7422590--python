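"""Derivation of the liver-model input signals from measured curves.

The liver sees three inputs: the plasma glucose mass G_p = G * V_g (mg/kg),
a delayed insulin signal I_d obtained by passing plasma insulin through a
chain of two first-order compartments with rate k_i, and the portal insulin
amount I_po = ISR / gamma (pmol/kg).  All three are evaluated on each meal
segment's own sample grid, re-initialised at that segment's t = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .data import MEAL_LABELS, DiurnalDataset, FixedConstants
from .errors import InvalidInputError


def glucose_mass(glucose, vg: float) -> np.ndarray:
    """Plasma glucose mass G_p = G * V_g (mg/kg)."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise InvalidInputError("empty glucose series")
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("non-finite glucose values")
    if vg <= 0:
        raise InvalidInputError(f"Vg must be > 0, got {vg!r}")
    return g * vg


def portal_insulin(isr, gamma: float) -> np.ndarray:
    """Portal insulin I_po = ISR / gamma (pmol/kg)."""
    s = np.asarray(isr, dtype=float)
    if s.size == 0:
        raise InvalidInputError("empty ISR series")
    if gamma <= 0:
        raise InvalidInputError(f"gamma must be > 0, got {gamma!r}")
    return s / gamma


def delayed_insulin(times, insulin, ki: float, insulin_basal: Optional[float] = None) -> np.ndarray:
    """Delayed insulin signal I_d via the two-compartment chain.

    dI1/dt = -ki (I1 - I(t)),  dId/dt = -ki (Id - I1),  I1(0) = Id(0) = Ib.

    I(t) between samples is piecewise-linear; the chain is integrated with a
    stiff-capable variable-step method (rtol 1e-8, atol 1e-10) and returned
    on the input grid.  ``insulin_basal`` defaults to I(0).
    """
    t = np.asarray(times, dtype=float)
    ins = np.asarray(insulin, dtype=float)
    if t.size != ins.size or t.size < 2:
        raise InvalidInputError("times and insulin must have equal length >= 2")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if ki < 0:
        raise InvalidInputError(f"ki must be >= 0, got {ki!r}")
    ib = float(ins[0]) if insulin_basal is None else float(insulin_basal)
    if ki == 0:
        return np.full_like(t, ib)
    # constant input at the steady state: skip the ODE solve entirely
    if np.allclose(ins, ib, rtol=0, atol=0):
        return np.full_like(t, ib)

    def rhs(tt, y):
        i_t = np.interp(tt, t, ins)
        return [-ki * (y[0] - i_t), -ki * (y[1] - y[0])]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [ib, ib],
        method="LSODA",
        t_eval=t,
        rtol=1e-8,
        atol=1e-10,
        max_step=float(np.min(np.diff(t))),
    )
    if not sol.success:  # pragma: no cover - LSODA failure on linear ODE is pathological
        raise RuntimeError(f"delayed-insulin integration failed: {sol.message}")
    return sol.y[1]


@dataclass(frozen=True)
class SegmentSignals:
    """Derived liver inputs for one segment on its sample grid."""

    gp: np.ndarray    # mg/kg
    idl: np.ndarray   # pmol/l, delayed insulin
    ipo: np.ndarray   # pmol/kg


@dataclass(frozen=True)
class DerivedSignals:
    breakfast: SegmentSignals
    lunch: SegmentSignals
    dinner: SegmentSignals

    def __getitem__(self, label: str) -> SegmentSignals:
        if label not in MEAL_LABELS:
            raise KeyError(label)
        return getattr(self, label)


@dataclass(frozen=True)
class SegmentAnchors:
    """Basal (t = 0) anchor values for one segment."""

    gp_b: float    # mg/kg
    id_b: float    # pmol/l
    ipo_b: float   # pmol/kg
    egp_b: float   # mg/kg/min


@dataclass(frozen=True)
class BasalAnchors:
    breakfast: SegmentAnchors
    lunch: SegmentAnchors
    dinner: SegmentAnchors

    def __getitem__(self, label: str) -> SegmentAnchors:
        if label not in MEAL_LABELS:
            raise KeyError(label)
        return getattr(self, label)


def derive_signals(dataset: DiurnalDataset, constants: FixedConstants) -> DerivedSignals:
    """Compute (G_p, I_d, I_po) per segment; the insulin chain restarts at
    each segment's own t = 0 with Ib = that segment's insulin at t = 0."""
    per = {}
    for seg in dataset.segments:
        per[seg.label] = SegmentSignals(
            gp=glucose_mass(seg.glucose, constants.vg),
            idl=delayed_insulin(seg.times, seg.insulin, constants.ki),
            ipo=portal_insulin(seg.isr, constants.gamma),
        )
    return DerivedSignals(**per)


def basal_anchors(signals: DerivedSignals, dataset: DiurnalDataset) -> BasalAnchors:
    """t = 0 values of the derived signals plus the supplied basal EGP."""
    per = {}
    for lab in MEAL_LABELS:
        sig = signals[lab]
        if sig.ipo[0] == 0:
            warnings.warn(
                f"segment {lab}: basal portal insulin is zero; "
                "the closed-form ratio/A oracle will be degenerate",
                stacklevel=2,
            )
        per[lab] = SegmentAnchors(
            gp_b=float(sig.gp[0]),
            id_b=float(sig.idl[0]),
            ipo_b=float(sig.ipo[0]),
            egp_b=float(dataset.egp_basal[lab]),
        )
    return BasalAnchors(**per)
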