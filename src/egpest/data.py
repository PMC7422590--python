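"""Containers and I/O for diurnal three-meal datasets.

A dataset is three meal segments (breakfast, lunch, dinner), each sampled on
minutes since that meal started, carrying plasma glucose (mg/dl), plasma
insulin (pmol/l), the insulin secretion rate ISR (pmol/kg/min) and optionally
a measured endogenous-glucose-production curve EGP (mg/kg/min).  Segments are
independent records: no absolute clock is kept, each segment restarts at
t = 0 when its meal is given.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

MEAL_LABELS = ("breakfast", "lunch", "dinner")

#: mmol/l -> mg/dl for glucose
GLUCOSE_MMOL_TO_MGDL = 18.02
#: umol/kg/min -> mg/kg/min for EGP
EGP_UMOL_TO_MG = 0.18

# (Vg dl/kg, ki 1/min) for the two reference subject classes; the cutoffs are
# the clinical fasting-glucose thresholds 99 and 126 mg/dl.
_NORMAL = (1.88, 0.0079)
_T2D = (1.49, 0.0066)
_FG_LO, _FG_HI = 99.0, 126.0

REQUIRED_COLUMNS = ("meal", "time_min", "glucose_mgdl", "insulin_pmoll", "isr_pmolkgmin")
EGP_COLUMN = "egp_mgkgmin"


def glucose_mmoll_to_mgdl(x):
    """Convert glucose from mmol/l to mg/dl (factor 18.02)."""
    return np.asarray(x, dtype=float) * GLUCOSE_MMOL_TO_MGDL


def egp_umolkgmin_to_mgkgmin(x):
    """Convert EGP from umol/kg/min to mg/kg/min (factor 0.18)."""
    return np.asarray(x, dtype=float) * EGP_UMOL_TO_MG


@dataclass(frozen=True)
class FixedConstants:
    """Kinetic constants not estimated from EGP dynamics.

    Parameters
    ----------
    vg : float
        Glucose distribution volume (dl/kg).
    ki : float
        Rate of the two-compartment delayed-insulin chain (1/min).
    gamma : float
        Portal-vein-to-liver transfer rate (1/min); fixed at 0.5.
    """

    vg: float
    ki: float
    gamma: float = 0.5

    def __post_init__(self):
        for name in ("vg", "ki", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be finite and > 0, got {v!r}")


def select_constants(fasting_glucose: float) -> FixedConstants:
    """Pick (Vg, ki, gamma) from the fasting plasma glucose (mg/dl).

    Below 99 mg/dl the healthy reference values apply (Vg = 1.88 dl/kg,
    ki = 0.0079 1/min); above 126 mg/dl the type-2-diabetic values
    (Vg = 1.49, ki = 0.0066); in between, linear interpolation of the two
    endpoint pairs.  gamma is always 0.5 1/min.
    """
    fg = float(fasting_glucose)
    if not np.isfinite(fg) or fg <= 0:
        raise InvalidInputError(f"fasting glucose must be finite and > 0, got {fasting_glucose!r}")
    if fg <= _FG_LO:
        vg, ki = _NORMAL
    elif fg >= _FG_HI:
        vg, ki = _T2D
    else:
        w = (fg - _FG_LO) / (_FG_HI - _FG_LO)
        vg = _NORMAL[0] + w * (_T2D[0] - _NORMAL[0])
        ki = _NORMAL[1] + w * (_T2D[1] - _NORMAL[1])
    return FixedConstants(vg=vg, ki=ki)


@dataclass(frozen=True)
class MealSegment:
    """One meal's sampled response curves on a minutes-since-meal grid."""

    label: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    isr: np.ndarray
    egp: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.label not in MEAL_LABELS:
            raise InvalidInputError(f"label must be one of {MEAL_LABELS}, got {self.label!r}")
        for name in ("times", "glucose", "insulin", "isr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.egp is not None:
            object.__setattr__(self, "egp", np.asarray(self.egp, dtype=float))
        n = self.times.size
        if n < 2:
            raise InvalidInputError(f"segment {self.label}: need at least 2 samples, got {n}")
        if self.times[0] != 0:
            raise InvalidInputError(f"segment {self.label}: times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError(f"segment {self.label}: times must be strictly increasing")
        for name in ("glucose", "insulin", "isr"):
            arr = getattr(self, name)
            if arr.size != n:
                raise InvalidInputError(
                    f"segment {self.label}: {name} length {arr.size} != times length {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"segment {self.label}: non-finite values in {name}")
        if self.egp is not None and self.egp.size != n:
            raise InvalidInputError(f"segment {self.label}: egp length mismatch")
        if np.any(self.glucose <= 0):
            raise InvalidInputError(f"segment {self.label}: glucose must be > 0")
        if np.any(self.insulin < 0) or np.any(self.isr < 0):
            raise InvalidInputError(f"segment {self.label}: insulin and ISR must be >= 0")
        if np.any(self.glucose < 30) or np.any(self.glucose > 600):
            warnings.warn(
                f"segment {self.label}: glucose outside the plausible 30-600 mg/dl range",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DiurnalDataset:
    """Breakfast/lunch/dinner segments plus per-segment basal EGP.

    ``egp_basal`` maps each meal label to its basal EGP (mg/kg/min), the
    t = 0 value of the (possibly unmeasured) EGP curve.  When a segment
    carries a measured EGP series, its basal value defaults to that series'
    first sample.
    """

    segments: tuple
    egp_basal: Mapping[str, float]

    def __post_init__(self):
        labels = tuple(s.label for s in self.segments)
        if labels != MEAL_LABELS:
            raise InvalidInputError(
                f"segments must be exactly (breakfast, lunch, dinner) in order, got {labels}"
            )
        basal = dict(self.egp_basal)
        for lab in MEAL_LABELS:
            if lab not in basal:
                raise InvalidInputError(f"egp_basal missing segment {lab!r}")
            if not np.isfinite(basal[lab]) or basal[lab] <= 0:
                raise InvalidInputError(f"egp_basal[{lab!r}] must be > 0, got {basal[lab]!r}")
        object.__setattr__(self, "egp_basal", basal)
        object.__setattr__(self, "segments", tuple(self.segments))

    @classmethod
    def from_segments(cls, segments: Sequence[MealSegment],
                      egp_basal: Optional[Mapping[str, float]] = None) -> "DiurnalDataset":
        """Build from segments in any order; infer basal EGP from EGP curves."""
        by_label = {s.label: s for s in segments}
        missing = [lab for lab in MEAL_LABELS if lab not in by_label]
        if missing:
            raise InvalidInputError(f"missing segment(s): {missing}")
        if len(segments) != 3:
            raise InvalidInputError("need exactly three segments")
        if egp_basal is None:
            egp_basal = {}
            for lab in MEAL_LABELS:
                seg = by_label[lab]
                if seg.egp is None:
                    raise InvalidInputError(
                        f"segment {lab!r} has no EGP curve; supply egp_basal explicitly"
                    )
                egp_basal[lab] = float(seg.egp[0])
        return cls(segments=tuple(by_label[lab] for lab in MEAL_LABELS), egp_basal=egp_basal)

    def __getitem__(self, label: str) -> MealSegment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def fasting_glucose(self) -> float:
        """Breakfast glucose at t = 0 (mg/dl)."""
        return float(self["breakfast"].glucose[0])

    @property
    def has_egp(self) -> bool:
        return all(s.egp is not None for s in self.segments)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            df = pd.DataFrame(
                {
                    "meal": seg.label,
                    "time_min": seg.times,
                    "glucose_mgdl": seg.glucose,
                    "insulin_pmoll": seg.insulin,
                    "isr_pmolkgmin": seg.isr,
                }
            )
            if seg.egp is not None:
                df[EGP_COLUMN] = seg.egp
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def read_dataset(path, egp_basal: Optional[Mapping[str, float]] = None) -> DiurnalDataset:
    """Read a diurnal dataset from CSV.

    Required columns: meal, time_min, glucose_mgdl, insulin_pmoll,
    isr_pmolkgmin; optional egp_mgkgmin.  Rows are sorted by segment then
    time.  When the EGP column is present, per-segment basal EGP defaults to
    the t = 0 value; otherwise ``egp_basal`` must be supplied.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}")
    numeric_cols = [c for c in df.columns if c != "meal"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value in column {col!r}, row {row}")
        df[col] = coerced
    segments = []
    for lab in MEAL_LABELS:
        sub = df[df["meal"] == lab].sort_values("time_min")
        if sub.empty:
            raise ParseError(f"missing segment {lab!r}")
        t = sub["time_min"].to_numpy(dtype=float)
        if np.unique(t).size != t.size:
            raise ParseError(f"duplicate time within segment {lab!r}")
        egp = sub[EGP_COLUMN].to_numpy(dtype=float) if EGP_COLUMN in sub.columns else None
        if egp is not None and np.any(np.isnan(egp)):
            egp = None
        segments.append(
            MealSegment(
                label=lab,
                times=t,
                glucose=sub["glucose_mgdl"].to_numpy(dtype=float),
                insulin=sub["insulin_pmoll"].to_numpy(dtype=float),
                isr=sub["isr_pmolkgmin"].to_numpy(dtype=float),
                egp=egp,
            )
        )
    return DiurnalDataset.from_segments(segments, egp_basal=egp_basal)


def write_dataset(dataset: DiurnalDataset, path) -> None:
    """Write a dataset to CSV at full precision (round-trips exactly)."""
    # shortest round-trip repr; reading back with float_precision="round_trip"
    # reproduces every double bit-for-bit
    dataset.to_dataframe().to_csv(path, index=False)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a resolved configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
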