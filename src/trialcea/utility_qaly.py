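"""EQ-5D-3L utility indexing and QALY computation by the area-under-curve method.

A value set (tariff) maps each of the 243 EQ-5D-3L health states to a utility
index with full health at 1.  The shipped default is the Japanese time
trade-off tariff (additive decrement model: a constant decrement for any
departure from full health plus a per-dimension, per-level decrement; worst
state ``33333`` indexes to -0.111).  Provenance: Tsuchiya et al. (2002),
"Estimating an EQ-5D population value set: the case of Japan", shipped as
``valuesets/jp_tto.csv``.

QALYs over the follow-up are the trapezoidal integral of the utility
trajectory over time in years (linear interpolation between visits, no
extrapolation beyond the last visit).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .trial_data import (
    DAYS_PER_YEAR,
    EQ5D_DIMENSIONS,
    EQ5D_VISIT_DAYS,
    EQ5D_VISITS,
    EQ5DState,
    PatientRecord,
)

__all__ = [
    "ValueSet3L",
    "jp_tto",
    "eq5d_index",
    "UtilityTrajectory",
    "qaly_auc",
    "trajectory_from_record",
    "arm_qaly_summary",
    "QALYSummary",
]


@dataclass
class ValueSet3L:
    """Additive-decrement EQ-5D-3L tariff.

    ``index = perfect_health_value - constant - sum(decrements)`` whenever any
    dimension departs from level 1, else ``perfect_health_value`` (1.0 for any
    published tariff).  Decrements are keyed ``decrements[dimension][level]``
    for levels 2 and 3.
    """

    name: str
    constant: float
    decrements: Mapping[str, Mapping[int, float]]
    perfect_health_value: float = 1.0

    def __post_init__(self) -> None:
        for dim in EQ5D_DIMENSIONS:
            levels = self.decrements.get(dim)
            if levels is None:
                raise ValueError(f"value set {self.name!r} missing dimension {dim!r}")
            for lvl in (2, 3):
                if levels.get(lvl) is None:
                    raise ValueError(
                        f"value set {self.name!r}: {dim} missing level-{lvl} decrement"
                    )
                if levels[lvl] < 0:
                    raise ValueError(f"value set {self.name!r}: negative decrement")

    def index(self, state: EQ5DState) -> float:
        levels = state.levels
        if all(l == 1 for l in levels):
            return float(self.perfect_health_value)
        total = self.constant
        for dim, lvl in zip(EQ5D_DIMENSIONS, levels):
            if lvl > 1:
                total += self.decrements[dim][lvl]
        return float(self.perfect_health_value - total)

    def state_table(self) -> pd.DataFrame:
        """All 243 states with their utilities (columns ``code``, ``utility``)."""
        rows = []
        for levels in itertools.product((1, 2, 3), repeat=5):
            state = EQ5DState(*levels)
            rows.append({"code": state.code, "utility": self.index(state)})
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path, name: Optional[str] = None) -> "ValueSet3L":
        """Load a tariff from CSV with columns ``term, level, decrement``.

        ``term`` is ``constant`` (level ``any``) or a dimension name with
        level 2 or 3.
        """
        df = pd.read_csv(path)
        constant = 0.0
        decs: dict[str, dict[int, float]] = {d: {} for d in EQ5D_DIMENSIONS}
        for _, row in df.iterrows():
            term = str(row["term"])
            if term == "constant":
                constant = float(row["decrement"])
            elif term in decs:
                decs[term][int(row["level"])] = float(row["decrement"])
            else:
                raise ValueError(f"unknown tariff term {term!r}")
        return cls(name=name or str(path), constant=constant, decrements=decs)


@lru_cache(maxsize=None)
def jp_tto() -> ValueSet3L:
    """The shipped Japanese time trade-off EQ-5D-3L tariff."""
    ref = resources.files("trialcea").joinpath("valuesets/jp_tto.csv")
    with resources.as_file(ref) as path:
        return ValueSet3L.from_csv(path, name="JP-TTO")


def eq5d_index(state: EQ5DState, valueset: Optional[ValueSet3L] = None) -> float:
    """Utility index of one EQ-5D-3L state under a value set (default JP-TTO)."""
    return (valueset or jp_tto()).index(state)


@dataclass
class UtilityTrajectory:
    """Time-stamped utility values for one patient (times in years from baseline)."""

    times: np.ndarray
    utilities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.utilities = np.asarray(self.utilities, float)
        if self.times.ndim != 1 or self.times.shape != self.utilities.shape:
            raise ValueError("times and utilities must be 1-D and equal length")
        if self.times.size == 0:
            raise ValueError("trajectory is empty")
        if self.times[0] != 0.0:
            raise ValueError("trajectory must start at time 0 (baseline)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.utilities)):
            raise ValueError("utilities must be finite")


def qaly_auc(trajectory: UtilityTrajectory) -> float:
    """QALYs: trapezoidal area under the utility trajectory.

    Linear interpolation between visits; nothing is extrapolated beyond the
    last visit, so a constant utility ``u`` over horizon ``T`` gives exactly
    ``u * T``.
    """
    if trajectory.times.size < 2:
        raise ValueError("qaly_auc needs at least two time points")
    return float(np.trapezoid(trajectory.utilities, trajectory.times))


def trajectory_from_record(
    record: PatientRecord, valueset: Optional[ValueSet3L] = None
) -> UtilityTrajectory:
    """Index a patient's six scheduled EQ-5D responses into a trajectory."""
    vs = valueset or jp_tto()
    missing = [v for v in EQ5D_VISITS if v not in record.eq5d_responses]
    if missing:
        raise ValueError(
            f"patient {record.patient_id}: incomplete trajectory, missing {missing}"
        )
    times = np.array([EQ5D_VISIT_DAYS[v] / DAYS_PER_YEAR for v in EQ5D_VISITS])
    utils = np.array([vs.index(record.eq5d_responses[v]) for v in EQ5D_VISITS])
    return UtilityTrajectory(times=times, utilities=utils)


@dataclass(frozen=True)
class QALYSummary:
    arm: str
    n: int
    mean: float
    sd: float


def patient_qalys(
    cohort: Iterable[PatientRecord], arm: str, valueset: Optional[ValueSet3L] = None
) -> np.ndarray:
    """Per-patient QALYs for one arm, in cohort order."""
    vs = valueset or jp_tto()
    values = [
        qaly_auc(trajectory_from_record(rec, vs)) for rec in cohort if rec.arm == arm
    ]
    return np.asarray(values, float)


def arm_qaly_summary(
    cohort: Sequence[PatientRecord], arm: str, valueset: Optional[ValueSet3L] = None
) -> QALYSummary:
    """Sample mean and sd of per-patient QALYs in one arm."""
    q = patient_qalys(cohort, arm, valueset)
    if q.size == 0:
        raise ValueError(f"no patients in arm {arm!r}")
    sd = float(np.std(q, ddof=1)) if q.size > 1 else 0.0
    return QALYSummary(arm=arm, n=int(q.size), mean=float(np.mean(q)), sd=sd)
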