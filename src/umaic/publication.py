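"""What a published single-arm trial exposes about its survival data.

A journal figure and its accompanying text give away four things: the
Kaplan-Meier step curve, a numbers-at-risk table underneath the figure,
aggregate covariate summaries (baseline table), and the total sample size
(optionally the total event count).  This module produces exactly that bundle
from simulated individual patient data, emulating figure digitization
programmatically: step corners are extracted with times rounded to whole days
and survival rounded to a configurable number of decimals, with an optional
uniform jitter model for digitization error (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import DataValidationError

#: Default numbers-at-risk grid (days): common journal practice over a
#: 2500-day follow-up horizon.
DEFAULT_RISK_TIMES: Tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0)

#: Default number of decimals kept on the survival axis of an extracted curve.
DEFAULT_PRECISION = 4


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step-function corners: (time, survival), starting (0, 1)."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1 or t.size == 0:
            raise DataValidationError("curve needs matching 1-d time/survival arrays")
        if t[0] != 0.0 or s[0] != 1.0:
            raise DataValidationError("curve must start at (0, 1)")
        if np.any(np.diff(t) < 0):
            raise DataValidationError("curve times must be nondecreasing")
        if np.any(np.diff(s) > 0):
            raise DataValidationError("curve survival must be nonincreasing")
        if np.any(s < 0) or np.any(s > 1):
            raise DataValidationError("curve survival must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk (time, n) as printed under a published KM figure."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=np.int64)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.shape != n.shape or t.ndim != 1 or t.size == 0:
            raise DataValidationError("risk table needs matching 1-d arrays")
        if t[0] != 0.0:
            raise DataValidationError("risk table must include time 0")
        if np.any(np.diff(t) <= 0):
            raise DataValidationError("risk-table times must be increasing")
        if np.any(np.diff(n) > 0):
            raise DataValidationError("numbers at risk must be nonincreasing")
        if np.any(n < 0):
            raise DataValidationError("numbers at risk must be nonnegative")


@dataclass(frozen=True)
class AggregateSummary:
    """Baseline-table aggregates of the published arm."""

    mean_age: float
    var_age: float
    p_postmenopausal: float
    p_grade2: float
    p_grade3: float
    n_total: int

    def __post_init__(self) -> None:
        if self.var_age <= 0:
            raise DataValidationError("var_age must be > 0")
        for name in ("p_postmenopausal", "p_grade2", "p_grade3"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DataValidationError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class KMPublication:
    """Everything a published single-arm trial reveals."""

    curve: KMCurve
    risk_table: RiskTable
    aggregates: AggregateSummary
    total_events: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.risk_table.n_at_risk[0]) != int(self.aggregates.n_total):
            raise DataValidationError(
                "risk table at time 0 must equal the published total n"
            )


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimate of the survival curve from patient records.

    Corners are reported at t = 0 and at each distinct event time; censoring
    does not create steps.
    """
    if len(records) == 0:
        raise DataValidationError("cannot estimate a KM curve from no records")
    if (records["time"] < 0).any():
        raise DataValidationError("observed times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    event_times = np.unique(records.loc[records["event"] == 1, "time"].to_numpy(float))
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    times = np.concatenate([[0.0], event_times])
    survival = np.concatenate([[1.0], surv])
    return KMCurve(times=times, survival=survival)


def extract_curve(
    curve: KMCurve,
    precision: Optional[int] = DEFAULT_PRECISION,
    round_times: bool = True,
    time_jitter: float = 0.0,
    survival_jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> KMCurve:
    """Programmatic stand-in for digitizing a printed KM figure.

    Times are rounded to the nearest day and survival to ``precision``
    decimals (``precision=None`` disables all rounding and returns the input
    unchanged).  Optional uniform jitter (half-widths in days / survival
    units) emulates pixel-level digitization error; monotonicity is restored
    afterwards and corners colliding on the same day keep the lower survival.
    """
    if precision is None and not round_times and not time_jitter and not survival_jitter:
        return curve
    t = curve.times.copy()
    s = curve.survival.copy()
    if time_jitter or survival_jitter:
        if rng is None:
            raise ValueError("jitter requires an rng")
        t = t + rng.uniform(-time_jitter, time_jitter, size=t.shape)
        s = s + rng.uniform(-survival_jitter, survival_jitter, size=s.shape)
        t[0], s[0] = 0.0, 1.0
    if round_times:
        t = np.round(t)
    if precision is not None:
        s = np.round(s, precision)
    t = np.maximum.accumulate(np.maximum(t, 0.0))
    s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    # collapse corners that landed on the same day, keeping the lower survival
    keep = np.ones(t.size, dtype=bool)
    keep[:-1] = t[:-1] != t[1:]
    t, s = t[keep], s[keep]
    if t[0] != 0.0 or s[0] != 1.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return KMCurve(times=t, survival=s)


def numbers_at_risk(records: pd.DataFrame, times: Sequence[float]) -> RiskTable:
    """Count subjects with observed time >= t for each requested time."""
    obs = records["time"].to_numpy(dtype=float)
    times = np.asarray(list(times), dtype=float)
    counts = np.array([(obs >= t).sum() for t in times], dtype=np.int64)
    return RiskTable(times=times, n_at_risk=counts)


def summarize_covariates(records: pd.DataFrame) -> AggregateSummary:
    """Baseline aggregates: mean/sample-variance of age, binary proportions."""
    return AggregateSummary(
        mean_age=float(records["age"].mean()),
        var_age=float(records["age"].var(ddof=1)),
        p_postmenopausal=float(records["postmenopausal"].mean()),
        p_grade2=float(records["grade2"].mean()),
        p_grade3=float(records["grade3"].mean()),
        n_total=int(len(records)),
    )


def publish(
    records: pd.DataFrame,
    risk_times: Sequence[float] = DEFAULT_RISK_TIMES,
    precision: Optional[int] = DEFAULT_PRECISION,
    round_times: bool = True,
    publish_total_events: bool = True,
    time_jitter: float = 0.0,
    survival_jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> KMPublication:
    """Bundle the published view of an arm: extracted curve, risk table,
    aggregates, and (by default) the total event count."""
    risk_times = list(risk_times)
    if 0.0 not in [float(t) for t in risk_times]:
        raise DataValidationError("risk_times must include 0")
    curve = extract_curve(
        km_estimate(records),
        precision=precision,
        round_times=round_times,
        time_jitter=time_jitter,
        survival_jitter=survival_jitter,
        rng=rng,
    )
    risk = numbers_at_risk(records, risk_times)
    aggregates = summarize_covariates(records)
    total_events = int(records["event"].sum()) if publish_total_events else None
    return KMPublication(
        curve=curve, risk_table=risk, aggregates=aggregates, total_events=total_events
    )
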