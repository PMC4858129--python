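"""Breast-cancer-specific survival (BCSS) machinery.

BCSS is the interval from operation to death from breast cancer; deaths
from other causes and patients still alive are censored at last follow-up.
Estimation and testing delegate to lifelines (product-limit estimator,
log-rank chi-square, Cox partial likelihood with Efron tie handling); this
module fixes the encoding conventions and returns plain containers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "EVENT_TYPES",
    "SurvivalRecord",
    "KMCurve",
    "ExtrapolationWarning",
    "bcss_encode",
    "encode_records",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "CoxResult",
    "bonferroni_adjust",
]

EVENT_TYPES = ("bc_death", "other_death", "alive")


class ExtrapolationWarning(UserWarning):
    """Survival queried beyond the last observed follow-up time."""


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up of one patient: time in years and vital status."""

    time: float
    event: str

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"follow-up time must be positive and finite: {self.time}")
        if self.event not in EVENT_TYPES:
            raise ValueError(f"event must be one of {EVENT_TYPES}, got {self.event!r}")


def bcss_encode(record: SurvivalRecord) -> tuple[float, int]:
    """(time, indicator): 1 for breast-cancer death, 0 otherwise (censored)."""
    return record.time, 1 if record.event == "bc_death" else 0


def encode_records(
    records: Sequence[SurvivalRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised bcss_encode: (durations, event indicators)."""
    pairs = [bcss_encode(r) for r in records]
    if not pairs:
        return np.empty(0), np.empty(0, dtype=int)
    t, e = zip(*pairs)
    return np.asarray(t, dtype=float), np.asarray(e, dtype=int)


@dataclass
class KMCurve:
    """A Kaplan-Meier curve over its event times.

    ``times`` are the distinct event times (ascending); ``survival`` the
    product-limit estimate just after each event time; ``at_risk`` and
    ``events`` the risk-set size and death count at each.  Survival before
    the first event is 1 by construction.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    max_follow_up: float

    def to_frame(self, group: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )
        if group is not None:
            df.insert(0, "group", group)
        return df


def km_estimate(records_or_durations, events: Sequence[int] | None = None) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    Accepts either a sequence of SurvivalRecord (BCSS-encoded internally)
    or parallel ``durations, events`` arrays.
    """
    if events is None:
        durations, indicators = encode_records(list(records_or_durations))
    else:
        durations = np.asarray(records_or_durations, dtype=float)
        indicators = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("cannot estimate a survival curve from no records")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, indicators)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    times = observed.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[observed.index, "KM_estimate"].to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=observed["at_risk"].to_numpy(dtype=int),
        events=observed["observed"].to_numpy(dtype=int),
        max_follow_up=float(durations.max()),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step evaluation of a KM curve at time ``t``.

    At an event time the post-drop value applies.  Querying beyond the
    last follow-up returns the last value with an ExtrapolationWarning.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    if t > curve.max_follow_up:
        warnings.warn(
            f"survival queried at t={t:g} beyond last follow-up "
            f"{curve.max_follow_up:g}; returning last value",
            ExtrapolationWarning,
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(groups: Sequence[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int, float]:
    """Log-rank chi-square across >=2 groups of (durations, events).

    Returns (statistic, degrees of freedom, two-sided p from the
    chi-square upper tail).  All-censored input is an error (the statistic
    is undefined without events).
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        durations.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    durations = np.concatenate(durations)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined: no events in any group")
    res = multivariate_logrank_test(durations, labels, events)
    dof = len(groups) - 1
    return float(res.test_statistic), dof, float(res.p_value)


@dataclass
class CoxResult:
    """Cox proportional-hazards fit: betas with Wald inference."""

    betas: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    n: int
    n_events: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.betas, "se": self.standard_errors, "p": self.p_values}
        )


def cox_fit(
    design: pd.DataFrame,
    durations: Sequence[float],
    events: Sequence[int],
    *,
    min_events: int | None = None,
) -> CoxResult:
    """Cox partial-likelihood fit of BCSS on covariate columns.

    Ties are handled by lifelines' Efron approximation.  A constant
    column, too few events (fewer than the covariate count by default)
    or non-convergence raise with diagnostics.
    """
    design = pd.DataFrame(design).astype(float)
    durations = np.asarray(durations, dtype=float)
    event_arr = np.asarray(events, dtype=int)
    n_events = int(event_arr.sum())
    if design.shape[1] == 0:
        raise ValueError("empty design matrix")
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")
    floor = design.shape[1] if min_events is None else min_events
    if n_events == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    if n_events < floor:
        raise ValueError(f"only {n_events} events for {design.shape[1]} covariates")
    df = design.copy()
    df["_time"] = durations
    df["_event"] = event_arr
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    return CoxResult(
        betas=cph.params_.rename(None),
        standard_errors=cph.standard_errors_.rename(None),
        p_values=cph.summary["p"].rename(None),
        n=int(design.shape[0]),
        n_events=n_events,
    )


def bonferroni_adjust(pvalues: Sequence[float], alpha: float = 0.01) -> list[bool]:
    """Significance flags at family-wise level alpha: flag iff p < alpha/m."""
    p = list(pvalues)
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {v}")
    m = len(p)
    if m == 0:
        return []
    threshold = alpha / m
    return [v < threshold for v in p]
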