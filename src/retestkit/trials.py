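"""Intra-subject (within-session) error from trial-level data.

Parameters that are averages over repeated trials carry an extra source of
variability: the gap between the true underlying mean and the mean
estimated from a finite number of trials.  The standard error of the trial
mean (SEM) of each participant-session series quantifies it; pooling the
SEMs across participants and both sessions and rescaling by sqrt(2)*1.64
puts this intra-subject (IS) error on the same scale as the
significant-change threshold SC = SD_diff * sqrt(2) * 1.64, so the two can
be compared directly.  In practice the IS error is a small fraction of SC,
i.e. between-assessment variation dominates within-assessment noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .transforms import InsufficientDataError

__all__ = ["TrialSeries", "ISErrorResult", "series_sem", "is_error"]


@dataclass(frozen=True)
class TrialSeries:
    """Trial measurements for one participant, session and parameter."""

    participant: str
    session: int
    parameter: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")


@dataclass(frozen=True)
class ISErrorResult:
    """Pooled within-session error, scaled for comparison against SC."""

    parameter: str
    n_series: int
    pooled_sem: float
    is_error: float
    ratio_to_sc: float


def series_sem(series: TrialSeries) -> float:
    """Standard error of the trial mean for one series.

    Sample SD of the trials (n-1 denominator) divided by sqrt(n_trials).
    """
    v = series.values
    if v.size < 2:
        raise InsufficientDataError(
            f"SEM needs >= 2 trials, series has {v.size}"
        )
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def is_error(
    all_series: Sequence[TrialSeries],
    sc: float,
    pooling: Literal["rms", "mean"] = "rms",
    ci_multiplier: float = 1.64,
) -> ISErrorResult:
    """Pool per-series SEMs and rescale into an SC-comparable IS error.

    SEMs from every participant and both sessions enter the pool.  The
    default pooling is root-mean-square, the natural combination for
    standard deviations of estimators; arithmetic-mean pooling is offered
    for sensitivity analysis.  is_error = pooled_sem * sqrt(2) * multiplier.
    """
    if sc <= 0 or not np.isfinite(sc):
        raise ValueError("sc must be positive and finite")
    sems = np.array([series_sem(s) for s in all_series], dtype=float)
    if sems.size == 0:
        raise InsufficientDataError("no trial series supplied")
    if pooling == "rms":
        pooled = float(np.sqrt(np.mean(sems**2)))
    elif pooling == "mean":
        pooled = float(np.mean(sems))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    err = pooled * math.sqrt(2.0) * ci_multiplier
    names = {s.parameter for s in all_series}
    name = names.pop() if len(names) == 1 else "+".join(sorted(names))
    return ISErrorResult(
        parameter=name,
        n_series=int(sems.size),
        pooled_sem=pooled,
        is_error=err,
        ratio_to_sc=err / sc,
    )
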