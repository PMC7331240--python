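"""Retest variability: SD_diff, confidence intervals, significant change, ICC.

The core quantities for one parameter (or one task score) measured on the
same participants in two sessions:

* ``SD_diff`` — standard deviation of the session-2 minus session-1
  difference scores, after excluding difference outliers (|d| above a
  threshold, default 3.2 Z-units: a paired difference that large should
  occur roughly 1 in 1000 times if scores were independent draws),
* ``CI = 1.64 * SD_diff`` — the band within which ~90% of healthy retest
  differences fall (one-tailed 95% in each direction),
* ``SC = sqrt(2) * CI`` — the threshold an observed change between two
  assessments must exceed to be called a real change,
* ``ICC-C`` — consistency-type intraclass correlation, the ratio of
  between-participant variance to between-participant plus error variance,
  ignoring any systematic session shift (which is quantified separately as
  a learning effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .transforms import (
    DegenerateDataError,
    InsufficientDataError,
    DEFAULT_Z_OUTLIER_THRESHOLD,
)

__all__ = [
    "ParameterSpec",
    "PairedObservations",
    "ReliabilityResult",
    "ThresholdConfig",
    "flag_difference_outliers",
    "compute_ci_sc",
    "sc_from_ci",
    "icc_consistency",
    "sd_diff_from_icc",
    "reliability_result",
]

SQRT2 = math.sqrt(2.0)

IccFormula = Literal["variance_components", "literal_eq5"]


@dataclass(frozen=True)
class ParameterSpec:
    """Identity and directionality of one assessment parameter.

    ``sidedness`` decides whether the one-sided Zeta fold is applied when
    building composite scores: one-sided parameters have a single "worse"
    direction (``higher_worse`` or ``higher_better``); two-sided parameters
    (e.g. lateral biases) are impaired in either direction and keep their
    raw Z-score.  ``n_trials`` is the number of within-session trials
    (0 = the parameter has no trial-level data).
    """

    name: str
    task: str = ""
    sidedness: Literal["one_sided", "two_sided"] = "two_sided"
    direction: Literal["higher_worse", "higher_better"] = "higher_worse"
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ValueError(f"invalid sidedness {self.sidedness!r}")
        if self.direction not in ("higher_worse", "higher_better"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.n_trials != 0 and self.n_trials < 2:
            raise ValueError("n_trials must be 0 or >= 2")


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds with their conventional defaults.

    ci_multiplier 1.64 gives the one-tailed 95% band (use 1.96 for a
    two-tailed question); diff_outlier_threshold 3.2 excludes ~1/1000
    paired differences; z_outlier_threshold 3.29 is the normalization
    trimming bound; alpha is the learning-effect test level and FDR level.
    """

    ci_multiplier: float = 1.64
    diff_outlier_threshold: float = 3.2
    z_outlier_threshold: float = DEFAULT_Z_OUTLIER_THRESHOLD
    alpha: float = 0.05
    icc_formula: IccFormula = "variance_components"

    def __post_init__(self) -> None:
        for name in ("ci_multiplier", "diff_outlier_threshold", "z_outlier_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.icc_formula not in ("variance_components", "literal_eq5"):
            raise ValueError(f"invalid icc_formula {self.icc_formula!r}")


@dataclass(frozen=True)
class PairedObservations:
    """Aligned session-1 / session-2 values for one parameter."""

    parameter: ParameterSpec
    participant_ids: tuple
    session1: np.ndarray
    session2: np.ndarray
    diff_outlier_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s1 = np.asarray(self.session1, dtype=float)
        s2 = np.asarray(self.session2, dtype=float)
        object.__setattr__(self, "session1", s1)
        object.__setattr__(self, "session2", s2)
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))
        flags = self.diff_outlier_flags
        if flags is None:
            flags = np.zeros(s1.size, dtype=bool)
        flags = np.asarray(flags, dtype=bool)
        object.__setattr__(self, "diff_outlier_flags", flags)
        n = len(self.participant_ids)
        if not (s1.size == s2.size == flags.size == n):
            raise ValueError("session vectors, flags and ids must align")

    @property
    def n_pairs(self) -> int:
        return len(self.participant_ids)

    @property
    def diffs(self) -> np.ndarray:
        """Session-2 minus session-1 differences (all pairs)."""
        return self.session2 - self.session1

    @property
    def n_flagged(self) -> int:
        return int(self.diff_outlier_flags.sum())

    def unflagged(self) -> "PairedObservations":
        """The subset of pairs not flagged as difference outliers."""
        keep = ~self.diff_outlier_flags
        return PairedObservations(
            parameter=self.parameter,
            participant_ids=tuple(
                p for p, k in zip(self.participant_ids, keep) if k
            ),
            session1=self.session1[keep],
            session2=self.session2[keep],
        )


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-parameter retest summary; sc = sqrt(2)*ci and ci = mult*sd_diff exactly."""

    n_pairs: int
    n_outliers_removed: int
    sd_diff: float
    ci: float
    sc: float
    icc_c: float
    ms_subjects: float
    ms_error: float


def flag_difference_outliers(
    pairs: PairedObservations, threshold: float = 3.2
) -> PairedObservations:
    """Flag pairs whose |session2 - session1| strictly exceeds ``threshold``.

    Flagged pairs are excluded from every downstream reliability, ICC and
    learning-effect computation but stay counted in reports.  The boundary
    is strict: a difference exactly at the threshold is retained.
    """
    if pairs.n_pairs < 2:
        raise InsufficientDataError("need >= 2 pairs to flag outliers")
    flags = np.abs(pairs.diffs) > threshold
    return replace(pairs, diff_outlier_flags=flags)


def sc_from_ci(ci: float) -> float:
    """Significant-change threshold from an assessment confidence interval."""
    return SQRT2 * ci


def compute_ci_sc(
    pairs: PairedObservations, config: ThresholdConfig = ThresholdConfig()
) -> tuple[float, float, float]:
    """(SD_diff, CI, SC) from the unflagged paired differences.

    SD_diff uses the n-1 sample denominator; CI = ci_multiplier * SD_diff;
    SC = sqrt(2) * CI.
    """
    d = pairs.unflagged().diffs
    if d.size < 2:
        raise InsufficientDataError(
            f"need >= 2 unflagged pairs, have {d.size}"
        )
    sd_diff = float(np.std(d, ddof=1))
    ci = config.ci_multiplier * sd_diff
    return sd_diff, ci, sc_from_ci(ci)


def _mean_squares(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Two-way crossed (subjects x sessions) mean squares for k = 2 sessions.

    MS_S is the between-subject mean square; MS_E the residual mean square
    after removing subject and session main effects.
    """
    n = s1.size
    table = np.column_stack([s1, s2])
    grand = table.mean()
    subj_means = table.mean(axis=1)
    sess_means = table.mean(axis=0)
    ms_s = 2.0 * np.sum((subj_means - grand) ** 2) / (n - 1)
    resid = table - subj_means[:, None] - sess_means[None, :] + grand
    ms_e = float(np.sum(resid**2) / (n - 1))  # df = (n-1)(k-1), k = 2
    return float(ms_s), ms_e


def icc_consistency(
    pairs: PairedObservations,
    formula: IccFormula = "variance_components",
) -> tuple[float, float, float]:
    """Consistency ICC with its mean squares: (icc_c, ms_subjects, ms_error).

    ``variance_components`` (default) is the standard two-session
    consistency form (MS_S - MS_E) / (MS_S + MS_E), whose expectation is
    sigma_subject^2 / (sigma_subject^2 + sigma_error^2); it is 1 when the
    sessions agree perfectly up to a constant shift and 0 when there is no
    subject effect.  ``literal_eq5`` returns MS_S / (MS_S + MS_E), kept for
    fidelity comparisons (it tends to 0.5, not 0, under no subject effect).
    """
    sub = pairs.unflagged()
    if sub.n_pairs < 3:
        raise InsufficientDataError(
            f"need >= 3 unflagged pairs for ICC, have {sub.n_pairs}"
        )
    ms_s, ms_e = _mean_squares(sub.session1, sub.session2)
    if ms_s + ms_e == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    if formula == "variance_components":
        icc = (ms_s - ms_e) / (ms_s + ms_e)
    elif formula == "literal_eq5":
        icc = ms_s / (ms_s + ms_e)
    else:
        raise ValueError(f"unknown ICC formula {formula!r}")
    return float(icc), ms_s, ms_e


def sd_diff_from_icc(sd_single_session: float, icc: float) -> float:
    """SD_diff substitute when only a single-session SD and an ICC are known.

    Uses the identity SD_diff = SD_pre * sqrt(1 - ICC) (equivalently with
    SD_post), valid when the two sessions share the same SD.
    """
    if not np.isfinite(sd_single_session) or sd_single_session <= 0:
        raise ValueError("sd_single_session must be positive and finite")
    if icc >= 1:
        raise ValueError("icc must be < 1")
    return float(sd_single_session * math.sqrt(1.0 - icc))


def reliability_result(
    pairs: PairedObservations, config: ThresholdConfig = ThresholdConfig()
) -> ReliabilityResult:
    """Flag difference outliers and compute the full retest summary."""
    flagged = flag_difference_outliers(pairs, config.diff_outlier_threshold)
    sd_diff, ci, sc = compute_ci_sc(flagged, config)
    icc, ms_s, ms_e = icc_consistency(flagged, config.icc_formula)
    return ReliabilityResult(
        n_pairs=flagged.n_pairs,
        n_outliers_removed=flagged.n_flagged,
        sd_diff=sd_diff,
        ci=ci,
        sc=sc,
        icc_c=icc,
        ms_subjects=ms_s,
        ms_error=ms_e,
    )
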