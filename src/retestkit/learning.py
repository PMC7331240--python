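"""Learning effects across repeated assessments, with FDR control.

A learning effect is a systematic shift in performance between the first
and second session: the mean of the session-2 minus session-1 differences.
Negative values mean lower (better) Z-scores at retest.  Each parameter is
tested with a two-sided paired-sample t-test; because a run typically
tests well over a hundred parameters, raw p-values are corrected across
the whole family with the Benjamini-Hochberg step-up false-discovery-rate
procedure rather than a (too conservative) Bonferroni bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reliability import (
    PairedObservations,
    ThresholdConfig,
    flag_difference_outliers,
)
from .transforms import InsufficientDataError

__all__ = [
    "LearningEffectResult",
    "paired_t_test",
    "benjamini_hochberg",
    "learning_effect_table",
]


@dataclass(frozen=True)
class LearningEffectResult:
    """Paired-test outcome for one parameter, with FDR-adjusted q-value."""

    parameter: str
    task: str
    n_pairs: int
    mean_diff: float
    t_statistic: float
    df: int
    p_value: float
    q_value: float
    significant_raw: bool
    significant_fdr: bool


def paired_t_test(session1, session2) -> tuple[float, float, int, float]:
    """Two-sided paired t-test on session2 - session1.

    Returns (mean_diff, t_statistic, df, p_value).  Degenerate cases are
    resolved explicitly: if every difference is identical with mean 0 the
    result is (0, 0, df, 1); identical with nonzero mean gives an infinite
    t and the smallest positive p representable.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.size != s2.size:
        raise ValueError("sessions must have equal length")
    n = s1.size
    if n < 3:
        raise InsufficientDataError(f"paired t-test needs >= 3 pairs, got {n}")
    d = s2 - s1
    mean_diff = float(np.mean(d))
    df = n - 1
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            return 0.0, 0.0, df, 1.0
        t = math.copysign(math.inf, mean_diff)
        return mean_diff, t, df, float(np.nextafter(0.0, 1.0))
    res = stats.ttest_rel(s2, s1)
    return mean_diff, float(res.statistic), df, float(res.pvalue)


def benjamini_hochberg(
    p_values, fdr_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Sorts the m p-values ascending, finds the largest rank i with
    p(i) <= i * fdr_level / m and rejects all hypotheses up to that rank.
    Returns (q_values, reject_flags) in the input order; q-values are the
    monotone-adjusted p * m / rank, capped at 1, so q >= p always.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must lie in (0, 1)")
    reject, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return q, reject


def learning_effect_table(
    pairs_by_parameter: Mapping[str, PairedObservations],
    config: ThresholdConfig = ThresholdConfig(),
    family: Literal["all", "per_task"] = "all",
) -> list[LearningEffectResult]:
    """Per-parameter learning effects with joint FDR correction.

    Difference outliers (|d| > config.diff_outlier_threshold) are excluded
    before testing, mirroring the reliability computations.  By default all
    parameters of all tasks form one FDR family; ``family="per_task"``
    corrects within each task separately.
    """
    if not pairs_by_parameter:
        raise InsufficientDataError("no parameters to test")
    partial: list[dict] = []
    for name, pairs in pairs_by_parameter.items():
        kept = flag_difference_outliers(
            pairs, config.diff_outlier_threshold
        ).unflagged()
        mean_diff, t, df, p = paired_t_test(kept.session1, kept.session2)
        partial.append(
            {
                "parameter": name,
                "task": pairs.parameter.task,
                "n_pairs": kept.n_pairs,
                "mean_diff": mean_diff,
                "t": t,
                "df": df,
                "p": p,
            }
        )

    results: list[LearningEffectResult] = []
    if family == "all":
        groups = [partial]
    elif family == "per_task":
        tasks = dict.fromkeys(r["task"] for r in partial)
        groups = [[r for r in partial if r["task"] == t] for t in tasks]
    else:
        raise ValueError(f"unknown family {family!r}")
    for group in groups:
        q, reject = benjamini_hochberg(
            [r["p"] for r in group], fdr_level=config.alpha
        )
        for r, qv, rej in zip(group, q, reject):
            results.append(
                LearningEffectResult(
                    parameter=r["parameter"],
                    task=r["task"],
                    n_pairs=r["n_pairs"],
                    mean_diff=r["mean_diff"],
                    t_statistic=r["t"],
                    df=r["df"],
                    p_value=r["p"],
                    q_value=float(qv),
                    significant_raw=bool(r["p"] < config.alpha),
                    significant_fdr=bool(rej),
                )
            )
    order = {name: i for i, name in enumerate(pairs_by_parameter)}
    results.sort(key=lambda r: order[r.parameter])
    return results
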