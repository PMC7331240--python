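"""Probabilistic impairment and change classification.

Because every observed score carries an assessment confidence interval,
impairment relative to a threshold is a probability, not a binary call.
With an impairment cutoff T (default 1.64: worse than ~95% of healthy
controls) and an assessment CI, the score axis splits into three regions:

* ``not_impaired``  — observed < T - CI (probability of true impairment < ~5%),
* ``possibly_impaired`` — within T +/- CI,
* ``impaired`` — observed >= T + CI (probability > ~95%).

The probability itself models the latent true score as Normal around the
observation with SD = CI / ci_multiplier, which makes the region edges land
exactly on the multiplier's tail quantiles.  The same logic applied to the
difference of two assessments against the significant-change threshold SC
classifies change as improved / possibly_changed / worse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["ImpairmentCall", "ChangeCall", "classify_impairment", "classify_change"]

ImpairmentCategory = Literal["not_impaired", "possibly_impaired", "impaired"]
ChangeCategory = Literal["improved", "possibly_changed", "worse"]


@dataclass(frozen=True)
class ImpairmentCall:
    observed: float
    threshold: float
    ci: float
    category: ImpairmentCategory
    probability_impaired: float


@dataclass(frozen=True)
class ChangeCall:
    score1: float
    score2: float
    sc: float
    category: ChangeCategory


def classify_impairment(
    observed: float,
    threshold: float = 1.64,
    ci: float = 1.0,
    ci_multiplier: float = 1.64,
) -> ImpairmentCall:
    """Classify one observed score against an impairment threshold.

    Region boundaries sit at threshold -/+ ci; an observation exactly on
    the upper edge is called impaired (ties go to the more severe
    category).  probability_impaired = P(true score >= threshold) =
    Phi((observed - threshold) / sigma) with sigma = ci / ci_multiplier,
    so it is exactly 0.5 at the threshold and hits the multiplier's tail
    probabilities (~5% / ~95% for 1.64) at the region edges.
    """
    if ci <= 0 or not np.isfinite(ci):
        raise ValueError("ci must be positive and finite")
    if ci_multiplier <= 0:
        raise ValueError("ci_multiplier must be positive")
    sigma = ci / ci_multiplier
    prob = float(stats.norm.cdf((observed - threshold) / sigma))
    if observed >= threshold + ci:
        category: ImpairmentCategory = "impaired"
    elif observed < threshold - ci:
        category = "not_impaired"
    else:
        category = "possibly_impaired"
    return ImpairmentCall(
        observed=float(observed),
        threshold=float(threshold),
        ci=float(ci),
        category=category,
        probability_impaired=prob,
    )


def classify_change(score1: float, score2: float, sc: float) -> ChangeCall:
    """Classify the change between two assessments of the same parameter.

    ``improved`` if score2 < score1 - sc, ``worse`` if score2 > score1 + sc,
    otherwise ``possibly_changed``; symmetric under negating both scores.
    """
    if sc <= 0 or not np.isfinite(sc):
        raise ValueError("sc must be positive and finite")
    if score2 < score1 - sc:
        category: ChangeCategory = "improved"
    elif score2 > score1 + sc:
        category = "worse"
    else:
        category = "possibly_changed"
    return ChangeCall(
        score1=float(score1), score2=float(score2), sc=float(sc), category=category
    )
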