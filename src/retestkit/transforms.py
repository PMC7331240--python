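"""Score normalization and one-sided composite-score transforms.

Behavioural task parameters arrive in heterogeneous units (seconds, metres,
counts).  Before any reliability analysis they are mapped onto a common
Z-score scale by an iterative de-skew (Box-Cox) and outlier-trim loop, and
parameter Z-scores are condensed into per-task composite scores:

* ``zeta_transform`` folds a two-sided standard-normal score into a
  one-sided "Zeta" score so that larger always means worse,
* ``rss_distance`` / ``mahalanobis_distance`` collapse a vector of
  parameter scores into a single distance,
* ``z_task_score`` re-standardizes that distance against a reference
  cohort, and ``task_score`` maps it onto the one-sided 0-to-infinity
  Task-Score scale,
* ``task_score_ci`` propagates a symmetric confidence interval on the
  Z-Task Score through the nonlinear one-sided transform, which makes the
  resulting Task-Score interval asymmetric.

The one-sided mapping is

    zeta(z) = sqrt(2) * erfcinv(0.5 * erfc(z / sqrt(2)))

which is exactly the standard-normal quantile of ``(1 + Phi(z)) / 2``: the
half of the normal mass lying in ``(-|q|, |q|)`` below ``z`` is folded onto
the positive axis.  ``zeta(0) = 0.6745`` (the 75th percentile) and
``zeta(z) -> z`` as ``z -> +inf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "NormalizationModel",
    "TaskScoreCI",
    "fit_normalization",
    "zeta_transform",
    "rss_distance",
    "mahalanobis_distance",
    "z_task_score",
    "task_score",
    "task_score_ci",
    "write_normalization_models",
    "read_normalization_models",
]

_SQRT2 = np.sqrt(2.0)

#: |Z| beyond which an observation is trimmed during normalization; the
#: two-sided standard-normal tail mass beyond 3.29 is ~0.1%.
DEFAULT_Z_OUTLIER_THRESHOLD = 3.29


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for an estimate."""


class DegenerateDataError(ValueError):
    """Raised when the data carry no usable variability."""


def _one_sided(z: np.ndarray | float) -> np.ndarray | float:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("one-sided transform requires finite input")
    out = _SQRT2 * special.erfcinv(0.5 * special.erfc(z / _SQRT2))
    return float(out) if out.ndim == 0 else out


def zeta_transform(z):
    """One-sided "Zeta" transform of a parameter Z-score.

    Parameters whose impairment direction is one-sided (e.g. object-hit
    counts, where more is always better) are folded so that impairment is
    always a higher value.  Strictly increasing; maps R onto (0, inf).

    Accepts a scalar or array; returns the same shape.
    """
    return _one_sided(z)


def task_score(z_task_score):
    """One-sided Task Score from a two-sided Z-Task Score.

    Identical functional form to :func:`zeta_transform`; 0 is best and
    larger values reflect poorer overall task performance.
    """
    return _one_sided(z_task_score)


@dataclass(frozen=True)
class TaskScoreCI:
    """One-sided Task Score with asymmetric confidence bounds."""

    z_task_score: float
    task_score: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not (self.lower_bound <= self.task_score <= self.upper_bound):
            raise ValueError("bounds must bracket the point estimate")


def task_score_ci(z_task_score: float, ci: float) -> TaskScoreCI:
    """Propagate a symmetric Z-Task-Score CI through the one-sided transform.

    The interval ``z +/- ci`` on the two-sided scale maps to
    ``[task_score(z - ci), task_score(z + ci)]``.  Because the one-sided
    transform compresses the left tail toward zero, the lower distance
    (point - lower) is smaller than the upper distance near z = 0 and both
    distances approach ``ci`` from below as z grows.
    """
    if not np.isfinite(ci) or ci <= 0:
        raise ValueError("ci must be a positive finite number")
    z = float(z_task_score)
    return TaskScoreCI(
        z_task_score=z,
        task_score=_one_sided(z),
        lower_bound=_one_sided(z - ci),
        upper_bound=_one_sided(z + ci),
    )


def rss_distance(z_two_sided, zeta_one_sided=()) -> float:
    """Root-sum-square distance over parameter scores.

    Euclidean length of the concatenated two-sided Z-scores and one-sided
    Zeta-scores for a task.  Missing (NaN) components are dropped from the
    sum; if every component is missing this is an error rather than 0.
    """
    parts = np.concatenate(
        [np.asarray(z_two_sided, dtype=float).ravel(),
         np.asarray(zeta_one_sided, dtype=float).ravel()]
    )
    finite = parts[np.isfinite(parts)]
    if finite.size == 0:
        raise InsufficientDataError("no finite components for rss distance")
    return float(np.sqrt(np.sum(finite**2)))


def mahalanobis_distance(z_vector, covariance, ridge: float = 1e-8) -> float:
    """Mahalanobis distance sqrt(z' Sigma^-1 z) of a parameter-score vector.

    A ridge of ``ridge * trace(Sigma)/dim`` is added to the diagonal so a
    near-singular covariance (collinear parameters) stays invertible.
    """
    z = np.asarray(z_vector, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape[0] != cov.shape[1] or cov.shape[0] != z.size:
        raise ValueError(
            f"covariance shape {cov.shape} does not match vector length {z.size}"
        )
    cov = cov + np.eye(z.size) * (ridge * np.trace(cov) / z.size)
    quad = float(z @ np.linalg.solve(cov, z))
    return float(np.sqrt(max(quad, 0.0)))


@dataclass(frozen=True)
class NormalizationModel:
    """Fitted de-skew + standardize model for one parameter.

    ``transform`` applies shift -> Box-Cox(lambda) -> (y - location)/scale.
    Fitting iterates Box-Cox maximum likelihood and |Z| > threshold trimming
    until no observation is dropped, so applying the model to its own
    retained training data yields mean ~0 and SD ~1.
    """

    box_cox_lambda: float
    shift: float
    location: float
    scale: float
    n_outliers_trimmed: int
    n_iterations: int
    z_outlier_threshold: float = DEFAULT_Z_OUTLIER_THRESHOLD

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale must be positive and finite")

    def transform(self, values):
        """Map raw values onto the fitted Z scale.

        Values at or below the positivity shift (possible for new data
        outside the training range) are floored just above zero before the
        power transform; they map to extreme negative Z-scores.
        """
        x = np.asarray(values, dtype=float) + self.shift
        x = np.maximum(x, np.finfo(float).tiny)
        y = stats.boxcox(x, lmbda=self.box_cox_lambda)
        out = (y - self.location) / self.scale
        return float(out) if np.ndim(values) == 0 else out


def _boxcox_mle_lambda(x: np.ndarray, bounds=(-5.0, 5.0)) -> float:
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x), bounds=bounds, method="bounded"
    )
    return float(res.x)


def fit_normalization(
    values,
    max_iterations: int = 10,
    z_outlier_threshold: float = DEFAULT_Z_OUTLIER_THRESHOLD,
) -> NormalizationModel:
    """Fit the iterative de-skew / outlier-trim normalization.

    Each pass shifts the data to positivity (once, from the full sample),
    Box-Cox transforms with the maximum-likelihood lambda (bounded to
    [-5, 5]), standardizes, and drops observations with |Z| beyond the
    threshold; passes repeat until nothing is dropped or ``max_iterations``
    is reached.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 finite values.
    DegenerateDataError
        All values identical (zero scale).
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise InsufficientDataError(
            f"normalization needs >= 10 finite values, got {vals.size}"
        )
    if np.ptp(vals) == 0:
        raise DegenerateDataError("all values identical; scale undefined")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    vmin = vals.min()
    shift = 1.0 - vmin if vmin <= 0 else 0.0

    retained = vals
    lam = loc = scale = None
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        if retained.size < 10:
            break
        if np.ptp(retained) == 0:
            raise DegenerateDataError("retained values became constant")
        x = retained + shift
        lam = _boxcox_mle_lambda(x)
        y = stats.boxcox(x, lmbda=lam)
        loc = float(np.mean(y))
        scale = float(np.std(y, ddof=1))
        if scale == 0 or not np.isfinite(scale):
            raise DegenerateDataError("degenerate scale after transform")
        z = (y - loc) / scale
        keep = np.abs(z) <= z_outlier_threshold
        if keep.all():
            break
        retained = retained[keep]

    return NormalizationModel(
        box_cox_lambda=lam,
        shift=shift,
        location=loc,
        scale=scale,
        n_outliers_trimmed=int(vals.size - retained.size),
        n_iterations=n_iter,
        z_outlier_threshold=z_outlier_threshold,
    )


def z_task_score(rss_values, value, max_iterations: int = 10) -> float:
    """Standardize a distance against a reference cohort of distances.

    Fits :func:`fit_normalization` on the reference cohort's RSS (or
    Mahalanobis) distances and applies the model to ``value``, yielding the
    two-sided Z-Task Score.  For repeated scoring, fit the model once and
    call :meth:`NormalizationModel.transform` directly.
    """
    model = fit_normalization(rss_values, max_iterations=max_iterations)
    return float(model.transform(float(value)))


# -- plain-text serialization -------------------------------------------------

def write_normalization_models(
    models: Mapping[str, NormalizationModel], path
) -> None:
    """Write fitted models as a flat key-value text file (one key per line)."""
    fields = (
        "box_cox_lambda", "shift", "location", "scale",
        "n_outliers_trimmed", "n_iterations", "z_outlier_threshold",
    )
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(models):
            m = models[name]
            for f in fields:
                fh.write(f"{name}.{f} = {getattr(m, f)!r}\n")


def read_normalization_models(path) -> dict[str, NormalizationModel]:
    """Read models written by :func:`write_normalization_models`."""
    raw: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            name, _, field = key.strip().rpartition(".")
            raw.setdefault(name, {})[field] = float(val)
    out = {}
    for name, d in raw.items():
        out[name] = NormalizationModel(
            box_cox_lambda=d["box_cox_lambda"],
            shift=d["shift"],
            location=d["location"],
            scale=d["scale"],
            n_outliers_trimmed=int(d["n_outliers_trimmed"]),
            n_iterations=int(d["n_iterations"]),
            z_outlier_threshold=d.get(
                "z_outlier_threshold", DEFAULT_Z_OUTLIER_THRESHOLD
            ),
        )
    return out
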