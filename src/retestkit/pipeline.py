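"""End-to-end retest analysis: from long-format tables to report files.

``analyze`` runs the full per-parameter chain — difference-outlier
flagging, SD_diff / CI / SC, consistency ICC, learning effects with joint
FDR correction, and (where trial data exist) the intra-subject error — and
returns the report tables; ``run_pipeline`` additionally writes them to an
output directory:

* ``parameters.csv``      — full-precision per-parameter report,
* ``parameters_2dp.csv``  — the same table rounded to 2 decimals for
  presentation,
* ``ci_distribution.csv``, ``learning_distribution.csv``,
  ``icc_distribution.csv`` — sorted values with cumulative fractions,
* ``run_manifest.txt``    — seed, thresholds and version as key-value text.

Report columns mirror the published per-task summary layout (outliers
removed, significant change, confidence interval, learning effect and its
p-value, ICC consistency), extended with q-values, significance flags and
the IS-error columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io import AssessmentData, read_assessments, read_trials, write_key_values
from .learning import learning_effect_table
from .reliability import (
    PairedObservations,
    ThresholdConfig,
    flag_difference_outliers,
    icc_consistency,
    compute_ci_sc,
)
from .trials import TrialSeries, is_error

__all__ = ["RunConfig", "analyze", "run_pipeline"]

log = logging.getLogger("retestkit")

REPORT_COLUMNS = [
    "task",
    "parameter",
    "n_pairs",
    "outliers_removed",
    "significant_change",
    "confidence_interval",
    "learning_effect",
    "le_p_value",
    "le_q_value",
    "le_significant_raw",
    "le_significant_fdr",
    "icc_consistency",
    "is_error",
    "is_error_to_sc",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    assessments: str | Path
    trials: str | Path | None = None
    output_dir: str | Path = "retestkit_out"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    verbosity: int = 0


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise labelled
                raise RuntimeError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def analyze(
    pairs_by_parameter: Mapping[str, PairedObservations] | AssessmentData,
    trial_series: Sequence[TrialSeries] = (),
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Per-parameter retest report as a DataFrame (full precision).

    Difference outliers are flagged once and excluded consistently from
    SD_diff/CI/SC, ICC and the learning tests; the FDR family spans all
    parameters jointly.
    """
    if isinstance(pairs_by_parameter, AssessmentData):
        pairs_by_parameter = pairs_by_parameter.pairs
    if not pairs_by_parameter:
        raise ValueError("no parameters to analyze")

    flagged = {
        name: flag_difference_outliers(p, config.diff_outlier_threshold)
        for name, p in pairs_by_parameter.items()
    }
    learning = {
        r.parameter: r
        for r in learning_effect_table(pairs_by_parameter, config)
    }
    trials_by_param: dict[str, list[TrialSeries]] = {}
    for s in trial_series:
        trials_by_param.setdefault(s.parameter, []).append(s)

    rows = []
    for name, pairs in flagged.items():
        sd_diff, ci, sc = compute_ci_sc(pairs, config)
        icc, _, _ = icc_consistency(pairs, config.icc_formula)
        le = learning[name]
        row = {
            "task": pairs.parameter.task,
            "parameter": name,
            "n_pairs": pairs.n_pairs,
            "outliers_removed": pairs.n_flagged,
            "significant_change": sc,
            "confidence_interval": ci,
            "learning_effect": le.mean_diff,
            "le_p_value": le.p_value,
            "le_q_value": le.q_value,
            "le_significant_raw": le.significant_raw,
            "le_significant_fdr": le.significant_fdr,
            "icc_consistency": icc,
            "is_error": np.nan,
            "is_error_to_sc": np.nan,
        }
        if name in trials_by_param:
            res = is_error(trials_by_param[name], sc=sc)
            row["is_error"] = res.is_error
            row["is_error_to_sc"] = res.ratio_to_sc
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _cumulative_table(values: pd.Series) -> pd.DataFrame:
    ordered = np.sort(values.to_numpy())
    frac = np.arange(1, ordered.size + 1) / ordered.size
    return pd.DataFrame(
        {"value": ordered, "cumulative_fraction": frac}
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis described by ``config`` and write report files.

    Returns a mapping from report name to written path.  Any stage failure
    aborts with a stage-labelled error and removes partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        data = _stage("read")(read_assessments)(config.assessments)
        series = (
            _stage("read")(read_trials)(config.trials) if config.trials else ()
        )
        report = _stage("analyze")(analyze)(data, series, config.thresholds)

        def _emit(name: str, frame: pd.DataFrame) -> None:
            path = outdir / name
            frame.to_csv(path, index=False)
            written[name] = path

        _emit("parameters.csv", report)
        rounded = report.copy()
        num_cols = rounded.select_dtypes(include=[float]).columns
        rounded[num_cols] = rounded[num_cols].round(2)
        _emit("parameters_2dp.csv", rounded)
        _emit("ci_distribution.csv", _cumulative_table(report["confidence_interval"]))
        _emit(
            "learning_distribution.csv",
            _cumulative_table(report["learning_effect"]),
        )
        _emit("icc_distribution.csv", _cumulative_table(report["icc_consistency"]))

        dropped_total = sum(data.n_dropped.values())
        manifest = {
            "retestkit_version": _version,
            "seed": config.seed,
            "assessments": config.assessments,
            "trials": config.trials or "",
            "n_parameters": len(report),
            "n_participants_dropped": dropped_total,
            "ci_multiplier": config.thresholds.ci_multiplier,
            "diff_outlier_threshold": config.thresholds.diff_outlier_threshold,
            "z_outlier_threshold": config.thresholds.z_outlier_threshold,
            "alpha": config.thresholds.alpha,
            "icc_formula": config.thresholds.icc_formula,
        }
        path = outdir / "run_manifest.txt"
        write_key_values(manifest, path)
        written["run_manifest.txt"] = path
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
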