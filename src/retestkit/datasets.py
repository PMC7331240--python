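"""Published reference values bundled for examples and cross-checks.

``ZTASK_SCORE_SUMMARY`` transcribes the published per-task retest summary
for the Z-Task Scores of the Kinarm Standard Test battery (11 task-arm
combinations, ~56 healthy adults assessed twice within 15 days): outliers
removed, significant change (SC), assessment confidence interval (CI),
learning effect with its paired-test p-value, and consistency ICC.  Tasks
ending in -D / -ND are dominant / non-dominant arm variants.  Values are
as printed (2 decimals); p-values below 1e-4 are stored as 1e-4.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ztask_score_summary"]

_ROWS = [
    # task, outliers_removed, significant_change, confidence_interval,
    # learning_effect, le_p_value, icc_consistency
    ("BOB", 0, 1.33, 0.94, -0.26, 0.017, 0.55),
    ("OH", 0, 1.65, 1.17, -0.18, 0.15, 0.49),
    ("OHA", 0, 1.42, 1.01, 0.27, 0.018, 0.64),
    ("PM-D", 1, 1.82, 1.28, -0.01, 0.95, 0.29),
    ("PM-ND", 0, 1.72, 1.21, -0.01, 0.94, 0.36),
    ("RVGR-D", 0, 1.34, 0.95, -0.78, 1e-4, 0.70),
    ("RVGR-ND", 0, 1.79, 1.27, -0.67, 1e-4, 0.67),
    ("SPS", 0, 1.48, 1.04, -0.39, 0.0024, 0.56),
    ("TMT", 0, 0.87, 0.61, -0.23, 0.0021, 0.75),
    ("VGR-D", 1, 1.05, 0.74, -0.07, 0.44, 0.30),
    ("VGR-ND", 0, 2.19, 1.55, -0.17, 0.31, 0.33),
]

_COLUMNS = [
    "task",
    "outliers_removed",
    "significant_change",
    "confidence_interval",
    "learning_effect",
    "le_p_value",
    "icc_consistency",
]


def ztask_score_summary() -> pd.DataFrame:
    """The published Z-Task-Score retest summary as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
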