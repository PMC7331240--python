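"""Readers and writers for long-format assessment tables (delimited text).

Assessment files are comma-separated UTF-8 with a header row and columns
``participant, session, task, parameter, value`` (sessions coded 1 and 2);
trial files add a ``trial`` column.  Ground truth and run manifests are
flat ``key = value`` text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datagen import SyntheticDataset
from .reliability import ParameterSpec, PairedObservations
from .trials import TrialSeries

__all__ = [
    "AssessmentData",
    "read_assessments",
    "write_assessments",
    "read_trials",
    "write_trials",
    "write_key_values",
    "read_key_values",
]

log = logging.getLogger("retestkit")

_ASSESSMENT_COLUMNS = ["participant", "session", "task", "parameter", "value"]
_TRIAL_COLUMNS = _ASSESSMENT_COLUMNS[:4] + ["trial", "value"]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True)
class AssessmentData:
    """Paired observations per parameter, with exclusion bookkeeping.

    ``n_dropped`` counts participants excluded per parameter because they
    were missing one of the two sessions; n_input = n_pairs + n_dropped
    for every parameter.
    """

    pairs: dict[str, PairedObservations]
    n_dropped: dict[str, int]

    def __iter__(self):
        return iter(self.pairs.items())


def _validate_frame(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    df = df[columns].copy()
    sessions = set(pd.unique(df["session"]))
    if not sessions <= {1, 2}:
        raise FormatError(
            f"session codes must be 1 or 2, found {sorted(sessions - {1, 2})}"
        )
    return df


def read_assessments(path_or_frame) -> AssessmentData:
    """Read a long-format assessment table into paired observations.

    Accepts a path to a CSV file or an in-memory DataFrame.  Participants
    missing either session for a parameter are dropped (with a logged,
    returned count); duplicate (participant, session, parameter) rows are
    a format error.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, float_precision="round_trip")
    df = _validate_frame(df, _ASSESSMENT_COLUMNS)
    dup = df.duplicated(subset=["participant", "session", "parameter"])
    if dup.any():
        rows = df.loc[dup, ["participant", "session", "parameter"]]
        raise FormatError(
            f"duplicate (participant, session, parameter) rows, e.g. "
            f"{rows.iloc[0].tolist()}"
        )
    pairs: dict[str, PairedObservations] = {}
    n_dropped: dict[str, int] = {}
    for (task, name), sub in df.groupby(["task", "parameter"], sort=False):
        wide = sub.pivot(index="participant", columns="session", values="value")
        for s in (1, 2):
            if s not in wide.columns:
                wide[s] = np.nan
        complete = wide.dropna(subset=[1, 2])
        dropped = len(wide) - len(complete)
        n_dropped[name] = dropped
        if dropped:
            log.info(
                "parameter %s: dropped %d participant(s) missing a session",
                name,
                dropped,
            )
        pairs[name] = PairedObservations(
            parameter=ParameterSpec(name=str(name), task=str(task)),
            participant_ids=tuple(complete.index),
            session1=complete[1].to_numpy(),
            session2=complete[2].to_numpy(),
        )
    return AssessmentData(pairs=pairs, n_dropped=n_dropped)


def write_assessments(data, path) -> None:
    """Write a long-format assessment table.

    Accepts a :class:`~retestkit.datagen.SyntheticDataset`, a long-format
    DataFrame, or a mapping of parameter name -> PairedObservations.
    """
    if isinstance(data, SyntheticDataset):
        frame = data.assessments
    elif isinstance(data, pd.DataFrame):
        frame = data
    elif isinstance(data, Mapping):
        rows = []
        for name, pairs in data.items():
            for pid, v1, v2 in zip(
                pairs.participant_ids, pairs.session1, pairs.session2
            ):
                for session, v in ((1, v1), (2, v2)):
                    rows.append(
                        (pid, session, pairs.parameter.task, name, float(v))
                    )
        frame = pd.DataFrame(rows, columns=_ASSESSMENT_COLUMNS)
    else:
        raise TypeError(f"cannot write assessments from {type(data)!r}")
    # %.17g keeps doubles bit-exact across a write -> read round trip
    frame[_ASSESSMENT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_trials(path_or_frame) -> list[TrialSeries]:
    """Read a long-format trial table into per-series objects."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, float_precision="round_trip")
    df = _validate_frame(df, _TRIAL_COLUMNS)
    series = []
    for (pid, session, name), sub in df.groupby(
        ["participant", "session", "parameter"], sort=False
    ):
        sub = sub.sort_values("trial")
        if sub["trial"].duplicated().any():
            raise FormatError(
                f"duplicate trial index for {pid}/{name}/session {session}"
            )
        series.append(
            TrialSeries(
                participant=str(pid),
                session=int(session),
                parameter=str(name),
                values=sub["value"].to_numpy(),
            )
        )
    return series


def write_trials(data, path) -> None:
    """Write a long-format trial table from a SyntheticDataset or DataFrame."""
    if isinstance(data, SyntheticDataset):
        if data.trials is None:
            raise ValueError("dataset has no trial-level data")
        frame = data.trials
    elif isinstance(data, pd.DataFrame):
        frame = data
    else:
        raise TypeError(f"cannot write trials from {type(data)!r}")
    frame[_TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def write_key_values(mapping: Mapping[str, object], path) -> None:
    """Write a flat key-value sidecar (one ``key = value`` pair per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in mapping:
            fh.write(f"{key} = {mapping[key]}\n")


def read_key_values(path) -> dict[str, str]:
    """Read a flat key-value file; values are returned as strings."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
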