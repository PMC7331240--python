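"""Synthetic paired-assessment generator.

Produces datasets with the statistical structure the reliability analysis
assumes, with known ground truth, so every downstream stage can be tested
against closed-form expectations.  For participant i, parameter p and
session j in {1, 2} the generated Z-score is

    x_ijp = s_ip + shift_p * 1[j = 2] + e_ijp

with subject ability s_ip ~ N(0, sigma_subject^2) (drawn once per
participant-parameter, shared by both sessions), session measurement error
e_ijp ~ N(0, sigma_error^2) independent across sessions, and a fixed
learning shift at session 2.  With probability ``outlier_rate`` an
observation additionally receives +/- ``outlier_magnitude`` (random sign).
If a parameter has trial-level data, trial t yields

    y_ijpt = x_ijp + tau_ijpt,   tau ~ N(0, sigma_trial^2).

Closed-form consequences used by the tests:

* Var(x_1) = sigma_subject^2 + sigma_error^2,
* SD(x_2 - x_1) = sqrt(2) * sigma_error,
* consistency ICC -> sigma_subject^2 / (sigma_subject^2 + sigma_error^2),
* per-session SEM of the trial mean -> sigma_trial / sqrt(n_trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reliability import ParameterSpec, PairedObservations

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_paired_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration of the paired-assessment generator.

    All SDs are in Z-units.  ``learning_shift`` is the additive session-2
    offset, either one signed value applied to every parameter or a
    mapping from parameter name to shift (parameters absent from the
    mapping get 0); negative means better (lower) scores at retest.
    """

    n_participants: int
    parameters: Sequence[ParameterSpec]
    sigma_subject: float = 1.0
    sigma_error: float = 0.5
    learning_shift: float | Mapping[str, float] = 0.0
    sigma_trial: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.parameters:
            raise ValueError("at least one ParameterSpec is required")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        for name in ("sigma_subject", "sigma_error", "sigma_trial"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if not np.isfinite(self.outlier_magnitude) or self.outlier_magnitude < 0:
            raise ValueError("outlier_magnitude must be finite and >= 0")
        shifts = self.learning_shift
        if isinstance(shifts, Mapping):
            bad = [v for v in shifts.values() if not np.isfinite(v)]
        else:
            bad = [] if np.isfinite(shifts) else [shifts]
        if bad:
            raise ValueError("learning_shift values must be finite")

    def shift_for(self, parameter: str) -> float:
        if isinstance(self.learning_shift, Mapping):
            return float(self.learning_shift.get(parameter, 0.0))
        return float(self.learning_shift)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated paired data plus the ground truth that produced it."""

    assessments: pd.DataFrame  # participant, session, task, parameter, value
    trials: pd.DataFrame | None  # + trial column; None if no trial-level data
    truth: dict

    def parameter_names(self) -> list[str]:
        return list(dict.fromkeys(self.assessments["parameter"]))

    def paired(self, parameter: str) -> PairedObservations:
        """Aligned session-1/session-2 observations for one parameter."""
        sub = self.assessments[self.assessments["parameter"] == parameter]
        if sub.empty:
            raise KeyError(f"unknown parameter {parameter!r}")
        wide = sub.pivot(index="participant", columns="session", values="value")
        spec = self.truth["parameters"][parameter]
        return PairedObservations(
            parameter=spec,
            participant_ids=tuple(wide.index),
            session1=wide[1].to_numpy(),
            session2=wide[2].to_numpy(),
        )

    def paired_all(self) -> dict[str, PairedObservations]:
        return {name: self.paired(name) for name in self.parameter_names()}


def generate_paired_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one paired-assessment dataset from the generative model.

    Returns long-format assessment rows (one per participant, session and
    parameter), optional long-format trial rows for parameters with
    ``n_trials > 0``, and a ``truth`` dict recording the generating
    sigma_subject, sigma_error, per-parameter learning shift, sigma_trial
    and the injected outlier positions.  Identical config (including seed)
    gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    participants = [f"P{i:04d}" for i in range(1, n + 1)]

    rows: list[dict] = []
    trial_rows: list[dict] = []
    n_outliers = 0

    for spec in config.parameters:
        shift = config.shift_for(spec.name)
        ability = rng.normal(0.0, config.sigma_subject, size=n)
        for session in (1, 2):
            err = rng.normal(0.0, config.sigma_error, size=n)
            x = ability + err + (shift if session == 2 else 0.0)
            is_out = rng.random(n) < config.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=n)
            x = x + is_out * signs * config.outlier_magnitude
            n_outliers += int(is_out.sum())
            for pid, val in zip(participants, x):
                rows.append(
                    {
                        "participant": pid,
                        "session": session,
                        "task": spec.task,
                        "parameter": spec.name,
                        "value": float(val),
                    }
                )
            if spec.n_trials > 0:
                tau = rng.normal(
                    0.0, config.sigma_trial, size=(n, spec.n_trials)
                )
                y = x[:, None] + tau
                for i, pid in enumerate(participants):
                    for t in range(spec.n_trials):
                        trial_rows.append(
                            {
                                "participant": pid,
                                "session": session,
                                "task": spec.task,
                                "parameter": spec.name,
                                "trial": t + 1,
                                "value": float(y[i, t]),
                            }
                        )

    assessments = pd.DataFrame(
        rows, columns=["participant", "session", "task", "parameter", "value"]
    )
    trials = (
        pd.DataFrame(
            trial_rows,
            columns=["participant", "session", "task", "parameter", "trial", "value"],
        )
        if trial_rows
        else None
    )
    truth = {
        "sigma_subject": config.sigma_subject,
        "sigma_error": config.sigma_error,
        "sigma_trial": config.sigma_trial,
        "learning_shift": {
            p.name: config.shift_for(p.name) for p in config.parameters
        },
        "outlier_rate": config.outlier_rate,
        "outlier_magnitude": config.outlier_magnitude,
        "n_outliers_injected": n_outliers,
        "seed": config.seed,
        "parameters": {p.name: p for p in config.parameters},
    }
    return SyntheticDataset(assessments=assessments, trials=trials, truth=truth)
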