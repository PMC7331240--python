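"""Generate a synthetic retest cohort and run the full analysis pipeline.

Builds a cohort of 56 participants assessed twice on four parameters (one
with 20 trials per session), with known between-subject spread, session
error and a learning shift on one parameter, then prints the per-parameter
report: significant-change threshold (SC), confidence interval (CI),
learning effect with FDR-corrected significance, consistency ICC, and the
within-session (IS) error for the trial-bearing parameter.
"""

import tempfile
from pathlib import Path

import pandas as pd

import retestkit as rk

params = [
    rk.ParameterSpec(name="reaction_time", task="VGR", sidedness="one_sided",
                     n_trials=20),
    rk.ParameterSpec(name="path_length_ratio", task="VGR", sidedness="one_sided"),
    rk.ParameterSpec(name="movement_time", task="RVGR", sidedness="one_sided"),
    rk.ParameterSpec(name="hand_bias", task="OH", sidedness="two_sided"),
]
config = rk.GeneratorConfig(
    n_participants=56,
    parameters=params,
    sigma_subject=1.0,       # between-participant ability spread (Z-units)
    sigma_error=0.55,        # session-to-session measurement error
    learning_shift={"movement_time": -0.6},  # practice effect on one task
    sigma_trial=0.3,
    seed=7,
)
dataset = rk.generate_paired_dataset(config)

workdir = Path(tempfile.mkdtemp())
rk.write_assessments(dataset, workdir / "assessments.csv")
rk.write_trials(dataset, workdir / "trials.csv")

written = rk.run_pipeline(
    rk.RunConfig(
        assessments=workdir / "assessments.csv",
        trials=workdir / "trials.csv",
        output_dir=workdir / "report",
    )
)
report = pd.read_csv(written["parameters_2dp.csv"])
print(report.to_string(index=False))
print()
print(
    "A difference between two assessments must exceed SC "
    "(= sqrt(2) x 1.64 x SD_diff) to be a real change; with sigma_error "
    "0.55 that is ~1.8 Z-units.  Only movement_time shows an FDR-significant "
    "learning effect — the injected practice shift, estimated within "
    "sampling error at n = 56 — and the IS error of reaction_time is a "
    "small fraction of its SC."
)
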