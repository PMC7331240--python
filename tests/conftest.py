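import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import retestkit as rk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_dataset():
    """A modest synthetic cohort: 60 participants, 3 parameters, one with trials."""
    params = [
        rk.ParameterSpec(name="reaction_time", task="VGR", sidedness="one_sided",
                         n_trials=20),
        rk.ParameterSpec(name="path_length", task="VGR", sidedness="one_sided"),
        rk.ParameterSpec(name="hand_bias", task="OH", sidedness="two_sided"),
    ]
    cfg = rk.GeneratorConfig(
        n_participants=60,
        parameters=params,
        sigma_subject=1.0,
        sigma_error=0.6,
        learning_shift=-0.2,
        sigma_trial=0.3,
        seed=42,
    )
    return rk.generate_paired_dataset(cfg)


def paired_from_diffs(diffs, base=None):
    """Build PairedObservations whose session2 - session1 equal ``diffs``."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    s1 = np.zeros(n) if base is None else np.asarray(base, dtype=float)
    return rk.PairedObservations(
        parameter=rk.ParameterSpec(name="p", task="t"),
        participant_ids=tuple(f"P{i}" for i in range(n)),
        session1=s1,
        session2=s1 + diffs,
    )
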