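import numpy as np
import pandas as pd
import pytest

from facelearn.synth import ArtifactRates, GeneratorConfig, generate_dataset
from facelearn.task import generate_schedule


@pytest.fixture(scope="session")
def clean_rl_dataset():
    """Small artifact-free cohort generated from the copy-bias model."""
    cfg = GeneratorConfig(
        n_participants=12,
        seed=101,
        artifact_rates=ArtifactRates(p_fast_noncompliance=0.0, p_no_response=0.0),
    )
    return generate_dataset(cfg, mode="rl_choices")


@pytest.fixture(scope="session")
def labelled_dataset():
    """Cohort with injected artifacts and ground-truth labels."""
    cfg = GeneratorConfig(n_participants=10, seed=202)
    return generate_dataset(cfg, mode="rl_choices")


@pytest.fixture(scope="session")
def schedule96():
    return generate_schedule(seed=42)


def make_records(rts_ms, responses=None, correct=None):
    """Minimal record frame for filter tests (single participant)."""
    n = len(rts_ms)
    if responses is None:
        responses = ["smile" if r == r else None for r in rts_ms]  # NaN -> None
    if correct is None:
        correct = [1] * n
    return pd.DataFrame(
        {
            "participant_id": ["p1"] * n,
            "trial_index": range(1, n + 1),
            "block": [1 if i < n / 2 else 2 for i in range(n)],
            "interactant": [1 + i % 2 for i in range(n)],
            "target_expression": ["smile"] * n,
            "condition": ["congruent"] * n,
            "correct_response": ["smile"] * n,
            "response": responses,
            "rt_ms": rts_ms,
            "shock": [1 - c for c in correct],
            "correct": correct,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
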