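"""Shared fixtures: small synthetic protocols and pre-decomposed recordings.

Cohort-level fixtures are session-scoped because the convex decomposition
dominates runtime; unit tests share one decomposed recording.
"""

import numpy as np
import pandas as pd
import pytest

from edascreen import decomp, featureset, sigproc, synthcohort


@pytest.fixture(scope="session")
def small_protocol() -> synthcohort.ProtocolSpec:
    """Five 60-s phases at a 32 Hz native rate: fast but structurally complete."""
    return synthcohort.ProtocolSpec(phase_duration_s=60.0, sampling_rate_hz=32.0)


@pytest.fixture(scope="session")
def small_policy() -> featureset.WindowPolicy:
    """Window policy scaled to the 60-s phases (same placements, 30-s windows)."""
    return featureset.WindowPolicy(window_length_s=30.0)


@pytest.fixture(scope="session")
def noiseless_fx() -> synthcohort.GroupEffectSpec:
    return synthcohort.GroupEffectSpec(
        noise_sd=0.0, tonic_drift_sd=0.0, scr_rate_per_min=2.0, reactivity_gain=1.5
    )


@pytest.fixture(scope="session")
def decomposed_small(small_protocol, noiseless_fx):
    """One noiseless recording: raw, preprocessed to 8 Hz, and decomposed."""
    rec, truth = synthcohort.synthesize_recording(small_protocol, noiseless_fx, seed=3)
    pre = sigproc.preprocess(rec, sigproc.FilterSpec(target_rate_hz=8.0))
    result = decomp.decompose(pre.samples, 8.0)
    return rec, truth, pre, result


def random_feature_table(
    n_per_group: int = 40,
    informative: dict[int, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A feature table of Gaussian noise with optional informative columns
    (column index -> mean shift added to the case group)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.normal(size=(n, len(featureset.FEATURE_COLUMNS)))
    y = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    for col, shift in (informative or {}).items():
        X[y == 1, col] += shift
    table = pd.DataFrame(X, columns=featureset.FEATURE_COLUMNS)
    table.insert(0, "group", np.where(y == 1, "case", "control"))
    table.insert(0, "subject_id", [f"s{i:03d}" for i in range(n)])
    return table


@pytest.fixture()
def feature_table_factory():
    return random_feature_table
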