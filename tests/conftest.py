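import numpy as np
import pytest

from eegmicrostates import (
    CohortSpec,
    MicrostateModel,
    default_ground_truth,
    generate_state_sequence,
    synthesize_eeg,
)


@pytest.fixture(scope="session")
def truth():
    """Default ground truth at the standard study conditions (snr=5)."""
    return default_ground_truth(seed=3, snr=5.0)


@pytest.fixture(scope="session")
def truth_noiseless():
    return default_ground_truth(seed=3, snr=np.inf)


@pytest.fixture(scope="session")
def true_model(truth):
    """A microstate model holding the generating topographies, labelled A-D."""
    return MicrostateModel(
        maps=truth.topographies, k=4, archetype_labels=("A", "B", "C", "D")
    )


def make_recording(truth, n_samples=10_000, rate_hz=500.0, seq_seed=11, eeg_seed=12, **meta):
    labels = generate_state_sequence(truth, n_samples, rate_hz, seed=seq_seed)
    rec = synthesize_eeg(truth, labels, seed=eeg_seed, **meta)
    return rec, labels


@pytest.fixture(scope="session")
def small_cohort_spec(truth):
    """A scaled-down two-group cohort (30 s per condition per subject)."""
    return CohortSpec(
        truth=truth, n_good=3, n_poor=2, rest_length_s=30.0, task_length_s=30.0
    )
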