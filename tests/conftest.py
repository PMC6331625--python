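import numpy as np
import pandas as pd
import pytest

from eegreversal.containers import EpochSet


def make_epochs(
    n_trials=12,
    n_channels=4,
    n_times=16,
    sample_rate=256.0,
    t_start=0.0,
    seed=0,
    participants=1,
    rt_ms=3500.0,
    data=None,
):
    """Small white-noise EpochSet with crossed, balanced labels."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_times))
    n_trials = data.shape[0]
    step = 1000.0 / sample_rate
    times = t_start + step * np.arange(data.shape[2])
    cells = [
        ("photograph", "animate"),
        ("photograph", "inanimate"),
        ("drawing", "animate"),
        ("drawing", "inanimate"),
    ]
    rows = [cells[i % 4] for i in range(n_trials)]
    per_participant = n_trials // participants
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials) % max(per_participant, 1),
            "participant_id": [
                f"P{min(i // max(per_participant, 1), participants - 1) + 1:02d}"
                for i in range(n_trials)
            ],
            "perceptual_label": [r[0] for r in rows],
            "semantic_label": [r[1] for r in rows],
            "rt_ms": rt_ms,
            "correct": 1,
            "lock": "stimulus_onset",
        }
    )
    positions = np.column_stack(
        [np.cos(np.linspace(0, 2 * np.pi, data.shape[1], endpoint=False)),
         np.sin(np.linspace(0, 2 * np.pi, data.shape[1], endpoint=False))]
    )
    return EpochSet(
        data=data,
        times=times,
        channel_labels=[f"CH{i:03d}" for i in range(data.shape[1])],
        channel_positions=positions,
        trials=trials,
    )


@pytest.fixture
def small_epochs():
    return make_epochs()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
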