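import numpy as np
import pandas as pd
import pytest

from gazedecode import EpochSet, GeneratorConfig


def make_trials(stims, rotations=None, directions=None):
    """Minimal valid trial table for hand-built epochs."""
    n = len(stims)
    rotations = rotations if rotations is not None else [0.0] * n
    directions = directions if directions is not None else ["CW"] * n
    sign = np.where(np.char.upper(np.asarray(directions, dtype=str)) == "CW",
                    1.0, -1.0)
    stims = np.asarray(stims, dtype=float)
    rotations = np.asarray(rotations, dtype=float)
    return pd.DataFrame({
        "trial": np.arange(n),
        "stimulus_orientation_deg": stims,
        "rotation_deg": rotations,
        "direction": directions,
        "target_orientation_deg": (stims + sign * rotations) % 180.0,
        "condition_label": ["toy"] * n,
        "block": [0] * n,
    })


def make_epochs(data, sfreq=50.0, t0=-0.3, stims=None):
    data = np.asarray(data, dtype=float)
    n, f, t = data.shape
    times = t0 + np.arange(t) / sfreq
    if stims is None:
        stims = np.resize([15.0, 75.0, 135.0], n)
    return EpochSet(data=data, times=times,
                    feature_labels=[f"ch{i}" for i in range(f)],
                    trials=make_trials(stims))


@pytest.fixture
def toy_epochs():
    rng = np.random.default_rng(0)
    return make_epochs(rng.standard_normal((6, 3, 40)))


@pytest.fixture
def tiny_cfg():
    """Small, fast generator configuration used across tests."""
    return GeneratorConfig(n_subjects=2, n_blocks=2, n_sensors=16,
                           sample_rate_hz=40.0, delay_s=2.0,
                           localizer_trials_per_orientation=20, seed=7)
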