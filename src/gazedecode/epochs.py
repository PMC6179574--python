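"""Core in-memory containers for epoched MEG-like and gaze data.

An :class:`EpochSet` is a dense ``(n_trials, n_features, n_times)`` block with
a shared, uniformly sampled time axis (seconds relative to stimulus onset),
feature labels (sensor names, or ``gaze_x``/``gaze_y`` in degrees visual
angle), and a per-trial metadata table.  The trial table uses a fixed column
order so that its on-disk TSV form is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "TRIAL_COLUMNS", "validate_trial_table"]

#: Fixed column order of the trial table (and of its TSV serialization).
TRIAL_COLUMNS = [
    "trial",
    "stimulus_orientation_deg",
    "rotation_deg",
    "direction",
    "target_orientation_deg",
    "condition_label",
    "block",
]

_DIRECTION_SIGN = {"CW": +1.0, "CCW": -1.0}


def _normalize_direction(value) -> str:
    """Map case-insensitive 'cw'/'ccw' onto canonical 'CW'/'CCW'."""
    s = str(value).strip().upper()
    if s not in _DIRECTION_SIGN:
        raise ValueError(f"invalid rotation direction {value!r}; expected CW or CCW")
    return s


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table.

    Checks column presence, orientation ranges, and the defining relation
    ``target = (stimulus + sign * rotation) mod 180`` with the sign given by
    the rotation direction (CW positive, CCW negative; degrees are measured
    clockwise from vertical).  Directions are normalized to upper case.

    Returns a normalized copy with columns in :data:`TRIAL_COLUMNS` order.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = trials.loc[:, TRIAL_COLUMNS].copy()
    t["direction"] = t["direction"].map(_normalize_direction)

    for col in ("stimulus_orientation_deg", "target_orientation_deg"):
        vals = np.asarray(t[col], dtype=float)
        if not np.all((vals >= 0.0) & (vals < 180.0)):
            raise ValueError(f"{col} must lie in [0, 180)")
    rot = np.asarray(t["rotation_deg"], dtype=float)
    if not np.all((rot >= 0.0) & (rot <= 180.0)):
        raise ValueError("rotation_deg must lie in [0, 180]")

    sign = t["direction"].map(_DIRECTION_SIGN).to_numpy()
    stim = np.asarray(t["stimulus_orientation_deg"], dtype=float)
    target = np.asarray(t["target_orientation_deg"], dtype=float)
    expected = (stim + sign * rot) % 180.0
    if not np.allclose(target, expected, atol=1e-9):
        bad = int(np.argmax(~np.isclose(target, expected, atol=1e-9)))
        raise ValueError(
            "target_orientation_deg inconsistent with stimulus/rotation/direction "
            f"at row {bad}: got {target[bad]}, expected {expected[bad]}"
        )
    return t.reset_index(drop=True)


@dataclass
class EpochSet:
    """Epoched multivariate time series plus trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_features, n_times)
        Signal block.  MEG features are in arbitrary consistent units; gaze
        features are degrees visual angle from screen center (x rightward,
        y upward).
    times : ndarray, shape (n_times,)
        Seconds relative to stimulus onset; strictly increasing, uniform step.
    feature_labels : list of str
    trials : DataFrame
        One row per trial with columns :data:`TRIAL_COLUMNS`.
    """

    data: np.ndarray
    times: np.ndarray
    feature_labels: list = field(default_factory=list)
    trials: pd.DataFrame = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.feature_labels = [str(s) for s in self.feature_labels]
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D [trial, feature, time]")
        self.trials = validate_trial_table(self.trials)
        n_tr, n_feat, n_t = self.data.shape
        if len(self.trials) != n_tr:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but data has {n_tr} trials"
            )
        if len(self.feature_labels) != n_feat:
            raise ValueError(
                f"{len(self.feature_labels)} feature labels for {n_feat} features"
            )
        if self.times.shape != (n_t,):
            raise ValueError("times length does not match data time axis")
        if n_t > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly sampled")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")

    # -- convenience -------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz."""
        if self.n_times < 2:
            raise ValueError("sampling rate undefined for a single sample")
        return 1.0 / (self.times[1] - self.times[0])

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            feature_labels=list(self.feature_labels),
            trials=self.trials.copy(),
        )

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1 (closed interval)."""
        return (self.times >= t0) & (self.times <= t1)

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times.copy(),
            feature_labels=list(self.feature_labels),
            trials=self.trials.loc[mask].reset_index(drop=True),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.times, other.times)
            and self.feature_labels == other.feature_labels
            and self.trials.equals(other.trials)
        )
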