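"""Synthetic MEG + gaze generator with an eye-movement confound.

The generator emulates a combined visual-working-memory / mental-rotation
(VWM/MR) experiment: on each trial a cue (417 ms) and blank (417 ms) precede
a grating (217 ms, orientation 15/75/135 deg) that must be held in mind —
and in the MR conditions mentally rotated by 60/120/180 deg clockwise or
counterclockwise at 30 deg/s — across a long blank delay, terminated by a
probe.  A separate functional localizer presents six orientations
(15..165 deg in steps of 30) for 250 ms each, 120 trials per orientation,
with attention held at fixation.

Three ingredients are simulated per subject:

* a *neural* orientation code: a fixed random sensor mapping ``A`` (two
  orthonormal columns) carrying the doubled-angle tuning
  ``pattern(alpha) = A [cos 2a, sin 2a]``, active transiently after stimulus
  onset and, optionally (``neural_sustained_gain``), throughout the delay
  following the current mental orientation;
* a *gaze confound*: from ~0.3 s after the stimulus the gaze drifts from
  fixation to a point on the remembered grating's orientation axis (subject-
  specific amplitude, ~0.05-1.5 deg visual angle, and a subject-specific
  axis end), tracks the mental rotation at 30 deg/s but saturates at
  +/-60 deg from the starting orientation, and holds until the probe;
* an *eyeball-dipole artifact*: the latent gaze position leaks into the
  sensors through a frontal-weighted mixing matrix ``G``.  By default ``G``
  is orthogonalized against the neural mapping (in both the plain and the
  noise-whitened metric), so decoders trained on confound-free localizer
  data are blind to the artifact by construction; set
  ``dipole_orthogonal=False`` for overlapping subspaces.

Sensor noise is multivariate Gaussian with exponential spatial correlation
and is white in time.  The localizer contains the transient neural response
only — same mapping ``A`` — and its gaze channel is pure tracker noise, so
localizer-trained decoders generalize to genuine neural signal but not to
the dipole artifact.  Everything is a deterministic function of
``(seed, subject)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, orth

from .angles import to_doubled_radians
from .epochs import TRIAL_COLUMNS, EpochSet

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "STIMULUS_ORIENTATIONS",
    "LOCALIZER_ORIENTATIONS",
    "orientation_pattern",
    "generate_task_data",
    "generate_localizer_data",
]

STIMULUS_ORIENTATIONS = (15.0, 75.0, 135.0)
LOCALIZER_ORIENTATIONS = tuple(15.0 + 30.0 * k for k in range(6))
ROTATIONS = (0.0, 60.0, 120.0, 180.0)
DIRECTIONS = ("CW", "CCW")

STIMULUS_DURATION_S = 0.217
LOCALIZER_STIMULUS_S = 0.25
TASK_EPOCH_START_S = -1.05       # covers the -200..0 ms pre-cue gaze baseline
TASK_EPOCH_TAIL_S = 0.2          # kept after probe onset
LOCALIZER_EPOCH = (-0.2, 0.75)
TRANSIENT_WINDOW_S = (0.0, 0.5)  # transient evoked response support
DRIFT_RAMP_S = 0.2               # gaze travel time from fixation to target


@dataclass
class GeneratorConfig:
    """Study conditions of the simulated experiment.

    Defaults are a scaled stand-in for the recorded study: 64 sensors for
    275, 120 Hz for 1200 Hz, the original 8.017 s delay (shorten via
    ``delay_s`` for quick runs), 3 trials per design cell x 8 cells x 6
    blocks = 144 task trials, and 120 localizer trials per orientation.
    ``neural_sustained_gain=0`` with ``eye_dipole_gain>0`` is the
    "confound-only" world in which all delay-period decodability stems from
    eye movements.
    """

    n_subjects: int = 8
    n_trials_per_cell: int = 3
    n_blocks: int = 6
    n_sensors: int = 64
    sample_rate_hz: float = 120.0
    delay_s: float = 8.017
    neural_transient_gain: float = 1.0
    neural_sustained_gain: float = 0.0
    eye_dipole_gain: float = 2.0
    gaze_amplitude_deg: float | None = None   # None: per subject, ~0.05-1.5
    gaze_saturation_deg: float = 60.0
    rotation_speed_deg_per_s: float = 30.0
    rotation_onset_s: float = 0.5
    drift_onset_s: float = 0.3
    noise_spatial_corr: float = 0.3
    noise_sd: float = 1.0
    gaze_noise_sd_deg: float = 0.2
    localizer_trials_per_orientation: int = 120
    dipole_orthogonal: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("neural_transient_gain", "neural_sustained_gain",
                     "eye_dipole_gain", "noise_sd", "gaze_noise_sd_deg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("n_subjects", "n_trials_per_cell", "n_blocks",
                     "n_sensors", "localizer_trials_per_orientation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.noise_spatial_corr < 1.0:
            raise ValueError("noise_spatial_corr must lie in [0, 1)")
        if self.sample_rate_hz <= 0 or self.delay_s <= 0:
            raise ValueError("sample_rate_hz and delay_s must be positive")

    @property
    def probe_onset_s(self) -> float:
        return STIMULUS_DURATION_S + self.delay_s

    @property
    def n_task_trials(self) -> int:
        return self.n_trials_per_cell * len(ROTATIONS) * len(DIRECTIONS) \
            * self.n_blocks


@dataclass
class GroundTruth:
    """Latent quantities stored alongside the generated data for recovery tests."""

    gaze_latent: np.ndarray          # (n_trials, 2, n_times), deg visual angle
    mental_orientation: np.ndarray   # (n_trials, n_times), unwrapped degrees
    neural_mixing: np.ndarray        # A, (n_sensors, 2), orthonormal columns
    dipole_mixing: np.ndarray        # G, (n_sensors, 2), unit-norm columns
    axis_sign: int                   # which end of the orientation axis
    gaze_amplitude_deg: float
    noise_covariance: np.ndarray     # true sensor noise covariance


def orientation_pattern(orientation_deg: float, n_sensors: int,
                        subject_seed: int) -> np.ndarray:
    """Sensor pattern of the neural orientation code for one orientation.

    ``pattern(a) = A [cos 2a, sin 2a]`` with ``A`` the subject's fixed random
    orthonormal sensor mapping, so the pattern is smooth and 180-deg periodic
    in orientation and has unit norm for every orientation.
    """
    if not 0.0 <= orientation_deg < 180.0:
        raise ValueError("orientation must lie in [0, 180)")
    a = _neural_mixing(n_sensors, subject_seed)
    d = to_doubled_radians(orientation_deg)
    return a @ np.array([np.cos(d), np.sin(d)])


def _neural_mixing(n_sensors: int, subject_seed) -> np.ndarray:
    rng = np.random.default_rng(subject_seed)
    q, r = np.linalg.qr(rng.standard_normal((n_sensors, 2)))
    return q * np.sign(np.diag(r))   # orthonormal columns, sign-fixed


def _noise_covariance(cfg: GeneratorConfig) -> np.ndarray:
    idx = np.arange(cfg.n_sensors)
    r = cfg.noise_spatial_corr ** np.abs(idx[:, None] - idx[None, :])
    return cfg.noise_sd ** 2 * r


@dataclass
class _Subject:
    mixing: np.ndarray
    dipole: np.ndarray
    axis_sign: int
    amplitude: float
    sigma0: np.ndarray
    noise_chol: np.ndarray
    task_seed: np.random.SeedSequence
    localizer_seed: np.random.SeedSequence


def _subject_structures(cfg: GeneratorConfig, subject: int) -> _Subject:
    root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject,))
    mixing_ss, misc_ss, task_ss, loc_ss = root.spawn(4)
    a = _neural_mixing(cfg.n_sensors, mixing_ss)
    rng = np.random.default_rng(misc_ss)
    # frontal-weighted dipole mixing: large loadings on low sensor indices
    frontal = 0.2 + 2.8 / (1.0 + np.exp((np.arange(cfg.n_sensors)
                                         - cfg.n_sensors / 3.0)
                                        / (cfg.n_sensors / 12.0)))
    g = frontal[:, None] * rng.standard_normal((cfg.n_sensors, 2))
    sigma0 = _noise_covariance(cfg)
    if cfg.dipole_orthogonal:
        # blind both plain and noise-whitened projections on the neural code
        span = orth(np.hstack([a, np.linalg.solve(sigma0, a)]))
        g = g - span @ (span.T @ g)
    g = g / np.linalg.norm(g, axis=0, keepdims=True)
    axis_sign = 1 if rng.random() < 0.5 else -1
    if cfg.gaze_amplitude_deg is None:
        amplitude = float(np.exp(rng.uniform(np.log(0.05), np.log(1.5))))
    else:
        amplitude = float(cfg.gaze_amplitude_deg)
    return _Subject(mixing=a, dipole=g, axis_sign=axis_sign,
                    amplitude=amplitude, sigma0=sigma0,
                    noise_chol=cholesky(sigma0, lower=True),
                    task_seed=task_ss, localizer_seed=loc_ss)


def _task_trial_table(cfg: GeneratorConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for block in range(cfg.n_blocks):
        block_rows = []
        for rot, direction in product(ROTATIONS, DIRECTIONS):
            for i in range(cfg.n_trials_per_cell):
                stim = STIMULUS_ORIENTATIONS[i % len(STIMULUS_ORIENTATIONS)]
                sign = 1.0 if direction == "CW" else -1.0
                block_rows.append({
                    "stimulus_orientation_deg": stim,
                    "rotation_deg": rot,
                    "direction": direction,
                    "target_orientation_deg": (stim + sign * rot) % 180.0,
                    "condition_label": "VWM" if rot == 0 else f"MR{int(rot)}",
                    "block": block,
                })
        rng.shuffle(block_rows)          # pseudorandomized within block
        rows.extend(block_rows)
    table = pd.DataFrame(rows)
    table.insert(0, "trial", np.arange(len(table)))
    return table.loc[:, TRIAL_COLUMNS]


def _gaze_trajectories(cfg: GeneratorConfig, trials: pd.DataFrame,
                       times: np.ndarray, subj: _Subject):
    """Latent gaze (n, 2, T) and mental orientation (n, T), both noise-free."""
    n = len(trials)
    stim = trials["stimulus_orientation_deg"].to_numpy()[:, None]
    rot = trials["rotation_deg"].to_numpy()[:, None]
    sign = np.where(trials["direction"].to_numpy() == "CW", 1.0, -1.0)[:, None]
    t = times[None, :]
    progress = np.clip((t - cfg.rotation_onset_s) * cfg.rotation_speed_deg_per_s,
                       0.0, rot)
    mental = stim + sign * progress                       # unwrapped degrees
    tracked = stim + sign * np.minimum(progress, cfg.gaze_saturation_deg)
    ramp = np.clip((t - cfg.drift_onset_s) / DRIFT_RAMP_S, 0.0, 1.0)
    ramp = np.broadcast_to(ramp, mental.shape)
    radius = subj.axis_sign * subj.amplitude * ramp
    ang = np.deg2rad(tracked)
    gaze = np.stack([radius * np.sin(ang), radius * np.cos(ang)], axis=1)
    return gaze, mental


def _doubled_basis(orientation_deg: np.ndarray) -> np.ndarray:
    d = to_doubled_radians(orientation_deg)
    return np.stack([np.cos(d), np.sin(d)])


def generate_task_data(cfg: GeneratorConfig, subject: int = 0):
    """Generate one subject's VWM/imagery task data.

    Returns ``(meg, gaze, ground_truth)``.  The epoch spans -1.05 s (before
    the cue at -0.834 s) to 200 ms after probe onset, at ``sample_rate_hz``.
    MEG = transient neural response to the presented grating (0-0.5 s)
    + optional sustained response following the mental orientation
    + eyeball-dipole leakage of the latent gaze + spatially correlated noise.
    """
    subj = _subject_structures(cfg, subject)
    rng = np.random.default_rng(subj.task_seed)
    trials = _task_trial_table(cfg, rng)
    n = len(trials)
    dt = 1.0 / cfg.sample_rate_hz
    t_end = cfg.probe_onset_s + TASK_EPOCH_TAIL_S
    times = np.arange(TASK_EPOCH_START_S, t_end + dt / 2, dt)

    gaze_latent, mental = _gaze_trajectories(cfg, trials, times, subj)

    transient_env = ((times >= TRANSIENT_WINDOW_S[0])
                     & (times <= TRANSIENT_WINDOW_S[1])).astype(float)
    sustained_env = ((times >= 0.0) & (times <= cfg.probe_onset_s)).astype(float)

    stim_basis = _doubled_basis(
        trials["stimulus_orientation_deg"].to_numpy())        # (2, n)
    meg = np.empty((n, cfg.n_sensors, len(times)))
    for k in range(n):
        signal = np.zeros((cfg.n_sensors, len(times)))
        if cfg.neural_transient_gain > 0:
            pat = subj.mixing @ stim_basis[:, k]
            signal += cfg.neural_transient_gain * np.outer(pat, transient_env)
        if cfg.neural_sustained_gain > 0:
            basis_t = _doubled_basis(mental[k])               # (2, T)
            signal += cfg.neural_sustained_gain \
                * (subj.mixing @ basis_t) * sustained_env[None, :]
        if cfg.eye_dipole_gain > 0:
            signal += cfg.eye_dipole_gain * (subj.dipole @ gaze_latent[k])
        noise = subj.noise_chol @ rng.standard_normal(
            (cfg.n_sensors, len(times)))
        meg[k] = signal + noise

    gaze_data = gaze_latent + cfg.gaze_noise_sd_deg * rng.standard_normal(
        gaze_latent.shape)

    sensor_labels = [f"MEG{i:03d}" for i in range(cfg.n_sensors)]
    meg_epochs = EpochSet(data=meg, times=times,
                          feature_labels=sensor_labels, trials=trials)
    gaze_epochs = EpochSet(data=gaze_data, times=times,
                           feature_labels=["gaze_x", "gaze_y"],
                           trials=trials.copy())
    gt = GroundTruth(gaze_latent=gaze_latent, mental_orientation=mental,
                     neural_mixing=subj.mixing, dipole_mixing=subj.dipole,
                     axis_sign=subj.axis_sign,
                     gaze_amplitude_deg=subj.amplitude,
                     noise_covariance=subj.sigma0)
    return meg_epochs, gaze_epochs, gt


def generate_localizer_data(cfg: GeneratorConfig, subject: int = 0):
    """Generate one subject's confound-free functional localizer data.

    Six orientations x ``localizer_trials_per_orientation`` trials; the MEG
    contains only the transient orientation-tuned response (same sensor
    mapping as the task) plus noise, and the gaze stays at fixation (tracker
    noise only), so localizer-trained decoders cannot inherit the eye
    confound.
    """
    subj = _subject_structures(cfg, subject)
    rng = np.random.default_rng(subj.localizer_seed)
    n_per = cfg.localizer_trials_per_orientation
    oris = np.repeat(LOCALIZER_ORIENTATIONS, n_per)
    rng.shuffle(oris)
    n = len(oris)
    trials = pd.DataFrame({
        "trial": np.arange(n),
        "stimulus_orientation_deg": oris,
        "rotation_deg": 0.0,
        "direction": "CW",
        "target_orientation_deg": oris,
        "condition_label": "localizer",
        "block": np.arange(n) * cfg.n_blocks // max(n, 1),
    })
    dt = 1.0 / cfg.sample_rate_hz
    times = np.arange(LOCALIZER_EPOCH[0], LOCALIZER_EPOCH[1] + dt / 2, dt)
    env = ((times >= 0.0) & (times <= LOCALIZER_STIMULUS_S + 0.05)).astype(float)

    basis = _doubled_basis(oris)                              # (2, n)
    patterns = subj.mixing @ basis                            # (F, n)
    meg = (cfg.neural_transient_gain
           * patterns.T[:, :, None] * env[None, None, :])
    noise = np.einsum(
        "fg,ngt->nft", subj.noise_chol,
        rng.standard_normal((n, cfg.n_sensors, len(times))))
    meg = meg + noise

    gaze = cfg.gaze_noise_sd_deg * rng.standard_normal((n, 2, len(times)))

    sensor_labels = [f"MEG{i:03d}" for i in range(cfg.n_sensors)]
    meg_epochs = EpochSet(data=meg, times=times,
                          feature_labels=sensor_labels, trials=trials)
    gaze_epochs = EpochSet(data=gaze, times=times,
                           feature_labels=["gaze_x", "gaze_y"],
                           trials=trials.copy())
    gt = GroundTruth(gaze_latent=np.zeros_like(gaze),
                     mental_orientation=np.broadcast_to(
                         oris[:, None], (n, len(times))).copy(),
                     neural_mixing=subj.mixing, dipole_mixing=subj.dipole,
                     axis_sign=subj.axis_sign,
                     gaze_amplitude_deg=subj.amplitude,
                     noise_covariance=subj.sigma0)
    return meg_epochs, gaze_epochs, gt
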