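"""Inverted (forward) encoding model for continuous orientation decoding.

The forward model posits 24 hypothetical orientation channels with von Mises
tuning curves (concentration kappa = 5) spaced equally around the doubled
orientation circle: a grating at orientation phi activates channel j by

    C_j(phi) = exp(kappa * (cos(2*phi - 2*mu_j) - 1)),

peak-normalized to 1 at the channel center ``mu_j``.  Channel patterns in
sensor space are estimated by least squares from training data; the model is
inverted with per-channel unit-gain spatial filters that take the correlated
noise structure of MEG data into account,

    w_j = Sigma^-1 p_j / (p_j' Sigma^-1 p_j),

where ``Sigma`` is the shrinkage-regularized residual covariance.  When
``Sigma`` is proportional to the identity this reduces to projection on the
patterns.  Decoded channel activities ``c = W x`` are collapsed to a single
orientation estimate via the activation-weighted circular mean, and decoding
performance across trials is summarized by the V-test statistic

    z = 1/N sum_k exp(i (2 theta_k - 2 phi_k)),   rho = |z| cos(arg z) = Re z,

the mean cosine of the doubled angular error: +1 for perfect decoding, 0 for
orthogonal (45 deg off) or unrelated orientations, -1 for counterphase
(90 deg off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .angles import from_doubled_radians, to_doubled_radians
from .classifier import TemporalGeneralizationMatrix, _shrunk_covariance
from .epochs import EpochSet

__all__ = [
    "EncodingBasis",
    "EncodingModel",
    "basis_responses",
    "fit_encoding_model",
    "decode_orientation",
    "rho",
    "rho_z",
    "rho_map",
    "localizer_decoded_orientations",
    "localizer_generalization",
]


@dataclass(frozen=True)
class EncodingBasis:
    """Equally spaced von Mises channel basis on the orientation circle."""

    n_channels: int = 24
    kappa: float = 5.0

    @property
    def centers_deg(self) -> np.ndarray:
        """Channel centers in orientation degrees, equally spaced in [0, 180)."""
        return 180.0 * np.arange(self.n_channels) / self.n_channels

    @property
    def centers_doubled_rad(self) -> np.ndarray:
        return to_doubled_radians(self.centers_deg)


@dataclass
class EncodingModel:
    """Fitted forward model: channel patterns, noise covariance, filters."""

    basis: EncodingBasis
    patterns: np.ndarray          # (F, J)
    noise_covariance: np.ndarray  # (F, F), shrinkage-regularized
    filters: np.ndarray           # (J, F); row j satisfies w_j' p_j = 1
    shrinkage: float


def basis_responses(basis: EncodingBasis, orientations_deg) -> np.ndarray:
    """Design matrix of channel responses, shape (n_trials, n_channels).

    Peak response is 1 at the channel center and ``exp(-2 kappa)`` for an
    orientation 90 deg away; periodic with 180 deg in orientation.
    """
    ori = np.asarray(orientations_deg, dtype=float)
    if np.any((ori < 0) | (ori >= 180.0)):
        raise ValueError("orientations must lie in [0, 180)")
    delta = to_doubled_radians(ori)[:, None] - basis.centers_doubled_rad[None, :]
    return np.exp(basis.kappa * (np.cos(delta) - 1.0))


def fit_encoding_model(X, orientations_deg, basis: EncodingBasis | None = None,
                       shrinkage: float = 0.05) -> EncodingModel:
    """Estimate channel patterns and noise-aware inverse filters.

    Patterns solve the least-squares regression of the sensor data on the
    channel design matrix (minimum-norm solution; with k distinct training
    orientations only a k-dimensional subspace of channel space is
    identifiable, which is expected and harmless for decoding).  The noise
    covariance comes from the regression residuals with shrinkage toward
    ``nu * I``, and each channel's spatial filter is the unit-gain
    noise-weighted inverse ``Sigma^-1 p_j / (p_j' Sigma^-1 p_j)``.
    """
    if basis is None:
        basis = EncodingBasis()
    X = np.asarray(X, dtype=float)
    ori = np.asarray(orientations_deg, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(ori):
        raise ValueError("X must be (n_trials, n_features) matching orientations")
    uniq, counts = np.unique(ori, return_counts=True)
    if len(uniq) < 3:
        raise ValueError(
            "need at least 3 distinct training orientations to identify a "
            "continuous orientation decoder; add orientations or trials"
        )
    if np.any(counts < 2):
        raise ValueError("every training orientation needs at least 2 trials")
    C = basis_responses(basis, ori)                      # (n, J)
    coef, _, rank, _ = np.linalg.lstsq(C, X, rcond=None)  # (J, F)
    patterns = coef.T                                    # (F, J)
    resid = X - C @ coef
    dof = max(X.shape[0] - rank, 1)
    sigma_raw = resid.T @ resid / dof
    sigma = _shrunk_covariance(sigma_raw[None], shrinkage)
    chol = cho_factor(sigma)
    sp = cho_solve(chol, patterns)                       # Sigma^-1 P, (F, J)
    gains = np.einsum("fj,fj->j", patterns, sp)          # p_j' Sigma^-1 p_j
    if np.any(gains <= 0):
        raise ValueError("degenerate channel pattern (zero noise-weighted norm)")
    filters = (sp / gains[None, :]).T                    # (J, F)
    return EncodingModel(basis=basis, patterns=patterns,
                         noise_covariance=sigma, filters=filters,
                         shrinkage=shrinkage)


def _channel_resultant(basis: EncodingBasis, c: np.ndarray) -> np.ndarray:
    """Complex resultant sum_j c_j exp(i mu_j) on the doubled circle."""
    return c @ np.exp(1j * basis.centers_doubled_rad)


def decode_orientation(model: EncodingModel, x):
    """Channel activities and orientation estimate for feature vector(s).

    ``x`` has shape ``(F,)`` or ``(..., F)``.  Returns ``(c, theta_deg)``;
    ``theta`` is the activation-weighted circular mean of the channel centers,
    mapped back from doubled space to [0, 180).  Trials whose channel
    resultant vector vanishes have no defined orientation and come back as
    NaN (they are excluded, with a count, from ``rho``).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.filters.shape[1]:
        raise ValueError("feature dimension does not match encoding model")
    c = x @ model.filters.T                              # (..., J)
    resultant = _channel_resultant(model.basis, c)
    theta = from_doubled_radians(np.angle(resultant))
    scale = np.abs(c).sum(axis=-1) + np.finfo(float).tiny
    theta = np.where(np.abs(resultant) / scale < 1e-12, np.nan, theta)
    return c, theta


def rho_z(theta_deg, phi_deg) -> complex:
    """Complex mean resultant of the doubled decoding errors.

    NaN decoded orientations (undefined circular mean) are dropped.
    """
    theta = np.asarray(theta_deg, dtype=float).ravel()
    phi = np.asarray(phi_deg, dtype=float).ravel()
    if theta.shape != phi.shape:
        raise ValueError("decoded and true orientations must have equal length")
    ok = ~np.isnan(theta)
    if not ok.any():
        raise ValueError("no defined decoded orientations")
    err = to_doubled_radians(theta[ok]) - to_doubled_radians(phi[ok])
    return complex(np.exp(1j * err).mean())


def rho(theta_deg, phi_deg) -> float:
    """V-test correspondence statistic ``|z| cos(arg z) = Re(z)`` in [-1, 1]."""
    return rho_z(theta_deg, phi_deg).real


def localizer_decoded_orientations(
    localizer: EpochSet,
    task: EpochSet,
    basis: EncodingBasis | None = None,
    shrinkage: float = 0.05,
    train_decim: int = 1,
    test_decim: int = 1,
):
    """Decode every task trial with models trained per localizer time point.

    Returns ``(train_times, test_times, theta)`` with ``theta`` of shape
    ``(n_task_trials, n_train, n_test)`` in degrees [0, 180) (NaN where the
    channel resultant vanishes).  Condition splits and alternative true-
    orientation references are then cheap re-reductions of this tensor.
    """
    if basis is None:
        basis = EncodingBasis()
    if localizer.feature_labels != task.feature_labels:
        raise ValueError("localizer and task feature spaces differ")
    loc_ori = localizer.trials["stimulus_orientation_deg"].to_numpy()
    tr_idx = np.arange(0, localizer.n_times, train_decim)
    te_idx = np.arange(0, task.n_times, test_decim)
    task_data = np.moveaxis(task.data[:, :, te_idx], 1, 2)   # (n, T, F)
    theta = np.empty((task.n_trials, len(tr_idx), len(te_idx)))
    for i, ti in enumerate(tr_idx):
        model = fit_encoding_model(localizer.data[:, :, ti], loc_ori,
                                   basis=basis, shrinkage=shrinkage)
        _, th = decode_orientation(model, task_data)         # (n, T)
        theta[:, i, :] = th
    return localizer.times[tr_idx], task.times[te_idx], theta


def rho_map(theta, true_orientations_deg) -> np.ndarray:
    """Reduce a decoded-orientation tensor to a rho map over (train, test).

    ``theta`` is ``(n_trials, n_train, n_test)``; NaNs are excluded per cell.
    """
    phi = np.asarray(true_orientations_deg, dtype=float)
    cos_err = np.cos(to_doubled_radians(theta)
                     - to_doubled_radians(phi)[:, None, None])
    return np.nanmean(cos_err, axis=0)


def localizer_generalization(
    localizer: EpochSet,
    task: EpochSet,
    basis: EncodingBasis | None = None,
    shrinkage: float = 0.05,
    true_orientations=None,
    condition_mask=None,
    train_decim: int = 1,
    test_decim: int = 1,
) -> TemporalGeneralizationMatrix:
    """Train the encoding model per localizer time, decode the task, map rho.

    At every (decimated) localizer time point the encoding model is fitted on
    all localizer trials; every task trial is decoded at every (decimated)
    task time point, and decoded orientations are compared with
    ``true_orientations`` (default: the presented stimulus orientation) via
    ``rho``.  ``condition_mask`` restricts which task trials enter each rho.
    """
    if true_orientations is None:
        true_orientations = task.trials["stimulus_orientation_deg"].to_numpy()
    phi = np.asarray(true_orientations, dtype=float)
    if condition_mask is None:
        condition_mask = np.ones(task.n_trials, dtype=bool)
    condition_mask = np.asarray(condition_mask, dtype=bool)
    if not condition_mask.any():
        raise ValueError("condition_mask selects no trials")
    task_sel = task.select_trials(condition_mask)
    tr_times, te_times, theta = localizer_decoded_orientations(
        localizer, task_sel, basis=basis, shrinkage=shrinkage,
        train_decim=train_decim, test_decim=test_decim)
    values = rho_map(theta, phi[condition_mask])
    return TemporalGeneralizationMatrix(
        train_times=tr_times, test_times=te_times,
        values=values, measure="rho", chance=0.0,
    )
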