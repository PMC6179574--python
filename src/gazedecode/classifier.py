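"""Multi-class Gaussian probabilistic classifier and temporal generalization.

The classifier models each class-conditional density as a Gaussian with a
common covariance ``S`` and a flat prior.  Inverting the model with Bayes'
rule gives posterior probabilities

    P(class = k | x) = exp(a_k) / sum_j exp(a_j),
    a_k = w_k' x + w_k0,   w_k = S^-1 m_k,   w_k0 = -1/2 m_k' S^-1 m_k,

where ``m_k`` is the training mean of class ``k``.  ``S`` is the unweighted
mean of the per-class sample covariances, regularized by shrinkage toward a
scaled identity: ``S = (1 - lam) S_raw + lam * nu * I`` with ``nu`` the mean
of the diagonal of ``S_raw``.

Decoding is evaluated with stratified k-fold cross-validation at every pair
of training and testing time points, producing a temporal generalization
matrix of the mean posterior probability assigned to a designated target
class per trial (by default the presented stimulus class).  The classifier is
trained on trials from all task conditions pooled; the *test* set may be
restricted to a condition subset, which is how condition-specific matrices
and time courses are obtained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .epochs import EpochSet

__all__ = [
    "ClassifierModel",
    "TemporalGeneralizationMatrix",
    "fit_classifier",
    "posterior",
    "stratified_folds",
    "crossval_posteriors",
    "crossval_posterior_tensor",
    "target_posterior",
    "crossval_temporal_generalization",
    "condition_profiles",
    "spatial_pattern",
]


@dataclass
class ClassifierModel:
    """Fitted Gaussian classifier with shared, shrinkage-regularized covariance."""

    class_labels: np.ndarray    # (K,)
    means: np.ndarray           # (K, F)
    covariance: np.ndarray      # (F, F), after shrinkage
    shrinkage: float
    weights: np.ndarray         # (K, F), S^-1 m_k
    offsets: np.ndarray         # (K,)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def class_index(self, labels) -> np.ndarray:
        """Map class labels to indices into ``class_labels``."""
        lookup = {lab: i for i, lab in enumerate(self.class_labels.tolist())}
        try:
            return np.array([lookup[l] for l in np.asarray(labels).tolist()])
        except KeyError as err:
            raise ValueError(f"unknown class label {err.args[0]!r}") from err


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time x test-time grid of a scalar decoding measure."""

    train_times: np.ndarray
    test_times: np.ndarray
    values: np.ndarray          # (n_train, n_test)
    measure: str = "mean_target_posterior"
    chance: float = np.nan

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.train_times), len(self.test_times)):
            raise ValueError("values shape does not match time axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temporal generalization values must be finite")

    def train_window_mean(self, window) -> np.ndarray:
        """Average over training rows with t0 <= t <= t1; 1-D over test times."""
        t0, t1 = window
        mask = (self.train_times >= t0) & (self.train_times <= t1)
        if not mask.any():
            raise ValueError(f"training window [{t0}, {t1}] s selects no rows")
        return self.values[mask].mean(axis=0)


def _shrunk_covariance(covs: np.ndarray, shrinkage: float) -> np.ndarray:
    s_raw = covs.mean(axis=0)
    nu = float(np.mean(np.diag(s_raw)))
    eye = np.eye(s_raw.shape[0])
    return (1.0 - shrinkage) * s_raw + shrinkage * nu * eye


def fit_classifier(X, labels, shrinkage: float = 0.05) -> ClassifierModel:
    """Fit the Gaussian classifier on a trials x features block.

    ``S`` is the unweighted mean of per-class sample covariances (each with
    denominator ``n_k - 1``), shrunk toward ``nu * I``.  Requires at least two
    trials per class and ``0 <= shrinkage <= 1``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("X must be (n_trials, n_features) matching labels")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    means, covs = [], []
    for c in classes:
        xc = X[labels == c]
        if len(xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
        means.append(xc.mean(axis=0))
        covs.append(np.cov(xc, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1]))
    means = np.asarray(means)
    cov = _shrunk_covariance(np.asarray(covs), shrinkage)
    chol = cho_factor(cov)
    weights = cho_solve(chol, means.T).T            # (K, F)
    offsets = -0.5 * np.einsum("kf,kf->k", means, weights)
    return ClassifierModel(
        class_labels=classes, means=means, covariance=cov,
        shrinkage=shrinkage, weights=weights, offsets=offsets,
    )


def posterior(model: ClassifierModel, x) -> np.ndarray:
    """Posterior class probabilities for one or many feature vectors.

    ``x`` may be shape ``(F,)`` or ``(..., F)``; the result appends a class
    axis.  Computed with log-sum-exp stabilization, so adding any constant to
    all discriminants leaves the output unchanged and no overflow occurs.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match model "
            f"({model.n_features})"
        )
    a = x @ model.weights.T + model.offsets
    a -= a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..n_folds-1 per trial).

    Trials are shuffled within each class with a seeded generator and dealt
    round-robin across folds, so fold sizes within a class differ by at most
    one; ties are broken by trial order.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {c!r} has {len(idx)} trials, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def crossval_posteriors(X, labels, n_folds: int = 8, shrinkage: float = 0.05,
                        seed: int = 0):
    """Held-out posterior for every trial under stratified k-fold CV.

    Returns ``(posteriors, class_labels)`` where ``posteriors`` is
    ``(n_trials, K)`` and each row comes from the model trained on the folds
    not containing that trial.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    folds = stratified_folds(labels, n_folds, seed=seed)
    classes = np.unique(labels)
    post = np.empty((len(labels), len(classes)))
    for f in range(n_folds):
        test = folds == f
        model = fit_classifier(X[~test], labels[~test], shrinkage=shrinkage)
        if not np.array_equal(model.class_labels, classes):
            raise RuntimeError("fold lost a class; stratification is broken")
        post[test] = posterior(model, X[test])
    return post, classes


def crossval_posterior_tensor(epochs: EpochSet, labels=None, n_folds: int = 8,
                              shrinkage: float = 0.05, seed: int = 0,
                              decim: int = 1):
    """Held-out posteriors for every trial at every (train, test) time pair.

    Returns ``(times, classes, tensor)`` with ``tensor`` of shape
    ``(n_trials, n_train_times, n_test_times, n_classes)``: entry
    ``[k, i, j, c]`` is the posterior that trial ``k`` (held out in its CV
    fold) belongs to class ``c`` when the classifier is trained at time ``i``
    and applied at time ``j``.  Condition-restricted temporal generalization
    matrices and target-class re-sortings (presented class, target class,
    stimulus +/- 60 deg, ...) are all averages over slices of this tensor, so
    it is computed once per subject.  Memory scales with ``T^2``; use
    ``decim`` to stride the time axes.
    """
    if labels is None:
        labels = epochs.trials["stimulus_orientation_deg"].to_numpy()
    labels = np.asarray(labels)
    if decim < 1:
        raise ValueError("decim must be >= 1")
    t_idx = np.arange(0, epochs.n_times, decim)
    times = epochs.times[t_idx]
    data = epochs.data[:, :, t_idx]
    folds = stratified_folds(labels, n_folds, seed=seed)
    classes = np.unique(labels)
    n_t = len(t_idx)
    tensor = np.empty((epochs.n_trials, n_t, n_t, len(classes)))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        x_test = np.moveaxis(data[test], 1, 2)       # (m, T, F)
        for i in range(n_t):
            model = fit_classifier(data[train, :, i], labels[train],
                                   shrinkage=shrinkage)
            tensor[test, i] = posterior(model, x_test)
    return times, classes, tensor


def target_posterior(tensor, classes, target_labels) -> np.ndarray:
    """Per-trial posterior of each trial's designated target class.

    Reduces the class axis of a :func:`crossval_posterior_tensor` output to
    ``(n_trials, n_train, n_test)``.
    """
    classes = np.asarray(classes)
    lookup = {lab: i for i, lab in enumerate(classes.tolist())}
    try:
        idx = np.array([lookup[l] for l in np.asarray(target_labels).tolist()])
    except KeyError as err:
        raise ValueError(f"target label {err.args[0]!r} is not a class") from err
    return tensor[np.arange(tensor.shape[0]), :, :, idx]


def crossval_temporal_generalization(
    epochs: EpochSet,
    labels=None,
    n_folds: int = 8,
    shrinkage: float = 0.05,
    seed: int = 0,
    target_labels=None,
    test_mask=None,
    decim: int = 1,
) -> TemporalGeneralizationMatrix:
    """Cross-validated temporal generalization matrix of target-class posterior.

    For each training time the classifier is fitted per CV fold on the pooled
    trials at that time, then applied to the held-out trials at *every*
    testing time.  The matrix entry (t, t') is the mean, over evaluated
    trials, of the posterior probability assigned to each trial's target
    class.

    Parameters
    ----------
    labels : array, optional
        Training class per trial; defaults to ``stimulus_orientation_deg``.
    target_labels : array, optional
        Class whose posterior is read out per trial (defaults to ``labels``,
        i.e. the presented stimulus).  Must be values of ``labels``.
    test_mask : boolean array, optional
        Restrict the *test* trials entering the average (e.g. one rotation
        condition) while training on all trials.
    decim : int
        Keep every ``decim``-th sample on both time axes.
    """
    if labels is None:
        labels = epochs.trials["stimulus_orientation_deg"].to_numpy()
    labels = np.asarray(labels)
    if target_labels is None:
        target_labels = labels
    target_labels = np.asarray(target_labels)
    if test_mask is None:
        test_mask = np.ones(epochs.n_trials, dtype=bool)
    test_mask = np.asarray(test_mask, dtype=bool)
    if test_mask.shape != (epochs.n_trials,):
        raise ValueError("test_mask must be one boolean per trial")
    if not test_mask.any():
        raise ValueError("test_mask selects no trials")
    if decim < 1:
        raise ValueError("decim must be >= 1")

    t_idx = np.arange(0, epochs.n_times, decim)
    times = epochs.times[t_idx]
    data = epochs.data[:, :, t_idx]                  # (n, F, T)
    folds = stratified_folds(labels, n_folds, seed=seed)
    classes = np.unique(labels)
    lookup = {lab: i for i, lab in enumerate(classes.tolist())}
    try:
        target_idx = np.array([lookup[l] for l in target_labels.tolist()])
    except KeyError as err:
        raise ValueError(f"target label {err.args[0]!r} is not a training class")

    n_t = len(t_idx)
    # Per-trial target-class posterior for every (train, test) time pair,
    # filled fold by fold, then averaged over the evaluated trial subset.
    sums = np.zeros((n_t, n_t))
    n_eval = int(test_mask.sum())
    for f in range(n_folds):
        test = folds == f
        ev = test & test_mask
        train = ~test
        if not ev.any():
            continue
        x_ev = data[ev]                              # (m, F, T)
        tgt = target_idx[ev]
        for i in range(n_t):
            model = fit_classifier(data[train, :, i], labels[train],
                                   shrinkage=shrinkage)
            # (m, T, K) posteriors of held-out trials at all test times
            p = posterior(model, np.moveaxis(x_ev, 1, 2))
            sums[i] += p[np.arange(len(tgt)), :, tgt].sum(axis=0)
    values = sums / n_eval
    return TemporalGeneralizationMatrix(
        train_times=times, test_times=times, values=values,
        measure="mean_target_posterior", chance=1.0 / len(classes),
    )


def condition_profiles(tg_by_condition, train_window):
    """Collapse condition-wise matrices over a training window.

    Parameters
    ----------
    tg_by_condition : mapping of condition label -> TemporalGeneralizationMatrix
    train_window : (t0, t1) seconds

    Returns
    -------
    dict mapping each condition to its 1-D time course over test times.
    """
    return {
        cond: tg.train_window_mean(train_window)
        for cond, tg in tg_by_condition.items()
    }


def spatial_pattern(epochs: EpochSet, labels=None, time_window=None):
    """Per-class spatial patterns: class-mean ERF minus grand-mean ERF.

    Averaged over ``time_window`` (defaults to the whole epoch).  For balanced
    classes the patterns sum to zero across classes feature-wise, so the
    cross-class summary returned alongside is the root-mean-square over
    classes rather than the plain mean.

    Returns ``(class_labels, patterns (K, F), rms_pattern (F,))``.
    """
    if labels is None:
        labels = epochs.trials["stimulus_orientation_deg"].to_numpy()
    labels = np.asarray(labels)
    if time_window is None:
        mask = np.ones(epochs.n_times, dtype=bool)
    else:
        mask = epochs.time_mask(*time_window)
        if not mask.any():
            raise ValueError("time_window selects no samples")
    erf = epochs.data[:, :, mask].mean(axis=2)       # (n, F)
    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    if len(set(counts.tolist())) > 1:
        warnings.warn(
            "classes are unbalanced; class patterns will not sum to zero",
            stacklevel=2,
        )
    grand = erf.mean(axis=0)
    patterns = np.stack([erf[labels == c].mean(axis=0) - grand for c in classes])
    rms = np.sqrt((patterns ** 2).mean(axis=0))
    return classes, patterns, rms
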