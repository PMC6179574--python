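"""Gaussian probabilistic classifier: fitting, posteriors, generalization."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazedecode import (condition_profiles, crossval_posteriors,
                        crossval_temporal_generalization, fit_classifier,
                        posterior, spatial_pattern, stratified_folds)
from gazedecode.classifier import TemporalGeneralizationMatrix

from conftest import make_epochs


def random_problem(rng, n_features, n_classes=3, n_per_class=12, sep=2.0):
    means = rng.standard_normal((n_classes, n_features)) * sep
    X = np.concatenate([
        m + rng.standard_normal((n_per_class, n_features)) for m in means
    ])
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return X, labels


class TestFit:
    def test_pooled_covariance_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X, labels = random_problem(rng, 2, n_per_class=7)
        lam = 0.3
        model = fit_classifier(X, labels, shrinkage=lam)
        covs = [np.cov(X[labels == c], rowvar=False, ddof=1)
                for c in np.unique(labels)]
        s_raw = np.mean(covs, axis=0)        # unweighted mean across classes
        nu = np.mean(np.diag(s_raw))
        expected = (1 - lam) * s_raw + lam * nu * np.eye(2)
        assert np.allclose(model.covariance, expected, atol=1e-12)
        for c in np.unique(labels):
            assert np.allclose(model.means[c], X[labels == c].mean(axis=0))

    def test_full_shrinkage_gives_scaled_identity(self):
        rng = np.random.default_rng(1)
        X, labels = random_problem(rng, 4)
        model = fit_classifier(X, labels, shrinkage=1.0)
        nu = model.covariance[0, 0]
        assert np.allclose(model.covariance, nu * np.eye(4), atol=1e-12)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_classifier(X, np.array([0, 0, 1]))

    def test_identical_classes_give_uniform_posterior(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((10, 3))
        X = np.concatenate([base, base, base])
        labels = np.repeat([0, 1, 2], 10)
        model = fit_classifier(X, labels, shrinkage=0.1)
        p = posterior(model, rng.standard_normal((20, 3)))
        assert np.allclose(p, 1.0 / 3.0, atol=1e-9)


class TestPosterior:
    def test_matches_gaussian_density_oracle(self):
        """Softmax discriminant form == explicit Bayes with Gaussian densities."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            f = rng.integers(2, 6)
            X, labels = random_problem(rng, f, n_per_class=8,
                                       sep=rng.uniform(0.5, 3.0))
            model = fit_classifier(X, labels, shrinkage=0.2)
            x = rng.standard_normal(f) * 3
            dens = np.array([
                multivariate_normal.pdf(x, mean=m, cov=model.covariance)
                for m in model.means
            ])
            assert np.allclose(posterior(model, x), dens / dens.sum(),
                               atol=1e-10)

    def test_sums_to_one_and_recovers_clear_class(self):
        rng = np.random.default_rng(4)
        X, labels = random_problem(rng, 3, sep=8.0)
        model = fit_classifier(X, labels, shrinkage=0.05)
        p = posterior(model, rng.standard_normal((50, 3)) * 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert posterior(model, model.means[1])[1] > 0.99

    def test_affine_feature_invariance_without_shrinkage(self):
        """lam=0: posteriors invariant to any shared invertible linear map."""
        rng = np.random.default_rng(5)
        X, labels = random_problem(rng, 3, n_per_class=20)
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        m0 = fit_classifier(X, labels, shrinkage=0.0)
        m1 = fit_classifier(X @ M.T + b, labels, shrinkage=0.0)
        x = rng.standard_normal((10, 3))
        assert np.allclose(posterior(m0, x), posterior(m1, x @ M.T + b),
                           atol=1e-8)

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(6)
        X, labels = random_problem(rng, 3)
        model = fit_classifier(X, labels)
        with pytest.raises(ValueError, match="feature dimension"):
            posterior(model, np.zeros(5))


class TestCrossValidation:
    def test_folds_stratified_and_deterministic(self):
        labels = np.repeat([0, 1, 2], 16)
        f1 = stratified_folds(labels, 4, seed=9)
        f2 = stratified_folds(labels, 4, seed=9)
        assert np.array_equal(f1, f2)
        for fold in range(4):
            for c in (0, 1, 2):
                assert np.sum((f1 == fold) & (labels == c)) == 4

    def test_too_few_trials_per_class_errors(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds(np.array([0, 0, 1, 1]), 4)

    def test_structureless_data_decodes_at_chance(self):
        rng = np.random.default_rng(10)
        vals = []
        for s in range(6):
            X = rng.standard_normal((144, 8))
            labels = np.repeat([15.0, 75.0, 135.0], 48)
            p, classes = crossval_posteriors(X, labels, 8, 0.05, seed=s)
            idx = np.searchsorted(classes, labels)
            vals.append(p[np.arange(len(labels)), idx].mean())
        assert np.mean(vals) == pytest.approx(1.0 / 3.0, abs=0.02)


class TestTemporalGeneralization:
    def _signal_epochs(self, rng, transient=True):
        """3-class epochs with a class-specific pattern in samples 10..20."""
        n_per, f, t = 16, 6, 30
        patterns = rng.standard_normal((3, f)) * 3
        data = rng.standard_normal((3 * n_per, f, t))
        labels = np.repeat([15.0, 75.0, 135.0], n_per)
        for k, lab in enumerate([15.0, 75.0, 135.0]):
            sel = labels == lab
            data[np.ix_(sel, range(f), range(10, 20))] += patterns[k][:, None]
        return make_epochs(data, stims=labels), labels

    def test_chance_on_label_independent_features(self):
        rng = np.random.default_rng(11)
        e = make_epochs(rng.standard_normal((48, 4, 12)),
                        stims=np.repeat([15.0, 75.0, 135.0], 16))
        tg = crossval_temporal_generalization(e, n_folds=4, seed=0)
        assert tg.chance == pytest.approx(1.0 / 3.0)
        assert tg.values.mean() == pytest.approx(1.0 / 3.0, abs=0.03)

    def test_diagonal_dominates_on_transient_signal(self):
        rng = np.random.default_rng(12)
        e, labels = self._signal_epochs(rng)
        tg = crossval_temporal_generalization(e, n_folds=4, seed=0)
        sig = slice(10, 20)
        on_diag = tg.values[sig, sig].diagonal().mean()
        off = tg.values[sig, 25:].mean()
        assert on_diag > off + 0.1
        assert on_diag > 0.5            # well above 1/3 chance

    def test_condition_restriction_changes_test_set_only(self):
        rng = np.random.default_rng(13)
        e, labels = self._signal_epochs(rng)
        mask = np.zeros(e.n_trials, dtype=bool)
        mask[::2] = True
        tg = crossval_temporal_generalization(e, n_folds=4, seed=0,
                                              test_mask=mask)
        assert np.isfinite(tg.values).all()
        with pytest.raises(ValueError, match="no trials"):
            crossval_temporal_generalization(e, n_folds=4,
                                             test_mask=np.zeros(e.n_trials,
                                                                bool))


class TestProfilesAndPatterns:
    def test_constant_matrix_profile_is_constant(self):
        times = np.linspace(0, 1, 11)
        tg = TemporalGeneralizationMatrix(times, times, np.full((11, 11), 0.4))
        profs = condition_profiles({"VWM": tg}, (0.2, 0.6))
        assert np.allclose(profs["VWM"], 0.4)

    def test_single_row_window_equals_that_row(self):
        rng = np.random.default_rng(14)
        times = np.linspace(0, 1, 11)
        tg = TemporalGeneralizationMatrix(times, times,
                                          rng.standard_normal((11, 11)))
        prof = tg.train_window_mean((times[3] - 1e-9, times[3] + 1e-9))
        assert np.allclose(prof, tg.values[3])

    def test_empty_window_errors(self):
        times = np.linspace(0, 1, 11)
        tg = TemporalGeneralizationMatrix(times, times, np.zeros((11, 11)))
        with pytest.raises(ValueError, match="no rows"):
            tg.train_window_mean((5.0, 6.0))

    def test_balanced_class_patterns_sum_to_zero(self):
        rng = np.random.default_rng(15)
        e = make_epochs(rng.standard_normal((30, 4, 20)),
                        stims=np.repeat([15.0, 75.0, 135.0], 10))
        classes, patterns, rms = spatial_pattern(e, time_window=(-0.1, 0.1))
        assert np.allclose(patterns.sum(axis=0), 0.0, atol=1e-10)
        assert rms.shape == (4,)

    def test_identical_classes_give_zero_patterns(self):
        base = np.ones((30, 4, 20)) * 2.0
        e = make_epochs(base, stims=np.repeat([15.0, 75.0, 135.0], 10))
        _, patterns, _ = spatial_pattern(e)
        assert np.allclose(patterns, 0.0, atol=1e-12)

    def test_unbalanced_classes_warn(self):
        rng = np.random.default_rng(16)
        e = make_epochs(rng.standard_normal((5, 2, 8)),
                        stims=[15.0, 15.0, 15.0, 75.0, 75.0])
        with pytest.warns(UserWarning, match="unbalanced"):
            spatial_pattern(e)
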