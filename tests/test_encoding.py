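"""Inverted encoding model: basis, inversion, circular decode, rho."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gazedecode import (EncodingBasis, basis_responses, decode_orientation,
                        fit_encoding_model, rho, rho_z)
from gazedecode.encoding import EncodingModel


def make_training_set(rng, n_sensors=16, n_per=8, noise=0.5,
                      orientations=(15.0, 45.0, 75.0, 105.0, 135.0, 165.0),
                      noise_chol=None):
    """Trials whose sensor data follow the doubled-angle code A[cos2a, sin2a]."""
    a = np.linalg.qr(rng.standard_normal((n_sensors, 2)))[0]
    ori = np.repeat(orientations, n_per)
    d = np.deg2rad(2 * ori)
    clean = np.stack([np.cos(d), np.sin(d)], axis=1) @ a.T
    eps = rng.standard_normal((len(ori), n_sensors))
    if noise_chol is not None:
        eps = eps @ noise_chol.T
    return clean + noise * eps, ori, a


class TestBasis:
    def test_center_response_is_one(self):
        basis = EncodingBasis()
        c = basis_responses(basis, basis.centers_deg)
        assert np.allclose(np.diag(c), 1.0, atol=1e-12)

    def test_orthogonal_orientation_response(self):
        # 90 deg from a center = 180 deg on the doubled circle: exp(-2 kappa)
        basis = EncodingBasis(n_channels=24, kappa=5.0)
        c = basis_responses(basis, [(basis.centers_deg[3] + 90.0) % 180.0])
        assert c[0, 3] == pytest.approx(np.exp(-2 * 5.0), rel=1e-12)

    def test_row_sums_constant_over_orientation(self):
        basis = EncodingBasis()
        c = basis_responses(basis, np.linspace(0, 179.9, 37))
        sums = c.sum(axis=1)
        assert np.allclose(sums, sums[0], atol=1e-9)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match=r"\[0, 180\)"):
            basis_responses(EncodingBasis(), [180.0])


class TestFit:
    def test_noiseless_patterns_recovered_in_design_rowspace(self):
        # ground-truth channel coefficients constructed inside the design row
        # space, where the minimum-norm least-squares solution is unique
        rng = np.random.default_rng(0)
        basis = EncodingBasis(n_channels=8, kappa=2.0)
        ori = np.repeat(np.arange(6) * 30.0 + 15.0, 4)
        C = basis_responses(basis, ori)
        coeffs = C.T @ rng.standard_normal((len(ori), 5))   # (8, 5) in rowspace
        X = C @ coeffs
        model = fit_encoding_model(X + 1e-9 * rng.standard_normal(X.shape),
                                   ori, basis=basis, shrinkage=0.01)
        assert np.allclose(model.patterns, coeffs.T, atol=1e-5)

    def test_white_noise_filters_proportional_to_patterns(self):
        rng = np.random.default_rng(1)
        X, ori, _ = make_training_set(rng, noise=1.0)
        model = fit_encoding_model(X, ori, shrinkage=1.0)  # Sigma = nu I
        for j in range(model.basis.n_channels):
            p = model.patterns[:, j]
            w = model.filters[j]
            cos = p @ w / (np.linalg.norm(p) * np.linalg.norm(w))
            assert cos == pytest.approx(1.0, abs=1e-10)
            assert w @ p == pytest.approx(1.0, abs=1e-10)   # unit gain

    def test_too_few_orientations_errors(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 4))
        with pytest.raises(ValueError, match="distinct training orientations"):
            fit_encoding_model(X, np.repeat([15.0, 75.0], 4))

    def test_correlated_noise_filters_beat_identity(self):
        """Noise-aware inversion lowers circular decoding error (paired sim)."""
        rng = np.random.default_rng(3)
        n_sensors = 12
        idx = np.arange(n_sensors)
        chol = np.linalg.cholesky(0.9 ** np.abs(idx[:, None] - idx[None, :]))
        wins = 0
        reps = 30
        for _ in range(reps):
            X, ori, a = make_training_set(rng, n_sensors=n_sensors, noise=1.5,
                                          noise_chol=chol)
            Xt, orit, _ = make_training_set(rng, n_sensors=n_sensors,
                                            noise=1.5, noise_chol=chol)
            # reuse the same mixing for test data
            d = np.deg2rad(2 * orit)
            Xt = np.stack([np.cos(d), np.sin(d)], axis=1) @ a.T \
                + 1.5 * (rng.standard_normal((len(orit), n_sensors)) @ chol.T)
            aware = fit_encoding_model(X, ori, shrinkage=0.05)
            blind = fit_encoding_model(X, ori, shrinkage=1.0)
            errs = []
            for m in (aware, blind):
                _, theta = decode_orientation(m, Xt)
                e = np.deg2rad(2 * (theta - orit))
                errs.append(np.sqrt(np.mean(np.arctan2(np.sin(e),
                                                       np.cos(e)) ** 2)))
            wins += errs[0] < errs[1]
        assert wins > reps * 0.7

    def test_recovery_error_decreases_with_snr(self):
        rng = np.random.default_rng(4)
        rmse = []
        for noise in (2.0, 0.8, 0.2):
            X, ori, a = make_training_set(rng, noise=noise, n_per=12)
            model = fit_encoding_model(X, ori, shrinkage=0.05)
            d = np.deg2rad(2 * ori)
            clean = np.stack([np.cos(d), np.sin(d)], axis=1) @ a.T
            test = clean + noise * rng.standard_normal(clean.shape)
            _, theta = decode_orientation(model, test)
            e = np.deg2rad(2 * (theta - ori))
            rmse.append(np.sqrt(np.mean(np.arctan2(np.sin(e),
                                                   np.cos(e)) ** 2)))
        assert rmse[0] > rmse[1] > rmse[2]


class TestDecode:
    def _identity_model(self, n=8):
        basis = EncodingBasis(n_channels=n, kappa=3.0)
        return EncodingModel(basis=basis, patterns=np.eye(n),
                             noise_covariance=np.eye(n), filters=np.eye(n),
                             shrinkage=0.0)

    def test_one_hot_activity_decodes_channel_center(self):
        model = self._identity_model()
        for j in range(8):
            x = np.zeros(8)
            x[j] = 1.0
            _, theta = decode_orientation(model, x)
            assert theta == pytest.approx(model.basis.centers_deg[j],
                                          abs=1e-9)

    def test_uniform_activity_is_flagged_undefined(self):
        model = self._identity_model()
        _, theta = decode_orientation(model, np.ones(8))
        assert np.isnan(theta)

    def test_noiseless_trial_decodes_generating_orientation(self):
        # dense training orientations keep the identifiable channel subspace
        # rich enough for sub-degree interpolation between design points
        rng = np.random.default_rng(5)
        X, ori, a = make_training_set(rng, noise=0.02, n_per=6,
                                      orientations=np.arange(12) * 15.0 + 7.5)
        model = fit_encoding_model(X, ori, shrinkage=0.05)
        d = np.deg2rad(2 * np.array([37.0]))
        x = np.stack([np.cos(d), np.sin(d)], axis=1) @ a.T
        _, theta = decode_orientation(model, x[0])
        diff = (theta - 37.0 + 90.0) % 180.0 - 90.0
        # the per-channel unit-gain inversion carries a degree-scale
        # interpolation ripple between channel centers; it is phase-locked to
        # the true orientation and cancels in rho across trials
        assert abs(diff) < 3.0


class TestRho:
    @pytest.mark.parametrize("offset,expected", [
        (0.0, 1.0),      # decoded == true
        (45.0, 0.0),     # orthogonal on the doubled circle
        (90.0, -1.0),    # counterphase on the doubled circle
    ])
    def test_analytic_offsets(self, offset, expected):
        rng = np.random.default_rng(6)
        phi = rng.uniform(0, 180, 100)
        theta = (phi + offset) % 180.0
        assert rho(theta, phi) == pytest.approx(expected, abs=1e-12)

    def test_matches_mean_cosine_oracle(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 180, 200)
        phi = rng.uniform(0, 180, 200)
        oracle = np.mean(np.cos(np.deg2rad(2 * theta) - np.deg2rad(2 * phi)))
        assert rho(theta, phi) == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hnp.arrays(float, st.integers(1, 40),
                      elements=st.floats(0, 179.99)),
           st.floats(0, 179.99))
    def test_quarter_turn_antisymmetry(self, phi, shift):
        theta = (phi + shift) % 180.0
        assert rho(theta, (phi + 90.0) % 180.0) == pytest.approx(
            -rho(theta, phi), abs=1e-9)

    def test_magnitude_bounded(self):
        rng = np.random.default_rng(8)
        z = rho_z(rng.uniform(0, 180, 50), rng.uniform(0, 180, 50))
        assert abs(z) <= 1.0 + 1e-12

    def test_empty_or_mismatched_errors(self):
        with pytest.raises(ValueError):
            rho([], [])
        with pytest.raises(ValueError, match="equal length"):
            rho([10.0], [10.0, 20.0])

    def test_nan_thetas_excluded(self):
        assert rho([10.0, np.nan, 10.0], [10.0, 50.0, 10.0]) == pytest.approx(
            1.0)
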