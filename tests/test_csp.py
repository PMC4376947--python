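"""CSP: covariance estimation, simultaneous diagonalization, features."""

import numpy as np
import pytest
import scipy.linalg

import pupilbci as pb
from pupilbci.csp import RankDeficiencyError, spatial_covariance
from pupilbci.synth import MONTAGE_32, _topography

from conftest import random_spd


def epoch_with_covariance(c, t_samples, rng):
    """Construct an epoch whose normalized spatial covariance is exactly
    c / trace(c): E = sqrtm(c) Q with Q having orthonormal rows."""
    n = c.shape[0]
    q, _ = np.linalg.qr(rng.standard_normal((t_samples, n)))
    return scipy.linalg.sqrtm(c).real @ q.T


def fit_from_covariances(c_left, c_nothing, m=1, **kw):
    rng = np.random.default_rng(0)
    t = 4 * c_left.shape[0]
    left = [epoch_with_covariance(c_left, t, rng) for _ in range(2)]
    nothing = [epoch_with_covariance(c_nothing, t, rng) for _ in range(2)]
    return pb.fit_csp(left, nothing, m=m, **kw)


class TestSpatialCovariance:
    def test_identity_epoch(self):
        c = spatial_covariance(np.eye(2)).matrix
        assert np.allclose(c, 0.5 * np.eye(2))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal((4, 100))
        c1 = spatial_covariance(e).matrix
        c2 = spatial_covariance(-3.7 * e).matrix
        assert np.allclose(c1, c2)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal((32, 704))
        c = spatial_covariance(e).matrix
        oracle = (e @ e.T) / np.trace(e @ e.T)
        assert np.abs(c - oracle).max() < 1e-12
        assert np.trace(c) == pytest.approx(1.0)
        assert np.allclose(c, c.T)

    def test_zero_epoch_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            spatial_covariance(np.zeros((3, 50)))


class TestSimultaneousDiagonalization:
    def test_eigenvalue_pairs_sum_to_one_and_whitening(self):
        """Over 100 random SPD pairs: lambda_nt + lambda_l = 1 elementwise
        and the whitener makes the composite the identity, both to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            c_nt, c_l = random_spd(rng, n), random_spd(rng, n)
            model = fit_from_covariances(c_l, c_nt, regularization=0.0)
            assert np.abs(model.lambda_nt + model.lambda_l - 1.0).max() < 1e-8
            c_c = (c_nt / np.trace(c_nt) + c_l / np.trace(c_l))
            w_cc = model.whitener @ c_c @ model.whitener.T
            assert np.abs(w_cc - np.eye(n)).max() < 1e-8

    def test_filters_match_generalized_eig_oracle(self):
        """CSP filters equal the generalized eigenvectors of (C_l, C_c) up
        to sign/scale on small random instances."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 5))
            c_nt = random_spd(rng, n) / 1.0
            c_l = random_spd(rng, n)
            c_nt /= np.trace(c_nt)
            c_l /= np.trace(c_l)
            model = fit_from_covariances(c_l, c_nt, regularization=0.0)
            vals, vecs = scipy.linalg.eigh(c_l, c_nt + c_l)  # ascending lam_l
            for i in range(n):
                w = model.W[i]  # sorted descending in lambda_nt = ascending lambda_l
                v = vecs[:, i]
                cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
                assert cos == pytest.approx(1.0, abs=1e-6)
                assert model.lambda_l[i] == pytest.approx(vals[i], abs=1e-8)

    def test_identical_classes_give_half_eigenvalues(self):
        rng = np.random.default_rng(8)
        c = random_spd(rng, 4)
        model = fit_from_covariances(c, c, regularization=0.0)
        assert np.allclose(model.lambda_nt, 0.5, atol=1e-8)

    def test_planted_two_channel_case(self):
        # C_nt = diag(.9,.1), C_l = diag(.1,.9): whitened no-task eigenvalues
        # are {0.9, 0.1} and the filters align with the coordinate axes
        model = fit_from_covariances(np.diag([0.1, 0.9]), np.diag([0.9, 0.1]),
                                     regularization=0.0)
        assert model.lambda_nt == pytest.approx([0.9, 0.1], abs=1e-10)
        for row in model.W:
            direction = np.abs(row) / np.linalg.norm(row)
            assert max(direction) == pytest.approx(1.0, abs=1e-8)

    def test_w_times_patterns_is_identity(self, strong_erd_trials):
        left = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "left"]
        nt = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "nothing"]
        model = pb.fit_csp(left, nt)
        k = model.W.shape[0]
        assert np.abs(model.W @ model.patterns - np.eye(k)).max() < 1e-8
        # descending order of the no-task eigenvalues
        assert (np.diff(model.lambda_nt) <= 1e-12).all()

    def test_rank_deficiency_error_names_dimensions(self):
        rng = np.random.default_rng(13)
        # 4-channel data living in a 2-D subspace cannot support m=2 (4 filters)
        basis = rng.standard_normal((4, 2))
        left = [basis @ rng.standard_normal((2, 64)) for _ in range(3)]
        nt = [basis @ rng.standard_normal((2, 64)) for _ in range(3)]
        with pytest.raises(RankDeficiencyError, match="deficient"):
            pb.fit_csp(left, nt, m=2, regularization=0.0)


class TestFeatures:
    def test_six_features_from_three_pairs(self, preprocessed_trials):
        left = [t.eeg_epoch for t in preprocessed_trials if t.class_label == "left"]
        nt = [t.eeg_epoch for t in preprocessed_trials if t.class_label == "nothing"]
        model = pb.fit_csp(left, nt, m=3)
        feats = pb.csp_features(model, preprocessed_trials[0].eeg_epoch)
        assert feats.shape == (6,)
        assert model.selected_filters.size == 6

    def test_scale_invariance_and_normalization(self, strong_erd_trials):
        left = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "left"]
        nt = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "nothing"]
        model = pb.fit_csp(left, nt)
        e = strong_erd_trials[0].eeg_epoch
        f1 = pb.csp_features(model, e)
        f2 = pb.csp_features(model, 17.3 * e)
        assert np.allclose(f1, f2)
        assert np.exp(f1).sum() == pytest.approx(1.0)

    def test_planted_case_features_separate_classes(self):
        # project both planted class distributions through the fitted model:
        # the first-filter log-variance separates them with a clear margin
        rng = np.random.default_rng(21)
        c_nt, c_l = np.diag([0.9, 0.1]), np.diag([0.1, 0.9])
        model = fit_from_covariances(c_l, c_nt, regularization=0.0)
        f_nt = [pb.csp_features(model, scipy.linalg.sqrtm(c_nt).real
                                @ rng.standard_normal((2, 500)))[0]
                for _ in range(40)]
        f_l = [pb.csp_features(model, scipy.linalg.sqrtm(c_l).real
                               @ rng.standard_normal((2, 500)))[0]
               for _ in range(40)]
        assert min(f_nt) > max(f_l) + 0.5

    def test_channel_mismatch_rejected(self, strong_erd_trials):
        left = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "left"]
        nt = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "nothing"]
        model = pb.fit_csp(left, nt)
        with pytest.raises(ValueError, match="channels"):
            pb.csp_features(model, np.zeros((5, 100)))


def test_top_pattern_matches_planted_topography(strong_erd_trials):
    """The leading no-task pattern recovers the planted mu-source scalp map
    (the source whose power the imagery condition suppresses)."""
    left = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "left"]
    nt = [t.eeg_epoch for t in strong_erd_trials if t.class_label == "nothing"]
    model = pb.fit_csp(left, nt)
    labels = list(MONTAGE_32)[:32]
    positions = np.array([MONTAGE_32[c] for c in labels])
    planted = _topography(positions, np.array([0.50, 0.00]))
    top = model.patterns[:, model.selected_filters[0]]
    r = np.corrcoef(top, planted)[0, 1]
    assert abs(r) >= 0.8
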