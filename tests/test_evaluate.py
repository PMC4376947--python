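"""Performance metrics, protocols, and association measures."""

import numpy as np
import pytest

import pupilbci as pb
from pupilbci.evaluate import (
    LeakageError,
    cross_block,
    crossval_within_block,
    itr_bits_per_trial,
    performance_metrics,
)
from pupilbci.pipeline import PipelineConfig


class TestScalarMetrics:
    def test_chance_level(self):
        rep = performance_metrics(5, 5, 5, 5)
        assert rep.accuracy == 0.5
        assert rep.itr_bits_per_trial == pytest.approx(0.0, abs=1e-12)
        assert rep.kappa == pytest.approx(0.0)

    def test_perfect_limit(self):
        rep = performance_metrics(10, 10, 0, 0)
        assert rep.itr_bits_per_trial == pytest.approx(1.0)
        assert rep.kappa == pytest.approx(1.0)

    def test_itr_at_printed_pupillometry_accuracy(self):
        # two targets at 73.3 % accuracy transmit 0.16 bits per trial
        b = itr_bits_per_trial(0.733, 2)
        assert b == pytest.approx(0.163, abs=2e-3)
        assert round(b, 2) == 0.16

    def test_bits_per_minute_uses_active_trial_duration(self):
        rep = performance_metrics(8, 7, 2, 3, trial_seconds=6.0)
        assert rep.itr_bits_per_min == pytest.approx(rep.itr_bits_per_trial * 10)

    def test_itr_strictly_increasing_above_chance(self):
        grid = np.linspace(0.5, 1.0, 101)
        vals = [itr_bits_per_trial(p, 2) for p in grid]
        assert all(b2 > b1 for b1, b2 in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[-1] == pytest.approx(1.0)

    def test_kappa_affine_in_accuracy(self):
        ps = np.linspace(0.0, 1.0, 11)
        ks = np.array([pb.cohen_kappa(p, 0.5) for p in ps])
        assert np.allclose(np.diff(ks), np.diff(ks)[0])
        assert pb.cohen_kappa(0.5, 0.5) == 0.0
        assert pb.cohen_kappa(1.0, 0.5) == 1.0

    def test_accuracy_consistency_invariant(self):
        rep = performance_metrics(7, 9, 3, 6)
        assert rep.accuracy == (rep.tp + rep.tn) / rep.n_trials
        assert rep.tp + rep.tn + rep.fp + rep.fn == rep.n_trials


class TestCrossValidation:
    def test_partition_property_and_determinism(self, preprocessed_trials):
        cfg = PipelineConfig.from_dict({"mode": "eeg"})
        r1 = crossval_within_block(preprocessed_trials, cfg, k=10, seed=3)
        r2 = crossval_within_block(preprocessed_trials, cfg, k=10, seed=3)
        assert r1 == r2
        # every trial scored exactly once
        assert r1.n_trials == len(preprocessed_trials)

    def test_k_larger_than_class_count_rejected(self, preprocessed_trials):
        with pytest.raises(ValueError, match="k="):
            crossval_within_block(preprocessed_trials, k=20)

    def test_separable_block_reaches_perfect_accuracy(self, strong_erd_trials):
        cfg = PipelineConfig.from_dict({"mode": "eeg"})
        rep = crossval_within_block(strong_erd_trials, cfg, k=10, seed=0)
        assert rep.accuracy == 1.0

    def test_label_permutation_canary(self, strong_erd_trials):
        """Shuffling the class labels destroys the signal: CV accuracy falls
        to chance, confirming no train/test leakage."""
        import copy

        rng = np.random.default_rng(0)
        accs = []
        for seed in range(5):
            shuffled = [copy.copy(t) for t in strong_erd_trials]
            labels = [t.class_label for t in shuffled]
            rng.shuffle(labels)
            for t, lab in zip(shuffled, labels):
                t.class_label = lab
            accs.append(crossval_within_block(
                shuffled, PipelineConfig.from_dict({"mode": "eeg"}),
                k=10, seed=seed).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1


class TestCrossBlock:
    def test_train_equals_test_is_leakage(self, preprocessed_trials):
        with pytest.raises(LeakageError):
            cross_block(preprocessed_trials, preprocessed_trials)

    def test_same_block_id_is_leakage(self, default_session):
        t1, _ = pb.epoch_session(pb.preprocess_session(default_session))
        t2, _ = pb.epoch_session(pb.preprocess_session(default_session))
        with pytest.raises(LeakageError):
            cross_block(t1, t2)

    def test_planted_shift_degrades_cross_block_accuracy(self):
        """Inter-block non-stationarity: cross-block accuracy falls below
        within-block CV, averaged over subjects."""
        cfg_kwargs = dict(erd_depth=0.6, sensor_noise_sd=4.0)
        cv_accs, cb_accs = [], []
        for seed in range(4):
            blocks = []
            for b in range(2):
                c = pb.SynthConfig(**cfg_kwargs, inter_block_shift=0.25 * b)
                s = pb.generate_session(c, seed=1000 + 10 * seed + b,
                                        block_id=f"b{b}")
                trials, _ = pb.epoch_session(pb.preprocess_session(s))
                blocks.append(trials)
            cfg = PipelineConfig.from_dict({"mode": "eeg"})
            cv_accs.append(np.mean([
                crossval_within_block(blk, cfg, k=10, seed=0).accuracy
                for blk in blocks]))
            cb_accs.append(cross_block(blocks[0], blocks[1], cfg).accuracy)
        assert np.mean(cb_accs) < np.mean(cv_accs)

    def test_no_signal_cross_block_near_chance(self):
        accs = []
        for seed in range(4):
            cfg = pb.SynthConfig(erd_depth=0.0, pupil_effect_mm=0.0)
            blocks = []
            for b in range(2):
                s = pb.generate_session(cfg, seed=2000 + 10 * seed + b,
                                        block_id=f"b{b}")
                trials, _ = pb.epoch_session(pb.preprocess_session(s))
                blocks.append(trials)
            accs.append(cross_block(
                blocks[0], blocks[1],
                PipelineConfig.from_dict({"mode": "eeg"})).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15


class TestMutualInformation:
    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        # at the 10-bin analysis configuration the plug-in bias is tiny
        rep10 = pb.mutual_information(x, y, bins=10, seed=1)
        assert 0.0 <= rep10.mutual_information < 0.05
        assert abs(rep10.permutation_z) < 3
        # under FD binning the permutation test still calls independence
        rep_fd = pb.mutual_information(x, y, seed=1)
        assert abs(rep_fd.permutation_z) < 3

    def test_identity_recovers_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        rep = pb.mutual_information(x, x, seed=0)
        assert rep.mutual_information == pytest.approx(rep.h_x, abs=1e-12)
        assert rep.permutation_z > 5

    def test_entropy_identity_arithmetic(self):
        # MI = H_x + H_y - H_joint for any estimate the histogram produces
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        rep = pb.mutual_information(x, y, seed=0)
        assert rep.mutual_information == pytest.approx(
            rep.h_x + rep.h_y - rep.h_joint, abs=1e-12)
        assert rep.mutual_information >= 0.0

    def test_constant_input_warns_mi_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            rep = pb.mutual_information(np.ones(100), np.arange(100.0))
        assert rep.mutual_information == 0.0

    def test_bins_override(self):
        rng = np.random.default_rng(3)
        rep = pb.mutual_information(rng.standard_normal(100),
                                    rng.standard_normal(100), bins=10)
        assert rep.n_bins == 10


class TestAssociation:
    def test_pearson_perfect_and_inverse(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        assert pb.pearson_association(a, a)[0] == pytest.approx(1.0)
        assert pb.pearson_association(a, -a + 1.4)[0] == pytest.approx(-1.0)

    def test_pearson_matches_hand_arithmetic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # textbook computation: r = cov(a, b) / (sd_a sd_b)
        r_hand = (((a - a.mean()) * (b - b.mean())).sum()
                  / np.sqrt(((a - a.mean()) ** 2).sum()
                            * ((b - b.mean()) ** 2).sum()))
        r, p = pb.pearson_association(a, b)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert 0.0 < p < 1.0

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pb.pearson_association([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])


class TestSubgroupComparison:
    def test_identical_vectors_give_zero_effect(self):
        a = np.array([0.50, 0.55, 0.60, 0.70, 0.80, 0.90, 0.75, 0.85])
        out = pb.subgroup_compare(a, a.copy())
        for rep in out.values():
            assert rep.t == 0.0 and rep.cohen_d == 0.0 and not rep.degenerate

    def test_constant_shift_flagged_degenerate(self):
        a = np.array([0.5, 0.55, 0.6, 0.7, 0.8, 0.9])
        out = pb.subgroup_compare(a, a + 0.1)
        for rep in out.values():
            assert rep.degenerate
            assert rep.t is None

    def test_matches_hand_worked_paired_t(self):
        # 6 participants, lower quartile = 2 lowest EEG accuracies
        eeg = np.array([0.50, 0.52, 0.70, 0.75, 0.80, 0.85])
        hyb = np.array([0.68, 0.64, 0.74, 0.78, 0.84, 0.86])
        out = pb.subgroup_compare(eeg, hyb, quartile_fraction=0.25)
        low = out["lower"]
        diff = np.array([0.18, 0.12])
        sd = diff.std(ddof=1)
        t_hand = diff.mean() / (sd / np.sqrt(2))
        assert low.n == 2
        assert low.t == pytest.approx(t_hand, abs=1e-12)
        assert low.cohen_d == pytest.approx(diff.mean() / sd, abs=1e-12)
        assert low.df == 1
        # subgroup means reported on the right slices
        assert low.mean_a == pytest.approx(0.51)
        assert out["upper"].n == 4

    def test_tiny_subgroup_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            pb.subgroup_compare([0.5, 0.9, 0.91, 0.92], [0.6, 0.9, 0.91, 0.92],
                                quartile_fraction=0.05)
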