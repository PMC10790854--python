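"""Evaluation machinery: SVM wrapper, bootstraps, sweeps, level restriction."""

import numpy as np
import pandas as pd
import pytest

import mibci
from mibci.csp import FeatureMatrix
from mibci.protocols import subject_seed, sweep_monotonicity


def toy_features(rng, n_per_class=10, gap=4.0):
    x_l = rng.standard_normal((n_per_class, 2))
    x_r = rng.standard_normal((n_per_class, 2)) + gap
    X = np.vstack([x_l, x_r])
    y = np.array(["left"] * n_per_class + ["right"] * n_per_class)
    return FeatureMatrix(X=X, y=y)


class TestTrainEval:
    def test_separable_features_perfect_accuracy(self, rng):
        train = toy_features(rng, gap=10.0)
        test = toy_features(rng, gap=10.0)
        assert mibci.train_eval(train, test) == 100.0

    def test_train_equals_test_sanity_path(self, rng):
        feats = toy_features(rng, gap=10.0)
        assert mibci.train_eval(feats, feats) == 100.0

    def test_single_class_train_rejected(self, rng):
        feats = toy_features(rng)
        bad = FeatureMatrix(X=feats.X[:10], y=feats.y[:10])
        with pytest.raises(ValueError, match="both classes"):
            mibci.train_eval(bad, feats)

    def test_permuted_labels_near_chance(self, rng):
        """Label permutation keeps mean accuracy within 3 SE of 50%."""
        accs = []
        for _ in range(200):
            X = rng.standard_normal((30, 6))
            y = np.array(["left"] * 15 + ["right"] * 15)
            rng.shuffle(y)
            tr = rng.permutation(30)[:20]
            te = np.setdiff1d(np.arange(30), tr)
            if len(np.unique(y[tr])) < 2:
                continue
            accs.append(mibci.train_eval(
                FeatureMatrix(X=X[tr], y=y[tr]), FeatureMatrix(X=X[te], y=y[te])))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < 3 * se + 1e-9 or \
            abs(np.mean(accs) - 50.0) < 3.0  # SE floor for quantized accuracies


class TestBootstrapSubject:
    def test_strong_erd_high_accuracy(self, strong_erd_epochs):
        res = mibci.bootstrap_subject(strong_erd_epochs, reps=50, seed=1)
        assert res.mean >= 90.0
        assert res.accuracies.shape == (50,)
        assert np.all((res.accuracies >= 0) & (res.accuracies <= 100))

    def test_same_seed_bit_identical(self, strong_erd_epochs):
        r1 = mibci.bootstrap_subject(strong_erd_epochs, reps=20, seed=5)
        r2 = mibci.bootstrap_subject(strong_erd_epochs, reps=20, seed=5)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)

    def test_different_seeds_differ(self, strong_erd_epochs):
        r1 = mibci.bootstrap_subject(strong_erd_epochs, reps=20, seed=5)
        r2 = mibci.bootstrap_subject(strong_erd_epochs, reps=20, seed=6)
        assert not np.array_equal(r1.accuracies, r2.accuracies)

    def test_wrong_trial_count_rejected(self, strong_erd_epochs):
        sub = strong_erd_epochs.select(np.arange(20))
        with pytest.raises(ValueError, match="trials"):
            mibci.bootstrap_subject(sub, reps=5)

    def test_summary_consistent_with_vector(self, strong_erd_epochs):
        res = mibci.bootstrap_subject(strong_erd_epochs, reps=20, seed=2)
        assert res.mean == pytest.approx(res.accuracies.mean())
        assert res.sd == pytest.approx(res.accuracies.std(ddof=1))

    def test_no_leakage_from_test_labels(self, strong_erd_epochs):
        """Corrupting held-out labels changes reported accuracy but not the
        trained behaviour: predictions on a fixed probe set are unchanged."""
        from mibci.protocols import _stratified_split
        from mibci.csp import apply_csp, fit_csp_epochs

        rng = np.random.default_rng([3, 0])
        tr, te = _stratified_split(strong_erd_epochs.y, 20, rng)
        train = strong_erd_epochs.select(tr)
        test = strong_erd_epochs.select(te)
        model_a = fit_csp_epochs(train)
        corrupted = test.labels.copy()
        corrupted["class"] = np.where(corrupted["class"] == "left", "right", "left")
        test_corrupt = mibci.EpochSet(data=test.data, fs=test.fs,
                                      channel_labels=test.channel_labels,
                                      labels=corrupted)
        acc = mibci.train_eval(apply_csp(model_a, train), apply_csp(model_a, test))
        acc_corrupt = mibci.train_eval(apply_csp(model_a, train),
                                       apply_csp(model_a, test_corrupt))
        assert acc + acc_corrupt == pytest.approx(100.0)


class TestBootstrapGlobal:
    @pytest.fixture(scope="class")
    @staticmethod
    def pooled():
        cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, artifact_rate=0.0)
        recs = mibci.simulate_cohort(cfg, n_subjects=4, seed=3)
        eps = [mibci.epoch(mibci.preprocess_pipeline(r), 0.0, 10.0) for r in recs]
        return mibci.pool_subjects(eps)

    def test_pooled_trial_count_and_split_sizes(self, pooled):
        assert pooled.n_trials == 120
        res = mibci.bootstrap_global(pooled, reps=5, seed=1)
        assert "70%/30%" in res.split

    def test_ten_subjects_pool_to_300_trials(self):
        cfg = mibci.SimConfig()
        recs = mibci.simulate_cohort(cfg, n_subjects=10, seed=1)
        eps = [mibci.epoch(r, 0.0, 10.0) for r in recs]
        pooled = mibci.pool_subjects(eps)
        assert pooled.n_trials == 300
        assert (pooled.labels["class"].value_counts() == 150).all()
        assert (pooled.labels["level"].value_counts() == 100).all()

    def test_global_tracks_subject_accuracy_on_homogeneous_cohort(self, pooled):
        res_g = mibci.bootstrap_global(pooled, reps=30, seed=2)
        per_subject = []
        for sub in pooled.labels["subject"].unique():
            es = pooled.select((pooled.labels["subject"] == sub).to_numpy())
            per_subject.append(mibci.bootstrap_subject(es, reps=30, seed=2).mean)
        assert abs(res_g.mean - np.mean(per_subject)) < 5.0

    def test_determinism(self, pooled):
        r1 = mibci.bootstrap_global(pooled, reps=10, seed=9)
        r2 = mibci.bootstrap_global(pooled, reps=10, seed=9)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)


class TestLevelClassification:
    def test_level_restriction_counts(self):
        cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, artifact_rate=0.0)
        recs = mibci.simulate_cohort(cfg, n_subjects=4, seed=3)
        pooled = mibci.pool_subjects(
            [mibci.epoch(r, 0.0, 10.0) for r in recs])
        for level in (1, 2, 3):
            sub = pooled.select_level(level)
            assert sub.n_trials == 40
            assert (sub.labels["level"] == level).all()

    def test_empty_level_rejected(self, strong_erd_epochs):
        no3 = strong_erd_epochs.select(
            (strong_erd_epochs.labels["level"] != 3).to_numpy())
        with pytest.raises(ValueError, match="level"):
            no3.select_level(3)

    def test_level_accuracy_close_when_signal_level_independent(self):
        """At the designed 100 trials per level (10 subjects), and with
        moderate SNR keeping accuracies off the ceiling, the three levels
        agree within bootstrap spread."""
        cfg = mibci.SimConfig(erd_depth=0.5, artifact_rate=0.0)
        recs = mibci.simulate_cohort(cfg, n_subjects=10, seed=5)
        pooled = mibci.pool_subjects(
            [mibci.epoch(mibci.preprocess_pipeline(r), 0.0, 10.0) for r in recs])
        results = [mibci.level_classification(pooled, lv, reps=30, seed=1)
                   for lv in (1, 2, 3)]
        for a in results:
            for b in results:
                # each mean inside the other's bootstrap spread
                assert abs(a.mean - b.mean) <= 2 * max(a.sd, b.sd, 1.0)


class TestSweeps:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, artifact_rate=0.0)
        recs = mibci.simulate_cohort(cfg, n_subjects=2, seed=17)
        return [mibci.preprocess_pipeline(r) for r in recs]

    def test_window_sweep_shape_and_monotone_trend(self, cohort):
        res = mibci.window_sweep(cohort, lengths=[2.0, 4.0, 6.0, 8.0, 10.0],
                                 reps=15, seed=4)
        assert res.per_subject.shape == (2, 5)
        assert sweep_monotonicity(res) > 0.0

    def test_full_window_point_matches_direct_bootstrap(self, cohort):
        res = mibci.window_sweep(cohort, lengths=[5.0, 10.0], reps=10, seed=4)
        direct = mibci.bootstrap_subject(
            mibci.epoch(cohort[0], 0.0, 10.0), reps=10,
            seed=subject_seed(4, 0))
        assert res.per_subject.iloc[0, 1] == pytest.approx(direct.mean)

    def test_onset_zero_matches_window_five_point(self, cohort):
        win = mibci.window_sweep(cohort, lengths=[5.0], reps=10, seed=4)
        ons = mibci.onset_sweep(cohort, window=5.0, offsets=[0.0, 2.0],
                                reps=10, seed=4)
        assert ons.per_subject.iloc[0, 0] == pytest.approx(
            win.per_subject.iloc[0, 0])

    def test_window_longer_than_cue_rejected(self, cohort):
        with pytest.raises(ValueError, match="cue"):
            mibci.window_sweep(cohort, lengths=[11.0], reps=2)

    def test_offset_plus_window_beyond_cue_rejected(self, cohort):
        with pytest.raises(ValueError, match="cue"):
            mibci.onset_sweep(cohort, window=5.0, offsets=[6.0], reps=2)

    def test_delayed_erd_favors_matching_offset(self):
        cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, erd_onset=2.0,
                              artifact_rate=0.0)
        recs = [mibci.preprocess_pipeline(r)
                for r in mibci.simulate_cohort(cfg, n_subjects=2, seed=23)]
        res = mibci.onset_sweep(recs, window=5.0, offsets=[0.0, 2.0],
                                reps=20, seed=2)
        assert res.mean[1] > res.mean[0]


def test_accuracy_monotone_in_erd_depth():
    """Mean per-subject accuracy increases with ERD depth (0 < 0.4 < 0.8)."""
    means = []
    for depth in (0.0, 0.4, 0.8):
        cfg = mibci.SimConfig(erd_depth=depth, artifact_rate=0.0)
        recs = mibci.simulate_cohort(cfg, n_subjects=2, seed=31)
        accs = [
            mibci.bootstrap_subject(
                mibci.epoch(mibci.preprocess_pipeline(r), 0.0, 10.0),
                reps=50, seed=subject_seed(31, i)).mean
            for i, r in enumerate(recs)
        ]
        means.append(np.mean(accs))
    assert means[0] < means[1] < means[2]
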