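"""Attention classification, ROC, information transfer rates, noise floor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfdecode.datamodel import LagSpec, LinearModel, TimeSeries
from trfdecode.decoding import (
    DecisionRecord,
    accuracy_from_records,
    apply_forward_classifier,
    class_separability,
    classify_argmax,
    noise_floor,
    nykopp_itr,
    phase_randomize,
    roc_from_decisions,
    segment_correlation_features,
    train_forward_classifier,
    wolpaw_itr,
)
from trfdecode.exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)


def _records_from_decisions(decisions, labels):
    recs = []
    for i, (d, lab) in enumerate(zip(decisions, labels)):
        r = DecisionRecord(i, lab, np.atleast_1d(d), np.atleast_1d(0.0),
                           decision_value=float(d),
                           predicted_label="A" if d >= 0 else "B")
        recs.append(r)
    return recs


class TestSegmentFeatures:
    def _backward_model(self, n_ch, fs=64.0):
        spec = LagSpec.for_direction(0.5, fs, "backward")
        w = np.zeros((spec.n_lags, n_ch, 1))
        w[-1, 0, 0] = 1.0  # reconstruct from channel 0 at lag 0
        return LinearModel(w, "backward", spec, fs)

    def test_segment_count_50s_trial_30s_window_1s_step(self, small_dataset):
        kernel = small_dataset.kernel
        fs = 64.0
        n = int(50 * fs)
        eeg = TimeSeries(np.random.default_rng(0).standard_normal((n, 2)), fs)
        env = TimeSeries(np.random.default_rng(1).standard_normal((n, 1)), fs)
        model = self._backward_model(2)
        recs = segment_correlation_features(model, eeg, env, env, "A",
                                            seg_len_s=30.0, step_s=1.0)
        assert len(recs) == 21  # floor((50-30)/1) + 1

    def test_full_trial_window_gives_one_segment(self):
        fs = 64.0
        n = int(20 * fs)
        eeg = TimeSeries(np.random.default_rng(2).standard_normal((n, 2)), fs)
        env = TimeSeries(np.random.default_rng(3).standard_normal((n, 1)), fs)
        model = self._backward_model(2)
        recs = segment_correlation_features(model, eeg, env, env, "A",
                                            seg_len_s=20.0)
        assert len(recs) == 1

    def test_window_shorter_than_kernel_rejected(self):
        fs = 64.0
        eeg = TimeSeries(np.zeros((640, 2)), fs)
        env = TimeSeries(np.zeros((640, 1)), fs)
        model = self._backward_model(2)
        with pytest.raises(InvalidParameterError):
            segment_correlation_features(model, eeg, env, env, "A",
                                         seg_len_s=0.25)

    def test_attended_stream_wins_every_segment_on_clean_data(self, clean_dataset):
        """With near-noiseless EEG and zero unattended gain, the attended
        correlation dominates in every decoding window."""
        from trfdecode.crossval import Trial, cross_validate
        from trfdecode.estimators import sweep_geometric_lambdas

        trials = [Trial(t.eeg, t.attended_env, t.unattended_env, t.attended)
                  for t in clean_dataset.trials]
        rep = cross_validate(trials, "backward", "ridge",
                             sweep_geometric_lambdas(1e-4, 100.0, 4),
                             n_folds=4, seed=0)
        model = rep.models[0]
        mu_x, sd_x, *_ = rep.fold_norms[0]
        ti = rep.folds.trials_in(0)[0]
        tr = trials[ti]
        eeg = tr.eeg.copy_with((tr.eeg.samples - mu_x) / sd_x)
        env_a = tr.attended_env if tr.label == "A" else tr.unattended_env
        env_b = tr.unattended_env if tr.label == "A" else tr.attended_env
        recs = segment_correlation_features(model, eeg, env_a, env_b,
                                            tr.label, seg_len_s=5.0)
        for r in recs:
            classify_argmax(r)
            assert r.predicted_label == tr.label


class TestArgmaxClassifier:
    def test_basic_decision(self):
        r = DecisionRecord(0, "A", np.array([0.2]), np.array([0.1]))
        assert classify_argmax(r) == "A"
        assert r.decision_value == pytest.approx(0.1)
        assert not r.tie

    def test_tie_goes_to_a_with_flag(self):
        r = DecisionRecord(0, "B", np.array([0.3]), np.array([0.3]))
        assert classify_argmax(r) == "A"
        assert r.tie

    def test_swapping_streams_negates_decision(self):
        r1 = DecisionRecord(0, "A", np.array([0.4]), np.array([-0.2]))
        r2 = DecisionRecord(0, "A", np.array([-0.2]), np.array([0.4]))
        classify_argmax(r1)
        classify_argmax(r2)
        assert r1.decision_value == pytest.approx(-r2.decision_value)


class TestForwardClassifier:
    def _toy_records(self, rng, n=40, dim=4, sep=2.0):
        recs = []
        for i in range(n):
            lab = "A" if i % 2 == 0 else "B"
            center = sep if lab == "A" else -sep
            fa = rng.normal(center, 0.3, dim)
            fb = rng.normal(-center, 0.3, dim)
            recs.append(DecisionRecord(i, lab, fa, fb))
        return recs

    def test_separable_features_classified_perfectly(self, rng):
        recs = self._toy_records(rng)
        clf = train_forward_classifier(recs)
        apply_forward_classifier(clf, recs)
        assert accuracy_from_records(recs) == 1.0

    def test_label_swap_negates_decision_values(self):
        recs = self._toy_records(np.random.default_rng(1234))
        clf = train_forward_classifier(recs)
        swapped = [DecisionRecord(r.segment_id,
                                  "B" if r.true_label == "A" else "A",
                                  r.features_b, r.features_a)
                   for r in recs]
        clf2 = train_forward_classifier(swapped)
        apply_forward_classifier(clf, recs)
        d1 = [r.decision_value for r in recs]
        probe = [DecisionRecord(r.segment_id, r.true_label, r.features_b,
                                r.features_a) for r in recs]
        apply_forward_classifier(clf2, probe)
        d2 = [r.decision_value for r in probe]
        np.testing.assert_allclose(d1, np.negative(d2), atol=1e-4)

    def test_accepts_two_by_66_channel_feature_vectors(self, rng):
        recs = self._toy_records(rng, n=30, dim=66)
        assert recs[0].features.size == 132
        clf = train_forward_classifier(recs)
        apply_forward_classifier(clf, recs)
        assert accuracy_from_records(recs) == 1.0

    def test_single_class_rejected(self, rng):
        recs = [DecisionRecord(i, "A", rng.normal(size=2), rng.normal(size=2))
                for i in range(6)]
        with pytest.raises(InvalidInputError):
            train_forward_classifier(recs)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        recs = _records_from_decisions([1.0, 2.0, -1.0, -2.0],
                                       ["A", "A", "B", "B"])
        roc = roc_from_decisions(recs)
        assert roc.auc == pytest.approx(1.0)

    def test_endpoints_and_monotonicity(self, rng):
        recs = _records_from_decisions(rng.normal(size=60),
                                       ["A", "B"] * 30)
        roc = roc_from_decisions(recs)
        assert roc.tpr[0] == 0.0 and roc.fpr[0] == 0.0
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.fraction_at_or_above) >= 0)

    def test_label_independent_decisions_near_chance(self, rng):
        n = 3000
        recs = _records_from_decisions(rng.normal(size=n),
                                       [rng.choice(["A", "B"]) for _ in range(n)])
        roc = roc_from_decisions(recs)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        d = rng.normal(size=80)
        labels = ["A" if v > 0 else "B" for v in rng.normal(size=80)]
        recs = _records_from_decisions(d, labels)
        roc = roc_from_decisions(recs)
        y = np.array([lab == "A" for lab in labels])
        assert roc.auc == pytest.approx(roc_auc_score(y, d), abs=1e-9)

    def test_accuracy_at_zero_threshold_consistent(self, rng):
        d = rng.normal(size=101)
        labels = ["A" if rng.uniform() > 0.4 else "B" for _ in d]
        recs = _records_from_decisions(d, labels)
        acc = accuracy_from_records(recs)
        # reconstruct accuracy from the ROC counts at threshold 0
        y = np.array([lab == "A" for lab in labels])
        tp = ((d >= 0) & y).sum()
        tn = ((d < 0) & ~y).sum()
        assert acc == pytest.approx((tp + tn) / d.size)

    def test_one_class_rejected(self):
        recs = _records_from_decisions([0.1, 0.3], ["A", "A"])
        with pytest.raises(DegenerateInputError):
            roc_from_decisions(recs)

    def test_auc_tracks_accuracy_across_snr(self, rng):
        """Across difficulty levels, AUC and accuracy rank the same way."""
        aucs, accs = [], []
        for sep in (0.1, 0.4, 0.8, 1.5, 3.0):
            d = np.concatenate([rng.normal(sep, 1.0, 150),
                                rng.normal(-sep, 1.0, 150)])
            labels = ["A"] * 150 + ["B"] * 150
            recs = _records_from_decisions(d, labels)
            aucs.append(roc_from_decisions(recs).auc)
            accs.append(accuracy_from_records(recs))
        assert np.corrcoef(np.argsort(aucs), np.argsort(accs))[0, 1] > 0.9


class TestWolpawITR:
    def test_reference_points(self):
        assert wolpaw_itr(0.5, 2, 1.0) == pytest.approx(0.0)
        assert wolpaw_itr(1.0, 2, 2.0) == pytest.approx(2.0)
        expected = 1 + 0.9 * np.log2(0.9) + 0.1 * np.log2(0.1)
        assert wolpaw_itr(0.9, 2, 1.0) == pytest.approx(expected)
        assert wolpaw_itr(0.9, 2, 1.0) == pytest.approx(0.531, abs=5e-4)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.51, 0.99), st.floats(0.51, 0.99))
    def test_strictly_increasing_in_accuracy(self, p1, p2):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-9:
            assert wolpaw_itr(hi, 2, 1.0) > wolpaw_itr(lo, 2, 1.0)

    def test_binary_closed_form_on_grid(self):
        v = 3.0
        for p in np.linspace(0.01, 0.99, 25):
            h = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
            assert wolpaw_itr(p, 2, v) == pytest.approx(v * (1 - h), abs=1e-12)

    def test_invalid_accuracy(self):
        with pytest.raises(InvalidParameterError):
            wolpaw_itr(1.2, 2, 1.0)


class TestNykoppITR:
    def test_perfect_classifier_reaches_channel_capacity(self, rng):
        d = np.concatenate([rng.uniform(0.5, 1, 30), rng.uniform(-1, -0.5, 30)])
        labels = ["A"] * 30 + ["B"] * 30
        recs = _records_from_decisions(d, labels)
        res = nykopp_itr(recs, v=2.0)
        assert res.nykopp_bits_per_min == pytest.approx(2.0)
        assert res.nykopp_fraction_classified == 1.0

    def test_label_independent_decisions_within_permutation_bound(self, rng):
        n = 400
        d = rng.normal(size=n)
        labels = ["A" if rng.uniform() < 0.5 else "B" for _ in range(n)]
        recs = _records_from_decisions(d, labels)
        observed = nykopp_itr(recs, v=1.0).nykopp_bits_per_min
        null = []
        for _ in range(30):
            perm = rng.permutation(n)
            null_recs = _records_from_decisions(d, [labels[i] for i in perm])
            null.append(nykopp_itr(null_recs, v=1.0).nykopp_bits_per_min)
        assert observed <= np.quantile(null, 0.99) + 1e-9

    def test_nykopp_dominates_wolpaw_on_synthetic_decisions(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = np.concatenate([r.normal(0.6, 1.0, 120), r.normal(-0.6, 1.0, 120)])
            labels = ["A"] * 120 + ["B"] * 120
            recs = _records_from_decisions(d, labels)
            res = nykopp_itr(recs, v=2.0)
            assert res.nykopp_bits_per_min >= res.wolpaw_bits_per_min - 1e-9


class TestPhaseRandomization:
    def test_power_spectrum_preserved(self, rng):
        x = rng.standard_normal((512, 3))
        surr = phase_randomize(x, rng)
        mag_in = np.abs(np.fft.rfft(x, axis=0))
        mag_out = np.abs(np.fft.rfft(surr, axis=0))
        np.testing.assert_allclose(mag_out, mag_in, rtol=1e-8)

    def test_output_is_real_and_decorrelated(self):
        # broadband input: randomizing phases destroys the waveform alignment
        # (a narrowband signal would merely be phase-shifted)
        local = np.random.default_rng(77)
        x = local.standard_normal((4096, 1))
        surr = phase_randomize(x, local)
        assert np.isrealobj(surr)
        from trfdecode.datamodel import pearson_r

        assert abs(pearson_r(surr[:, 0], x[:, 0])) < 0.2

    def test_noise_floor_contains_zero_and_roughly_symmetric(self, small_dataset):
        """The null distribution of reconstruction accuracy straddles zero."""
        from trfdecode.crossval import Trial, cross_validate, regression_accuracy_backward
        from trfdecode.estimators import sweep_geometric_lambdas

        trials = [Trial(t.eeg, t.attended_env, t.unattended_env, t.attended)
                  for t in small_dataset.trials]
        rep = cross_validate(trials, "backward", "ridge",
                             sweep_geometric_lambdas(1e-3, 100.0, 4),
                             n_folds=4, seed=2)
        model = rep.models[0]
        ti = rep.folds.trials_in(0)[0]
        tr = trials[ti]
        mu_x, sd_x, *_ = rep.fold_norms[0]
        eeg_norm = tr.eeg.copy_with((tr.eeg.samples - mu_x) / sd_x)

        def score(surrogate_eeg):
            return regression_accuracy_backward(model, surrogate_eeg,
                                                tr.attended_env)

        lo, hi, scores = noise_floor(score, eeg_norm, n_randomizations=60,
                                     seed=5)
        assert lo < 0 < hi
        assert abs(np.median(scores)) < 0.1
        # the model's true score sits above the null band
        assert score(eeg_norm) > hi

    def test_floor_width_shrinks_with_test_length(self, rng):
        from trfdecode.datamodel import pearson_r as pr

        def width(n, seed):
            r = np.random.default_rng(seed)
            x = TimeSeries(r.standard_normal((n, 1)), 64.0)
            y = r.standard_normal(n)
            lo, hi, _ = noise_floor(lambda s: pr(s.samples[:, 0], y), x,
                                    n_randomizations=80, seed=seed)
            return hi - lo

        w1 = np.mean([width(500, s) for s in range(3)])
        w4 = np.mean([width(2000, s) for s in range(3)])
        assert 1.4 < w1 / w4 < 2.9  # ~ sqrt(4) = 2

    def test_few_randomizations_warns(self, rng):
        x = TimeSeries(rng.standard_normal((256, 1)), 64.0)
        with pytest.warns(RuntimeWarning):
            noise_floor(lambda s: 0.0, x, n_randomizations=5, seed=0)


class TestClassSeparability:
    def test_identical_classes_zero_difference(self):
        recs = []
        for i in range(10):
            lab = "A" if i % 2 else "B"
            recs.append(DecisionRecord(i, lab, np.array([0.3 + 0.01 * i]),
                                       np.array([0.3 + 0.01 * i])))
        diff, spread = class_separability(recs)
        assert diff == pytest.approx(0.0)

    def test_shift_moves_mean_not_spread(self, rng):
        base = rng.normal(0.2, 0.05, 20)
        recs1, recs2 = [], []
        for i, b in enumerate(base):
            recs1.append(DecisionRecord(i, "A", np.array([b]), np.array([0.0])))
            recs2.append(DecisionRecord(i, "A", np.array([b + 0.1]),
                                        np.array([0.0])))
        d1, s1 = class_separability(recs1)
        d2, s2 = class_separability(recs2)
        assert d2 - d1 == pytest.approx(0.1, abs=1e-12)
        assert s2 == pytest.approx(s1)

    def test_lower_spread_wins_at_equal_mean_difference(self, rng):
        """Equal class-mean separation but smaller within-class spread gives
        higher argmax accuracy — the mechanism by which a scheme with better
        regression accuracy can fail to classify better."""
        def simulate(spread, seed):
            r = np.random.default_rng(seed)
            recs = []
            for i in range(4000):
                att = r.normal(0.2, spread)
                un = r.normal(0.1, spread)
                recs.append(DecisionRecord(i, "A", np.array([att]),
                                           np.array([un])))
            for rec in recs:
                classify_argmax(rec)
            return accuracy_from_records(recs)

        assert simulate(0.05, 1) > simulate(0.15, 1)
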