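"""Tests of the balanced, cross-validated history decoding protocol."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import trialhist as th
from trialhist.decoding import (
    DecoderProtocol,
    DecodingResult,
    _one_hot,
    _stratified_folds,
    balanced_subsample,
    cross_temporal_matrix,
    decode_timecourse,
    decode_twoback,
    default_penalty_grid,
    fit_timepoint_decoder,
    make_plan,
    marginal_accuracy,
    ridge_logistic_path,
    accuracy_by_iti,
)


class TestBalancedSubsample:
    def test_balanced_input_includes_everything(self, rng):
        y = np.repeat(list("ABCD"), 10).astype(object)
        rounds = balanced_subsample(y, 5, rng)
        for r in rounds:
            assert len(r) == 40
            np.testing.assert_array_equal(np.sort(r), np.arange(40))

    def test_majority_inclusion_counts_within_one(self, rng):
        y = np.array(["A"] * 40 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10, dtype=object)
        rounds = balanced_subsample(y, 20, rng)
        usage = np.zeros(40)
        for r in rounds:
            assert len(r) == 40
            members, counts = np.unique(y[r], return_counts=True)
            assert (counts == 10).all()
            for idx in r:
                if idx < 40:
                    usage[idx] += 1
        # each majority item used 20*10/40 = 5 times, +/- 1
        assert usage.min() >= 4 and usage.max() <= 6

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError):
            balanced_subsample(np.array(["A"] * 5, dtype=object), 3, rng)


class TestFoldHygiene:
    def test_folds_partition_rounds(self, rng):
        y = np.repeat(list("ABCD"), 12).astype(object)
        plan = make_plan(y, DecoderProtocol(n_rounds=3), rng)
        for round_idx, folds in plan:
            all_pos = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(all_pos, np.arange(len(round_idx)))
            for i in range(len(folds)):
                for j in range(i + 1, len(folds)):
                    assert not set(folds[i]) & set(folds[j])

    def test_protocol_consistency_checked(self):
        with pytest.raises(ValueError):
            DecoderProtocol(n_folds=8, train_fraction=0.9)


class TestSolverOracle:
    def test_matches_sklearn_at_fixed_penalty(self, rng):
        # independent optimizer oracle for the ridge-logistic solver
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(float)
        for lam in (1e-2, 1.0, 1e2):
            W = ridge_logistic_path(X, y[:, None], np.array([lam]),
                                    max_iter=100, tol=1e-10)
            ref = LogisticRegression(C=1.0 / lam, tol=1e-12, max_iter=5000)
            ref.fit(X, y)
            np.testing.assert_allclose(W[0, 0, :-1], ref.coef_[0], atol=2e-4)
            np.testing.assert_allclose(W[0, 0, -1], ref.intercept_[0], atol=2e-4)

    def test_cv_accuracy_matches_reference_protocol(self, rng):
        # tiny 2-class problem, exhaustive CV with sklearn as the reference
        X = rng.normal(size=(32, 3))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=32) > 0, "R", "L").astype(object)
        protocol = DecoderProtocol(n_rounds=2, penalty_grid=np.array([1.0]))
        plan = make_plan(y, protocol, np.random.default_rng(1))
        acc, _, _, _ = fit_timepoint_decoder(
            X, y, protocol, np.random.default_rng(1), classes=["L", "R"], plan=plan
        )
        ref_accs = []
        for round_idx, folds in plan:
            y_r = y[round_idx]
            for f in range(len(folds)):
                test = folds[f]
                train = np.concatenate(
                    [folds[g] for g in range(len(folds)) if g != f]
                )
                Xtr = X[round_idx[train]]
                mu, sd = Xtr.mean(0), Xtr.std(0)
                sd = np.where(sd < 1e-12, 1.0, sd)
                clf = LogisticRegression(C=1.0, tol=1e-10, max_iter=5000)
                clf.fit((Xtr - mu) / sd, y_r[train])
                pred = clf.predict((X[round_idx[test]] - mu) / sd)
                ref_accs.append((pred == y_r[test]).mean())
        n_test = len(plan[0][1][0])
        assert abs(acc - np.mean(ref_accs)) <= 1.0 / n_test


class TestTimepointDecoder:
    def test_separable_blobs(self, rng):
        n = 60
        X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(6, 1, (n, 4))])
        y = np.array(["A"] * n + ["B"] * n, dtype=object)
        acc, _, _, _ = fit_timepoint_decoder(
            X, y, DecoderProtocol(n_rounds=3), rng
        )
        assert acc >= 0.95

    def test_shuffled_four_class_near_chance(self, rng):
        X = rng.normal(size=(120, 8))
        y = np.repeat(list("ABCD"), 30).astype(object)
        rng.shuffle(y)
        acc, _, _, _ = fit_timepoint_decoder(
            X, y, DecoderProtocol(n_rounds=5), rng
        )
        assert 0.15 < acc < 0.35

    def test_duplicated_features_equivalent(self, rng):
        X = rng.normal(size=(80, 5))
        y = np.where(X[:, 0] > 0, "A", "B").astype(object)
        protocol = DecoderProtocol(n_rounds=3)
        plan = make_plan(y, protocol, np.random.default_rng(0))
        a1, _, _, _ = fit_timepoint_decoder(
            X, y, protocol, rng, classes=["A", "B"], plan=plan
        )
        a2, _, _, _ = fit_timepoint_decoder(
            np.hstack([X, X]), y, protocol, rng, classes=["A", "B"], plan=plan
        )
        assert abs(a1 - a2) < 0.05


class TestDecodeTimecourse:
    def test_history_population_beats_shuffle_in_early_iti(
        self, base_tensor, quick_protocol
    ):
        tps = np.array([5, 15, 25])  # early-ITI timepoints
        res = decode_timecourse(
            base_tensor, quick_protocol, seed=0, timepoints=tps
        )
        assert len(res.classes) == 4
        assert res.accuracy.mean() > res.shuffled_accuracy.mean() + 0.2
        # confusion rows are normalized per true class
        np.testing.assert_allclose(res.confusion.sum(axis=2), 1.0, atol=1e-9)
        assert ((res.accuracy >= 0) & (res.accuracy <= 1)).all()

    def test_null_population_at_chance(self, null_tensor, quick_protocol):
        res = decode_timecourse(
            null_tensor, quick_protocol, seed=0, timepoints=np.array([5, 60]),
            shuffle_control=False,
        )
        assert abs(res.accuracy.mean() - 0.25) < 0.12

    def test_determinism(self, base_tensor, quick_protocol):
        tps = np.array([10])
        a = decode_timecourse(base_tensor, quick_protocol, seed=4, timepoints=tps)
        b = decode_timecourse(base_tensor, quick_protocol, seed=4, timepoints=tps)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        np.testing.assert_array_equal(a.shuffled_accuracy, b.shuffled_accuracy)


class TestMarginalAccuracy:
    def _result_from_confusion(self, conf):
        conf = np.asarray(conf, dtype=float)[None]
        return DecodingResult(
            classes=list(th.HISTORY_LABELS), accuracy=np.array([np.nan]),
            class_accuracy=np.full((1, 4), np.nan), confusion=conf,
            shuffled_accuracy=None, timepoint_index=np.array([0]), models=None,
        )

    def test_perfect_predictions(self):
        res = self._result_from_confusion(np.eye(4))
        assert marginal_accuracy(res, "choice")[0] == pytest.approx(1.0)
        assert marginal_accuracy(res, "outcome")[0] == pytest.approx(1.0)

    def test_uniform_predictions(self):
        res = self._result_from_confusion(np.full((4, 4), 0.25))
        assert marginal_accuracy(res, "choice")[0] == pytest.approx(0.5)
        assert marginal_accuracy(res, "outcome")[0] == pytest.approx(0.5)

    def test_no_deficit_vs_dedicated_binary_decoder(
        self, base_tensor, quick_protocol
    ):
        tp = np.array([10])
        res4 = decode_timecourse(
            base_tensor, quick_protocol, seed=0, timepoints=tp,
            shuffle_control=False,
        )
        marg = marginal_accuracy(res4, "choice")[0]
        labels = base_tensor.labels()
        mask = np.array([l is not None for l in labels])
        y_bin = np.array([l[-1] for l in labels[mask]], dtype=object)
        rng = np.random.default_rng(0)
        acc_bin, _, _, _ = fit_timepoint_decoder(
            base_tensor.activity[mask][:, 10, :], y_bin, quick_protocol, rng
        )
        assert marg > acc_bin - 0.1


class TestCrossTemporal:
    def test_diagonal_matches_timecourse(self, base_tensor):
        protocol = DecoderProtocol(n_rounds=2)
        tps = np.array([5, 40, 80])
        mat, res = cross_temporal_matrix(
            base_tensor, protocol, seed=1, timepoints=tps
        )
        np.testing.assert_allclose(np.diag(mat), res.accuracy, atol=1e-12)

    def test_stable_code_generalizes(self):
        cfg = th.SessionConfig(
            n_trials=170, n_video_components=6,
            behavior=th.BehaviorParams(beta1=0.8),
            population=th.PopulationConfig(
                n_neurons=12, frac_history=0.7, frac_movement=0.0,
                frac_mixed=0.0, noise_sd=0.4, history_regime="stable",
            ),
        )
        s = th.make_session(cfg, seed=9)
        t = th.align_activity(s.recording.spike_rate, 30.0, s.trial_table,
                              smooth=True)
        tps = np.array([5, 25, 45])  # all within the ITI
        mat, _ = cross_temporal_matrix(
            t, DecoderProtocol(n_rounds=3), seed=0, timepoints=tps
        )
        off = mat[~np.eye(3, dtype=bool)]
        assert off.mean() > 0.6  # time-constant code -> near-uniform matrix


class TestAccuracyByIti:
    def test_decaying_code_loses_accuracy_at_long_itis(self):
        cfg = th.SessionConfig(
            n_trials=260, n_video_components=6,
            behavior=th.BehaviorParams(beta1=0.8),
            population=th.PopulationConfig(
                n_neurons=14, frac_history=0.7, frac_movement=0.0,
                frac_mixed=0.0, noise_sd=0.4, iti_decay_tau=1.5,
            ),
        )
        s = th.make_session(cfg, seed=13)
        t = th.align_activity(s.recording.spike_rate, 30.0, s.trial_table,
                              smooth=True)
        edges = np.array([0.0, 3.5, 40.0])
        accs = accuracy_by_iti(
            t, edges, DecoderProtocol(n_rounds=2), seed=0,
            timepoints_stride=15,
        )
        assert accs[0] is not None and accs[1] is not None
        assert accs[0] > accs[1]

    def test_empty_bin_reported_absent(self, base_tensor):
        edges = np.array([0.0, 1e-6, 100.0])
        accs = accuracy_by_iti(
            base_tensor, edges, DecoderProtocol(n_rounds=2), seed=0,
            timepoints_stride=40,
        )
        assert accs[0] is None
        assert accs[1] is not None


class TestTwoBackDecoding:
    def test_oneback_code_gives_twoback_chance(self, base_tensor):
        res = decode_twoback(
            base_tensor, DecoderProtocol(n_rounds=3), seed=0,
            timepoints=np.array([10]),
        )
        assert len(res.classes) == 4
        assert abs(res.accuracy.mean() - 0.25) < 0.15

    def test_eligibility_excludes_after_withdrawals(self, base_tensor):
        labels2 = base_tensor.labels(back=2)
        n_eligible = sum(l is not None for l in labels2)
        res = decode_twoback(
            base_tensor, DecoderProtocol(n_rounds=2), seed=0,
            timepoints=np.array([0]),
        )
        assert res is not None
        assert n_eligible < base_tensor.n_trials
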