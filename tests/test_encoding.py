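"""Tests of the encoding design matrix, ridge fit and variance partition."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

import trialhist as th
from trialhist.encoding import (
    ALL_VARIABLES,
    DesignMatrix,
    _lagged,
    build_design_matrix,
    default_lambda_grid,
    fit_ridge_per_neuron,
    orthogonalize_video,
    shuffle_variable_blocks,
    timecourse_r2,
    variance_partition,
)


@pytest.fixture(scope="module")
def small_session():
    cfg = th.SessionConfig(
        n_trials=80, n_video_components=10,
        population=th.PopulationConfig(n_neurons=8, noise_sd=0.3),
    )
    return th.make_session(cfg, seed=21)


@pytest.fixture(scope="module")
def small_tensor(small_session):
    return th.align_activity(
        small_session.recording.fluorescence, 30.0,
        small_session.trial_table, smooth=False,
    )


@pytest.fixture(scope="module")
def small_design(small_session, small_tensor):
    return build_design_matrix(small_session, small_tensor)


class TestDesignMatrix:
    def test_block_sizes(self, small_design):
        d = small_design
        T = d.n_timepoints
        assert T == 129
        assert d.blocks["trial_time"].stop - d.blocks["trial_time"].start == T
        assert d.blocks["choice"].stop - d.blocks["choice"].start == T
        assert d.blocks["trial_history"].stop - d.blocks["trial_history"].start == 4 * T
        # 60 six-degree bins per head-orientation angle
        assert d.blocks["head_angles"].stop - d.blocks["head_angles"].start == 180
        # stimulus kernel: lags 0..0.5 s inclusive at 30 Hz
        assert d.blocks["stimulus_events"].stop - d.blocks["stimulus_events"].start == 16
        # poke kernels: lags -0.5..+1.0 s for each of three ports
        assert d.blocks["pokes"].stop - d.blocks["pokes"].start == 3 * 46
        assert d.blocks["video"].stop - d.blocks["video"].start == 10
        assert len(d.column_map) == d.n_columns

    def test_kernel_blocks_binary_and_angle_one_hot(self, small_design):
        d = small_design
        for var in ("trial_time", "choice", "outcome", "trial_history",
                    "stimulus_events", "pokes", "head_angles", "chest_position"):
            block = d.X[:, d.blocks[var]]
            assert set(np.unique(block)) <= {0.0, 1.0}
        for a in range(3):
            cols = d.X[:, d.blocks["head_angles"]][:, a * 60:(a + 1) * 60]
            np.testing.assert_array_equal(cols.sum(axis=1), 1.0)
        np.testing.assert_array_equal(
            d.X[:, d.blocks["chest_position"]].sum(axis=1), 1.0
        )

    def test_unknown_variable_rejected(self, small_session, small_tensor):
        with pytest.raises(ValueError, match="unknown"):
            build_design_matrix(small_session, small_tensor, variables=["nope"])

    def test_lagged_index_arithmetic(self):
        # a single event: 1s exactly on the lag diagonal
        ev = np.zeros((1, 20))
        ev[0, 7] = 1.0
        lags = np.arange(-2, 4)
        out = _lagged(ev, lags).reshape(20, len(lags))
        for j, l in enumerate(lags):
            expect = np.zeros(20)
            if 0 <= 7 + l < 20:
                expect[7 + l] = 1.0
            np.testing.assert_array_equal(out[:, j], expect)

    def test_default_video_component_count(self, base_session):
        # full default design retains the top 200 components per stream
        tensor = th.align_activity(
            base_session.recording.fluorescence, 30.0,
            base_session.trial_table, smooth=False,
        ).select_phase("action")
        cfg = th.SessionConfig()
        assert cfg.n_video_components == 200
        d = build_design_matrix(base_session, tensor,
                                variables=["trial_time", "video", "motion_energy"])
        # this session was generated with 16 components; the block takes all
        assert d.blocks["video"].stop - d.blocks["video"].start == 16


class TestOrthogonalization:
    def test_zero_inner_product_and_projection_oracle(self, small_design):
        d = orthogonalize_video(small_design)
        S = d.X[:, d.blocks["stimulus_events"]]
        for var in ("video", "motion_energy"):
            V = d.X[:, d.blocks[var]]
            assert np.abs(S.T @ V).max() < 1e-8
            # oracle: explicit projector P = I - S (S^T S)^+ S^T
            V0 = small_design.X[:, small_design.blocks[var]]
            P_V = V0 - S @ np.linalg.lstsq(S, V0, rcond=None)[0]
            np.testing.assert_allclose(V, P_V, atol=1e-8)

    def test_task_blocks_unchanged(self, small_design):
        d = orthogonalize_video(small_design)
        for var in ("trial_time", "trial_history", "stimulus_events"):
            np.testing.assert_array_equal(
                d.X[:, d.blocks[var]], small_design.X[:, small_design.blocks[var]]
            )

    def test_video_copy_of_stimulus_column_vanishes(self, small_design):
        d = DesignMatrix(
            X=small_design.X.copy(), blocks=small_design.blocks,
            column_map=small_design.column_map, n_trials=small_design.n_trials,
            n_timepoints=small_design.n_timepoints,
            frame_rate=small_design.frame_rate,
        )
        s0 = d.X[:, d.blocks["stimulus_events"].start]
        d.X[:, d.blocks["video"].start] = s0
        out = orthogonalize_video(d)
        assert np.abs(out.X[:, out.blocks["video"].start]).max() < 1e-8


def _toy_design(n_trials=20, T=10, p_extra=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = n_trials * T
    X = np.hstack([np.tile(np.eye(T), (n_trials, 1)),
                   rng.normal(size=(rows, p_extra))])
    blocks = {"trial_time": slice(0, T), "noise": slice(T, T + p_extra)}
    cmap = [("trial_time", i) for i in range(T)] + [
        ("noise", i) for i in range(p_extra)
    ]
    return DesignMatrix(X=X, blocks=blocks, column_map=cmap,
                        n_trials=n_trials, n_timepoints=T, frame_rate=30.0)


class TestRidgeFit:
    def test_closed_form_oracle(self):
        # n=200 x p=20 dense problem against the analytic ridge solution
        rng = np.random.default_rng(3)
        n, p, lam = 200, 20, 7.5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        from trialhist.encoding import ridge_solve

        w = ridge_solve(X, y[:, None], lam)[:, 0]
        w_ref = np.linalg.inv(X.T @ X + lam * np.eye(p)) @ X.T @ y
        assert np.abs(w - w_ref).max() / np.abs(w_ref).max() < 1e-6
        # independent library oracle
        sk = Ridge(alpha=lam, fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(w, sk.coef_, atol=1e-8)

    def test_fold_path_matches_direct_solution(self):
        design = _toy_design()
        rng = np.random.default_rng(5)
        w_true = rng.normal(size=design.n_columns)
        y = design.X @ w_true + 0.1 * rng.normal(size=design.n_rows)
        lam = 10.0
        fit = fit_ridge_per_neuron(design, y, n_folds=2,
                                   lambda_grid=np.array([lam]), seed=0)
        # recompute one fold directly
        T = design.n_timepoints
        test_tr = np.flatnonzero(fit.fold_of_trial == 0)
        train_tr = np.flatnonzero(fit.fold_of_trial != 0)
        rows = (train_tr[:, None] * T + np.arange(T)).ravel()
        Xtr = design.X[rows]
        ymu, ysd = y[rows].mean(), y[rows].std()
        ytr = (y[rows] - ymu) / ysd
        w_direct = np.linalg.solve(
            Xtr.T @ Xtr + lam * np.eye(design.n_columns), Xtr.T @ ytr
        )
        rows_te = (test_tr[:, None] * T + np.arange(T)).ravel()
        pred_direct = (design.X[rows_te] @ w_direct) * ysd + ymu
        np.testing.assert_allclose(
            fit.predictions[rows_te, 0], pred_direct, atol=1e-8
        )

    def test_noiseless_linear_neuron(self):
        design = _toy_design(seed=1)
        rng = np.random.default_rng(2)
        y = design.X @ rng.normal(size=design.n_columns)
        fit = fit_ridge_per_neuron(design, y, n_folds=5, seed=0)
        assert fit.cv_r2[0] >= 0.99
        assert fit.lambdas.min() >= default_lambda_grid()[0]

    def test_pure_noise_neuron(self):
        design = _toy_design(seed=2)
        y = np.random.default_rng(9).normal(size=design.n_rows)
        fit = fit_ridge_per_neuron(design, y, n_folds=5, seed=0)
        assert fit.cv_r2[0] <= 0.05  # slightly negative is allowed

    def test_infinite_shrinkage_limit(self):
        design = _toy_design(seed=3)
        rng = np.random.default_rng(4)
        y = design.X @ rng.normal(size=design.n_columns)
        fit = fit_ridge_per_neuron(design, y, n_folds=5,
                                   lambda_grid=np.array([1e12]), seed=0)
        assert fit.cv_r2[0] <= 0.01

    def test_nonfinite_neuron_skipped(self):
        design = _toy_design(seed=4)
        Y = np.random.default_rng(0).normal(size=(design.n_rows, 2))
        Y[5, 1] = np.nan
        fit = fit_ridge_per_neuron(design, Y, n_folds=4, seed=0)
        assert list(fit.skipped_neurons) == [1]
        assert np.isnan(fit.cv_r2[1]) and np.isfinite(fit.cv_r2[0])


class TestVariancePartition:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_partition():
        cfg = th.SessionConfig(
            n_trials=120, n_video_components=16,
            population=th.PopulationConfig(n_neurons=24, noise_sd=0.5),
        )
        s = th.make_session(cfg, seed=31)
        tensor = th.align_activity(
            s.recording.fluorescence, 30.0, s.trial_table, smooth=False
        ).select_phase("earlyITI")
        design = build_design_matrix(
            s, tensor,
            variables=["trial_time", "trial_history", "chest_position", "video"],
        )
        Y = tensor.activity.reshape(-1, tensor.n_neurons)
        part = variance_partition(
            design, Y, variables=["trial_history", "video"], seed=0
        )
        return s, part

    def test_class_recovery(self, planted_partition):
        s, part = planted_partition
        cls = s.ground_truth.classes
        u_hist = part.unique["trial_history"].to_numpy()
        u_vid = part.unique["video"].to_numpy()
        assert u_hist[cls == "history"].mean() > u_hist[cls == "movement"].mean()
        assert u_hist[cls == "history"].mean() > u_hist[cls == "null"].mean()
        assert u_vid[cls == "movement"].mean() > u_vid[cls == "history"].mean()

    def test_null_neurons_near_zero(self, planted_partition):
        s, part = planted_partition
        null = s.ground_truth.classes == "null"
        assert np.abs(part.unique.to_numpy()[null]).max() < 0.05
        assert np.abs(part.maximal.to_numpy()[null]).max() < 0.05

    def test_partition_bounds(self, planted_partition):
        _, part = planted_partition
        ok = part.cv_r2_full > 0.05
        for v in part.variables:
            assert (
                part.unique[v].to_numpy()[ok]
                <= part.cv_r2_full[ok] + 1e-9
            ).all()
            # maximal is recomputable from its stored parts, and is bounded
            # by the single-variable R^2 whenever the time-only model does
            # not have negative held-out R^2
            np.testing.assert_allclose(
                part.maximal[v].to_numpy(),
                part.cv_r2_single[v].to_numpy() - part.cv_r2_time_only,
            )
            valid = ok & (part.cv_r2_time_only >= 0)
            assert (
                part.maximal[v].to_numpy()[valid]
                <= part.cv_r2_single[v].to_numpy()[valid] + 1e-9
            ).all()

    def test_collinear_variables_share_maximal_not_unique(self):
        # plant a second block that is an exact copy of the first
        rng = np.random.default_rng(11)
        n_trials, T = 40, 8
        rows = n_trials * T
        sig = np.repeat(rng.normal(size=(n_trials, 3)), T, axis=0)
        X = np.hstack([np.tile(np.eye(T), (n_trials, 1)), sig, sig.copy()])
        design = DesignMatrix(
            X=X,
            blocks={"trial_time": slice(0, T), "a": slice(T, T + 3),
                    "b": slice(T + 3, T + 6)},
            column_map=[("trial_time", i) for i in range(T)]
            + [("a", i) for i in range(3)] + [("b", i) for i in range(3)],
            n_trials=n_trials, n_timepoints=T, frame_rate=30.0,
        )
        y = sig @ np.array([1.0, -0.5, 0.8]) + 0.05 * rng.normal(size=rows)
        part = variance_partition(design, y, variables=["a", "b"], seed=0)
        assert part.maximal["a"][0] > 0.5 and part.maximal["b"][0] > 0.5
        assert abs(part.unique["a"][0]) < 0.05
        assert abs(part.unique["b"][0]) < 0.05

    def test_shuffle_preserves_within_trial_structure(self):
        design = _toy_design(n_trials=6, T=4, p_extra=2, seed=6)
        rng = np.random.default_rng(0)
        X_shuf = shuffle_variable_blocks(design, ["noise"], rng)
        orig = design.X[:, design.blocks["noise"]].reshape(6, 4, 2)
        shuf = X_shuf[:, design.blocks["noise"]].reshape(6, 4, 2)
        # every shuffled trial block equals some original trial block
        matched = [
            any(np.allclose(shuf[i], orig[j]) for j in range(6)) for i in range(6)
        ]
        assert all(matched)
        np.testing.assert_array_equal(
            X_shuf[:, design.blocks["trial_time"]],
            design.X[:, design.blocks["trial_time"]],
        )

    def test_deterministic_given_seed(self):
        design = _toy_design(seed=8)
        y = np.random.default_rng(1).normal(size=design.n_rows)
        a = variance_partition(design, y, variables=["noise"], n_folds=4, seed=3)
        b = variance_partition(design, y, variables=["noise"], n_folds=4, seed=3)
        np.testing.assert_array_equal(
            a.unique.to_numpy(), b.unique.to_numpy()
        )
        np.testing.assert_array_equal(a.cv_r2_full, b.cv_r2_full)


class TestTimecourseR2:
    def test_flat_profile_for_homogeneous_signal(self):
        design = _toy_design(n_trials=60, T=6, p_extra=4, seed=9)
        rng = np.random.default_rng(10)
        w = rng.normal(size=design.n_columns)
        y = design.X @ w + 0.05 * rng.normal(size=design.n_rows)
        fit = fit_ridge_per_neuron(design, y, n_folds=5, seed=0)
        r2 = timecourse_r2(fit, design, y)
        assert r2.shape == (6, 1)
        assert np.nanmin(r2) > 0.5
        assert np.nanmax(r2) - np.nanmin(r2) < 0.4

    def test_zero_variance_timepoint_is_nan(self):
        design = _toy_design(n_trials=20, T=5, p_extra=2, seed=12)
        y = np.random.default_rng(2).normal(size=design.n_rows)
        y = y.reshape(20, 5)
        y[:, 2] = 3.14  # constant across trials at one timepoint
        fit = fit_ridge_per_neuron(design, y.ravel(), n_folds=4, seed=0)
        r2 = timecourse_r2(fit, design, y.ravel())
        assert np.isnan(r2[2, 0])
        assert np.isfinite(r2[0, 0])


class TestNoiselessSelfConsistency:
    def test_full_model_recovers_planted_neuron(self):
        cfg = th.SessionConfig(
            n_trials=100, n_video_components=10,
            population=th.PopulationConfig(n_neurons=6, noise_sd=0.0),
        )
        s = th.make_session(cfg, seed=41)
        tensor = th.align_activity(
            s.recording.spike_rate, 30.0, s.trial_table, smooth=False
        )
        design = orthogonalize_video(build_design_matrix(s, tensor))
        Y = tensor.activity.reshape(-1, tensor.n_neurons)
        fit = fit_ridge_per_neuron(design, Y, seed=0)
        hist = s.ground_truth.classes == "history"
        assert (fit.cv_r2[hist] >= 0.95).all()
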