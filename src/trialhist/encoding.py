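"""Event-kernel ridge encoding models with variance partitioning.

Single-neuron activity on the aligned trial time base is modelled as a
linear function of a block-structured design matrix:

- trial time: one indicator per aligned timepoint (a time-varying intercept),
- choice / outcome / trial history: full-trial kernels (one time-shifted
  indicator per aligned timepoint per condition),
- stimulus events: event kernel spanning lags 0 to 0.5 s,
- port pokes (left / center / right): event kernels spanning -0.5 to +1 s,
- head-orientation angles: 60 one-hot bins of 6 degrees per angle,
- chest position: one-hot occupancy bins of 1.28 x 1.28 cm,
- video and motion-energy factors: analog regressors, optionally
  orthogonalized against the stimulus-event columns by QR projection.

Models are fitted per neuron by ridge regression with 10-fold
cross-validation over trials; the penalty is selected per fold (and per
neuron) from decades 1e-3 to 1e5 by held-out R^2. Variance is partitioned
by refitting with structure-preserving trial-block shuffles: the maximal
variance of a variable is the R^2 of a model with every other variable
shuffled (minus the time-only model), and its unique variance is the full
model R^2 minus that of a model with only this variable shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignedTensor
from .task import (
    CHEST_BIN_CM,
    HISTORY_LABELS,
    N_ANGLE_BINS,
    POKE_KERNEL_SPAN,
    PORTS,
    STIM_KERNEL_SPAN,
)

#: All design variables in canonical order.
ALL_VARIABLES: tuple[str, ...] = (
    "trial_time",
    "choice",
    "outcome",
    "trial_history",
    "stimulus_events",
    "pokes",
    "head_angles",
    "chest_position",
    "video",
    "motion_energy",
)

#: Variables whose columns are analog (standardized on training folds).
ANALOG_VARIABLES = frozenset({"video", "motion_energy"})


def default_lambda_grid() -> np.ndarray:
    """Ridge penalty decades from 1e-3 to 1e5."""
    return 10.0 ** np.arange(-3.0, 5.0 + 1e-9, 1.0)


@dataclass
class DesignMatrix:
    """Block-structured regressor matrix on (trials x timepoints) rows."""

    X: np.ndarray
    blocks: dict  # variable -> slice into columns
    column_map: list  # per column: (variable, detail)
    n_trials: int
    n_timepoints: int
    frame_rate: float
    dropped_position_bins: np.ndarray | None = None
    n_clamped_pose: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def variables(self) -> list:
        return list(self.blocks)

    def trial_rows(self, i: int) -> slice:
        return slice(i * self.n_timepoints, (i + 1) * self.n_timepoints)

    def analog_columns(self) -> np.ndarray:
        cols = []
        for v, sl in self.blocks.items():
            if v in ANALOG_VARIABLES:
                cols.extend(range(sl.start, sl.stop))
        return np.array(cols, dtype=int)


def _lagged(events: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Shift a (trials x T) event raster along aligned time for each lag.

    Column for lag l is 1 at timepoint tau when an event occurred at
    tau - l; shifts are within-trial with zero padding.
    """
    n, T = events.shape
    out = np.zeros((n, T, len(lags)))
    for j, l in enumerate(lags):
        if l >= 0:
            out[:, l:, j] = events[:, : T - l] if l else events
        else:
            out[:, :l, j] = events[:, -l:]
    return out.reshape(n * T, len(lags))


def build_design_matrix(
    session,
    tensor: AlignedTensor,
    variables: list | None = None,
    n_video: int | None = None,
) -> DesignMatrix:
    """Assemble the encoding design for the trials retained in ``tensor``.

    Parameters
    ----------
    session
        A :class:`~trialhist.synthetic.Session` (or any object exposing
        ``trial_table``, ``pose``, ``video_factors`` and ``config``).
    tensor
        Aligned activity whose ``frame_index`` maps aligned samples to
        recording frames.
    variables
        Subset of :data:`ALL_VARIABLES` to include (default: all).
    n_video
        Number of video / motion-energy components to include (default:
        all available).
    """
    variables = list(variables) if variables is not None else list(ALL_VARIABLES)
    unknown = set(variables) - set(ALL_VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")
    trials = session.trial_table
    cfg = session.config
    fs = tensor.frame_rate
    fi = tensor.frame_index
    n, T = fi.shape
    kept = tensor.trial_meta["trial"].to_numpy(dtype=int)
    sub = trials.loc[kept]

    parts: list[np.ndarray] = []
    blocks: dict = {}
    col_map: list = []
    n_clamped = 0
    dropped_bins = None

    def add(var: str, mat: np.ndarray, details: list) -> None:
        start = sum(p.shape[1] for p in parts)
        parts.append(mat)
        blocks[var] = slice(start, start + mat.shape[1])
        col_map.extend((var, d) for d in details)

    eye_T = np.eye(T)
    if "trial_time" in variables:
        add("trial_time", np.tile(eye_T, (n, 1)), list(range(T)))
    if "choice" in variables:
        ind = (sub["choice"] == "right").to_numpy(dtype=float)
        add("choice", np.kron(ind[:, None], eye_T).reshape(n * T, T),
            [("right", t) for t in range(T)])
    if "outcome" in variables:
        ind = (sub["outcome"] == "correct").to_numpy(dtype=float)
        add("outcome", np.kron(ind[:, None], eye_T).reshape(n * T, T),
            [("correct", t) for t in range(T)])
    if "trial_history" in variables:
        hist = tensor.trial_meta["history"].to_numpy(dtype=object)
        mats = []
        details = []
        for lab in HISTORY_LABELS:
            ind = (hist == lab).astype(float)
            mats.append(np.kron(ind[:, None], eye_T).reshape(n * T, T))
            details.extend((lab, t) for t in range(T))
        add("trial_history", np.hstack(mats), details)

    n_frames = session.recording.n_frames
    if "stimulus_events" in variables:
        vec = np.zeros(n_frames)
        for _, tr in trials.iterrows():
            if np.isnan(tr["t_stim_onset"]):
                continue
            for off in tr["stim_events"]:
                f = int(np.floor((tr["t_stim_onset"] + off) * fs))
                if 0 <= f < n_frames:
                    vec[f] = 1.0
        raster = vec[fi]
        lags = np.arange(
            int(round(STIM_KERNEL_SPAN[0] * fs)),
            int(round(STIM_KERNEL_SPAN[1] * fs)) + 1,
        )
        add("stimulus_events", _lagged(raster, lags), [int(l) for l in lags])
    if "pokes" in variables:
        port_events = {p: np.zeros(n_frames) for p in PORTS}
        for _, tr in trials.iterrows():
            if not np.isnan(tr["t_initiation"]):
                f = int(np.floor(tr["t_initiation"] * fs))
                if 0 <= f < n_frames:
                    port_events["center"][f] = 1.0
            if tr["completed"] and tr["choice"] in ("left", "right"):
                f = int(np.floor(tr["t_report"] * fs))
                if 0 <= f < n_frames:
                    port_events[tr["choice"]][f] = 1.0
        lags = np.arange(
            int(round(POKE_KERNEL_SPAN[0] * fs)),
            int(round(POKE_KERNEL_SPAN[1] * fs)) + 1,
        )
        mats, details = [], []
        for p in PORTS:
            mats.append(_lagged(port_events[p][fi], lags))
            details.extend((p, int(l)) for l in lags)
        add("pokes", np.hstack(mats), details)
    if "head_angles" in variables:
        angles = session.pose.angles[fi.ravel()]  # (n*T, 3)
        mats, details = [], []
        for a, name in enumerate(("pitch", "roll", "yaw")):
            bins = np.floor(angles[:, a] / (360.0 / N_ANGLE_BINS)).astype(int)
            bins = np.clip(bins, 0, N_ANGLE_BINS - 1)
            hot = np.zeros((len(bins), N_ANGLE_BINS))
            hot[np.arange(len(bins)), bins] = 1.0
            mats.append(hot)
            details.extend((name, b) for b in range(N_ANGLE_BINS))
        add("head_angles", np.hstack(mats), details)
    if "chest_position" in variables:
        pos = session.pose.position[fi.ravel()]  # (n*T, 2)
        w, h = cfg.arena_size
        nx = int(np.ceil(w / CHEST_BIN_CM))
        ny = int(np.ceil(h / CHEST_BIN_CM))
        ix = np.floor(pos[:, 0] / CHEST_BIN_CM).astype(int)
        iy = np.floor(pos[:, 1] / CHEST_BIN_CM).astype(int)
        out_of_arena = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        n_clamped = int(out_of_arena.sum())
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        flat = iy * nx + ix
        hot = np.zeros((len(flat), nx * ny))
        hot[np.arange(len(flat)), flat] = 1.0
        occupied = hot.sum(axis=0) > 0
        dropped_bins = np.flatnonzero(~occupied)
        keep_cols = np.flatnonzero(occupied)
        add("chest_position", hot[:, keep_cols],
            [(int(b) % nx, int(b) // nx) for b in keep_cols])
    for var, attr in (("video", "video"), ("motion_energy", "motion_energy")):
        if var in variables:
            mat = getattr(session.video_factors, attr)
            k = mat.shape[1] if n_video is None else min(n_video, mat.shape[1])
            add(var, mat[fi.ravel(), :k], list(range(k)))

    return DesignMatrix(
        X=np.hstack(parts),
        blocks=blocks,
        column_map=col_map,
        n_trials=n,
        n_timepoints=T,
        frame_rate=fs,
        dropped_position_bins=dropped_bins,
        n_clamped_pose=n_clamped,
    )


def orthogonalize_video(design: DesignMatrix) -> DesignMatrix:
    """Project video blocks off the stimulus-event columns (QR-based).

    After this, every video and motion-energy column has (numerically) zero
    inner product with every stimulus-event column; all other blocks are
    untouched.
    """
    if "stimulus_events" not in design.blocks:
        return design
    X = design.X.copy()
    S = X[:, design.blocks["stimulus_events"]]
    nonzero = S.any(axis=0)
    if nonzero.any():
        Q, _ = np.linalg.qr(S[:, nonzero])
        for var in ("video", "motion_energy"):
            if var in design.blocks:
                sl = design.blocks[var]
                X[:, sl] -= Q @ (Q.T @ X[:, sl])
    return DesignMatrix(
        X=X,
        blocks=design.blocks,
        column_map=design.column_map,
        n_trials=design.n_trials,
        n_timepoints=design.n_timepoints,
        frame_rate=design.frame_rate,
        dropped_position_bins=design.dropped_position_bins,
        n_clamped_pose=design.n_clamped_pose,
    )


# --------------------------------------------------------------------------
# ridge fitting
# --------------------------------------------------------------------------

@dataclass
class EncodingFit:
    """Per-neuron ridge fit with cross-validated predictions."""

    weights: np.ndarray  # columns x neurons, mean over folds (standardized units)
    lambdas: np.ndarray  # folds x neurons
    cv_r2: np.ndarray  # neurons
    predictions: np.ndarray  # rows x neurons, held-out, original units
    fold_of_trial: np.ndarray  # trials
    lambda_grid: np.ndarray
    skipped_neurons: np.ndarray
    seed: int


def ridge_solve(
    X: np.ndarray, Y: np.ndarray, lam: float
) -> np.ndarray:
    """Closed-form ridge weights (X^T X + lam I)^{-1} X^T Y."""
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y)


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Coefficient of determination per column; columns may be 1-D."""
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - ss_res / ss_tot


def fit_ridge_per_neuron(
    design: DesignMatrix,
    activity: np.ndarray,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> EncodingFit:
    """Cross-validated ridge encoding fit for every neuron.

    Folds partition *trials* so that every fold samples all trial
    timepoints equally. Within each fold, analog regressors and the neural
    activity are standardized by training statistics, the penalty is chosen
    per neuron from the grid by held-out R^2, and held-out predictions are
    assembled back in original row order; the reported cross-validated R^2
    is computed on those concatenated predictions.
    """
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid)
    rng = np.random.default_rng(seed)
    Y = np.asarray(activity, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n_rows:
        raise ValueError("activity rows must match design rows")
    skipped = ~np.isfinite(Y).all(axis=0)
    N = Y.shape[1]
    n, T = design.n_trials, design.n_timepoints

    order = rng.permutation(n)
    fold_of_trial = np.empty(n, dtype=int)
    for f in range(n_folds):
        fold_of_trial[order[f::n_folds]] = f

    analog = design.analog_columns()
    preds = np.full_like(Y, np.nan)
    lambdas = np.zeros((n_folds, N))
    weight_sum = np.zeros((design.n_columns, N))
    for f in range(n_folds):
        test_tr = np.flatnonzero(fold_of_trial == f)
        train_tr = np.flatnonzero(fold_of_trial != f)
        train_rows = (train_tr[:, None] * T + np.arange(T)).ravel()
        test_rows = (test_tr[:, None] * T + np.arange(T)).ravel()
        Xtr = design.X[train_rows].copy()
        Xte = design.X[test_rows].copy()
        if analog.size:
            mu = Xtr[:, analog].mean(axis=0)
            sd = Xtr[:, analog].std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            Xtr[:, analog] = (Xtr[:, analog] - mu) / sd
            Xte[:, analog] = (Xte[:, analog] - mu) / sd
        ymu = Y[train_rows].mean(axis=0)
        ysd = Y[train_rows].std(axis=0)
        ysd = np.where(ysd < 1e-12, 1.0, ysd)
        Ytr = (Y[train_rows] - ymu) / ysd
        Yte = (Y[test_rows] - ymu) / ysd

        G = Xtr.T @ Xtr
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        XtY = Xtr.T @ Ytr
        VtXtY = V.T @ XtY  # (p, N)
        XteV = Xte @ V
        r2_grid = np.empty((len(lambda_grid), N))
        pred_grid = []
        for li, lam in enumerate(lambda_grid):
            coef_rot = VtXtY / (w + lam)[:, None]
            pred = XteV @ coef_rot
            pred_grid.append(pred)
            r2_grid[li] = _r2(Yte, pred)
        best = np.argmax(r2_grid, axis=0)  # per neuron
        lambdas[f] = lambda_grid[best]
        for li in np.unique(best):
            cols = np.flatnonzero(best == li)
            preds[np.ix_(test_rows, cols)] = (
                pred_grid[li][:, cols] * ysd[cols] + ymu[cols]
            )
            coef = V @ (VtXtY[:, cols] / (w + lambda_grid[li])[:, None])
            weight_sum[:, cols] += coef
    cv_r2 = _r2(Y, preds)
    cv_r2[skipped] = np.nan
    return EncodingFit(
        weights=weight_sum / n_folds,
        lambdas=lambdas,
        cv_r2=cv_r2,
        predictions=preds,
        fold_of_trial=fold_of_trial,
        lambda_grid=lambda_grid,
        skipped_neurons=np.flatnonzero(skipped),
        seed=seed,
    )


# --------------------------------------------------------------------------
# variance partitioning
# --------------------------------------------------------------------------

def shuffle_variable_blocks(
    design: DesignMatrix,
    variables: list,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return a copy of X with the given variables' columns trial-shuffled.

    The shuffle permutes whole trials: the targeted columns of trial i are
    replaced by those of a permuted trial, preserving within-trial temporal
    structure so the shuffled regressors remain a fair null.
    """
    X = design.X.copy()
    n, T = design.n_trials, design.n_timepoints
    perm = rng.permutation(n)
    row_src = (perm[:, None] * T + np.arange(T)).ravel()
    for v in variables:
        sl = design.blocks[v]
        X[:, sl] = design.X[np.ix_(row_src, np.arange(sl.start, sl.stop))]
    return X


def _with_matrix(design: DesignMatrix, X: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        X=X, blocks=design.blocks, column_map=design.column_map,
        n_trials=design.n_trials, n_timepoints=design.n_timepoints,
        frame_rate=design.frame_rate,
        dropped_position_bins=design.dropped_position_bins,
        n_clamped_pose=design.n_clamped_pose,
    )


@dataclass
class PartitionResult:
    variables: list
    maximal: pd.DataFrame  # neurons x variables
    unique: pd.DataFrame
    cv_r2_full: np.ndarray
    cv_r2_time_only: np.ndarray
    cv_r2_single: pd.DataFrame
    cv_r2_one_removed: pd.DataFrame
    full_fit: EncodingFit


def variance_partition(
    design: DesignMatrix,
    activity: np.ndarray,
    variables: list | None = None,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> PartitionResult:
    """Maximal and unique cross-validated explained variance per variable.

    maximal(v) = R^2(only v + trial time intact) - R^2(trial time only)
    unique(v)  = R^2(full) - R^2(all but v intact)

    The trial-time block is kept intact in every reduced model, serving as
    the time-varying intercept.
    """
    shuffleable = [v for v in design.blocks if v != "trial_time"]
    variables = list(variables) if variables is not None else shuffleable
    bad = [v for v in variables if v not in shuffleable]
    if bad:
        raise ValueError(f"cannot partition variables {bad}")
    rng = np.random.default_rng(seed)

    def fit_r2(X: np.ndarray) -> np.ndarray:
        f = fit_ridge_per_neuron(
            _with_matrix(design, X), activity,
            n_folds=n_folds, lambda_grid=lambda_grid, seed=seed,
        )
        return f.cv_r2

    full_fit = fit_ridge_per_neuron(
        design, activity, n_folds=n_folds, lambda_grid=lambda_grid, seed=seed
    )
    r2_full = full_fit.cv_r2
    r2_time = fit_r2(shuffle_variable_blocks(design, shuffleable, rng))
    singles, removed = {}, {}
    for v in variables:
        others = [u for u in shuffleable if u != v]
        singles[v] = fit_r2(shuffle_variable_blocks(design, others, rng))
        removed[v] = fit_r2(shuffle_variable_blocks(design, [v], rng))
    single_df = pd.DataFrame(singles)
    removed_df = pd.DataFrame(removed)
    maximal = single_df.sub(r2_time, axis=0)
    unique = (-removed_df).add(r2_full, axis=0)
    return PartitionResult(
        variables=variables,
        maximal=maximal,
        unique=unique,
        cv_r2_full=r2_full,
        cv_r2_time_only=r2_time,
        cv_r2_single=single_df,
        cv_r2_one_removed=removed_df,
        full_fit=full_fit,
    )


def timecourse_r2(fit: EncodingFit, design: DesignMatrix, activity: np.ndarray) -> np.ndarray:
    """Held-out R^2 computed separately at each aligned timepoint.

    Timepoints with zero across-trial variance are reported as NaN.
    """
    Y = np.asarray(activity, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, T = design.n_trials, design.n_timepoints
    Yr = Y.reshape(n, T, -1)
    Pr = fit.predictions.reshape(n, T, -1)
    out = np.full((T, Yr.shape[2]), np.nan)
    for t in range(T):
        yt, pt = Yr[:, t, :], Pr[:, t, :]
        ss_tot = ((yt - yt.mean(axis=0)) ** 2).sum(axis=0)
        ok = ss_tot > 0
        ss_res = ((yt - pt) ** 2).sum(axis=0)
        out[t, ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return out
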