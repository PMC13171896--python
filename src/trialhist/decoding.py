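"""Per-timepoint population decoding of trial history.

Decoders are L2-regularized logistic regressions (one-vs-all for the 4-class
history problem) trained independently at every aligned timepoint. Class
imbalance is handled by subsampling the majority classes to the minority
count over 20 rounds; within each round the balanced set is split into 8
stratified folds (87.5% train / 12.5% test). Features are standardized by
training-fold statistics, the penalty is selected per fold from an
exponential grid (decades from 1e-10 to 1e12) by test-fold accuracy, and
reported accuracies average over all folds and rounds.

The solver is a damped Newton iteration vectorized over classes and the
whole penalty grid at once, which keeps the grid search cheap on the small
per-timepoint problems this protocol produces; it is cross-checked against
an independent general-purpose optimizer in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedTensor
from .task import HISTORY_LABELS

_EPS_SD = 1e-12


# --------------------------------------------------------------------------
# protocol and result containers
# --------------------------------------------------------------------------

def default_penalty_grid() -> np.ndarray:
    """Exponential penalty series, decade steps from 1e-10 to 1e12."""
    return 10.0 ** np.arange(-10.0, 12.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class DecoderProtocol:
    """Cross-validated, balanced decoding protocol parameters."""

    n_rounds: int = 20
    n_folds: int = 8
    train_fraction: float = 0.875
    penalty_grid: np.ndarray = field(default_factory=default_penalty_grid)

    def __post_init__(self) -> None:
        if abs((1.0 - self.train_fraction) * self.n_folds - 1.0) > 1e-9:
            raise ValueError("train_fraction and n_folds are inconsistent")


@dataclass
class TimepointModel:
    """One trained fold model: scaler, per-class weights, chosen penalty."""

    mean: np.ndarray
    sd: np.ndarray
    weights: np.ndarray  # classes x (features + 1), intercept last
    penalty: float
    test_index: np.ndarray  # indices into the label array


@dataclass
class DecodingResult:
    classes: list
    accuracy: np.ndarray  # timepoints
    class_accuracy: np.ndarray  # timepoints x classes (recall)
    confusion: np.ndarray  # timepoints x classes x classes, row-normalized
    shuffled_accuracy: np.ndarray | None
    timepoint_index: np.ndarray
    models: list | None  # per timepoint: list of TimepointModel
    seed: int | None = None

    @property
    def overall_accuracy(self) -> float:
        return float(np.mean(self.accuracy))


# --------------------------------------------------------------------------
# balanced subsampling
# --------------------------------------------------------------------------

def balanced_subsample(
    labels: np.ndarray, n_rounds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets with equal class counts, balancing inclusion across rounds.

    Each round draws ``minority count`` items per class without replacement;
    across rounds, items of a majority class are drawn preferring those used
    least so far, so inclusion counts stay within +/-1 of each other whenever
    feasible.
    """
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or len(classes) < 2:
        raise ValueError("need at least two non-empty classes")
    m = int(counts.min())
    usage = {c: np.zeros(int(k), dtype=int) for c, k in zip(classes, counts)}
    index_of = {c: np.flatnonzero(labels == c) for c in classes}
    rounds = []
    for _ in range(n_rounds):
        picked = []
        for c in classes:
            idx = index_of[c]
            if len(idx) == m:
                picked.append(idx)
                continue
            # least-used first, random tie-break
            order = np.lexsort((rng.random(len(idx)), usage[c]))
            sel = order[:m]
            usage[c][sel] += 1
            picked.append(idx[sel])
        rounds.append(np.sort(np.concatenate(picked)))
    return rounds


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition positions 0..n-1 into folds with balanced labels."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        pos = np.flatnonzero(labels == c)
        rng.shuffle(pos)
        for i, p in enumerate(pos):
            folds[i % n_folds].append(int(p))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


# --------------------------------------------------------------------------
# batched ridge-logistic Newton solver
# --------------------------------------------------------------------------

def ridge_logistic_path(
    X: np.ndarray,
    Y: np.ndarray,
    penalties: np.ndarray,
    max_iter: int = 12,
    tol: float = 1e-5,
) -> np.ndarray:
    """Fit binary L2 logistic regressions for every (target, penalty) pair.

    Minimizes mean log-loss + 0.5 * penalty / n * ||w||^2 with an
    unpenalized intercept; equivalent to the standard formulation with the
    penalty applied to the summed loss. A damped Newton iteration is run
    jointly over all targets and penalties; near-separable problems at the
    weak end of the grid are capped by the iteration limit (their decision
    function has converged long before the weights have).

    Parameters
    ----------
    X : (n, p) design (no intercept column).
    Y : (n, C) binary targets, one column per one-vs-all problem.
    penalties : (L,) ridge strengths.

    Returns
    -------
    (C, L, p + 1) weights, intercept last.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    C = Y.shape[1]
    L = len(penalties)
    P = p + 1
    Xa = np.hstack([X, np.ones((n, 1))])
    outer = Xa[:, :, None] * Xa[:, None, :]  # (n, P, P), shared across batch
    outer = outer.reshape(n, P * P)
    lam = np.asarray(penalties, dtype=float)[None, :, None] / n
    pen_mask = np.ones(P)
    pen_mask[-1] = 0.0
    ridge_diag = lam[..., None] * np.diag(pen_mask)[None, None]
    ridge_diag = ridge_diag + 1e-10 * np.eye(P)

    W = np.zeros((C, L, P))
    Yt = Y.T[:, None, :]  # (C, 1, n)
    sign = 2 * Yt - 1

    def objective(W):
        z = np.einsum("clp,np->cln", W, Xa)
        loss = np.logaddexp(0.0, -sign * z).mean(axis=-1)
        return loss + 0.5 * lam[..., 0] * ((pen_mask * W) * W).sum(axis=-1)

    obj = objective(W)
    for _ in range(max_iter):
        z = np.einsum("clp,np->cln", W, Xa)
        mu = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
        grad = np.einsum("cln,np->clp", mu - Yt, Xa) / n + lam * (pen_mask * W)
        if np.abs(grad).max() < tol:
            break
        s = np.clip(mu * (1 - mu), 1e-10, None)  # (C, L, n)
        H = (s @ outer).reshape(C, L, P, P) / n + ridge_diag
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # halve steps that fail to decrease the objective
        alpha = np.ones((C, L, 1))
        for _ in range(25):
            obj_new = objective(W - alpha * step)
            bad = obj_new > obj + 1e-12
            if not bad.any():
                break
            alpha[bad] *= 0.5
        W = W - alpha * step
        obj = objective(W)
    return W


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    out = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        out[labels == c, j] = 1.0
    return out


def _predict(model: TimepointModel, X: np.ndarray) -> np.ndarray:
    """Class indices predicted by a fold model (argmax one-vs-all scores)."""
    Z = (X - model.mean) / model.sd
    scores = Z @ model.weights[:, :-1].T + model.weights[:, -1]
    return np.argmax(scores, axis=1)


# --------------------------------------------------------------------------
# decoder fitting
# --------------------------------------------------------------------------

def fit_timepoint_decoder(
    X: np.ndarray,
    y: np.ndarray,
    protocol: DecoderProtocol,
    rng: np.random.Generator,
    classes: list | None = None,
    plan: list[tuple[np.ndarray, list[np.ndarray]]] | None = None,
    keep_models: bool = False,
):
    """Balanced, cross-validated decoding accuracy at a single timepoint.

    Returns ``(accuracy, class_accuracy, confusion_counts, models)`` where
    accuracy averages over folds and rounds, class accuracy is the per-true-
    class recall, and confusion counts are summed predicted-vs-true counts.

    ``plan`` optionally fixes the subsample rounds and fold splits (shared
    across timepoints for the time-resolved analyses).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    if plan is None:
        plan = make_plan(y, protocol, rng)

    k = len(classes)
    fold_accs = []
    conf = np.zeros((k, k))
    models = [] if keep_models else None
    for round_idx, folds in plan:
        y_r = y[round_idx]
        y_codes = np.array([classes.index(c) for c in y_r])
        for f in range(len(folds)):
            test_pos = folds[f]
            train_pos = np.concatenate([folds[g] for g in range(len(folds)) if g != f])
            Xtr, Xte = X[round_idx[train_pos]], X[round_idx[test_pos]]
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd < _EPS_SD, 1.0, sd)
            Ztr = (Xtr - mean) / sd
            Zte = (Xte - mean) / sd
            Ytr = _one_hot(y_r[train_pos], classes)
            Yte = _one_hot(y_r[test_pos], classes)
            W = ridge_logistic_path(Ztr, Ytr, protocol.penalty_grid)
            scores = (
                np.einsum("clp,np->lnc", W[:, :, :-1], Zte)
                + W[:, :, -1].T[:, None, :]
            )
            # penalty selection: best held-out predictions, measured as the
            # summed one-vs-all log-likelihood on the test fold
            sgn = 2 * Yte[None] - 1  # (1, n_test, C)
            dev = np.logaddexp(0.0, -sgn * scores).sum(axis=(1, 2))  # (L,)
            best = int(np.argmin(dev))
            pred = np.argmax(scores[best], axis=1)
            acc = float((pred == y_codes[test_pos]).mean())
            fold_accs.append(acc)
            for yt, yp in zip(y_codes[test_pos], pred):  # confusion counts
                conf[yt, yp] += 1
            if keep_models:
                models.append(
                    TimepointModel(
                        mean=mean,
                        sd=sd,
                        weights=W[:, best, :],
                        penalty=float(protocol.penalty_grid[best]),
                        test_index=round_idx[test_pos],
                    )
                )
    accuracy = float(np.mean(fold_accs))
    row_tot = conf.sum(axis=1)
    class_acc = np.divide(np.diag(conf), row_tot, out=np.zeros(k), where=row_tot > 0)
    return accuracy, class_acc, conf, models


def make_plan(
    y: np.ndarray, protocol: DecoderProtocol, rng: np.random.Generator
) -> list[tuple[np.ndarray, list[np.ndarray]]]:
    """Draw the subsample rounds and stratified fold splits for a label set."""
    y = np.asarray(y, dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < protocol.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} trials; at least "
            f"{protocol.n_folds} (one per fold) are required"
        )
    rounds = balanced_subsample(y, protocol.n_rounds, rng)
    plan = []
    for round_idx in rounds:
        folds = _stratified_folds(y[round_idx], protocol.n_folds, rng)
        plan.append((round_idx, folds))
    return plan


def decode_timecourse(
    tensor: AlignedTensor,
    protocol: DecoderProtocol | None = None,
    seed: int = 0,
    timepoints: np.ndarray | None = None,
    back: int = 1,
    shuffle_control: bool = True,
    keep_models: bool = False,
) -> DecodingResult:
    """Fit one history decoder per aligned timepoint.

    ``timepoints`` optionally restricts to a subset of aligned timepoints
    (defaults to all). The subsample rounds and fold splits are drawn once
    and shared across timepoints so that cross-temporal analyses can reuse
    the trained models fold-for-fold.
    """
    protocol = protocol or DecoderProtocol()
    rng = np.random.default_rng(seed)
    labels = tensor.labels(back=back)
    eligible = np.array([l is not None for l in labels])
    y = labels[eligible]
    act = tensor.activity[eligible]
    classes = [c for c in HISTORY_LABELS if (y == c).any()]
    if len(classes) < len(HISTORY_LABELS):
        missing = sorted(set(HISTORY_LABELS) - set(classes))
        raise ValueError(f"history context(s) absent: {missing}")
    if timepoints is None:
        timepoints = np.arange(tensor.n_timepoints)
    timepoints = np.asarray(timepoints, dtype=int)

    plan = make_plan(y, protocol, rng)
    k = len(classes)
    acc = np.empty(len(timepoints))
    class_acc = np.empty((len(timepoints), k))
    confusion = np.empty((len(timepoints), k, k))
    all_models: list = []
    shuf_acc = np.empty(len(timepoints)) if shuffle_control else None
    y_shuf = None
    if shuffle_control:
        y_shuf = y.copy()
        rng.shuffle(y_shuf)
        shuf_plan = make_plan(y_shuf, protocol, rng)
    for i, tp in enumerate(timepoints):
        X = act[:, tp, :]
        a, ca, conf, models = fit_timepoint_decoder(
            X, y, protocol, rng, classes=classes, plan=plan, keep_models=keep_models
        )
        acc[i] = a
        class_acc[i] = ca
        row = conf.sum(axis=1, keepdims=True)
        confusion[i] = np.divide(conf, row, out=np.zeros_like(conf), where=row > 0)
        if keep_models:
            all_models.append(models)
        if shuffle_control:
            sa, _, _, _ = fit_timepoint_decoder(
                X, y_shuf, protocol, rng, classes=classes, plan=shuf_plan
            )
            shuf_acc[i] = sa
    return DecodingResult(
        classes=classes,
        accuracy=acc,
        class_accuracy=class_acc,
        confusion=confusion,
        shuffled_accuracy=shuf_acc,
        timepoint_index=timepoints,
        models=all_models if keep_models else None,
        seed=seed,
    )


def marginal_accuracy(result: DecodingResult, factor: str) -> np.ndarray:
    """Accuracy with respect to previous choice or outcome only.

    A 4-class prediction counts as correct when it agrees with the true
    label on the requested factor, ignoring the other one.
    """
    if factor == "choice":
        group = {c: c[-1] for c in result.classes}  # L vs R
    elif factor == "outcome":
        group = {c: c[0] for c in result.classes}  # C vs I
    else:
        raise ValueError("factor must be 'choice' or 'outcome'")
    k = len(result.classes)
    agree = np.array(
        [
            [1.0 if group[result.classes[i]] == group[result.classes[j]] else 0.0
             for j in range(k)]
            for i in range(k)
        ]
    )
    out = np.empty(result.confusion.shape[0])
    for t in range(result.confusion.shape[0]):
        conf = result.confusion[t]  # rows sum to 1 per true class
        out[t] = float((conf * agree).sum(axis=1).mean())
    return out


def cross_temporal_matrix(
    tensor: AlignedTensor,
    protocol: DecoderProtocol | None = None,
    seed: int = 0,
    timepoints: np.ndarray | None = None,
) -> tuple[np.ndarray, DecodingResult]:
    """Train decoders at each timepoint, test them at every other one.

    Entry (i, j) is the accuracy of models trained at timepoint i applied to
    activity at timepoint j, using each fold's own held-out trials and
    averaging prediction accuracies over folds and rounds (models are never
    averaged). The diagonal equals the per-timepoint accuracy of
    :func:`decode_timecourse` run with the same seed.
    """
    result = decode_timecourse(
        tensor,
        protocol,
        seed=seed,
        timepoints=timepoints,
        shuffle_control=False,
        keep_models=True,
    )
    labels = tensor.labels()
    eligible = np.array([l is not None for l in labels])
    y = labels[eligible]
    act = tensor.activity[eligible]
    y_codes = np.array([result.classes.index(c) for c in y])
    T = len(result.timepoint_index)
    mat = np.empty((T, T))
    for i in range(T):
        models = result.models[i]
        for j, tp in enumerate(result.timepoint_index):
            accs = []
            for m in models:
                pred = _predict(m, act[m.test_index][:, tp, :])
                accs.append(float((pred == y_codes[m.test_index]).mean()))
            mat[i, j] = np.mean(accs)
    return mat, result


def accuracy_by_iti(
    tensor: AlignedTensor,
    bin_edges: np.ndarray,
    protocol: DecoderProtocol | None = None,
    seed: int = 0,
    timepoints_stride: int = 1,
) -> list[float | None]:
    """Stimulus-phase decoding accuracy for trials binned by ITI duration.

    Bins in which any history class is missing (or that are empty) are
    reported as ``None`` rather than zero. ``timepoints_stride`` decodes
    every stride-th stimulus-phase timepoint.
    """
    protocol = protocol or DecoderProtocol()
    rng = np.random.default_rng(seed)
    labels = tensor.labels()
    eligible = np.array([l is not None for l in labels])
    itis = tensor.trial_meta["iti_duration"].to_numpy(dtype=float)
    stim = tensor.phase_slice("stimulus")
    timepoints = np.arange(stim.start, stim.stop, timepoints_stride)
    out: list[float | None] = []
    for b in range(len(bin_edges) - 1):
        sel = eligible & (itis >= bin_edges[b]) & (itis < bin_edges[b + 1])
        y = labels[sel]
        if len(y) == 0 or any((y == c).sum() < protocol.n_folds for c in HISTORY_LABELS):
            out.append(None)
            continue
        plan = make_plan(y, protocol, rng)
        accs = []
        act = tensor.activity[sel]
        for tp in timepoints:
            a, _, _, _ = fit_timepoint_decoder(
                act[:, tp, :], y, protocol, rng,
                classes=list(HISTORY_LABELS), plan=plan,
            )
            accs.append(a)
        out.append(float(np.mean(accs)))
    return out


def shuffled_chance(
    tensor: AlignedTensor,
    n_runs: int = 200,
    protocol: DecoderProtocol | None = None,
    seed: int = 0,
    timepoints: np.ndarray | None = None,
    factor: str | None = None,
) -> np.ndarray:
    """Label-shuffled decoding accuracy over many seeded runs.

    Each run independently permutes the history labels (4-class, or the
    binary previous-choice / previous-outcome factor), redraws the
    subsample rounds and folds, and runs the full decoding protocol at the
    given timepoints. Returns the per-run accuracies (mean over timepoints
    and folds); their average calibrates the decoder's chance level.
    """
    protocol = protocol or DecoderProtocol()
    labels = tensor.labels()
    mask = np.array([l is not None for l in labels])
    y = labels[mask].astype(object)
    if factor == "choice":
        y = np.array([l[-1] for l in y], dtype=object)
    elif factor == "outcome":
        y = np.array([l[0] for l in y], dtype=object)
    elif factor is not None:
        raise ValueError("factor must be None, 'choice' or 'outcome'")
    if timepoints is None:
        timepoints = np.arange(tensor.n_timepoints)
    act = tensor.activity[mask]
    classes = sorted(np.unique(y).tolist())
    out = np.empty(n_runs)
    for run, child in enumerate(np.random.SeedSequence(seed).spawn(n_runs)):
        rng = np.random.default_rng(child)
        ys = y.copy()
        rng.shuffle(ys)
        plan = make_plan(ys, protocol, rng)
        accs = []
        for tp in timepoints:
            a, _, _, _ = fit_timepoint_decoder(
                act[:, tp, :], ys, protocol, rng, classes=classes, plan=plan
            )
            accs.append(a)
        out[run] = float(np.mean(accs))
    return out


def decode_twoback(
    tensor: AlignedTensor,
    protocol: DecoderProtocol | None = None,
    seed: int = 0,
    timepoints: np.ndarray | None = None,
) -> DecodingResult:
    """Decode the history context of two trials back.

    Restricted to trials whose two preceding trials were both completed.
    """
    labels2 = tensor.labels(back=2)
    keep = np.array([l is not None for l in labels2])
    sub = AlignedTensor(
        activity=tensor.activity[keep],
        phase_of_timepoint=tensor.phase_of_timepoint,
        time_offset=tensor.time_offset,
        frame_index=tensor.frame_index[keep],
        trial_meta=tensor.trial_meta.loc[keep].reset_index(drop=True),
        frame_rate=tensor.frame_rate,
    )
    return decode_timecourse(
        sub, protocol, seed=seed, timepoints=timepoints, back=2,
        shuffle_control=False,
    )
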