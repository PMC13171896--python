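"""Psychometric and trial-history choice models of behavior.

Choices in the evidence-accumulation task are modelled two ways:

1. A four-parameter psychometric function of stimulus rate x,

       p(right) = gamma + (1 - gamma - lambda) * Phi(beta * (x - alpha)),

   with perceptual bias alpha (Hz), sensitivity beta (1/Hz) and lower/upper
   lapse rates gamma, lambda; fitted by Bernoulli maximum likelihood.

2. A logistic regression of choice on the scaled stimulus rate plus one
   categorical regressor per trial-history context (previous correct left,
   incorrect left, incorrect right, correct right),

       ln(p/(1-p)) = b0 + b1 * x_rate + b_hist . x_history.

   Left/right choice counts are balanced by subsampling the majority class
   over 20 rounds with 10-fold cross-validation inside each round; the L2
   penalty is fixed at 1 (not tuned) so that weights remain comparable
   across sessions. The Euclidean norm of the four history weights is the
   session's "history strength".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

from .alignment import derive_history_labels
from .decoding import balanced_subsample, _stratified_folds
from .task import HISTORY_LABELS, TaskConfig


# --------------------------------------------------------------------------
# stimulus-rate scaling
# --------------------------------------------------------------------------

def scale_stimulus_rate(rate: float, cfg: TaskConfig | None = None) -> float:
    """Map stimulus rate to [-1, 1] with the category boundary at 0.

    With the default rate set, 4 Hz -> -1, 12 Hz -> 0 and 20 Hz -> +1.
    """
    cfg = cfg or TaskConfig()
    if not (cfg.rate_min <= rate <= cfg.rate_max):
        raise ValueError(
            f"rate {rate} outside configured range "
            f"[{cfg.rate_min}, {cfg.rate_max}]"
        )
    half_range = (cfg.rate_max - cfg.rate_min) / 2.0
    return float((rate - cfg.category_boundary) / half_range)


# --------------------------------------------------------------------------
# psychometric model
# --------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    lambda_: float
    n_trials_used: int
    log_likelihood: float = np.nan
    degenerate: bool = False


def psychometric_value(x: float | np.ndarray, fit: PsychometricFit) -> np.ndarray:
    """p(right) under the cumulative-Gaussian lapse model."""
    F = norm.cdf(fit.beta * (np.asarray(x, dtype=float) - fit.alpha))
    return fit.gamma + (1.0 - fit.gamma - fit.lambda_) * F


def _psy_nll(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    a, b, g, l = params
    p = g + (1.0 - g - l) * norm.cdf(b * (x - a))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def fit_psychometric(
    trials: pd.DataFrame,
    subset: str | None = None,
    cfg: TaskConfig | None = None,
) -> PsychometricFit:
    """Maximum-likelihood psychometric fit on completed trials.

    ``subset`` restricts to trials whose predecessor was completed and whose
    history context matches (one of CL, IL, IR, CR). The optimizer is a
    bounded quasi-Newton (L-BFGS-B) started from 5 deterministic initial
    points; ties are broken by likelihood, then by smaller total lapse.
    """
    cfg = cfg or TaskConfig()
    t = trials[trials["completed"].astype(bool)]
    if subset is not None:
        if subset not in HISTORY_LABELS:
            raise ValueError(f"unknown history context {subset!r}")
        hist = derive_history_labels(trials)
        t = trials[(trials["completed"].astype(bool)) & (hist == subset)]
    x = t["stimulus_rate"].to_numpy(dtype=float)
    y = (t["choice"] == "right").to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct stimulus rates")

    bounds = [
        (cfg.rate_min - 5.0, cfg.rate_max + 5.0),
        (1e-3, 10.0),
        (0.0, 0.45),
        (0.0, 0.45),
    ]
    if y.min() == y.max():
        # all one class: parameters pinned at the bounds, flagged
        at = bounds[0][1] if y[0] == 0 else bounds[0][0]
        return PsychometricFit(
            alpha=at, beta=1e-3, gamma=0.0, lambda_=0.0,
            n_trials_used=len(t), degenerate=True,
        )

    starts = [
        (cfg.category_boundary, 0.3, 0.02, 0.02),
        (float(np.mean(x)), 0.1, 0.02, 0.02),
        (float(np.quantile(x, 0.25)), 0.5, 0.05, 0.05),
        (float(np.quantile(x, 0.75)), 0.5, 0.05, 0.05),
        (cfg.category_boundary, 1.0, 0.1, 0.1),
    ]
    best = None
    for s in starts:
        res = minimize(
            _psy_nll, np.array(s), args=(x, y), method="L-BFGS-B", bounds=bounds
        )
        key = (round(res.fun, 9), round(res.x[2] + res.x[3], 9))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    a, b, g, l = res.x
    return PsychometricFit(
        alpha=float(a), beta=float(b), gamma=float(g), lambda_=float(l),
        n_trials_used=len(t), log_likelihood=float(-res.fun),
    )


# --------------------------------------------------------------------------
# trial-history logistic choice model
# --------------------------------------------------------------------------

@dataclass
class ChoiceModelFit:
    beta0: float
    beta1: float
    beta_hist: np.ndarray  # ordered (CL, IL, IR, CR)
    history_strength: float
    cv_info: dict = field(default_factory=dict)


def history_strength(fit: ChoiceModelFit | np.ndarray) -> float:
    """Euclidean norm of the four trial-history weights."""
    v = fit.beta_hist if isinstance(fit, ChoiceModelFit) else np.asarray(fit)
    return float(np.linalg.norm(np.asarray(v, dtype=float)))


def _history_design(
    trials: pd.DataFrame, cfg: TaskConfig
) -> tuple[np.ndarray, np.ndarray]:
    hist = derive_history_labels(trials)
    keep = trials["completed"].astype(bool).to_numpy() & hist.notna().to_numpy()
    t = trials[keep]
    h = hist[keep]
    x = np.array([scale_stimulus_rate(r, cfg) for r in t["stimulus_rate"]])
    H = np.zeros((len(t), 4))
    for j, lab in enumerate(HISTORY_LABELS):
        H[(h == lab).to_numpy(), j] = 1.0
    missing = [lab for j, lab in enumerate(HISTORY_LABELS) if H[:, j].sum() == 0]
    if missing:
        raise ValueError(f"history context(s) absent from data: {missing}")
    X = np.column_stack([x, H])
    y = (t["choice"] == "right").to_numpy(dtype=float)
    return X, y


def _balanced_cv_logistic(
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int,
    n_folds: int,
    penalty: float,
    seed: int,
) -> tuple[np.ndarray, float, dict]:
    """Mean coefficients over balanced subsample rounds x CV folds.

    The fixed L2 penalty maps to scikit-learn's C = 1 / penalty; the
    intercept is unpenalized.
    """
    rng = np.random.default_rng(seed)
    labels = np.where(y > 0.5, "right", "left").astype(object)
    rounds = balanced_subsample(labels, n_rounds, rng)
    coefs, intercepts = [], []
    for ridx in rounds:
        folds = _stratified_folds(labels[ridx], n_folds, rng)
        for f in range(n_folds):
            train = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            idx = ridx[train]
            clf = LogisticRegression(
                C=1.0 / penalty, solver="lbfgs", tol=1e-8, max_iter=2000,
            )
            clf.fit(X[idx], y[idx])
            coefs.append(clf.coef_[0])
            intercepts.append(clf.intercept_[0])
    info = {"n_rounds": n_rounds, "n_folds": n_folds, "penalty": penalty,
            "seed": seed, "n_fits": len(coefs)}
    return np.mean(coefs, axis=0), float(np.mean(intercepts)), info


def fit_choice_model(
    trials: pd.DataFrame,
    cfg: TaskConfig | None = None,
    n_rounds: int = 20,
    n_folds: int = 10,
    penalty: float = 1.0,
    seed: int = 0,
) -> ChoiceModelFit:
    """Logistic choice model with stimulus-rate and 4 history regressors.

    Uses completed trials with a defined history context; raises when any of
    the four contexts is absent. Coefficients average over all fold x round
    fits at the fixed penalty.
    """
    cfg = cfg or TaskConfig()
    X, y = _history_design(trials, cfg)
    coef, b0, info = _balanced_cv_logistic(X, y, n_rounds, n_folds, penalty, seed)
    bh = coef[1:5]
    return ChoiceModelFit(
        beta0=b0, beta1=float(coef[0]), beta_hist=bh,
        history_strength=history_strength(bh), cv_info=info,
    )


# --------------------------------------------------------------------------
# two-back model
# --------------------------------------------------------------------------

@dataclass
class TwoBackFit:
    beta0: float
    beta_stim: float
    choice_1back: float
    outcome_1back: float
    interaction_1back: float
    choice_2back: float
    outcome_2back: float
    interaction_2back: float
    cv_info: dict = field(default_factory=dict)

    def coefficients(self) -> np.ndarray:
        return np.array(
            [
                self.beta0, self.beta_stim,
                self.choice_1back, self.outcome_1back, self.interaction_1back,
                self.choice_2back, self.outcome_2back, self.interaction_2back,
            ]
        )


def twoback_design(
    trials: pd.DataFrame, cfg: TaskConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Design for the two-back model: scaled rate + dummy-coded main effects
    and interactions at t-1 and t-2.

    Main effects are 1 for right choices / correct outcomes; each
    interaction is the product of its two main-effect indicators (1 only for
    correct right choices). Only trials with two completed predecessors
    enter.
    """
    cfg = cfg or TaskConfig()
    completed = trials["completed"].to_numpy(dtype=bool)
    choice = (trials["choice"] == "right").to_numpy(dtype=float)
    outcome = (trials["outcome"] == "correct").to_numpy(dtype=float)
    rows, ys = [], []
    for t in range(2, len(trials)):
        if not (completed[t] and completed[t - 1] and completed[t - 2]):
            continue
        x = scale_stimulus_rate(float(trials["stimulus_rate"].iloc[t]), cfg)
        c1, o1 = choice[t - 1], outcome[t - 1]
        c2, o2 = choice[t - 2], outcome[t - 2]
        rows.append([x, c1, o1, c1 * o1, c2, o2, c2 * o2])
        ys.append(choice[t])
    return np.asarray(rows, dtype=float), np.asarray(ys, dtype=float)


def fit_twoback_model(
    trials: pd.DataFrame,
    cfg: TaskConfig | None = None,
    n_rounds: int = 20,
    n_folds: int = 10,
    penalty: float = 1.0,
    seed: int = 0,
) -> TwoBackFit:
    """Fit the two-back choice model with the same balanced CV protocol."""
    X, y = twoback_design(trials, cfg)
    if len(y) == 0:
        raise ValueError("no trials with two completed predecessors")
    coef, b0, info = _balanced_cv_logistic(X, y, n_rounds, n_folds, penalty, seed)
    return TwoBackFit(
        beta0=b0, beta_stim=float(coef[0]),
        choice_1back=float(coef[1]), outcome_1back=float(coef[2]),
        interaction_1back=float(coef[3]),
        choice_2back=float(coef[4]), outcome_2back=float(coef[5]),
        interaction_2back=float(coef[6]), cv_info=info,
    )


# --------------------------------------------------------------------------
# Wilson interval and session filters
# --------------------------------------------------------------------------

def wilson_interval(
    successes: int, n: int, conf: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


def filter_sessions(summaries: pd.DataFrame) -> tuple[list, dict]:
    """Apply the four session-inclusion criteria.

    Expected columns: ``wait_time`` (achieved center wait incl. delay, s),
    ``stimulus_rates`` (iterable of presented rates), ``n_completed``,
    ``withdrawal_rate``. A session is included when the animal waited more
    than 1 s, experienced at least two boundary-symmetric rate pairs,
    completed at least 100 trials and withdrew early on at most 55% of
    trials.

    Returns the included index list and a per-session list of exclusion
    reasons (empty for included sessions).
    """
    included = []
    reasons: dict = {}
    for idx, row in summaries.iterrows():
        why = []
        if not row["wait_time"] > 1.0:
            why.append("wait<=1s")
        rates = set(row["stimulus_rates"])
        boundary_sum = 24  # pairs symmetric about the 12 Hz boundary
        pairs = sum(
            1 for r in rates if r < 12 and (boundary_sum - r) in rates
        )
        if pairs < 2:
            why.append("rate_pairs<2")
        if row["n_completed"] < 100:
            why.append("completed<100")
        if row["withdrawal_rate"] > 0.55:
            why.append("withdrawal>55%")
        reasons[idx] = why
        if not why:
            included.append(idx)
    return included, reasons
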