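"""Synthetic session generator with recorded ground truth.

Generates complete sessions of the freely-moving evidence-accumulation
task — trial tables, chest-position and head-angle traces, low-rank video
factors, and frames x neurons activity — with the statistical structure the
analysis modules assume and with every generative parameter recorded, so
that decoding, encoding-model and geometry analyses can be validated by
parameter recovery.

Generative neural model: each neuron's latent rate is a linear function of
exactly the feature expansion the encoding design matrix uses — per-context
trial-history kernels over aligned trial time, choice and outcome kernels,
a stimulus-event lag kernel (0 to 0.5 s), port-poke kernels (-0.5 to +1 s),
piecewise-constant head-angle tuning over the 60 angle bins,
piecewise-constant place fields over the chest occupancy grid, and linear
loadings on the video factors. Neurons belong to one of four classes:
history-coding, movement-coding, mixed, or null (all task weights exactly
zero). Emitted traces are an inferred-spike-rate-like signal (latent +
noise) and a fluorescence-like signal (latent convolved with a 1 s
exponential decay + noise), both floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import aligned_time_base, align_activity
from .task import (
    CHEST_BIN_CM,
    HISTORY_LABELS,
    N_ANGLE_BINS,
    POKE_KERNEL_SPAN,
    PORTS,
    STIM_KERNEL_SPAN,
    TaskConfig,
)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters of the logistic choice policy.

    ``beta_hist`` is ordered (CL, IL, IR, CR) on the log-odds-of-right
    scale; positive values push toward right choices. Defaults plant a
    moderate win-stay pattern (repeat rewarded sides) on top of a strong
    stimulus weight, with small symmetric lapses.
    """

    beta0: float = 0.0
    beta1: float = 2.5
    beta_hist: tuple[float, float, float, float] = (-0.6, -0.1, 0.1, 0.6)
    lapse_lo: float = 0.02
    lapse_hi: float = 0.02
    p_early_withdrawal: float = 0.15
    iti_median: float = 3.0
    iti_sigma_log: float = 0.6
    iti_max: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_lo + self.lapse_hi < 1:
            raise ValueError("lapse rates must satisfy 0 <= lo + hi < 1")
        if not 0 <= self.p_early_withdrawal < 1:
            raise ValueError("p_early_withdrawal must be in [0, 1)")


@dataclass(frozen=True)
class PopulationConfig:
    """Composition and noise of the simulated neuron population."""

    n_neurons: int = 60
    frac_history: float = 0.25
    frac_movement: float = 0.25
    frac_mixed: float = 0.25
    noise_sd: float = 0.5
    amplitude: float = 1.0
    baseline: float = 3.0
    fluor_tau: float = 1.0
    #: "stable": one history pattern across all phases; "reorganize": the
    #: ITI pattern and the stimulus/action pattern are independent.
    history_regime: str = "reorganize"
    #: optional e-folding time (s): history drive during stimulus/action
    #: phases decays with the trial's elapsed ITI duration.
    iti_decay_tau: float | None = None


@dataclass(frozen=True)
class SessionConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_trials: int = 300
    n_video_components: int = 200
    video_noise_sd: float = 0.5


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class PoseTrack:
    position: np.ndarray  # frames x 2, cm, origin at arena corner
    angles: np.ndarray  # frames x 3 (pitch, roll, yaw), degrees in [0, 360)
    frame_rate: float


@dataclass
class VideoFactors:
    video: np.ndarray  # frames x k
    motion_energy: np.ndarray  # frames x k


@dataclass
class NeuralRecording:
    fluorescence: np.ndarray  # frames x neurons
    spike_rate: np.ndarray  # frames x neurons
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[1]


@dataclass
class GroundTruth:
    """Planted generative weights; null neurons have all task weights zero."""

    classes: np.ndarray  # neuron class label per neuron
    history_kernels: np.ndarray  # neurons x 4 x aligned timepoints
    choice_kernel: np.ndarray  # neurons x aligned timepoints
    outcome_kernel: np.ndarray  # neurons x aligned timepoints
    stim_kernel: np.ndarray  # neurons x stim lags
    poke_kernels: np.ndarray  # neurons x 3 ports x poke lags
    angle_tuning: np.ndarray  # neurons x 3 angles x 60 bins
    place_field: np.ndarray  # neurons x position bins
    video_loadings: np.ndarray  # neurons x k
    baseline: np.ndarray  # neurons
    noise_sd: np.ndarray  # neurons


@dataclass
class Session:
    trial_table: pd.DataFrame
    pose: PoseTrack
    video_factors: VideoFactors
    recording: NeuralRecording
    ground_truth: GroundTruth | None
    config: TaskConfig
    session_config: SessionConfig
    seed: int


# --------------------------------------------------------------------------
# stimulus trains
# --------------------------------------------------------------------------

def generate_stimulus_train(
    rate: int, cfg: TaskConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pseudo-random event-onset times for one stimulus train.

    Uses rejection-free gap allocation: the slack time left after placing
    the mandatory event durations and minimum gaps is divided among
    ``rate + 1`` segments with exponential proportions, so every draw
    satisfies the minimum-gap constraint by construction.
    """
    cfg = cfg or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if rate not in cfg.stimulus_rates:
        raise ValueError(f"rate {rate} not in configured stimulus rates")
    n = int(rate)
    free = cfg.train_duration - n * cfg.event_duration - (n - 1) * cfg.min_gap
    if free < 0:
        raise ValueError("infeasible rate/duration combination")
    slack = rng.exponential(1.0, size=n + 1)
    slack = slack / slack.sum() * free
    step = cfg.event_duration + cfg.min_gap
    onsets = np.cumsum(slack[:n]) + np.arange(n) * step
    return onsets


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_behavior(
    params: BehaviorParams,
    n_trials: int,
    cfg: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a trial table from the logistic history-biased policy.

    Choices follow ``p(right) = lo + (1 - lo - hi) * sigmoid(b0 + b1*x +
    b_hist . h)`` where x is the scaled stimulus rate and h the one-back
    history indicators; history indicators are zero when the directly
    preceding trial was not completed. Outcomes follow the fixed rule
    (rate above the boundary rewards right). Early withdrawals carry no
    choice or outcome and break history chains. All event timestamps and
    inter-trial intervals are populated.
    """
    cfg = cfg or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    half_range = (cfg.rate_max - cfg.rate_min) / 2.0
    bh = np.asarray(params.beta_hist, dtype=float)

    rows = []
    t_init = 2.0  # leave room for pre-stimulus windows at recording start
    prev = None  # (completed, choice, outcome)
    for t in range(n_trials):
        rate = int(rng.choice(cfg.stimulus_rates))
        events = generate_stimulus_train(rate, cfg, rng)
        t_stim = t_init + rng.uniform(0.05, 0.25)
        withdrawn = rng.random() < params.p_early_withdrawal
        row = {
            "stimulus_rate": rate,
            "stim_events": events,
            "completed": not withdrawn,
            "choice": None,
            "outcome": None,
            "t_initiation": t_init,
            "t_stim_onset": t_stim,
            "t_go_cue": np.nan,
            "t_center_exit": np.nan,
            "t_report": np.nan,
            "t_outcome_end": np.nan,
        }
        if withdrawn:
            t_withdraw = t_stim + rng.uniform(0.1, 0.9)
            row["t_center_exit"] = t_withdraw
            next_init = t_withdraw + cfg.timeout + rng.uniform(0.5, 2.0)
            prev = (False, None, None)
        else:
            x = (rate - cfg.category_boundary) / half_range
            h = np.zeros(4)
            if prev is not None and prev[0]:
                lab = ("C" if prev[2] == "correct" else "I") + (
                    "L" if prev[1] == "left" else "R"
                )
                h[HISTORY_LABELS.index(lab)] = 1.0
            p_right = params.lapse_lo + (
                1.0 - params.lapse_lo - params.lapse_hi
            ) * _sigmoid(params.beta0 + params.beta1 * x + bh @ h)
            choice = "right" if rng.random() < p_right else "left"
            correct = (rate > cfg.category_boundary) == (choice == "right")
            t_go = t_stim + cfg.train_duration + min(rng.exponential(0.3), 1.5)
            t_exit = t_go + rng.uniform(0.05, 0.3)
            # movement to the side port takes > 0.3 s, so the action window
            # (center exit + 0.3 s) never spills into the next earlyITI
            t_report = t_exit + rng.uniform(0.35, 0.7)
            if correct:
                t_out_end = t_report + rng.uniform(1.0, 2.5)
            else:
                t_out_end = t_report + cfg.timeout
            iti = np.exp(rng.normal(np.log(params.iti_median), params.iti_sigma_log))
            iti = min(iti, params.iti_max)
            # the animal stays at the outcome port until the outcome ends and
            # does not re-initiate within < 0.85 s of leaving it, keeping the
            # late-ITI window clear of the next stimulus window
            iti = max(iti, (t_out_end - t_report) + 0.85)
            row.update(
                choice=choice,
                outcome="correct" if correct else "incorrect",
                t_go_cue=t_go,
                t_center_exit=t_exit,
                t_report=t_report,
                t_outcome_end=t_out_end,
            )
            next_init = t_report + iti
            prev = (True, choice, "correct" if correct else "incorrect")
        rows.append(row)
        t_init = next_init
    table = pd.DataFrame(rows)
    table.index.name = "trial"
    return table


# --------------------------------------------------------------------------
# pose
# --------------------------------------------------------------------------

def port_locations(cfg: TaskConfig) -> dict[str, np.ndarray]:
    """Port positions (cm): along the back wall at a quarter, half and
    three quarters of the arena width."""
    w, _ = cfg.arena_size
    return {
        "left": np.array([0.25 * w, 1.0]),
        "center": np.array([0.50 * w, 1.0]),
        "right": np.array([0.75 * w, 1.0]),
    }


def _session_n_frames(trials: pd.DataFrame, cfg: TaskConfig) -> int:
    t_end = float(
        np.nanmax(trials[["t_initiation", "t_center_exit", "t_outcome_end"]].to_numpy())
    )
    return int(np.ceil((t_end + 2.0) * cfg.frame_rate))


def simulate_pose(
    trials: pd.DataFrame,
    cfg: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    n_frames: int | None = None,
) -> PoseTrack:
    """Smooth chest trajectory through the ports, plus head-angle traces.

    The chest visits the center port around each initiation and the chosen
    side port around each choice report (deliberately inducing the
    choice-position collinearity present in real freely-moving data), and
    wanders through the arena interior mid-ITI. Angles are smoothed random
    walks wrapped to [0, 360).
    """
    cfg = cfg or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    fs = cfg.frame_rate
    if n_frames is None:
        n_frames = _session_n_frames(trials, cfg)
    ports = port_locations(cfg)
    w, h = cfg.arena_size

    way_t: list[float] = [0.0]
    way_xy: list[np.ndarray] = [np.array([w / 2, h / 2])]

    def visit(t: float, xy: np.ndarray, hold: float = 0.25) -> None:
        way_t.extend([t - hold, t + hold])
        way_xy.extend([xy, xy])

    for _, tr in trials.iterrows():
        visit(tr["t_initiation"], ports["center"], hold=0.3)
        if tr["completed"]:
            visit(tr["t_report"], ports[tr["choice"]], hold=0.3)
            visit(tr["t_outcome_end"], ports[tr["choice"]], hold=0.2)
            # mid-ITI wander point
            mid = tr["t_outcome_end"] + 0.6
            way_t.append(mid)
            way_xy.append(np.array([rng.uniform(2, w - 2), rng.uniform(4, h - 2)]))
        else:
            mid = tr["t_center_exit"] + 1.0
            way_t.append(mid)
            way_xy.append(np.array([rng.uniform(2, w - 2), rng.uniform(4, h - 2)]))
    order = np.argsort(way_t)
    way_t_arr = np.array(way_t)[order]
    way_xy_arr = np.array(way_xy)[order]
    # drop near-duplicate times to keep interpolation well-defined
    keep = np.concatenate([[True], np.diff(way_t_arr) > 1e-6])
    way_t_arr, way_xy_arr = way_t_arr[keep], way_xy_arr[keep]

    t_grid = np.arange(n_frames) / fs
    pos = np.column_stack(
        [np.interp(t_grid, way_t_arr, way_xy_arr[:, d]) for d in range(2)]
    )
    # light smoothing plus small jitter; clamp inside the arena
    from scipy.ndimage import gaussian_filter1d

    pos = gaussian_filter1d(pos, sigma=1.5, axis=0, mode="nearest")
    pos += rng.normal(0.0, 0.1, size=pos.shape)
    pos[:, 0] = np.clip(pos[:, 0], 0.0, w - 1e-9)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, h - 1e-9)

    vel = np.gradient(pos, axis=0)
    yaw = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    walk = np.cumsum(rng.normal(0.0, 2.0, size=(n_frames, 2)), axis=0)
    walk = gaussian_filter1d(walk, sigma=10.0, axis=0, mode="nearest")
    angles = np.column_stack([walk[:, 0], walk[:, 1], yaw + walk[:, 1] * 0.1])
    angles = np.mod(angles, 360.0)
    return PoseTrack(position=pos, angles=angles, frame_rate=fs)


# --------------------------------------------------------------------------
# video factors
# --------------------------------------------------------------------------

def _pose_signals(pose: PoseTrack) -> np.ndarray:
    """Standardized frame-level signals derived from pose."""
    pos, ang = pose.position, pose.angles
    vel = np.gradient(pos, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    rad = np.radians(ang)
    S = np.column_stack(
        [pos, vel, speed[:, None], np.sin(rad), np.cos(rad)]
    )
    S = S - S.mean(axis=0)
    sd = S.std(axis=0)
    return S / np.where(sd < 1e-12, 1.0, sd)


def simulate_video_factors(
    pose: PoseTrack,
    k: int = 200,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.5,
) -> VideoFactors:
    """Two frames x k factor matrices emulating video and motion-energy SVDs.

    Columns are linear mixtures of pose-derived signals plus independent
    noise, rescaled so column variance is non-increasing in the column
    index (as for singular-value-ordered components). With ``noise_sd = 0``
    the factors lie exactly in the span of the pose signals.
    """
    rng = rng if rng is not None else np.random.default_rng()
    S = _pose_signals(pose)
    Sm = np.abs(np.gradient(S, axis=0))  # motion-energy-like magnitudes
    Sm = Sm - Sm.mean(axis=0)
    n_sig = S.shape[1]
    scales = 1.0 / np.sqrt(1.0 + np.arange(k))
    out = []
    for src in (S, Sm):
        M = rng.normal(size=(n_sig, k))
        F = src @ M
        F = F / np.maximum(F.std(axis=0), 1e-12)
        if noise_sd > 0:
            F = F + rng.normal(0.0, noise_sd, size=F.shape)
        F = F / np.maximum(F.std(axis=0), 1e-12) * scales
        out.append(F)
    return VideoFactors(video=out[0], motion_energy=out[1])


# --------------------------------------------------------------------------
# ground truth and neurons
# --------------------------------------------------------------------------

def _n_lags(span: tuple[float, float], fs: float) -> int:
    return int(round(span[1] * fs)) - int(round(span[0] * fs)) + 1


def sample_ground_truth(
    pop: PopulationConfig,
    cfg: TaskConfig,
    k_video: int,
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw per-neuron generative weights for each variable block."""
    fs = cfg.frame_rate
    phase_labels, _ = aligned_time_base(fs)
    T = len(phase_labels)
    iti_mask = np.isin(phase_labels, ("earlyITI", "lateITI")).astype(float)
    trial_mask = 1.0 - iti_mask
    N = pop.n_neurons
    n_hist = int(round(pop.frac_history * N))
    n_move = int(round(pop.frac_movement * N))
    n_mixed = int(round(pop.frac_mixed * N))
    classes = np.array(
        ["history"] * n_hist
        + ["movement"] * n_move
        + ["mixed"] * n_mixed
        + ["null"] * (N - n_hist - n_move - n_mixed),
        dtype=object,
    )
    amp = pop.amplitude
    has_hist = np.isin(classes, ("history", "mixed"))
    has_move = np.isin(classes, ("movement", "mixed"))

    hist = np.zeros((N, 4, T))
    a = rng.normal(0.0, amp, size=(N, 4))
    b = a if pop.history_regime == "stable" else rng.normal(0.0, amp, size=(N, 4))
    hist += a[:, :, None] * iti_mask[None, None, :]
    hist += b[:, :, None] * trial_mask[None, None, :]
    hist *= has_hist[:, None, None]

    def _two_level(scale: float) -> np.ndarray:
        u = rng.normal(0.0, scale, size=(N, 1)) * iti_mask[None, :]
        v = rng.normal(0.0, scale, size=(N, 1)) * trial_mask[None, :]
        return (u + v) * has_hist[:, None]

    choice_k = _two_level(0.3 * amp)
    outcome_k = _two_level(0.3 * amp)

    n_stim = _n_lags(STIM_KERNEL_SPAN, fs)
    stim_lag = np.arange(n_stim) / fs
    stim_k = (
        rng.normal(0.0, 0.4 * amp, size=(N, 1))
        * np.exp(-stim_lag / 0.15)[None, :]
        * has_move[:, None]
    )
    n_poke = _n_lags(POKE_KERNEL_SPAN, fs)
    poke_lag = np.arange(n_poke) / fs + POKE_KERNEL_SPAN[0]
    poke_shape = np.exp(-0.5 * ((poke_lag - 0.1) / 0.2) ** 2)
    poke_k = (
        rng.normal(0.0, 0.4 * amp, size=(N, len(PORTS), 1))
        * poke_shape[None, None, :]
        * has_move[:, None, None]
    )

    centers = rng.uniform(0.0, 360.0, size=(N, 3))
    bin_centers = (np.arange(N_ANGLE_BINS) + 0.5) * (360.0 / N_ANGLE_BINS)
    d = np.abs(bin_centers[None, None, :] - centers[:, :, None])
    d = np.minimum(d, 360.0 - d)
    angle_t = (
        rng.normal(0.0, 0.5 * amp, size=(N, 3, 1))
        * np.exp(-0.5 * (d / 40.0) ** 2)
        * has_move[:, None, None]
    )

    w, h = cfg.arena_size
    nx = int(np.ceil(w / CHEST_BIN_CM))
    ny = int(np.ceil(h / CHEST_BIN_CM))
    bx = (np.arange(nx) + 0.5) * CHEST_BIN_CM
    by = (np.arange(ny) + 0.5) * CHEST_BIN_CM
    gx, gy = np.meshgrid(bx, by)  # (ny, nx)
    cx = rng.uniform(0.0, w, size=N)
    cy = rng.uniform(0.0, h, size=N)
    dist2 = (gx.ravel()[None, :] - cx[:, None]) ** 2 + (
        gy.ravel()[None, :] - cy[:, None]
    ) ** 2
    place = (
        rng.normal(0.0, 0.6 * amp, size=(N, 1))
        * np.exp(-dist2 / (2 * 3.0**2))
        * has_move[:, None]
    )

    loadings = np.zeros((N, k_video))
    n_loaded = min(10, k_video)
    loadings[:, :n_loaded] = rng.normal(0.0, 0.3 * amp, size=(N, n_loaded))
    loadings *= has_move[:, None]

    return GroundTruth(
        classes=classes,
        history_kernels=hist,
        choice_kernel=choice_k,
        outcome_kernel=outcome_k,
        stim_kernel=stim_k,
        poke_kernels=poke_k,
        angle_tuning=angle_t,
        place_field=place,
        video_loadings=loadings,
        baseline=np.full(N, pop.baseline),
        noise_sd=np.full(N, pop.noise_sd),
    )


def simulate_neurons(
    truth: GroundTruth,
    trials: pd.DataFrame,
    pose: PoseTrack,
    video: VideoFactors,
    cfg: TaskConfig,
    rng: np.random.Generator,
    n_frames: int | None = None,
    iti_decay_tau: float | None = None,
    fluor_tau: float = 1.0,
) -> NeuralRecording:
    """Render frame-level activity from planted weights.

    Raises if the planted video loadings do not match the provided factor
    matrices.
    """
    fs = cfg.frame_rate
    if n_frames is None:
        n_frames = _session_n_frames(trials, cfg)
    N = len(truth.classes)
    if truth.video_loadings.shape[1] != video.video.shape[1]:
        raise ValueError(
            "video loading dimension does not match the number of factors"
        )
    latent = np.tile(truth.baseline, (n_frames, 1))

    # aligned trial-time kernels (history, choice, outcome)
    aligned = align_activity(np.zeros((n_frames, 1)), fs, trials)
    phase_labels = aligned.phase_of_timepoint
    iti_part = np.isin(phase_labels, ("earlyITI", "lateITI"))
    meta = aligned.trial_meta
    for i in range(aligned.n_trials):
        frames = aligned.frame_index[i]
        hidx = HISTORY_LABELS.index(meta["history"].iloc[i])
        drive = truth.history_kernels[:, hidx, :].copy()  # (N, T)
        if iti_decay_tau is not None:
            iti = meta["iti_duration"].iloc[i]
            if np.isfinite(iti):
                drive[:, ~iti_part] *= np.exp(-iti / iti_decay_tau)
        if meta["choice"].iloc[i] == "right":
            drive = drive + truth.choice_kernel
        if meta["outcome"].iloc[i] == "correct":
            drive = drive + truth.outcome_kernel
        # overlapping phase windows may revisit a frame within the trial;
        # each frame receives its drive once (first aligned occurrence)
        _, first = np.unique(frames, return_index=True)
        np.add.at(latent, frames[first], drive.T[first])

    # stimulus-event kernel
    lag0 = int(round(STIM_KERNEL_SPAN[0] * fs))
    for _, tr in trials.iterrows():
        if np.isnan(tr["t_stim_onset"]):
            continue
        for off in tr["stim_events"]:
            f0 = int(np.floor((tr["t_stim_onset"] + off) * fs))
            for l in range(truth.stim_kernel.shape[1]):
                f = f0 + lag0 + l
                if 0 <= f < n_frames:
                    latent[f] += truth.stim_kernel[:, l]
    # poke kernels
    plag0 = int(round(POKE_KERNEL_SPAN[0] * fs))
    poke_frames: dict[str, list[int]] = {p: [] for p in PORTS}
    for _, tr in trials.iterrows():
        if not np.isnan(tr["t_initiation"]):
            poke_frames["center"].append(int(np.floor(tr["t_initiation"] * fs)))
        if tr["completed"]:
            poke_frames[tr["choice"]].append(int(np.floor(tr["t_report"] * fs)))
    for pi, p in enumerate(PORTS):
        for f0 in poke_frames[p]:
            for l in range(truth.poke_kernels.shape[2]):
                f = f0 + plag0 + l
                if 0 <= f < n_frames:
                    latent[f] += truth.poke_kernels[:, pi, l]

    # angle tuning (piecewise constant over the 60 bins)
    bins = np.floor(pose.angles[:n_frames] / (360.0 / N_ANGLE_BINS)).astype(int)
    bins = np.clip(bins, 0, N_ANGLE_BINS - 1)
    for a in range(3):
        latent += truth.angle_tuning[:, a, bins[:, a]].T
    # place field (piecewise constant on the occupancy grid)
    w, _ = cfg.arena_size
    nx = int(np.ceil(w / CHEST_BIN_CM))
    ix = np.clip(
        np.floor(pose.position[:n_frames, 0] / CHEST_BIN_CM).astype(int), 0, nx - 1
    )
    ny = int(np.ceil(cfg.arena_size[1] / CHEST_BIN_CM))
    iy = np.clip(
        np.floor(pose.position[:n_frames, 1] / CHEST_BIN_CM).astype(int), 0, ny - 1
    )
    latent += truth.place_field[:, iy * nx + ix].T
    # video loadings
    latent += video.video[:n_frames] @ truth.video_loadings.T

    spike = latent + rng.normal(0.0, truth.noise_sd, size=latent.shape)
    np.maximum(spike, 0.0, out=spike)
    decay = np.exp(-1.0 / (fluor_tau * fs))
    fluor = np.empty_like(latent)
    acc = np.zeros(N)
    for f in range(n_frames):
        acc = acc * decay + latent[f] * (1.0 - decay)
        fluor[f] = acc
    fluor += rng.normal(0.0, truth.noise_sd, size=fluor.shape)
    np.maximum(fluor, 0.0, out=fluor)
    return NeuralRecording(fluorescence=fluor, spike_rate=spike, frame_rate=fs)


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

def make_session(
    config: SessionConfig | None = None,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> Session:
    """Generate a full session, deterministic given the seed.

    All randomness flows from one seeded root sequence split per component
    (behavior, pose, video, ground truth, neurons). Passing an existing
    ``ground_truth`` reuses the same planted population (e.g., repeated
    sessions imaging one subject's field of view).
    """
    config = config or SessionConfig()
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(5)
    ]
    rng_beh, rng_pose, rng_video, rng_truth, rng_neur = streams
    cfg = config.task
    trials = simulate_behavior(config.behavior, config.n_trials, cfg, rng_beh)
    n_frames = _session_n_frames(trials, cfg)
    pose = simulate_pose(trials, cfg, rng_pose, n_frames=n_frames)
    video = simulate_video_factors(
        pose, config.n_video_components, rng_video, config.video_noise_sd
    )
    truth = ground_truth if ground_truth is not None else sample_ground_truth(
        config.population, cfg, config.n_video_components, rng_truth
    )
    recording = simulate_neurons(
        truth,
        trials,
        pose,
        video,
        cfg,
        rng_neur,
        n_frames=n_frames,
        iti_decay_tau=config.population.iti_decay_tau,
        fluor_tau=config.population.fluor_tau,
    )
    return Session(
        trial_table=trials,
        pose=pose,
        video_factors=video,
        recording=recording,
        ground_truth=truth,
        config=cfg,
        session_config=config,
        seed=seed,
    )
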