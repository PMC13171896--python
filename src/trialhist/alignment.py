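"""History labels and phase-aligned activity tensors.

Analyses of trial-history coding follow neural signals from the moment the
animal reports a choice until it reports the next one. Frame-indexed signals
are therefore cut into four phases on a common per-trial time base:

- earlyITI: 1 s following the *previous* trial's choice report,
- lateITI:  1 s before to 0.3 s after the previous trial's outcome end
  (leaving the reward port after correct choices; end of punishment and
  timeout after incorrect ones),
- stimulus: 0.5 s before to 1 s after the current stimulus onset,
- action:   0.2 s before to 0.3 s after the current center-port exit.

A trial's history context is the previous completed trial's choice crossed
with its outcome (CL, IL, IR, CR). Trials whose predecessor was not completed
(early withdrawal) have undefined history and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .task import PHASES, PHASE_WINDOWS, phase_n_timepoints


def derive_history_labels(trials: pd.DataFrame, back: int = 1) -> pd.Series:
    """Trial-history context label per trial, or ``None`` when undefined.

    The label of trial ``t`` is the choice x outcome combination of trial
    ``t - back``, defined only when all trials ``t-1 .. t-back`` were
    completed (an early withdrawal breaks the history chain).

    Parameters
    ----------
    trials
        Trial table with ``completed``, ``choice`` and ``outcome`` columns.
    back
        How many trials back the context refers to (1 or 2).
    """
    if back not in (1, 2):
        raise ValueError("back must be 1 or 2")
    completed = trials["completed"].to_numpy(dtype=bool)
    choice = trials["choice"].to_numpy(dtype=object)
    outcome = trials["outcome"].to_numpy(dtype=object)
    n = len(trials)
    labels = np.full(n, None, dtype=object)
    for t in range(back, n):
        chain = completed[t - back : t]
        if not chain.all():
            continue
        src = t - back
        c, o = choice[src], outcome[src]
        if c not in ("left", "right") or o not in ("correct", "incorrect"):
            continue
        labels[t] = ("C" if o == "correct" else "I") + ("L" if c == "left" else "R")
    return pd.Series(labels, index=trials.index, name=f"history_{back}back")


def iti_duration(trials: pd.DataFrame) -> pd.Series:
    """Seconds from each trial's choice report to the next trial initiation.

    Undefined (NaN) for the last trial and for trials without a choice
    report (early withdrawals).
    """
    report = trials["t_report"].to_numpy(dtype=float)
    init = trials["t_initiation"].to_numpy(dtype=float)
    out = np.full(len(trials), np.nan)
    out[:-1] = init[1:] - report[:-1]
    return pd.Series(out, index=trials.index, name="iti_duration")


@dataclass
class AlignedTensor:
    """Trials x timepoints x neurons activity on the common phase time base.

    ``phase_of_timepoint`` names the phase of each aligned sample and
    ``time_offset`` gives its time relative to that phase's anchor.
    ``frame_index`` records, per retained trial and timepoint, the source
    frame in the recording (used by the encoding design matrix to look up
    frame-indexed covariates). ``trial_meta`` holds, per retained trial, the
    original trial index, history labels, current choice/outcome, and the
    duration of the ITI preceding the trial.
    """

    activity: np.ndarray
    phase_of_timepoint: np.ndarray
    time_offset: np.ndarray
    frame_index: np.ndarray
    trial_meta: pd.DataFrame
    frame_rate: float
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[2]

    def phase_slice(self, phase: str) -> slice:
        idx = np.flatnonzero(self.phase_of_timepoint == phase)
        if idx.size == 0:
            raise KeyError(f"phase {phase!r} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def labels(self, back: int = 1) -> np.ndarray:
        col = "history" if back == 1 else "history_2back"
        return self.trial_meta[col].to_numpy(dtype=object)

    def select_timepoints(self, index: np.ndarray | slice) -> "AlignedTensor":
        """Restrict the tensor to a subset of aligned timepoints."""
        if isinstance(index, slice):
            index = np.arange(self.n_timepoints)[index]
        index = np.asarray(index, dtype=int)
        return AlignedTensor(
            activity=self.activity[:, index, :],
            phase_of_timepoint=self.phase_of_timepoint[index],
            time_offset=self.time_offset[index],
            frame_index=self.frame_index[:, index],
            trial_meta=self.trial_meta,
            frame_rate=self.frame_rate,
            n_dropped=self.n_dropped,
        )

    def select_phase(self, phase: str) -> "AlignedTensor":
        return self.select_timepoints(self.phase_slice(phase))


def _phase_anchors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial anchor times of the four phases (NaN when undefined).

    ITI phases anchor on the previous trial's events; stimulus/action on the
    current trial's.
    """
    report_prev = trials["t_report"].shift(1)
    outcome_end_prev = trials["t_outcome_end"].shift(1)
    return pd.DataFrame(
        {
            "earlyITI": report_prev,
            "lateITI": outcome_end_prev,
            "stimulus": trials["t_stim_onset"],
            "action": trials["t_center_exit"],
        },
        index=trials.index,
    )


def aligned_time_base(frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """(phase label, within-phase time offset) for each aligned timepoint."""
    counts = phase_n_timepoints(frame_rate)
    phases = []
    offsets = []
    for phase in PHASES:
        lo, _ = PHASE_WINDOWS[phase]
        n = counts[phase]
        phases.extend([phase] * n)
        offsets.extend(lo + np.arange(n) / frame_rate)
    return np.array(phases, dtype=object), np.array(offsets)


def align_activity(
    activity: np.ndarray,
    frame_rate: float,
    trials: pd.DataFrame,
    smooth: bool = False,
) -> AlignedTensor:
    """Cut a frames x neurons signal into the four trial phases.

    Parameters
    ----------
    activity
        Frames x neurons array (inferred spike rate for decoding, raw
        fluorescence for encoding).
    frame_rate
        Sampling rate in Hz.
    trials
        Trial table; trials must be completed, have a defined history label
        and all four windows inside the recording span to be retained.
    smooth
        If set (decoding path), the trace is Gaussian-smoothed along time
        with sigma = 1 frame before sampling.

    Returns
    -------
    AlignedTensor
        Retained trials only; dropped-trial count in ``n_dropped``.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2:
        raise ValueError("activity must be frames x neurons")
    if smooth:
        activity = gaussian_filter1d(activity, sigma=1.0, axis=0, mode="nearest")
    n_frames = activity.shape[0]

    hist1 = derive_history_labels(trials, back=1)
    hist2 = derive_history_labels(trials, back=2)
    itis = iti_duration(trials)
    anchors = _phase_anchors(trials)
    phase_labels, offsets = aligned_time_base(frame_rate)

    rows = []
    frame_rows = []
    meta = []
    n_dropped = 0
    for t in range(len(trials)):
        tr = trials.iloc[t]
        if not bool(tr["completed"]) or hist1.iloc[t] is None:
            continue
        anc = anchors.iloc[t]
        if anc.isna().any():
            n_dropped += 1
            continue
        # frame assignment: nearest frame at or before the target time
        target = np.empty(len(offsets))
        pos = 0
        for phase in PHASES:
            n = int((phase_labels == phase).sum())
            target[pos : pos + n] = anc[phase] + offsets[pos : pos + n]
            pos += n
        frames = np.floor(target * frame_rate).astype(int)
        if frames.min() < 0 or frames.max() >= n_frames:
            n_dropped += 1
            continue
        rows.append(activity[frames, :])
        frame_rows.append(frames)
        meta.append(
            {
                "trial": int(trials.index[t]),
                "history": hist1.iloc[t],
                "history_2back": hist2.iloc[t],
                "choice": tr["choice"],
                "outcome": tr["outcome"],
                "iti_duration": float(itis.iloc[t - 1]) if t > 0 else np.nan,
            }
        )

    if not rows:
        raise ValueError("no trials could be aligned")
    return AlignedTensor(
        activity=np.stack(rows),
        phase_of_timepoint=phase_labels,
        time_offset=offsets,
        frame_index=np.stack(frame_rows),
        trial_meta=pd.DataFrame(meta),
        frame_rate=frame_rate,
        n_dropped=n_dropped,
    )


def interpolate_gaps(activity: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate dropped frames (``valid == False``) per neuron."""
    activity = np.asarray(activity, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return activity.copy()
    idx = np.arange(activity.shape[0])
    out = activity.copy()
    good = np.flatnonzero(valid)
    for j in range(activity.shape[1]):
        out[~valid, j] = np.interp(idx[~valid], good, activity[good, j])
    return out
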