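"""Shared task definitions: configuration, trial-history labels, phase windows.

The task is a freely-moving pulsatile evidence-accumulation paradigm: a mouse
initiates a trial at a center port, views a 1 s train of brief visual flashes
whose event rate must be compared against an implicit category boundary
(12 events/s), and reports high-rate vs. low-rate by poking a right or left
side port. The constants here (stimulus rates, event geometry, trial-phase
windows, encoding-kernel spans) are referenced by both the synthetic session
generator and the analysis modules so that the generative model and the
fitted models share one description of the task.
"""

from __future__ import annotations

from dataclasses import dataclass


#: Trial-history contexts, ordered package-wide: previous Correct-Left,
#: Incorrect-Left, Incorrect-Right, Correct-Right.
HISTORY_LABELS: tuple[str, ...] = ("CL", "IL", "IR", "CR")

#: Trial phases on the common aligned time base, in temporal order.
PHASES: tuple[str, ...] = ("earlyITI", "lateITI", "stimulus", "action")

#: Phase windows in seconds relative to each phase anchor:
#: earlyITI anchors on the previous trial's choice report, lateITI on the
#: previous trial's reward-port exit (correct) or punishment/timeout end
#: (incorrect), stimulus on the current stimulus onset, and action on the
#: current center-port exit.
PHASE_WINDOWS: dict[str, tuple[float, float]] = {
    "earlyITI": (0.0, 1.0),
    "lateITI": (-1.0, 0.3),
    "stimulus": (-0.5, 1.0),
    "action": (-0.2, 0.3),
}

#: Encoding-model kernel spans in seconds (relative to the event).
STIM_KERNEL_SPAN: tuple[float, float] = (0.0, 0.5)
POKE_KERNEL_SPAN: tuple[float, float] = (-0.5, 1.0)

#: Head-orientation tuning: 360 degrees divided into 6-degree bins.
N_ANGLE_BINS: int = 60

#: Chest-position occupancy bin edge length in cm.
CHEST_BIN_CM: float = 1.28

#: Number of retained video / motion-energy factor components.
N_VIDEO_COMPONENTS: int = 200

#: Port identifiers in fixed order (left, center, right).
PORTS: tuple[str, ...] = ("left", "center", "right")


@dataclass(frozen=True)
class TaskConfig:
    """Static parameters of the evidence-accumulation task.

    Attributes
    ----------
    stimulus_rates
        Admissible event counts per second; the category boundary itself is
        never presented.
    category_boundary
        Rate (events/s) separating low-rate (left rewarded) from high-rate
        (right rewarded) trials.
    train_duration
        Duration of one stimulus train in seconds.
    event_duration
        Duration of a single flash in seconds.
    min_gap
        Minimum silent gap between consecutive flashes in seconds.
    frame_rate
        Acquisition rate (Hz) shared by imaging, pose and video streams.
    arena_size
        Arena side lengths (width, height) in cm.
    timeout
        Punishment timeout after incorrect choices, in seconds.
    """

    stimulus_rates: tuple[int, ...] = (4, 6, 8, 10, 14, 16, 18, 20)
    category_boundary: float = 12.0
    train_duration: float = 1.0
    event_duration: float = 0.015
    min_gap: float = 0.025
    frame_rate: float = 30.0
    arena_size: tuple[float, float] = (20.0, 20.0)
    timeout: float = 2.0

    def __post_init__(self) -> None:
        if self.category_boundary in self.stimulus_rates:
            raise ValueError("category boundary must not be a presented rate")
        for r in self.stimulus_rates:
            occupied = r * self.event_duration + (r - 1) * self.min_gap
            if occupied > self.train_duration:
                raise ValueError(
                    f"rate {r} events/s cannot be packed into "
                    f"{self.train_duration} s with event duration "
                    f"{self.event_duration} s and minimum gap {self.min_gap} s"
                )

    @property
    def rate_min(self) -> float:
        return min(self.stimulus_rates)

    @property
    def rate_max(self) -> float:
        return max(self.stimulus_rates)


def phase_n_timepoints(frame_rate: float) -> dict[str, int]:
    """Number of aligned samples per phase at the given frame rate.

    Window lengths are fixed (1.0, 1.3, 1.5, 0.5 s); sample counts use
    round-half-even on length x frame_rate.
    """
    out = {}
    for phase, (lo, hi) in PHASE_WINDOWS.items():
        # round-half-even via Python's round()
        out[phase] = int(round((hi - lo) * frame_rate))
    return out


def total_aligned_timepoints(frame_rate: float) -> int:
    return sum(phase_n_timepoints(frame_rate).values())
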