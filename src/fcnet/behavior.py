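"""Behavioral indices: sucrose preference, tone-locked freezing, motion index.

The fear-conditioning session layout is a 180 s baseline followed by four 20 s
tones separated by 190 s inter-trial intervals (a 17 min session).  Freezing
is quantified in one 60 s epoch per trial — the 20 s pre-shock tone interval
plus a 40 s post-shock interval, anchored at tone onset — as a bout count
(bouts assigned to the epoch containing their start) and as percent time
(overlap duration / 60 s).  Bouts must last at least 30 frames at 30 fps
(1 s).  The motion index is averaged over the same epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SucroseRecord",
    "FearSessionSpec",
    "FreezeEventLog",
    "sucrose_index",
    "epoch_windows",
    "freezing_counts",
    "motion_epoch_summary",
]


@dataclass(frozen=True)
class SucroseRecord:
    subject_id: str
    s: float  # sucrose consumed over 24 h, mL
    w: float  # water consumed over 24 h, mL

    def __post_init__(self) -> None:
        if self.s < 0 or self.w < 0:
            raise ValueError("volumes must be nonnegative")


@dataclass(frozen=True)
class FearSessionSpec:
    baseline_s: float = 180.0
    tone_dur_s: float = 20.0
    iti_s: float = 190.0
    n_trials: int = 4
    pre_shock_s: float = 20.0
    post_shock_s: float = 40.0
    fps: int = 30
    min_freeze_frames: int = 30

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.pre_shock_s + self.post_shock_s <= 0:
            raise ValueError("epoch length must be positive")

    @property
    def epoch_s(self) -> float:
        return self.pre_shock_s + self.post_shock_s

    @property
    def min_bout_s(self) -> float:
        return self.min_freeze_frames / self.fps

    @property
    def session_s(self) -> float:
        # baseline, then each tone followed by a full inter-trial interval
        return self.baseline_s + self.n_trials * (self.tone_dur_s + self.iti_s)


@dataclass
class FreezeEventLog:
    """Non-overlapping, time-ordered freezing bouts for one subject-day."""

    subject_id: str
    day: int
    events: list[tuple[float, float]] = field(default_factory=list)

    def validate(self, spec: FearSessionSpec) -> None:
        prev_end = -np.inf
        for start, end in self.events:
            if end <= start:
                raise ValueError(f"bout ({start}, {end}) has nonpositive duration")
            if start < prev_end:
                raise ValueError("bouts must be ordered and non-overlapping")
            if end - start < spec.min_bout_s - 1e-12:
                raise ValueError(
                    f"bout ({start}, {end}) shorter than the minimum "
                    f"{spec.min_bout_s:.2f} s ({spec.min_freeze_frames} frames)"
                )
            prev_end = end


def sucrose_index(rec: SucroseRecord) -> float:
    """Sucrose preference index S_I = (s - w) / (s + w), in [-1, 1]."""
    total = rec.s + rec.w
    if total <= 0:
        raise ValueError("s + w must be positive for a defined index")
    return (rec.s - rec.w) / total


def epoch_windows(spec: FearSessionSpec) -> list[tuple[float, float]]:
    """The per-trial 60 s quantification windows, anchored at tone onsets.

    Tone onsets fall at baseline + (trial - 1) * (tone + ITI).
    """
    windows = []
    for trial in range(spec.n_trials):
        onset = spec.baseline_s + trial * (spec.tone_dur_s + spec.iti_s)
        windows.append((onset, onset + spec.epoch_s))
    return windows


def freezing_counts(
    log: FreezeEventLog, spec: FearSessionSpec
) -> tuple[np.ndarray, int, np.ndarray]:
    """Per-trial bout counts, daily total, and percent-time freezing.

    A bout is counted in the window containing its *start*; percent time is
    the summed bout overlap with each window divided by the window length.
    """
    log.validate(spec)
    windows = epoch_windows(spec)
    counts = np.zeros(len(windows), dtype=int)
    pct_time = np.zeros(len(windows))
    for start, end in log.events:
        for t, (w0, w1) in enumerate(windows):
            if w0 <= start < w1:
                counts[t] += 1
            overlap = max(0.0, min(end, w1) - max(start, w0))
            pct_time[t] += overlap / (w1 - w0)
    return counts, int(counts.sum()), pct_time


def motion_epoch_summary(
    samples: Sequence[tuple[float, float]], spec: FearSessionSpec
) -> np.ndarray:
    """Mean motion index (a.u.) per 60 s epoch; empty epochs are NaN.

    ``samples`` is a time-sorted sequence of (time_s, motion_au) pairs.
    """
    times = np.array([t for t, _ in samples], dtype=float)
    vals = np.array([v for _, v in samples], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("motion samples must be sorted by time")
    out = np.full(spec.n_trials, np.nan)
    for t, (w0, w1) in enumerate(epoch_windows(spec)):
        mask = (times >= w0) & (times < w1)
        if mask.any():
            out[t] = float(vals[mask].mean())
    return out
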