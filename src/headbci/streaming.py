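"""Pseudo-online evaluation: frame-by-frame classification of a held-out stream.

The fitted classifier is slid across the continuous 128 Hz test stream in
250-ms windows shifted by one frame (7.8 ms), producing a per-frame
probability triple (none, left, right). Probabilities are indexed at the
CENTER of their window; in a live system that information only becomes
available half a window (125 ms) later, so the availability delay is carried
as metadata rather than silently shifted.

Onset-locked averaging aligns the trace to rotation onsets (time 0) and
averages across events, yielding the mean and standard deviation of each class
probability as a function of time before the movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import RotationEvent, scored
from .model import RotationFit

__all__ = ["ProbabilityTrace", "OnsetLockedAverage", "stream_classify", "lock_to_onsets"]


@dataclass
class ProbabilityTrace:
    """Per-position class probabilities over a continuous stream.

    ``times`` are window centers on the stream's own clock; add
    ``availability_delay`` to get the earliest moment each triple could be
    acted on in real time.
    """

    times: np.ndarray             # (n_positions,) window-center times, s
    probs: np.ndarray             # (n_positions, 3) in (none, left, right) order
    rate: float
    width_frames: int
    convention: str = "center"

    @property
    def availability_delay(self) -> float:
        return self.width_frames / (2.0 * self.rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "p_none": self.probs[:, 0],
                "p_left": self.probs[:, 1],
                "p_right": self.probs[:, 2],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OnsetLockedAverage:
    """Mean +/- sd of class probabilities at each time relative to onset."""

    times: np.ndarray             # strictly increasing, s relative to onset
    mean: np.ndarray              # (n_times, 3)
    sd: np.ndarray                # (n_times, 3), >= 0
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for i, name in enumerate(("none", "left", "right")):
            cols[f"p_{name}"] = self.mean[:, i]
            cols[f"sd_{name}"] = self.sd[:, i]
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stream_classify(
    fit: RotationFit,
    eeg: np.ndarray,
    rate: float = 128.0,
    t0: float = 0.0,
    width_frames: int = 32,
    batch: int = 4096,
) -> ProbabilityTrace:
    """Classify every window position of a continuous (channels x frames) stream.

    Position p covers frames [p, p + width) and is indexed at its center time;
    the number of positions is n_frames - width + 1. Each triple equals
    ``fit.predict_proba`` on the window cut at that position.
    """
    n_ch, n_frames = eeg.shape
    if n_frames < width_frames:
        raise ValueError(f"stream of {n_frames} frames shorter than one {width_frames}-frame window")
    n_pos = n_frames - width_frames + 1
    # (channels, positions, width) view; no copy until a batch is flattened.
    view = np.lib.stride_tricks.sliding_window_view(eeg, width_frames, axis=1)
    probs = np.empty((n_pos, 3), dtype=np.float32)
    for lo in range(0, n_pos, batch):
        hi = min(lo + batch, n_pos)
        block = np.ascontiguousarray(view[:, lo:hi].transpose(1, 0, 2)).reshape(hi - lo, n_ch * width_frames)
        probs[lo:hi] = fit.predict_proba(block)
    times = t0 + (np.arange(n_pos) + width_frames / 2.0) / rate
    return ProbabilityTrace(times=times, probs=probs, rate=rate, width_frames=width_frames)


def lock_to_onsets(
    trace: ProbabilityTrace,
    events: Sequence[RotationEvent],
    window: tuple[float, float] = (-1.0, 0.0),
    direction: Optional[str] = None,
    center_outward_only: bool = True,
) -> OnsetLockedAverage:
    """Average the probability trace across onsets of one direction.

    Only center-outward events are locked by default. Events whose relative
    window is not fully covered by the trace are skipped. Raises when no
    usable event remains.
    """
    use = scored(events) if center_outward_only else list(events)
    if direction is not None:
        use = [e for e in use if e.direction == direction]

    rate = trace.rate
    rel = np.arange(round(window[0] * rate), round(window[1] * rate) + 1) / rate
    t_start = trace.times[0]
    n_pos = trace.probs.shape[0]

    stacks = []
    for e in use:
        pos = np.round((e.onset + rel - t_start) * rate).astype(int)
        if pos[0] < 0 or pos[-1] >= n_pos:
            continue
        stacks.append(trace.probs[pos])
    if not stacks:
        raise ValueError("no event with full trace coverage in the requested window")
    arr = np.stack(stacks)  # (events, times, 3)
    return OnsetLockedAverage(
        times=rel,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0),
        n_events=arr.shape[0],
    )
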