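"""Head-rotation extraction from the IMU yaw-velocity trace.

Movement onset is the first sample at which |velocity| exceeds a noise
threshold and stays above it for a full sliding window (125 ms by default).
The threshold is a multiple of the velocity standard deviation measured while
the head is steady. Detected spans yield per-frame labels (none/left/right),
and cumulative integration of the velocity decides which rotations start from
center — only those are scored downstream, because for a rotation launched
from a side the direction of the next movement is already known.

Sign convention: rightward rotation is positive yaw velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .events import LEFT, RIGHT, RotationEvent

__all__ = [
    "OnsetDetectorConfig",
    "estimate_noise_threshold",
    "detect_onsets",
    "label_and_filter",
    "NONE_LABEL",
    "LEFT_LABEL",
    "RIGHT_LABEL",
]

NONE_LABEL, LEFT_LABEL, RIGHT_LABEL = 0, 1, 2


@dataclass(frozen=True)
class OnsetDetectorConfig:
    """Detector parameters.

    ``window``: the sliding window (s) the velocity must stay above threshold.
    ``threshold_multiplier``: threshold = multiplier x sd(stationary velocity).
    ``stationary_segment``: (start, end) seconds of known head-steady data, or
    "auto" to use the quietest 2-s chunk of the trace.
    ``center_tolerance``: |integrated yaw| (deg) at onset below which the head
    counts as facing center.
    """

    window: float = 0.125
    threshold_multiplier: float = 3.0
    stationary_segment: Union[tuple[float, float], str] = "auto"
    center_tolerance: float = 5.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")


def estimate_noise_threshold(
    velocity: np.ndarray, cfg: OnsetDetectorConfig = OnsetDetectorConfig(), imu_rate: float = 128.0
) -> float:
    """Noise threshold = multiplier x sd of the stationary-segment velocity."""
    velocity = np.asarray(velocity, dtype=float)
    if cfg.stationary_segment == "auto":
        chunk = int(round(2.0 * imu_rate))
        n_chunks = velocity.size // chunk
        if n_chunks < 1:
            raise ValueError("trace too short to find a stationary segment")
        sds = velocity[: n_chunks * chunk].reshape(n_chunks, chunk).std(axis=1)
        sd = float(sds.min())
    else:
        start, end = cfg.stationary_segment
        if end - start < cfg.window:
            raise ValueError("stationary segment shorter than the detector window")
        seg = velocity[int(round(start * imu_rate)) : int(round(end * imu_rate))]
        sd = float(seg.std())
    if sd <= 0:
        raise ValueError("stationary segment has zero variance; cannot calibrate a threshold")
    return cfg.threshold_multiplier * sd


def _sustained(mask: np.ndarray, width: int) -> np.ndarray:
    """sustained[t] is True iff mask[t:t+width] is all True (False near the end)."""
    counts = np.convolve(mask.astype(int), np.ones(width, dtype=int), mode="full")[width - 1 : mask.size]
    out = np.zeros(mask.size, dtype=bool)
    out[: counts.size] = counts == width
    return out


def detect_onsets(
    velocity: np.ndarray,
    threshold: float,
    cfg: OnsetDetectorConfig = OnsetDetectorConfig(),
    imu_rate: float = 128.0,
) -> list[RotationEvent]:
    """Scan the trace for sustained supra-threshold velocity excursions.

    Onset: first sample where |v| > threshold with the whole following window
    above threshold. Offset: first subsequent sample opening a full window
    below threshold (end of trace if it never returns). Direction is the sign
    of the velocity at onset. Events are non-overlapping and time-ordered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    velocity = np.asarray(velocity, dtype=float)
    if velocity.size == 0:
        return []
    width = max(1, int(round(cfg.window * imu_rate)))
    above = np.abs(velocity) > threshold
    onset_ok = _sustained(above, width)
    offset_ok = _sustained(~above, width)

    events: list[RotationEvent] = []
    i = 0
    n = velocity.size
    while i < n:
        onset_idx = np.argmax(onset_ok[i:]) + i
        if not onset_ok[onset_idx]:
            break
        off_candidates = offset_ok[onset_idx:]
        off_rel = int(np.argmax(off_candidates))
        offset_idx = onset_idx + off_rel if off_candidates[off_rel] else n
        direction = RIGHT if velocity[onset_idx] > 0 else LEFT
        events.append(
            RotationEvent(
                onset=onset_idx / imu_rate,
                direction=direction,
                offset=offset_idx / imu_rate,
                from_center=True,  # provisional; label_and_filter decides
            )
        )
        i = offset_idx if offset_idx > onset_idx else onset_idx + 1
    return events


def label_and_filter(
    events: Sequence[RotationEvent],
    n_frames: int,
    velocity: Optional[np.ndarray] = None,
    imu_rate: float = 128.0,
    cfg: OnsetDetectorConfig = OnsetDetectorConfig(),
) -> tuple[np.ndarray, list[RotationEvent]]:
    """Per-frame labels plus the center-outward subset of ``events``.

    Head position is obtained by integrating the velocity only inside detected
    rotation spans (suppressing noise drift between movements). An event is
    from-center when the integrated yaw at its onset is within
    ``cfg.center_tolerance`` degrees of the starting orientation.

    Returns (labels, scored_events): labels is an int array over the IMU frame
    grid with 0=none, 1=left, 2=right exactly inside detected spans;
    scored_events carries every event with its ``from_center`` flag resolved.
    """
    labels = np.zeros(n_frames, dtype=np.int8)
    masked = None
    if velocity is not None:
        masked = np.zeros(n_frames, dtype=float)

    spans = []
    for e in events:
        i0 = int(round(e.onset * imu_rate))
        i1 = min(int(round(e.offset * imu_rate)), n_frames)
        spans.append((i0, i1, e))
        labels[i0:i1] = LEFT_LABEL if e.direction == LEFT else RIGHT_LABEL
        if masked is not None:
            masked[i0:i1] = velocity[i0:i1]

    if masked is not None:
        position = np.concatenate([[0.0], np.cumsum(masked) / imu_rate])
    else:
        position = None

    resolved: list[RotationEvent] = []
    for i0, _i1, e in spans:
        if position is not None:
            from_center = abs(position[i0]) <= cfg.center_tolerance
        else:
            from_center = e.from_center
        resolved.append(RotationEvent(e.onset, e.direction, e.offset, from_center))
    return labels, resolved
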