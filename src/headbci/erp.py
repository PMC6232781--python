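"""Pre-onset ERP and lateralization topography.

For each electrode, the mean voltage over the 1000 ms preceding rotation onset
is computed from onset-locked epochs baselined at -1000 ms (a short 3-frame
mean by default: a single-sample baseline would inject that sample's noise
into every time point). The left-minus-right difference map is built with
equal numbers of left and right rotations per participant (seeded
subsampling), averaging first within and then across participants so every
participant weighs equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import LEFT, RIGHT, RotationEvent, scored
from .montage import CHANNELS_32

__all__ = ["ERPResult", "TopographyMap", "pre_onset_erp", "lateralization_difference"]

logger = logging.getLogger(__name__)


@dataclass
class ERPResult:
    """Onset-locked, baselined pre-movement potentials for one direction."""

    epochs: np.ndarray        # (n_events, n_channels, n_times), baselined
    times: np.ndarray         # s relative to onset (negative)
    channels: Sequence[str]
    n_events: int

    @property
    def timecourse(self) -> np.ndarray:
        """(n_channels, n_times) mean over events."""
        return self.epochs.mean(axis=0)

    @property
    def window_mean(self) -> np.ndarray:
        """Per-electrode mean voltage over the whole pre-onset window."""
        return self.timecourse.mean(axis=1)


def baseline_epochs(epochs: np.ndarray, baseline_frames: int = 3) -> np.ndarray:
    """Subtract each epoch's per-channel mean over its first ``baseline_frames``.

    Idempotent: the baseline of an already-baselined epoch is zero.
    """
    base = epochs[:, :, :baseline_frames].mean(axis=2, keepdims=True)
    return epochs - base


def pre_onset_erp(
    eeg: np.ndarray,
    events: Sequence[RotationEvent],
    direction: Optional[str] = None,
    rate: float = 128.0,
    window: float = 1.0,
    baseline_frames: int = 3,
    channels: Sequence[str] = CHANNELS_32,
    center_outward_only: bool = True,
) -> ERPResult:
    """Cut, baseline and average the ``window`` seconds before each onset.

    Epochs are baselined on the segment at -window (default -1000 ms). Events
    without full pre-onset coverage are skipped with a log entry.
    """
    use = scored(events) if center_outward_only else list(events)
    if direction is not None:
        use = [e for e in use if e.direction == direction]
    width = int(round(window * rate))
    stacks = []
    for e in use:
        i1 = int(round(e.onset * rate))
        i0 = i1 - width
        if i0 < 0 or i1 > eeg.shape[1]:
            logger.info("skipping onset %.3fs: no full %.0f ms pre-onset coverage", e.onset, window * 1e3)
            continue
        stacks.append(eeg[:, i0:i1])
    if not stacks:
        raise ValueError("no event with full pre-onset coverage")
    epochs = baseline_epochs(np.stack(stacks), baseline_frames)
    times = (np.arange(width) - width) / rate
    return ERPResult(epochs=epochs, times=times, channels=tuple(channels), n_events=epochs.shape[0])


@dataclass
class TopographyMap:
    """Per-electrode scalar map (mean voltage or left-minus-right difference)."""

    values: np.ndarray
    channels: Sequence[str]
    n_events_per_side: list[int]
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode": list(self.channels), "value": self.values})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __getitem__(self, electrode: str) -> float:
        return float(self.values[list(self.channels).index(electrode)])


def lateralization_difference(
    per_participant: Sequence[tuple[ERPResult, ERPResult]],
    rng: np.random.Generator,
) -> TopographyMap:
    """Grand-average left-minus-right pre-onset voltage per electrode.

    ``per_participant`` holds one (left ERP, right ERP) pair per participant.
    Within each participant the more numerous side is subsampled (seeded) to
    the smaller count, the per-electrode window means are differenced, and the
    grand map is the unweighted mean over participants. Participants missing a
    side are excluded with a log entry.
    """
    maps = []
    counts = []
    channels = None
    for i, (left_erp, right_erp) in enumerate(per_participant):
        if left_erp.n_events == 0 or right_erp.n_events == 0:
            logger.info("participant %d missing one rotation side; excluded", i)
            continue
        channels = left_erp.channels
        n = min(left_erp.n_events, right_erp.n_events)
        sides = []
        for erp in (left_erp, right_erp):
            idx = np.sort(rng.choice(erp.n_events, size=n, replace=False))
            sides.append(erp.epochs[idx].mean(axis=0).mean(axis=1))  # per-electrode window mean
        maps.append(sides[0] - sides[1])
        counts.append(n)
    if not maps:
        raise ValueError("no participant with both rotation directions")
    return TopographyMap(
        values=np.mean(maps, axis=0),
        channels=channels,
        n_events_per_side=counts,
        provenance=f"left-minus-right, {len(maps)} participant(s), equal counts per side",
    )
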