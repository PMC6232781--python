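"""Building the labeled-epoch dataset.

Each scored (center-outward) rotation contributes seven partially overlapping
250-ms windows: the closest ends 188 ms before onset, the furthest starts
488 ms before onset, so the seven start offsets are spaced evenly over
[-488, -438] ms and the middle window is centered 338 ms before onset.
No-rotation windows never overlap a rotation span and always end at least
1000 ms before the next onset. Classes are balanced by undersampling to the
smaller of the left/right counts. The data are split 72/18/10, the 10% being
one contiguous test stream (4 minutes of a 40-minute session); all seven
windows of one rotation stay in the same partition.

Features are the flattened channel x sample window, channel-major
(channel index outer, time inner): 32 channels x 32 samples = 1024 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .events import LEFT, RotationEvent, scored
from .preprocess import PreprocConfig, reject_interval

__all__ = [
    "WindowSpec",
    "SplitSpec",
    "EpochDataset",
    "rotation_windows",
    "no_rotation_windows",
    "balance_classes",
    "split",
    "build_dataset",
    "CLASS_NAMES",
]

logger = logging.getLogger(__name__)

# Class-index convention fixed by the probability-vector ordering (none, left, right).
CLASS_NAMES = ("none", "left", "right")
NONE, LEFT_CLS, RIGHT_CLS = 0, 1, 2


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the pre-rotation windows (seconds)."""

    width: float = 0.250
    closest_end: float = 0.188      # closest window ends this long before onset
    furthest_start: float = 0.488   # furthest window starts this long before onset
    n_windows: int = 7
    no_rotation_clearance: float = 1.000  # no-rotation windows end >= this before an onset

    def __post_init__(self) -> None:
        # Overlap: the furthest window's end must fall inside the closest
        # window, i.e. before that window's start-side edge plus its width.
        if not self.furthest_start - self.width < self.closest_end + self.width:
            raise ValueError("windows must overlap: furthest end must reach past the closest start")
        if self.n_windows % 2 == 0:
            raise ValueError("n_windows must be odd (a middle window must exist)")

    @property
    def middle_center(self) -> float:
        """Time before onset of the middle window's center."""
        starts = np.linspace(-self.furthest_start, -(self.closest_end + self.width), self.n_windows)
        return float(-(starts[self.n_windows // 2] + self.width / 2))


@dataclass(frozen=True)
class SplitSpec:
    """72/18/10 split with a contiguous test stream; repeated n_repetitions times."""

    train_frac: float = 0.72
    val_frac: float = 0.18
    test_frac: float = 0.10
    n_repetitions: int = 3

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def rotation_windows(onset: float, spec: WindowSpec = WindowSpec()) -> list[tuple[float, float]]:
    """The seven (start, end) spans preceding ``onset``.

    Start offsets are evenly spaced from onset - furthest_start to
    onset - (closest_end + width); their union spans exactly
    [onset - furthest_start, onset - closest_end].
    """
    if onset - spec.furthest_start < 0:
        raise ValueError(f"onset {onset:.3f}s too early for a {spec.furthest_start}s look-back")
    starts = onset + np.linspace(-spec.furthest_start, -(spec.closest_end + spec.width), spec.n_windows)
    return [(float(s), float(s + spec.width)) for s in starts]


def no_rotation_windows(
    events: Sequence[RotationEvent],
    duration: float,
    n_required: int,
    rng: np.random.Generator,
    spec: WindowSpec = WindowSpec(),
    rate: float = 128.0,
) -> list[tuple[float, float]]:
    """Sample no-rotation window spans, uniform over the eligible frame grid.

    A start frame is eligible when its window overlaps no rotation span and
    ends at least ``spec.no_rotation_clearance`` before every subsequent
    onset (detected returns count too: any movement makes a frame ineligible).
    """
    width_f = int(round(spec.width * rate))
    n_starts = int(round(duration * rate)) - width_f + 1
    if n_starts <= 0:
        raise ValueError("recording shorter than one window")
    eligible = np.ones(n_starts, dtype=bool)
    clearance_f = int(round(spec.no_rotation_clearance * rate))
    for e in events:
        onset_f = int(round(e.onset * rate))
        offset_f = int(round(e.offset * rate))
        lo = max(0, onset_f - clearance_f - width_f)
        hi = min(n_starts, offset_f)
        eligible[lo:hi] = False
    pool = np.flatnonzero(eligible)
    if pool.size < n_required:
        raise ValueError(
            f"only {pool.size} eligible no-rotation start frames, {n_required} requested "
            f"(short by {n_required - pool.size})"
        )
    starts = np.sort(rng.choice(pool, size=n_required, replace=False))
    return [(float(s / rate), float((s + width_f) / rate)) for s in starts]


def balance_classes(
    indices_by_class: dict[int, np.ndarray], rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Undersample every class to min(count_left, count_right), seeded.

    Surplus epochs are dropped uniformly at random; order within a class is
    preserved.
    """
    for cls in (NONE, LEFT_CLS, RIGHT_CLS):
        if cls not in indices_by_class or len(indices_by_class[cls]) == 0:
            raise ValueError(f"class {CLASS_NAMES[cls]!r} is empty; cannot balance")
    n = min(len(indices_by_class[LEFT_CLS]), len(indices_by_class[RIGHT_CLS]))
    if len(indices_by_class[NONE]) < n:
        raise ValueError("fewer no-rotation epochs than rotation epochs; sample more")
    out = {}
    for cls, idx in indices_by_class.items():
        idx = np.asarray(idx)
        keep = np.sort(rng.choice(len(idx), size=n, replace=False))
        out[cls] = idx[keep]
    return out


@dataclass
class EpochDataset:
    """Flat container of labeled epochs with provenance.

    ``group`` ties the seven windows of one rotation together (no-rotation
    windows get singleton groups) so splits cannot leak a rotation across the
    train/test boundary. ``block`` and window times are on each block's own
    128 Hz timeline.
    """

    features: np.ndarray          # (n, n_channels*width_frames) float32
    labels: np.ndarray            # (n,) int8, 0=none 1=left 2=right
    t_center: np.ndarray          # (n,) float, window center minus onset; nan for none
    group: np.ndarray             # (n,) int
    block: np.ndarray             # (n,) int
    start: np.ndarray             # (n,) float, window start (s, block timeline)
    end: np.ndarray               # (n,) float
    split_tag: Optional[np.ndarray] = None  # (n,) of {"train","val","test"} after split()
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, mask: np.ndarray) -> "EpochDataset":
        return EpochDataset(
            features=self.features[mask],
            labels=self.labels[mask],
            t_center=self.t_center[mask],
            group=self.group[mask],
            block=self.block[mask],
            start=self.start[mask],
            end=self.end[mask],
            split_tag=None if self.split_tag is None else self.split_tag[mask],
            meta=dict(self.meta),
        )

    def partition(self, tag: str) -> "EpochDataset":
        if self.split_tag is None:
            raise ValueError("dataset has not been split")
        return self.subset(self.split_tag == tag)

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == i)) for i, name in enumerate(CLASS_NAMES)}

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("features", "labels", "t_center", "group", "block", "start", "end"):
                f.create_dataset(name, data=getattr(self, name))
            if self.split_tag is not None:
                f.create_dataset("split_tag", data=np.char.encode(self.split_tag.astype(str)))
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "EpochDataset":
        with h5py.File(path, "r") as f:
            kw = {name: f[name][()] for name in ("features", "labels", "t_center", "group", "block", "start", "end")}
            tag = np.char.decode(f["split_tag"][()]) if "split_tag" in f else None
            meta = dict(f.attrs)
        return cls(split_tag=tag, meta=meta, **kw)


def _cut(eeg: np.ndarray, span: tuple[float, float], rate: float, width_f: int) -> Optional[np.ndarray]:
    """Cut one window, snapped to the frame grid; None when out of bounds."""
    i0 = int(round(span[0] * rate))
    if i0 < 0 or i0 + width_f > eeg.shape[1]:
        return None
    return eeg[:, i0 : i0 + width_f]


def build_dataset(
    blocks: Sequence[tuple[np.ndarray, Sequence[RotationEvent]]],
    rng: np.random.Generator,
    spec: WindowSpec = WindowSpec(),
    preproc: PreprocConfig = PreprocConfig(),
    rate: float = 128.0,
    none_per_rotation: Optional[int] = None,
) -> EpochDataset:
    """Cut, reject, and assemble epochs from preprocessed blocks.

    ``blocks`` is a list of (eeg at ``rate``, detected events) pairs. Only
    center-outward events contribute rotation windows; every detected event
    constrains no-rotation sampling. ``none_per_rotation`` defaults to
    2 x n_windows so balancing never starves the none class.
    """
    width_f = int(round(spec.width * rate))
    feats, labels, t_center, group, block_ids, starts, ends = [], [], [], [], [], [], []
    next_group = 0
    rejected = 0
    for b, (eeg, evts) in enumerate(blocks):
        duration = eeg.shape[1] / rate
        used = scored(evts)
        for e in used:
            try:
                spans = rotation_windows(e.onset, spec)
            except ValueError:
                logger.info("block %d: skipping onset %.3fs (too early in recording)", b, e.onset)
                continue
            gid = next_group
            next_group += 1
            cls = LEFT_CLS if e.direction == LEFT else RIGHT_CLS
            for s0, s1 in spans:
                win = _cut(eeg, (s0, s1), rate, width_f)
                if win is None:
                    continue
                if not reject_interval(win, preproc):
                    rejected += 1
                    continue
                feats.append(win.astype(np.float32).ravel())
                labels.append(cls)
                t_center.append((s0 + s1) / 2 - e.onset)
                group.append(gid)
                block_ids.append(b)
                starts.append(s0)
                ends.append(s1)
        n_none = (none_per_rotation or 2 * spec.n_windows) * max(len(used), 1)
        for s0, s1 in no_rotation_windows(evts, duration, n_none, rng, spec, rate):
            win = _cut(eeg, (s0, s1), rate, width_f)
            if win is None:
                continue
            if not reject_interval(win, preproc):
                rejected += 1
                continue
            feats.append(win.astype(np.float32).ravel())
            labels.append(NONE)
            t_center.append(np.nan)
            group.append(next_group)
            next_group += 1
            block_ids.append(b)
            starts.append(s0)
            ends.append(s1)
    if rejected:
        logger.info("rejected %d epochs exceeding the %.0f-unit amplitude threshold", rejected, preproc.artifact_threshold)
    return EpochDataset(
        features=np.array(feats, dtype=np.float32),
        labels=np.array(labels, dtype=np.int8),
        t_center=np.array(t_center, dtype=float),
        group=np.array(group, dtype=int),
        block=np.array(block_ids, dtype=int),
        start=np.array(starts, dtype=float),
        end=np.array(ends, dtype=float),
        meta={"rate": rate, "width_frames": width_f, "n_rejected": rejected},
    )


def split(
    dataset: EpochDataset,
    block_durations: Sequence[float],
    rng: np.random.Generator,
    spec: SplitSpec = SplitSpec(),
    test_block: int = -1,
) -> tuple[EpochDataset, tuple[int, float, float]]:
    """Assign every epoch to train/val/test; the test set is one contiguous stream.

    The test stream (test_frac of the total duration, 4 min of 40 by default)
    sits at the end of the last block. Epochs lying wholly inside it are test
    epochs; the rest are split train/val per block at the rotation-group level
    in the 72:18 ratio. Returns the tagged dataset and (block, t0, t1) of the
    test stream.
    """
    total = float(sum(block_durations))
    test_dur = spec.test_frac * total
    tb = test_block % len(block_durations)
    t1 = float(block_durations[tb])
    t0 = t1 - test_dur
    if t0 < 0:
        raise ValueError("test stream longer than its block")

    tags = np.empty(len(dataset), dtype=object)
    in_test = (dataset.block == tb) & (dataset.start >= t0) & (dataset.end <= t1)
    # A rotation group straddling the boundary is dropped entirely (no leakage).
    test_groups = set(dataset.group[in_test])
    straddle = np.array([g in test_groups for g in dataset.group]) & ~in_test
    tags[in_test] = "test"
    tags[straddle] = "dropped"

    test_events = np.sum(in_test & (dataset.labels != NONE))
    if test_events == 0:
        raise ValueError("test stream contains zero rotation epochs; regenerate or move it")

    train_share = spec.train_frac / (spec.train_frac + spec.val_frac)
    rest = ~(in_test | straddle)
    for b in range(len(block_durations)):
        sel = rest & (dataset.block == b)
        groups = np.unique(dataset.group[sel])
        perm = rng.permutation(groups)
        n_train = int(round(train_share * len(groups)))
        train_groups = set(perm[:n_train])
        for i in np.flatnonzero(sel):
            tags[i] = "train" if dataset.group[i] in train_groups else "val"

    out = EpochDataset(
        features=dataset.features,
        labels=dataset.labels,
        t_center=dataset.t_center,
        group=dataset.group,
        block=dataset.block,
        start=dataset.start,
        end=dataset.end,
        split_tag=tags.astype(str),
        meta=dict(dataset.meta, test_block=tb, test_start=t0, test_end=t1),
    )
    return out, (tb, t0, t1)


def balanced_partition(dataset: EpochDataset, tag: str, rng: np.random.Generator) -> EpochDataset:
    """One split partition, balanced to equal class counts."""
    part = dataset.partition(tag)
    by_class = {c: np.flatnonzero(part.labels == c) for c in (NONE, LEFT_CLS, RIGHT_CLS)}
    balanced = balance_classes(by_class, rng)
    keep = np.sort(np.concatenate(list(balanced.values())))
    return part.subset(keep)
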