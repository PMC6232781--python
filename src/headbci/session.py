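"""Recording container and on-disk round trip.

A :class:`RecordingSession` holds one block of synchronized data: multichannel
EEG, the co-registered head yaw angular-velocity trace from the headset IMU,
and sampling metadata. Sessions are written as a directory with

- ``eeg.h5``      — HDF5 container: dataset ``eeg`` (channels x samples), attrs
                    ``rate_hz`` and ``channels``
- ``imu.csv``     — two columns ``time_s,yaw_velocity`` (deg/s, right positive)
- ``ground_truth.json`` — planted events and artifact intervals, when known
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .events import RotationEvent
from .montage import CHANNELS_32

EEG_FILE = "eeg.h5"
IMU_FILE = "imu.csv"
GT_FILE = "ground_truth.json"


@dataclass
class GroundTruth:
    """Planted schedule of a synthetic session: scored events + artifact spans."""

    events: list[RotationEvent] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be strictly time-ordered")

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "onset": e.onset,
                    "direction": e.direction,
                    "offset": e.offset,
                    "from_center": e.from_center,
                }
                for e in self.events
            ],
            "artifact_intervals": [list(iv) for iv in self.artifact_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            events=[RotationEvent(**e) for e in d["events"]],
            artifact_intervals=[tuple(iv) for iv in d["artifact_intervals"]],
        )


@dataclass
class RecordingSession:
    """One block: EEG (channels x samples), yaw velocity, rates, metadata."""

    eeg: np.ndarray
    eeg_rate: float
    imu: np.ndarray
    imu_rate: float
    channels: Sequence[str] = CHANNELS_32
    ground_truth: Optional[GroundTruth] = None

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    @property
    def imu_times(self) -> np.ndarray:
        return np.arange(self.imu.shape[0]) / self.imu_rate

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with h5py.File(directory / EEG_FILE, "w") as f:
            ds = f.create_dataset("eeg", data=self.eeg)
            ds.attrs["rate_hz"] = float(self.eeg_rate)
            ds.attrs["channels"] = list(self.channels)
        pd.DataFrame({"time_s": self.imu_times, "yaw_velocity": self.imu}).to_csv(
            directory / IMU_FILE, index=False
        )
        if self.ground_truth is not None:
            (directory / GT_FILE).write_text(json.dumps(self.ground_truth.to_dict(), indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "RecordingSession":
        directory = Path(directory)
        with h5py.File(directory / EEG_FILE, "r") as f:
            ds = f["eeg"]
            eeg = ds[()]
            rate = float(ds.attrs["rate_hz"])
            channels = [c if isinstance(c, str) else c.decode() for c in ds.attrs["channels"]]
        imu_df = pd.read_csv(directory / IMU_FILE)
        if imu_df.shape[0] > 1:
            dt = float(imu_df["time_s"].iloc[1] - imu_df["time_s"].iloc[0])
            imu_rate = 1.0 / dt
        else:
            imu_rate = 128.0
        gt = None
        gt_path = directory / GT_FILE
        if gt_path.exists():
            gt = GroundTruth.from_dict(json.loads(gt_path.read_text()))
        return cls(
            eeg=eeg,
            eeg_rate=rate,
            imu=imu_df["yaw_velocity"].to_numpy(),
            imu_rate=imu_rate,
            channels=tuple(channels),
            ground_truth=gt,
        )
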