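"""EEG cleaning: band-pass, downsampling, amplitude-based interval rejection.

The pipeline keeps the slow (0.75-8 Hz) components the pre-movement signature
lives in: zero-phase band-pass at the native rate (which doubles as the
anti-alias stage for the band of interest), then polyphase resampling to the
128 Hz analysis grid shared with the IMU. Interval rejection is a decision
applied when selecting epochs — the continuous record is never zeroed, so
streaming classification still sees every frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = ["PreprocConfig", "bandpass", "resample", "reject_interval", "preprocess_session"]


@dataclass(frozen=True)
class PreprocConfig:
    """Cleaning parameters.

    ``artifact_threshold`` is in recorded amplitude units (default 80); an
    epoch containing any sample with |amplitude| strictly above it is
    discarded. Band edges default to 0.75-8 Hz; filtering is zero-phase
    (forward-backward Butterworth of the configured order).
    """

    artifact_threshold: float = 80.0
    band: tuple[float, float] = (0.75, 8.0)
    target_rate: float = 128.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_rate / 2):
            raise ValueError("band edges must satisfy 0 < low < high < target_rate/2")
        if self.artifact_threshold <= 0:
            raise ValueError("artifact_threshold must be positive")


def bandpass(eeg: np.ndarray, rate: float, cfg: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Zero-phase band-pass over the last axis; same shape out as in."""
    low, high = cfg.band
    if rate < 2 * high:
        raise ValueError(f"sampling rate {rate} Hz too low for a {high} Hz band edge")
    sos = signal.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, eeg, axis=-1)


def resample(eeg: np.ndarray, from_rate: float, to_rate: float = 128.0) -> np.ndarray:
    """Decimate from ``from_rate`` to ``to_rate`` (rational ratio, anti-aliased)."""
    if from_rate < to_rate:
        raise ValueError("upsampling is not supported")
    if from_rate == to_rate:
        return eeg
    ratio = Fraction(to_rate / from_rate).limit_denominator(1000)
    return signal.resample_poly(eeg, ratio.numerator, ratio.denominator, axis=-1)


def reject_interval(epoch: np.ndarray, cfg: PreprocConfig = PreprocConfig()) -> bool:
    """True when the epoch is kept.

    Discards iff any sample on any channel has raw absolute amplitude strictly
    over the threshold ("amplitudes over 80" — a sample exactly at threshold
    is kept).
    """
    epoch = np.asarray(epoch)
    if epoch.size == 0:
        raise ValueError("empty epoch")
    return bool(np.max(np.abs(epoch)) <= cfg.artifact_threshold)


def preprocess_session(eeg: np.ndarray, rate: float, cfg: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Filter at the native rate, then resample to the analysis grid."""
    return resample(bandpass(eeg, rate, cfg), rate, cfg.target_rate)
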