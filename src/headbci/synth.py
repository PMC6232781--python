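"""Seeded synthetic recording sessions with planted ground truth.

The generator emulates the recording conditions: a participant making self-paced
left/right head rotations (center -> side -> center) during 20-minute blocks,
with at least 2 s between rotations, recorded as a 128 Hz yaw-velocity trace
plus 32-channel EEG. Into the EEG it plants a readiness-potential-like
signature: a slow fronto-central negative ramp beginning ``rp_lead`` seconds
before each rotation onset, plus a lateralised component whose hemispheric
sign flips with rotation direction. Optional high-amplitude artifact segments
exercise the amplitude-rejection stage.

Every quantity is drawn from named substreams of one seed, so the same
(config, seed) pair reproduces the session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import LEFT, RIGHT, RotationEvent
from .montage import CHANNELS_32, LATERAL_SIGNS, RP_WEIGHTS, weight_vector
from .session import GroundTruth, RecordingSession
from .utils import substream

__all__ = ["SynthConfig", "generate_schedule", "render_imu", "render_eeg", "generate_session", "generate_blocks"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic block.

    Amplitudes are in arbitrary recorded units, calibrated so that the default
    artifact amplitude (150) exceeds the default rejection threshold (80)
    while background noise plus the planted signature stays well below it.
    """

    n_channels: int = 32
    raw_eeg_rate: float = 512.0      # Hz; downsampling to 128 Hz is a real pipeline step
    imu_rate: float = 128.0          # Hz, the headset IMU output rate
    block_duration: float = 1200.0   # s (20-minute block)
    min_inter_rotation_gap: float = 2.0   # s between center-outward onsets
    rotation_rate: float = 6.0       # rotations/min (center-outward)
    rp_lead: float = 0.45            # s before onset where the planted ramp begins
    rp_amplitude: float = 25.0       # ramp magnitude at onset, recorded units
    lateralization_fraction: float = 0.5  # lateral component as fraction of rp_amplitude
    noise_sd: float = 6.0            # background EEG noise sd, recorded units
    artifact_rate: float = 0.5       # artifact segments/min
    artifact_amplitude: float = 150.0  # artifact peak, recorded units (> threshold)
    artifact_duration: float = 0.5   # s
    velocity_peak: float = 200.0     # deg/s at the middle of a rotation (brisk turn)
    rotation_duration: float = 0.3   # s for one center->side sweep (~30 deg amplitude)
    hold_duration: float = 0.4       # s pause at the side before returning to center
    imu_noise_sd: float = 0.3        # deg/s gyro noise between movements
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("raw_eeg_rate", "imu_rate", "rotation_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.rp_lead < self.min_inter_rotation_gap:
            raise ValueError("rp_lead must be shorter than min_inter_rotation_gap")
        if not self.block_duration > 10 * self.min_inter_rotation_gap:
            raise ValueError("block_duration must exceed 10 x min_inter_rotation_gap")

    @property
    def movement_span(self) -> float:
        """Out-and-back duration: sweep out, hold, sweep back."""
        return 2 * self.rotation_duration + self.hold_duration


def generate_schedule(cfg: SynthConfig, stream: str = "schedule") -> GroundTruth:
    """Draw the ground-truth rotation schedule for one block.

    Center-outward onsets are spaced by a reserved quiet interval (the minimum
    gap plus the full out-and-back movement) plus an exponential margin tuned
    to the configured rotation rate; directions are a fair coin per event. A
    block too short to fit a single rotation yields an empty schedule.
    """
    rng = substream(cfg.seed, stream)
    reserved = cfg.min_inter_rotation_gap + cfg.movement_span
    mean_extra = max(60.0 / cfg.rotation_rate - reserved, 0.1)

    events: list[RotationEvent] = []
    # Keep the block head quiet so a stationary segment always exists for
    # noise-threshold estimation.
    t = max(reserved, 3.0)
    while True:
        onset = t + rng.exponential(mean_extra)
        if onset + cfg.movement_span + cfg.min_inter_rotation_gap > cfg.block_duration:
            break
        direction = LEFT if rng.random() < 0.5 else RIGHT
        events.append(RotationEvent(onset=onset, direction=direction, offset=onset + cfg.rotation_duration))
        t = onset + reserved

    artifacts: list[tuple[float, float]] = []
    n_art = rng.poisson(cfg.artifact_rate * cfg.block_duration / 60.0)
    starts = np.sort(rng.uniform(0.0, cfg.block_duration - cfg.artifact_duration, size=n_art))
    for s in starts:
        iv = (float(s), float(s + cfg.artifact_duration))
        if artifacts and iv[0] < artifacts[-1][1]:
            artifacts[-1] = (artifacts[-1][0], iv[1])  # merge overlaps
        else:
            artifacts.append(iv)
    return GroundTruth(events=events, artifact_intervals=artifacts)


def _raised_cosine_pulse(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Smooth unimodal unit pulse supported on [start, start+duration]."""
    x = (t - start) / duration
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    pulse[(x < 0) | (x > 1)] = 0.0
    return pulse


def render_imu(gt: GroundTruth, cfg: SynthConfig, stream: str = "imu") -> np.ndarray:
    """Render the yaw-velocity trace (deg/s, right positive) at cfg.imu_rate.

    Each scored event contributes an outward raised-cosine velocity pulse of
    the event's sign starting at its onset, followed after ``hold_duration``
    by the return pulse of opposite sign, so the head ends back at center.
    Between movements the trace is low-level gyro noise.
    """
    rng = substream(cfg.seed, stream)
    n = round(cfg.block_duration * cfg.imu_rate)
    t = np.arange(n) / cfg.imu_rate
    v = rng.normal(0.0, cfg.imu_noise_sd, size=n)
    for e in gt.events:
        sign = 1.0 if e.direction == RIGHT else -1.0
        v += sign * cfg.velocity_peak * _raised_cosine_pulse(t, e.onset, cfg.rotation_duration)
        ret_start = e.onset + cfg.rotation_duration + cfg.hold_duration
        v -= sign * cfg.velocity_peak * _raised_cosine_pulse(t, ret_start, cfg.rotation_duration)
    return v


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, per-channel sd equal to ``sd``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    shaped *= sd / shaped.std(axis=1, keepdims=True)
    return shaped


def render_eeg(gt: GroundTruth, cfg: SynthConfig, stream: str = "eeg") -> np.ndarray:
    """Render multichannel EEG (channels x samples) at cfg.raw_eeg_rate.

    Background is pink noise of sd ``noise_sd``. Each event adds, on the
    fronto-central sites, a linear negative-going ramp from zero at
    (onset - rp_lead) to -rp_amplitude at onset (decaying back to zero over
    the rotation), plus a lateralised component of magnitude
    lateralization_fraction x rp_amplitude whose hemispheric sign flips with
    direction. Artifact intervals carry a band-limited 3 Hz burst of peak
    ``artifact_amplitude``.
    """
    rng = substream(cfg.seed, stream)
    n = round(cfg.block_duration * cfg.raw_eeg_rate)
    channels = CHANNELS_32[: cfg.n_channels]
    if cfg.noise_sd > 0:
        eeg = _pink_noise(rng, cfg.n_channels, n, cfg.noise_sd)
    else:
        eeg = np.zeros((cfg.n_channels, n))
    t = np.arange(n) / cfg.raw_eeg_rate

    w_rp = weight_vector(RP_WEIGHTS, channels)
    w_lat = weight_vector(LATERAL_SIGNS, channels)
    for e in gt.events:
        i0 = int(round((e.onset - cfg.rp_lead) * cfg.raw_eeg_rate))
        i1 = int(round(e.onset * cfg.raw_eeg_rate))
        i2 = int(round((e.onset + cfg.rotation_duration) * cfg.raw_eeg_rate))
        if i0 < 0 or i2 > n:
            continue
        envelope = np.zeros(i2 - i0)
        envelope[: i1 - i0] = np.linspace(0.0, 1.0, i1 - i0, endpoint=False)
        envelope[i1 - i0 :] = np.linspace(1.0, 0.0, i2 - i1, endpoint=False)
        dir_sign = 1.0 if e.direction == LEFT else -1.0
        amp = -cfg.rp_amplitude * w_rp + dir_sign * cfg.lateralization_fraction * cfg.rp_amplitude * w_lat
        eeg[:, i0:i2] += amp[:, None] * envelope[None, :]

    for a0, a1 in gt.artifact_intervals:
        j0, j1 = int(round(a0 * cfg.raw_eeg_rate)), int(round(a1 * cfg.raw_eeg_rate))
        j1 = min(j1, n)
        if j1 <= j0:
            continue
        tt = t[j0:j1] - a0
        burst = np.sin(2 * np.pi * 3.0 * tt) * _raised_cosine_pulse(tt, 0.0, (j1 - j0) / cfg.raw_eeg_rate)
        eeg[:, j0:j1] += 1.5 * cfg.artifact_amplitude * burst[None, :]
    return eeg


def generate_session(cfg: SynthConfig, block: int = 0) -> RecordingSession:
    """Generate one complete block (schedule + IMU + EEG)."""
    prefix = f"block{block}/"
    gt = generate_schedule(cfg, stream=prefix + "schedule")
    imu = render_imu(gt, cfg, stream=prefix + "imu")
    eeg = render_eeg(gt, cfg, stream=prefix + "eeg")
    return RecordingSession(
        eeg=eeg,
        eeg_rate=cfg.raw_eeg_rate,
        imu=imu,
        imu_rate=cfg.imu_rate,
        channels=CHANNELS_32[: cfg.n_channels],
        ground_truth=gt,
    )


def generate_blocks(cfg: SynthConfig, n_blocks: int = 2) -> list[RecordingSession]:
    """The session structure: ``n_blocks`` blocks per participant."""
    return [generate_session(cfg, block=b) for b in range(n_blocks)]


def participant_config(cfg: SynthConfig, participant: int) -> SynthConfig:
    """Derive a per-participant config by shifting the seed substream."""
    return replace(cfg, seed=cfg.seed + 10_000 * (participant + 1))
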