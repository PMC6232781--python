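"""Shared fixtures: small synthetic sessions and one fitted participant.

Everything is generated at test time from fixed seeds; block durations are
kept short so the whole suite trains real networks in minutes. Seeds were
fixed when the fixtures were written and are not tuned per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from headbci import (
    ExperimentConfig,
    ModelConfig,
    OnsetDetectorConfig,
    SynthConfig,
    detect_onsets,
    estimate_noise_threshold,
    generate_session,
    label_and_filter,
)
from headbci.experiment import run_participant

FAST_MODEL = ModelConfig(epochs=30, batch_size=64)


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    """One short block at default signal/noise levels."""
    return SynthConfig(block_duration=200.0, seed=7)


@pytest.fixture(scope="session")
def session(synth_cfg):
    return generate_session(synth_cfg)


@pytest.fixture(scope="session")
def detected(session):
    """(threshold, all events, frame labels, resolved events) for `session`."""
    dcfg = OnsetDetectorConfig()
    thr = estimate_noise_threshold(session.imu, dcfg, session.imu_rate)
    events = detect_onsets(session.imu, thr, dcfg, session.imu_rate)
    labels, resolved = label_and_filter(events, session.imu.shape[0], session.imu, session.imu_rate, dcfg)
    return thr, events, labels, resolved


@pytest.fixture(scope="session")
def strong_run():
    """Full pipeline on one strong-signal participant (2 x 600 s blocks)."""
    cfg = ExperimentConfig(
        seed=11,
        synth=SynthConfig(block_duration=600.0, seed=11),
        model=ModelConfig(epochs=40, batch_size=150),
    )
    return cfg, run_participant(cfg, 0)


def pooled_runs(synth_overrides: dict, seeds, block_duration=600.0, epochs=20):
    # 600 s blocks keep the contiguous test stream long enough (~120 s, about
    # 12 rotations) that both directions are virtually always represented.
    """Train one participant per seed under modified generator settings."""
    out = []
    for s in seeds:
        cfg = ExperimentConfig(
            seed=int(s),
            synth=SynthConfig(block_duration=block_duration, seed=int(s), **synth_overrides),
            model=ModelConfig(epochs=epochs, batch_size=64),
        )
        out.append(run_participant(cfg, 0))
    return out


@pytest.fixture(scope="session")
def null_runs():
    """Ten seeds with no planted EEG signal at all (rp_amplitude = 0)."""
    return pooled_runs({"rp_amplitude": 0.0}, seeds=range(10))


@pytest.fixture(scope="session")
def nolat_runs():
    """Ten seeds with a ramp but zero lateralization (directions unknowable)."""
    return pooled_runs({"lateralization_fraction": 0.0}, seeds=range(20, 30))


def onset_errors_frames(session, resolved) -> np.ndarray:
    """|detected - planted| onset error in IMU frames, per planted event."""
    det = np.array([e.onset for e in resolved if e.from_center])
    errs = []
    for e in session.ground_truth.events:
        errs.append(np.min(np.abs(det - e.onset)) * session.imu_rate)
    return np.array(errs)
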