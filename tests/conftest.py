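"""Shared fixtures: small synthetic recordings with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from somnoresp.synth import HypnogramParams, SynthConfig, generate_recording


def rem_only_hypnogram_params() -> HypnogramParams:
    """Architecture that is REM almost throughout (short NREM lead-in)."""
    return HypnogramParams(
        bout_mean_s={"W": 30.0, "NREM": 30.0, "REM": 100000.0},
        transition_weights={"W": {"NREM": 1.0}, "NREM": {"REM": 1.0}, "REM": {"NREM": 1.0}},
        initial_stage="NREM",
    )


def wake_only_hypnogram_params() -> HypnogramParams:
    return HypnogramParams(
        bout_mean_s={"W": 1e9, "NREM": 100.0, "REM": 60.0},
        transition_weights={"W": {}, "NREM": {"W": 1.0}, "REM": {"W": 1.0}},
        initial_stage="W",
    )


def quiet_config(seed: int = 0, duration_s: float = 120.0) -> SynthConfig:
    """Noiseless, regular breathing with no sniffs, flow limitation or events."""
    cfg = SynthConfig(seed=seed, duration_s=duration_s)
    cfg.breath.rate_cv = 0.0
    cfg.breath.amplitude_noise_sd = 0.0
    cfg.breath.signal_noise_sd = 0.0
    cfg.sniff.probability = 0.0
    cfg.flow_limitation.probability = 0.0
    cfg.apnea.rate_per_h = {"W": 0.0, "NREM": 0.0, "REM": 0.0}
    cfg.spo2.noise_sd_pct = 0.0
    return cfg


@pytest.fixture(scope="session")
def default_recording():
    """One default 600-s recording with truth, shared across tests."""
    rec, truth = generate_recording(SynthConfig(seed=11, duration_s=600.0))
    return rec, truth


@pytest.fixture(scope="session")
def sinusoid_flow():
    """Unit-amplitude 2.5 Hz sinusoidal flow, 60 s at 1000 Hz."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    return np.sin(2 * np.pi * 2.5 * t), fs
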