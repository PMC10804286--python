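"""Sleep-wake staging from EEG/EMG in 5-s epochs, and architecture summaries.

Stages follow the standard rodent criteria: wakefulness shows low-amplitude,
high-frequency (~10-20 Hz) EEG with high EMG tone; NREM sleep shows
high-amplitude, low-frequency (~2-5 Hz) EEG with much lower EMG; REM sleep
shows low-amplitude, mixed-frequency (~5-10 Hz, theta-dominated) EEG with
EMG at or below the NREM level.  The automated stager here renders those
visual criteria as band-power ratios plus a self-calibrated EMG threshold;
an externally scored hypnogram is a first-class input everywhere else in
the pipeline, so no downstream stage depends on this classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, periodogram, sosfiltfilt

from .core import ConfigurationError, ChannelRole, Recording, Stage

__all__ = [
    "EPOCH_LEN_S",
    "Hypnogram",
    "EpochFeatures",
    "StagingThresholds",
    "epoch_features",
    "calibrate_thresholds",
    "stage_epoch",
    "stage_recording",
    "architecture_summary",
]

EPOCH_LEN_S = 5.0

# EEG bands (Hz) characterizing each stage.
BAND_LOW = (2.0, 5.0)     # NREM delta-dominant band
BAND_THETA = (5.0, 10.0)  # REM theta band
BAND_HIGH = (10.0, 20.0)  # wake fast activity
EMG_HIGHPASS_HZ = 30.0


@dataclass
class Hypnogram:
    """Stage labels on a fixed 5-s epoch grid."""

    stages: list[Stage]
    epoch_len: float = EPOCH_LEN_S
    source: str = "scored"  # "scored" | "external"

    def __post_init__(self) -> None:
        self.stages = [Stage(s) for s in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len

    def stage_at(self, t: float) -> Stage:
        """Stage of the epoch containing time ``t`` (s from start)."""
        i = int(t // self.epoch_len)
        if 0 <= i < len(self.stages):
            return self.stages[i]
        return Stage.UNKNOWN

    def epoch_bounds(self, i: int) -> tuple[float, float]:
        return i * self.epoch_len, (i + 1) * self.epoch_len

    def stage_seconds(self, stage: Stage) -> float:
        return sum(1 for s in self.stages if s == stage) * self.epoch_len

    def total_sleep_seconds(self) -> float:
        return self.stage_seconds(Stage.NREM) + self.stage_seconds(Stage.REM)

    def runs(self) -> list[tuple[Stage, float, float]]:
        """Maximal same-stage runs as (stage, t_start, t_end) intervals."""
        out: list[tuple[Stage, float, float]] = []
        if not self.stages:
            return out
        start = 0
        for i in range(1, len(self.stages) + 1):
            if i == len(self.stages) or self.stages[i] != self.stages[start]:
                out.append((self.stages[start], start * self.epoch_len, i * self.epoch_len))
                start = i
        return out


@dataclass
class EpochFeatures:
    """Spectral and amplitude features of one 5-s epoch."""

    p_low: float     # 2-5 Hz band power
    p_theta: float   # 5-10 Hz band power
    p_high: float    # 10-20 Hz band power
    eeg_rms: float
    emg_rms: float


@dataclass
class StagingThresholds:
    """Self-calibrated decision thresholds (see :func:`calibrate_thresholds`)."""

    emg_split: float
    eeg_amp_split: float
    calibrated: bool = True


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    return float(np.sum(psd[mask]))


def epoch_features(
    eeg: np.ndarray, emg: np.ndarray, sample_rate: float
) -> EpochFeatures:
    """Band powers (periodogram) and RMS amplitudes for one epoch.

    EMG RMS is computed after a 30 Hz high-pass to isolate muscle tone from
    any low-frequency contamination.
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if np.allclose(eeg, 0.0) and np.allclose(emg, 0.0):
        return EpochFeatures(0.0, 0.0, 0.0, 0.0, 0.0)
    freqs, psd = periodogram(eeg, fs=sample_rate)
    if np.any(np.abs(emg) > 0):
        sos = butter(4, EMG_HIGHPASS_HZ, btype="high", fs=sample_rate, output="sos")
        emg_hp = sosfiltfilt(sos, emg)
    else:
        emg_hp = emg
    return EpochFeatures(
        p_low=_band_power(freqs, psd, BAND_LOW),
        p_theta=_band_power(freqs, psd, BAND_THETA),
        p_high=_band_power(freqs, psd, BAND_HIGH),
        eeg_rms=float(np.sqrt(np.mean(eeg**2))),
        emg_rms=float(np.sqrt(np.mean(emg_hp**2))),
    )


def _otsu_split(values: np.ndarray) -> float:
    """Histogram-valley (Otsu) split of a 1-D sample; returns the threshold."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return float(hi)
    hist, edges = np.histogram(v, bins=64, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best_t, best_var = centers[0], -1.0
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    for i in range(len(centers) - 1):
        w0 = cum_w[i] / total
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0 or cum_w[i] == 0:
            continue
        mu0 = cum_mu[i] / cum_w[i]
        mu1 = (cum_mu[-1] - cum_mu[i]) / (cum_w[-1] - cum_w[i])
        var_b = w0 * w1 * (mu0 - mu1) ** 2
        if var_b > best_var:
            best_var, best_t = var_b, centers[i]
    return float(best_t)


def calibrate_thresholds(features: list[EpochFeatures]) -> StagingThresholds:
    """Self-calibrate decision thresholds over one recording.

    The EMG threshold splits the (log) per-epoch EMG RMS distribution at its
    between-class-variance optimum, separating the high-tone wake mode from
    the sleep mode.  The EEG amplitude split is the 50th percentile of epoch
    EEG RMS, separating high-amplitude NREM epochs from the rest.
    """
    if not features:
        raise ConfigurationError("cannot calibrate staging thresholds on zero epochs")
    emg = np.array([f.emg_rms for f in features])
    eeg_amp = np.array([f.eeg_rms for f in features])
    log_emg = np.log10(np.maximum(emg, 1e-12))
    emg_split = 10.0 ** _otsu_split(log_emg)
    # bimodality guard: with no distinct wake mode (class means closer than
    # 2x) the split falls inside a single mode, so disable the EMG criterion
    # and let the EEG band rules carry the decision
    lo, hi = emg[emg < emg_split], emg[emg >= emg_split]
    if lo.size == 0 or hi.size == 0 or hi.mean() < 2.0 * max(lo.mean(), 1e-12):
        emg_split = float("inf")
    return StagingThresholds(
        emg_split=float(emg_split),
        eeg_amp_split=float(np.percentile(eeg_amp, 50.0)),
    )


def stage_epoch(
    features: EpochFeatures,
    thresholds: StagingThresholds,
    previous: Stage = Stage.NREM,
) -> Stage:
    """Stage one epoch from its features.

    Decision rules: high EMG -> Wake; otherwise the dominant EEG band
    decides — fast (10-20 Hz) low-amplitude activity is Wake, slow
    (2-5 Hz) high-amplitude activity is NREM, theta (5-10 Hz) is REM.
    Ties keep the previous epoch's stage.
    """
    if not thresholds.calibrated:
        raise ConfigurationError("staging thresholds are not calibrated")
    if features.emg_rms >= thresholds.emg_split:
        return Stage.WAKE
    if features.p_high > features.p_low and features.p_high > features.p_theta:
        return Stage.WAKE
    if features.p_low > features.p_theta and features.p_low > features.p_high:
        return Stage.NREM
    if features.p_theta > features.p_low and features.p_theta > features.p_high:
        return Stage.REM
    return previous


def stage_recording(rec: Recording) -> tuple[Hypnogram, list[EpochFeatures]]:
    """Score a whole recording into a 5-s-epoch hypnogram.

    Deterministic given the recording: features per epoch, one calibration
    pass, then the epoch-wise decision rule.
    """
    eeg = rec.get(ChannelRole.EEG)
    emg = rec.get(ChannelRole.EMG)
    n_epochs = int(min(eeg.duration, emg.duration) // EPOCH_LEN_S)
    if n_epochs == 0:
        raise ConfigurationError("recording shorter than one 5-s epoch")
    feats = []
    for i in range(n_epochs):
        t0, t1 = i * EPOCH_LEN_S, (i + 1) * EPOCH_LEN_S
        feats.append(
            epoch_features(
                eeg.slice_seconds(t0, t1), emg.slice_seconds(t0, t1), eeg.sample_rate
            )
        )
    thr = calibrate_thresholds(feats)
    stages: list[Stage] = []
    prev = Stage.NREM
    for f in feats:
        s = stage_epoch(f, thr, previous=prev)
        stages.append(s)
        prev = s
    return Hypnogram(stages, source="scored"), feats


@dataclass
class ArchitectureSummary:
    """Totals and bout statistics of a hypnogram."""

    total_sleep_s: float
    stage_seconds: dict[str, float] = field(default_factory=dict)
    bout_counts: dict[str, int] = field(default_factory=dict)
    bout_mean_s: dict[str, float] = field(default_factory=dict)


def architecture_summary(hyp: Hypnogram) -> ArchitectureSummary:
    """Total sleep time, per-stage time, and bout counts/mean lengths.

    A bout is a maximal run of consecutive same-stage epochs.
    """
    if len(hyp) == 0:
        raise ConfigurationError("empty hypnogram")
    runs = hyp.runs()
    stage_seconds: dict[str, float] = {s.value: 0.0 for s in (Stage.WAKE, Stage.NREM, Stage.REM)}
    bout_counts: dict[str, int] = {s.value: 0 for s in (Stage.WAKE, Stage.NREM, Stage.REM)}
    bout_lengths: dict[str, list[float]] = {s.value: [] for s in (Stage.WAKE, Stage.NREM, Stage.REM)}
    for stage, t0, t1 in runs:
        key = stage.value
        if key not in stage_seconds:
            continue
        stage_seconds[key] += t1 - t0
        bout_counts[key] += 1
        bout_lengths[key].append(t1 - t0)
    bout_mean = {
        k: (float(np.mean(v)) if v else 0.0) for k, v in bout_lengths.items()
    }
    return ArchitectureSummary(
        total_sleep_s=stage_seconds[Stage.NREM.value] + stage_seconds[Stage.REM.value],
        stage_seconds=stage_seconds,
        bout_counts=bout_counts,
        bout_mean_s=bout_mean,
    )


def staging_accuracy(scored: Hypnogram, truth: Hypnogram) -> float:
    """Fraction of epochs on which two hypnograms agree."""
    n = min(len(scored), len(truth))
    if n == 0:
        warnings.warn("accuracy over zero epochs", stacklevel=2)
        return float("nan")
    agree = sum(1 for a, b in zip(scored.stages[:n], truth.stages[:n]) if a == b)
    return agree / n
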