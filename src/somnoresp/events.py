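"""Apnea and oxygen-desaturation scoring with per-hour stage indices.

Apneas are scored as a >=90% reduction in airflow lasting at least two
breath cycles at the baseline respiratory rate, or at least 0.7 s
(either duration criterion suffices by default; a stricter both-required
mode is configurable).  Candidate intervals are found on a sliding-maximum
envelope of |flow| whose window equals one baseline breath period: during
normal breathing the envelope tracks peak inspiratory flow, during an
apnea it collapses, and dilating the sub-threshold region by half a window
restores the true event boundaries.  Each candidate's depth is verified
against the local baseline — the median V_I_max of the 10 preceding
non-event breaths.

The oxygen desaturation index (ODI) counts >=4% drops of SpO2 below a
running baseline (90th percentile of the preceding 120 s) lasting at least
two local breath cycles, per hour of total sleep (NREM + REM); dips during
wakefulness are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .core import BreathRecord, ConfigurationError, RespiratoryEvent, Stage
from .staging import Hypnogram

__all__ = [
    "ApneaScoringConfig",
    "DesatScoringConfig",
    "detect_apneas",
    "apnea_index",
    "detect_desaturations",
    "OdiResult",
]

APNEA_FLOW_REDUCTION = 0.90       # >=90% reduction in airflow
APNEA_MIN_ALTERNATIVE_S = 0.7     # ... for >=2 breath cycles or >=0.7 s
DESAT_THRESHOLD_PCT = 4.0         # >=4% drop from baseline
DESAT_MIN_BREATHS = 2.0


@dataclass
class ApneaScoringConfig:
    flow_reduction: float = APNEA_FLOW_REDUCTION
    min_duration_alt_s: float = APNEA_MIN_ALTERNATIVE_S
    #: "either": duration >= min(2 cycles, 0.7 s); "both": >= max(2 cycles, 0.7 s)
    duration_rule: str = "either"
    n_baseline_breaths: int = 10


@dataclass
class DesatScoringConfig:
    threshold_pct: float = DESAT_THRESHOLD_PCT
    baseline_window_s: float = 120.0
    baseline_percentile: float = 90.0
    min_breath_cycles: float = DESAT_MIN_BREATHS
    scoring_rate_hz: float = 10.0  # SpO2 is decimated to this rate for scoring


def _required_duration(baseline_rr: float, cfg: ApneaScoringConfig) -> float:
    two_cycles = 2.0 * 60.0 / baseline_rr
    if cfg.duration_rule == "either":
        return min(two_cycles, cfg.min_duration_alt_s)
    if cfg.duration_rule == "both":
        return max(two_cycles, cfg.min_duration_alt_s)
    raise ConfigurationError(f"unknown duration_rule {cfg.duration_rule!r}")


def _local_baseline_peak(
    breaths: list[BreathRecord], t: float, n: int, global_median: float
) -> float:
    """Median V_I_max of the last ``n`` non-event breaths ending before ``t``.

    Breaths with peaks below half the global median are treated as in-event
    and skipped so that an apnea does not poison its own reference.
    """
    peaks = []
    for b in reversed(breaths):
        if b.t_end <= t:
            if b.v_i_max >= 0.5 * global_median:
                peaks.append(b.v_i_max)
            if len(peaks) == n:
                break
    if not peaks:
        return global_median
    return float(np.median(peaks))


def detect_apneas(
    flow: np.ndarray,
    sample_rate: float,
    breaths: list[BreathRecord],
    hypnogram: Hypnogram | None = None,
    baseline_rr: float | None = None,
    cfg: ApneaScoringConfig | None = None,
) -> list[RespiratoryEvent]:
    """Score apneas on a flow trace.

    ``baseline_rr`` (breaths/min) defaults to the mean instantaneous rate
    over all segmented breaths.  Each event carries the sleep stage of its
    onset epoch and its flow reduction (%) relative to the local baseline.
    """
    if cfg is None:
        cfg = ApneaScoringConfig()
    if not breaths:
        raise ConfigurationError("apnea scoring needs baseline breaths")
    if baseline_rr is None:
        baseline_rr = float(np.mean([b.inst_rr for b in breaths]))
    if baseline_rr <= 0:
        raise ConfigurationError("baseline respiratory rate must be positive")
    flow = np.asarray(flow, dtype=float)

    period_s = 60.0 / baseline_rr
    w = max(3, int(round(period_s * sample_rate)))
    env = maximum_filter1d(np.abs(flow), size=w, mode="nearest")
    global_median = float(np.median([b.v_i_max for b in breaths]))
    threshold = (1.0 - cfg.flow_reduction) * global_median

    below = env <= threshold
    if not np.any(below):
        return []
    # maximal sub-threshold intervals, dilated by half a window to undo the
    # erosion introduced by the sliding maximum
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = list(edges[below[edges + 1] == True] + 1)  # noqa: E712
    ends = list(edges[below[edges + 1] == False] + 1)  # noqa: E712
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)

    required = _required_duration(baseline_rr, cfg)
    events: list[RespiratoryEvent] = []
    half_w = w // 2
    for i0, i1 in zip(starts, ends):
        if i1 >= below.size:
            # the recording ends mid-candidate (e.g. the zero-padded tail
            # after the final complete breath); completion cannot be scored
            continue
        t0 = max(0.0, (i0 - half_w) / sample_rate)
        t1 = min(flow.size / sample_rate, (i1 + half_w) / sample_rate)
        duration = t1 - t0
        if duration < required:
            continue
        baseline_peak = _local_baseline_peak(
            breaths, t0, cfg.n_baseline_breaths, global_median
        )
        j0, j1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        core = np.abs(flow[j0 + half_w : max(j0 + half_w + 1, j1 - half_w)])
        residual = float(core.max()) if core.size else 0.0
        reduction = 1.0 - residual / baseline_peak if baseline_peak > 0 else 0.0
        if reduction < cfg.flow_reduction:
            continue
        stage = hypnogram.stage_at(t0) if hypnogram is not None else Stage.UNKNOWN
        events.append(
            RespiratoryEvent(
                kind="apnea",
                t_start=t0,
                duration=duration,
                stage=stage,
                magnitude=100.0 * reduction,
            )
        )
    return events


def apnea_index(
    events: list[RespiratoryEvent], hypnogram: Hypnogram, stage: Stage
) -> float:
    """Apneas per hour of the given sleep stage; NaN (flagged) if no stage time."""
    stage_h = hypnogram.stage_seconds(stage) / 3600.0
    if stage_h <= 0:
        warnings.warn(f"no time spent in stage {stage.value}; index undefined", stacklevel=2)
        return float("nan")
    n = sum(1 for e in events if e.kind == "apnea" and e.stage == stage)
    return n / stage_h


@dataclass
class OdiResult:
    events: list[RespiratoryEvent]
    odi_per_h: float
    sleep_hours: float


def detect_desaturations(
    spo2: np.ndarray,
    sample_rate: float,
    hypnogram: Hypnogram,
    breaths: list[BreathRecord],
    cfg: DesatScoringConfig | None = None,
) -> OdiResult:
    """Score >=4% desaturations during sleep and compute the ODI.

    The running baseline is the 90th percentile of SpO2 over the preceding
    120 s, computed on a decimated (10 Hz) copy of the trace.  Events must
    last at least two median breath cycles; events whose onset falls in a
    wake epoch are excluded from the index, whose denominator is hours of
    total sleep.
    """
    if cfg is None:
        cfg = DesatScoringConfig()
    spo2 = np.asarray(spo2, dtype=float)
    if spo2.size == 0:
        raise ConfigurationError("SpO2 channel is empty")
    step = max(1, int(round(sample_rate / cfg.scoring_rate_hz)))
    s = spo2[::step]
    fs = sample_rate / step

    import pandas as pd

    win = max(1, int(round(cfg.baseline_window_s * fs)))
    baseline = (
        pd.Series(s).rolling(win, min_periods=1).quantile(cfg.baseline_percentile / 100.0)
    ).to_numpy()
    below = s <= baseline - cfg.threshold_pct

    median_ttot = float(np.median([b.ttot for b in breaths])) if breaths else 0.4
    min_dur = cfg.min_breath_cycles * median_ttot

    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = list(edges[~below[edges]] + 1)
    ends = list(edges[below[edges]] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)

    events: list[RespiratoryEvent] = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = i0 / fs, i1 / fs
        if t1 - t0 < min_dur:
            continue
        depth = float((baseline[i0:i1] - s[i0:i1]).max())
        stage = hypnogram.stage_at(t0)
        events.append(
            RespiratoryEvent(
                kind="desaturation", t_start=t0, duration=t1 - t0, stage=stage, magnitude=depth
            )
        )
    sleep_h = hypnogram.total_sleep_seconds() / 3600.0
    sleep_events = [e for e in events if e.stage in (Stage.NREM, Stage.REM)]
    if sleep_h <= 0:
        warnings.warn("no sleep time; ODI undefined", stacklevel=2)
        return OdiResult(events, float("nan"), 0.0)
    return OdiResult(events, len(sleep_events) / sleep_h, sleep_h)
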