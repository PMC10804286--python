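"""Breath segmentation and per-breath timing/volume/flow-landmark features.

Breaths are delimited by signed zero crossings of the airflow signal with a
hysteresis band, under the convention that positive flow is inspiration
(invertible via ``invert_sign``).  The hysteresis band is 3x a robust noise
SD estimated from the first differences of the flow (median absolute
deviation scaled to a Gaussian SD), so sub-threshold oscillations around
zero do not create breaths.

Per breath, the inspired volume VT is the trapezoidal integral of
inspiratory flow; ``V_Imax1``, ``V_I50`` and ``V_Imax2`` are the peak flows
over the first half of inspiration, at its midpoint, and over the second
half — the landmarks used downstream to detect mid-inspiratory flow
plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BreathRecord, ConfigurationError, Stage
from .staging import Hypnogram

__all__ = [
    "segment_breaths",
    "breath_features",
    "analyze_flow",
    "select_analysis_windows",
    "aggregate_ventilation",
    "StageWindows",
    "VentilationSummary",
]

HYSTERESIS_NOISE_MULTIPLE = 3.0
NREM_BLOCK_S = 1800.0   # one NREM stretch sampled per half-hour block
NREM_STRETCH_S = 20.0


def robust_noise_sd(flow: np.ndarray) -> float:
    """Noise SD of a flow trace from the MAD of its first differences.

    For white noise of SD sigma the first difference has SD sigma*sqrt(2);
    the slowly varying respiratory component contributes little to the
    sample-to-sample difference, so this is a noise-floor estimate rather
    than a signal-amplitude estimate.
    """
    d = np.diff(flow)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def segment_breaths(
    flow: np.ndarray,
    sample_rate: float,
    hysteresis: float | None = None,
    invert_sign: bool = False,
    min_segment_s: float = 0.02,
) -> list[tuple[int, int, int]]:
    """Delimit breaths as (i_start, i_insp_end, i_end) sample indices.

    A breath is a positive-flow (inspiratory) segment followed by its
    negative-flow (expiratory) segment.  Zero-crossing segments whose peak
    magnitude stays inside the hysteresis band are merged into the
    preceding significant segment, so noise around zero never creates
    breaths.  A flat (all-zero) signal yields an empty list.
    """
    flow = np.asarray(flow, dtype=float)
    if invert_sign:
        flow = -flow
    if flow.size < 2 * int(sample_rate):
        raise ConfigurationError("segmentation requires at least 2 s of flow")
    if hysteresis is None:
        hysteresis = HYSTERESIS_NOISE_MULTIPLE * robust_noise_sd(flow)
    if not np.any(np.abs(flow) > hysteresis):
        return []

    sign = np.where(flow > 0, 1, -1)
    change = np.flatnonzero(np.diff(sign) != 0) + 1
    bounds = np.concatenate(([0], change, [flow.size]))
    min_samples = max(2, int(round(min_segment_s * sample_rate)))
    # significant zero-crossing segments (peak beyond the hysteresis band and
    # at least min_segment_s long), each extended over any following
    # sub-threshold segments
    segments: list[tuple[int, int, int]] = []  # (sign, i0, i1)
    for k in range(len(bounds) - 1):
        i0, i1 = int(bounds[k]), int(bounds[k + 1])
        peak = float(np.max(np.abs(flow[i0:i1])))
        s = int(sign[i0])
        significant = peak >= hysteresis and (i1 - i0) >= min_samples
        if significant and (not segments or segments[-1][0] != s):
            segments.append((s, i0, i1))
        elif segments:
            prev = segments[-1]
            segments[-1] = (prev[0], prev[1], i1)

    breaths: list[tuple[int, int, int]] = []
    for k in range(len(segments) - 1):
        s, i0, i1 = segments[k]
        s2, j0, j1 = segments[k + 1]
        if s == 1 and s2 == -1:
            breaths.append((i0, j0, j1))
    return breaths


def breath_features(
    flow: np.ndarray,
    bounds: tuple[int, int, int],
    sample_rate: float,
    index: int = 0,
    stage: Stage = Stage.UNKNOWN,
) -> BreathRecord:
    """Timing, volume and inspiratory flow landmarks for one breath."""
    i_start, i_insp_end, i_end = bounds
    if i_insp_end <= i_start:
        raise ConfigurationError("zero-length inspiration")
    if not (i_start < i_insp_end < i_end):
        raise ConfigurationError(f"invalid breath bounds {bounds}")
    dt = 1.0 / sample_rate
    insp = np.asarray(flow[i_start:i_insp_end], dtype=float)
    vt = float(np.trapezoid(np.maximum(insp, 0.0), dx=dt))
    n = insp.size
    mid = n // 2
    v_i_max = float(insp.max())
    v_imax1 = float(insp[:mid].max()) if mid > 0 else v_i_max
    v_i50 = float(insp[mid])
    v_imax2 = float(insp[mid:].max())
    return BreathRecord(
        index=index,
        t_start=i_start * dt,
        t_insp_end=i_insp_end * dt,
        t_end=i_end * dt,
        vt_ml=vt,
        v_i_max=v_i_max,
        v_imax1=v_imax1,
        v_i50=v_i50,
        v_imax2=v_imax2,
        stage=stage,
    )


def analyze_flow(
    flow: np.ndarray,
    sample_rate: float,
    hypnogram: Hypnogram | None = None,
    hysteresis: float | None = None,
    invert_sign: bool = False,
) -> list[BreathRecord]:
    """Segment a flow trace and compute features for every breath."""
    bounds = segment_breaths(flow, sample_rate, hysteresis=hysteresis, invert_sign=invert_sign)
    sgn_flow = -np.asarray(flow, dtype=float) if invert_sign else np.asarray(flow, dtype=float)
    records = []
    for k, b in enumerate(bounds):
        stage = hypnogram.stage_at(b[0] / sample_rate) if hypnogram is not None else Stage.UNKNOWN
        records.append(breath_features(sgn_flow, b, sample_rate, index=k, stage=stage))
    return records


@dataclass
class StageWindows:
    """Per-stage analysis windows, half-open intervals in seconds."""

    rem: list[tuple[float, float]]
    nrem: list[tuple[float, float]]


def select_analysis_windows(hypnogram: Hypnogram) -> StageWindows:
    """Respiratory analysis windows: all REM periods, sampled NREM stretches.

    Every contiguous REM period is analyzed in full.  NREM is sampled
    periodically: within each 30-min block of the recording, the first NREM
    run lasting at least 20 s contributes its first 20 s.  Wake is excluded
    (the CO2-challenge analysis handles wakefulness separately).
    """
    runs = hypnogram.runs()
    rem = [(t0, t1) for s, t0, t1 in runs if s == Stage.REM]
    nrem: list[tuple[float, float]] = []
    n_blocks = int(np.ceil(hypnogram.duration / NREM_BLOCK_S))
    nrem_runs = [(t0, t1) for s, t0, t1 in runs if s == Stage.NREM]
    for b in range(n_blocks):
        b0, b1 = b * NREM_BLOCK_S, (b + 1) * NREM_BLOCK_S
        for t0, t1 in nrem_runs:
            lo, hi = max(t0, b0), min(t1, b1)
            if hi - lo >= NREM_STRETCH_S:
                nrem.append((lo, lo + NREM_STRETCH_S))
                break
    return StageWindows(rem=rem, nrem=nrem)


@dataclass
class VentilationSummary:
    """Per-stage ventilation summary (means and medians over breaths)."""

    stage: Stage
    n_breaths: int
    vt_ml: float
    rr_bpm: float
    ve_ml_min: float
    v_i_max: float
    mean_insp_flow: float
    vt_ml_median: float
    ve_ml_min_median: float
    missing: bool = False


def breaths_in_windows(
    breaths: list[BreathRecord], windows: list[tuple[float, float]]
) -> list[BreathRecord]:
    """Breaths whose onset falls inside any of the given windows."""
    out = []
    for b in breaths:
        if any(t0 <= b.t_start < t1 for t0, t1 in windows):
            out.append(b)
    return out


def aggregate_ventilation(
    breaths: list[BreathRecord],
    stage: Stage,
    mass_g: float | None = None,
) -> VentilationSummary:
    """Summaries of VT, RR, VE, V_I_max and mean inspiratory flow.

    ``mass_g``, when given, normalizes volumes per 100 g body mass
    (off by default).  An empty breath list yields a flagged missing-value
    summary rather than an error.
    """
    if not breaths:
        warnings.warn(f"no breaths for stage {stage.value}; summary is missing", stacklevel=2)
        nan = float("nan")
        return VentilationSummary(stage, 0, nan, nan, nan, nan, nan, nan, nan, missing=True)
    scale = (100.0 / mass_g) if mass_g else 1.0
    vt = np.array([b.vt_ml for b in breaths]) * scale
    rr = np.array([b.inst_rr for b in breaths])
    ve = np.array([b.inst_ve for b in breaths]) * scale
    vmax = np.array([b.v_i_max for b in breaths]) * scale
    mif = np.array([b.mean_insp_flow for b in breaths]) * scale
    return VentilationSummary(
        stage=stage,
        n_breaths=len(breaths),
        vt_ml=float(vt.mean()),
        rr_bpm=float(rr.mean()),
        ve_ml_min=float(ve.mean()),
        v_i_max=float(vmax.mean()),
        mean_insp_flow=float(mif.mean()),
        vt_ml_median=float(np.median(vt)),
        ve_ml_min_median=float(np.median(ve)),
    )
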