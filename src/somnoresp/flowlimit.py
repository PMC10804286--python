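"""Classification of breaths as sniff, inspiratory-flow-limited, or normal.

Inspiratory flow limitation — the signature of partial upper-airway
obstruction — is an early plateau of inspiratory airflow while respiratory
effort continues to rise.  The classifier proceeds in two steps:

1. *Sniff filter*: breaths with an unusually short inspiration (robust Z
   score of Ti at or below -1.75 within the analysis window) are sniffs and
   are defined as non-flow-limited without further testing.  Sniffs are
   short; the Z criterion is therefore applied on the short-duration side,
   with both threshold and side configurable.
2. *Plateau test* on each remaining breath: the breath is flow-limited iff
   (a) the flow first comes within ``plateau_flatness_tau`` of its maximum
   at or before ``early_peak_fraction`` of inspiration (early peak), and
   (b) the relative flow variation (max-min)/V_I_max over the middle 50%
   of inspiration is at most ``plateau_flatness_tau`` (mid-inspiratory
   plateau), and (c) optionally, the effort channel still rises between
   plateau onset and plateau end.

A clean half-sine breath has a mid-span variation of 1 - sin(pi/4) ~ 29%
of its peak, so the default tolerance tau = 0.10 rejects unobstructed
breaths while accepting strongly clipped ones.  Flow is lightly smoothed
(boxcar, ~1/8 of inspiration capped at 25 ms) before landmarking so that
additive sensor noise does not inflate the plateau's apparent variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BreathLabel, BreathRecord, Stage

__all__ = [
    "FlowLimitConfig",
    "PlateauResult",
    "sniff_filter",
    "detect_plateau",
    "classify_breaths",
    "ClassificationSummary",
]

MIN_BREATHS_FOR_Z = 10


@dataclass
class FlowLimitConfig:
    sniff_z_threshold: float = 1.75     # applied on the short-Ti side
    plateau_flatness_tau: float = 0.10  # relative variation tolerated over the plateau
    early_peak_fraction: float = 0.5    # peak must be reached in this fraction of Ti
    require_effort_rise: bool = False   # use the effort channel as a hard criterion
    smoothing_max_s: float = 0.025

    def __post_init__(self) -> None:
        if self.sniff_z_threshold <= 0 or self.plateau_flatness_tau <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.early_peak_fraction < 1.0):
            raise ValueError("early_peak_fraction must be in (0, 1)")


def _robust_z(ti: np.ndarray) -> np.ndarray | None:
    """Robust Z scores of inspiratory times; None when the spread is zero.

    MAD-based scale with a classical-SD fallback: a constant majority makes
    the MAD zero even when genuine outliers exist.
    """
    center = np.median(ti)
    mad = np.median(np.abs(ti - center))
    scale = 1.4826 * mad
    if scale == 0.0:
        center = float(np.mean(ti))
        scale = float(np.std(ti, ddof=1)) if ti.size > 1 else 0.0
    if scale == 0.0:
        return None
    return (ti - center) / scale


def sniff_filter(breaths: list[BreathRecord], cfg: FlowLimitConfig) -> np.ndarray:
    """Boolean sniff flags for a list of breaths sharing one scoring context.

    Fewer than 10 breaths cannot support a Z-score distribution: no flags
    are set and a warning is issued.
    """
    if len(breaths) < MIN_BREATHS_FOR_Z:
        if breaths:
            warnings.warn(
                f"only {len(breaths)} breaths in scoring context; sniff filter skipped",
                stacklevel=2,
            )
        return np.zeros(len(breaths), dtype=bool)
    ti = np.array([b.ti for b in breaths])
    z = _robust_z(ti)
    if z is None:
        return np.zeros(len(breaths), dtype=bool)
    return z <= -cfg.sniff_z_threshold


@dataclass
class PlateauResult:
    is_flow_limited: bool
    flatness: float            # (max - min) / V_I_max over the middle 50% of Ti
    t_plateau_onset: float     # first near-peak attainment, fraction of Ti
    degenerate: bool = False


def _smooth(x: np.ndarray, n_window: int) -> np.ndarray:
    if n_window <= 1 or x.size < 3:
        return x
    n_window = min(n_window, x.size)
    kernel = np.ones(n_window) / n_window
    pad = n_window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def detect_plateau(
    insp_flow: np.ndarray,
    cfg: FlowLimitConfig,
    sample_rate: float,
    effort: np.ndarray | None = None,
) -> PlateauResult:
    """Mid-inspiratory plateau test on one breath's inspiratory flow segment."""
    insp = np.asarray(insp_flow, dtype=float)
    n = insp.size
    if n < 4:
        raise ValueError("inspiration must span at least 4 samples")
    window = int(round(min(cfg.smoothing_max_s, n / (8 * sample_rate)) * sample_rate))
    sm = _smooth(insp, window)
    v_max = float(sm.max())
    if v_max <= 0:
        return PlateauResult(False, float("nan"), float("nan"), degenerate=True)

    onset_idx = int(np.argmax(sm >= (1.0 - cfg.plateau_flatness_tau) * v_max))
    t_onset = onset_idx / n
    early_peak = t_onset <= cfg.early_peak_fraction

    lo, hi = int(round(0.25 * n)), int(round(0.75 * n))
    mid = sm[lo:hi]
    if mid.size == 0:
        return PlateauResult(False, float("nan"), t_onset, degenerate=True)
    flatness = float((mid.max() - mid.min()) / v_max)
    flat = flatness <= cfg.plateau_flatness_tau

    effort_ok = True
    if cfg.require_effort_rise and effort is not None:
        eff = np.asarray(effort, dtype=float)
        end_idx = min(eff.size - 1, hi)
        effort_ok = eff[end_idx] > eff[min(onset_idx, eff.size - 1)]

    return PlateauResult(bool(early_peak and flat and effort_ok), flatness, t_onset)


@dataclass
class ClassificationSummary:
    """Per-stage flow-limitation prevalence among non-sniff breaths."""

    flow_limited_fraction: dict[str, float] = field(default_factory=dict)
    n_by_label: dict[str, int] = field(default_factory=dict)


def classify_breaths(
    breaths: list[BreathRecord],
    flow: np.ndarray,
    sample_rate: float,
    cfg: FlowLimitConfig | None = None,
    effort: np.ndarray | None = None,
) -> ClassificationSummary:
    """Label every breath sniff / flow_limited / normal (labels set in place).

    The sniff Z-score context is the full list supplied (callers pass one
    analysis window at a time to keep the context local).  Returns per-stage
    flow-limited fractions among non-sniff breaths.
    """
    if cfg is None:
        cfg = FlowLimitConfig()
    sniffs = sniff_filter(breaths, cfg)
    for b, is_sniff in zip(breaths, sniffs):
        if is_sniff:
            b.label = BreathLabel.SNIFF
            continue
        i0 = int(round(b.t_start * sample_rate))
        i1 = int(round(b.t_insp_end * sample_rate))
        insp = flow[i0:i1]
        eff = effort[i0:i1] if effort is not None else None
        if insp.size < 4:
            b.label = BreathLabel.NORMAL
            continue
        res = detect_plateau(insp, cfg, sample_rate, effort=eff)
        b.label = BreathLabel.FLOW_LIMITED if res.is_flow_limited else BreathLabel.NORMAL

    summary = ClassificationSummary()
    for label in BreathLabel:
        summary.n_by_label[label.value] = sum(1 for b in breaths if b.label == label)
    for stage in (Stage.WAKE, Stage.NREM, Stage.REM, Stage.UNKNOWN):
        non_sniff = [b for b in breaths if b.stage == stage and b.label != BreathLabel.SNIFF]
        if non_sniff:
            fl = sum(1 for b in non_sniff if b.label == BreathLabel.FLOW_LIMITED)
            summary.flow_limited_fraction[stage.value] = fl / len(non_sniff)
    return summary
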