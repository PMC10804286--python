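"""Hypercapnic ventilatory response: slope of VE on inspired CO2.

The HCVR is the least-squares slope of minute ventilation (mL/min) on
inspired CO2 fraction (%) across challenge levels (typically room air vs
8% CO2), measured during wakefulness.  Within each level window the first
60 s after the gas switch are excluded, by which time a first-order
ventilatory transition (tau ~= 15 s) has settled to within 2% of its
asymptote; VE is then averaged over the remaining wake breaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .breaths import analyze_flow
from .core import BreathRecord, ChannelRole, ConfigurationError, Recording, Stage
from .staging import Hypnogram

__all__ = ["HCVRResult", "plateau_ventilation", "hcvr_slope", "run_hcvr"]

PLATEAU_EXCLUDE_S = 60.0
MIN_WINDOW_S = 90.0


@dataclass
class HCVRResult:
    levels_pct: list[float]
    ve_ml_min: list[float]
    slope: float                  # mL/min per % inspired CO2
    intercept: float              # mL/min
    r_squared: float
    plateau_windows: list[tuple[float, float]] = field(default_factory=list)


def plateau_ventilation(
    breaths: list[BreathRecord],
    window: tuple[float, float],
    hypnogram: Hypnogram | None = None,
) -> float:
    """Mean VE (mL/min) over plateau breaths of one CO2-level window.

    Breaths are restricted to those starting between 60 s after the gas
    switch and the window end, and to wake epochs when a hypnogram is
    given.  Returns NaN (with a warning) when no eligible breaths exist.
    """
    t0, t1 = window
    if t1 - t0 < MIN_WINDOW_S:
        raise ConfigurationError(
            f"CO2-level window of {t1 - t0:.0f} s is shorter than {MIN_WINDOW_S:.0f} s"
        )
    sel = [b for b in breaths if t0 + PLATEAU_EXCLUDE_S <= b.t_start < t1]
    if hypnogram is not None and len(hypnogram):
        sel = [b for b in sel if hypnogram.stage_at(b.t_start) == Stage.WAKE]
    if not sel:
        warnings.warn("no wake breaths in the plateau window; VE missing", stacklevel=2)
        return float("nan")
    return float(np.mean([b.inst_ve for b in sel]))


def hcvr_slope(levels_pct: list[float], ve_ml_min: list[float]) -> HCVRResult:
    """Ordinary least squares of VE on inspired CO2 (%).

    With exactly two levels the slope reduces to the difference quotient
    dVE / dCO2.
    """
    x = np.asarray(levels_pct, dtype=float)
    y = np.asarray(ve_ml_min, dtype=float)
    if x.size < 2:
        raise ConfigurationError("HCVR needs at least two CO2 levels")
    if np.ptp(x) == 0:
        raise ConfigurationError("CO2 levels are identical; slope undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return HCVRResult(
        levels_pct=list(map(float, x)),
        ve_ml_min=list(map(float, y)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


def run_hcvr(
    rec: Recording,
    protocol: list[tuple[float, float]],
    hypnogram: Hypnogram | None = None,
) -> HCVRResult:
    """End-to-end HCVR from a recording and its (CO2 %, duration s) protocol."""
    flow = rec.get(ChannelRole.FLOW)
    breaths = analyze_flow(flow.samples, flow.sample_rate, hypnogram=hypnogram)
    levels, ves, windows = [], [], []
    cursor = 0.0
    for pct, dur in protocol:
        window = (cursor, cursor + dur)
        cursor += dur
        ve = plateau_ventilation(breaths, window, hypnogram=hypnogram)
        if np.isnan(ve):
            continue
        levels.append(pct)
        ves.append(ve)
        windows.append(window)
    result = hcvr_slope(levels, ves)
    result.plateau_windows = windows
    return result
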