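"""Open-circuit indirect calorimetry: VO2, VCO2, RER, activity, coupling.

Gas exchange is computed from inflow/outflow O2 and CO2 fractions with the
Haldane transformation, which corrects for the inequality of inflow and
outflow volumes using the inert-gas balance:

    H    = (1 - FiO2_in - FiCO2_in) / (1 - FiO2_out - FiCO2_out)
    VO2  = Q * (FiO2_in - FiO2_out * H)
    VCO2 = Q * (FiCO2_out * H - FiCO2_in)

with Q the (inflow) chamber flow.  Rates inherit Q's units (mL/h here)
and are summarized on an 11-min sampling grid with an optional light/dark
partition.  Ventilation/metabolism coupling ratios (VE/VO2, VE/VCO2) are
dimensionless, with both numerator and denominator converted to mL/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ChannelRole, ConfigurationError, Recording

__all__ = [
    "MetabolicSummary",
    "open_circuit_rates",
    "sample_grid",
    "activity_counts",
    "coupling_ratios",
    "summarize_recording",
]

GRID_S = 660.0  # 11-min collection interval


@dataclass
class MetabolicSummary:
    vo2_ml_h: float
    vco2_ml_h: float
    rer: float
    activity_total: float = float("nan")
    vo2_bins: np.ndarray = field(default_factory=lambda: np.zeros(0))
    vco2_bins: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rer_bins: np.ndarray = field(default_factory=lambda: np.zeros(0))
    light_bins: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def open_circuit_rates(
    fio2_in: np.ndarray,
    fio2_out: np.ndarray,
    fico2_in: np.ndarray,
    fico2_out: np.ndarray,
    flow_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Haldane-corrected VO2 and VCO2 per sample, in flow-rate units.

    All gas fractions must lie in (0, 1) — except CO2 inflow, which may be
    zero in scrubbed air — and O2+CO2 must sum below 1 in both streams.
    """
    fio2_in = np.asarray(fio2_in, dtype=float)
    fio2_out = np.asarray(fio2_out, dtype=float)
    fico2_in = np.asarray(fico2_in, dtype=float)
    fico2_out = np.asarray(fico2_out, dtype=float)
    if flow_rate <= 0:
        raise ConfigurationError("chamber flow rate must be positive")
    for name, f in (
        ("fio2_in", fio2_in),
        ("fio2_out", fio2_out),
        ("fico2_in", fico2_in),
        ("fico2_out", fico2_out),
    ):
        if np.any(f < 0) or np.any(f >= 1):
            raise ConfigurationError(f"{name} outside [0, 1)")
    if np.any(fio2_in + fico2_in >= 1) or np.any(fio2_out + fico2_out >= 1):
        raise ConfigurationError("gas fractions sum to >= 1")
    haldane = (1.0 - fio2_in - fico2_in) / (1.0 - fio2_out - fico2_out)
    vo2 = flow_rate * (fio2_in - fio2_out * haldane)
    vco2 = flow_rate * (fico2_out * haldane - fico2_in)
    return vo2, vco2


def sample_grid(
    rates: np.ndarray,
    sample_rate: float,
    grid_s: float = GRID_S,
    lights_on: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a rate trace into per-grid means; optionally mark light-phase bins.

    ``lights_on`` is a (start_s, end_s) window within the 24-h day for the
    light phase (e.g. lights on 7 am - 7 pm with a 10 am recording start is
    ``(0, 9*3600)``); bins are assigned by their midpoint.
    """
    rates = np.asarray(rates, dtype=float)
    per_bin = int(round(grid_s * sample_rate))
    if rates.size < per_bin:
        raise ConfigurationError("recording shorter than one grid step")
    n_bins = rates.size // per_bin
    binned = rates[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    mid = (np.arange(n_bins) + 0.5) * grid_s
    if lights_on is None:
        light = np.ones(n_bins, dtype=bool)
    else:
        day = np.mod(mid, 86400.0)
        light = (day >= lights_on[0]) & (day < lights_on[1])
    return binned, light


def activity_counts(
    activity: np.ndarray, sample_rate: float, grid_s: float = GRID_S
) -> tuple[np.ndarray, float]:
    """Beam-break sums per grid bin and in total (total = sum of bins exactly)."""
    activity = np.asarray(activity, dtype=float)
    per_bin = max(1, int(round(grid_s * sample_rate)))
    n_bins = max(1, activity.size // per_bin)
    usable = activity[: n_bins * per_bin] if activity.size >= per_bin else activity
    if activity.size >= per_bin:
        bins = usable.reshape(n_bins, per_bin).sum(axis=1)
    else:
        bins = np.array([usable.sum()])
    return bins, float(bins.sum())


def coupling_ratios(
    ve_ml_min: float, vo2_ml_h: float, vco2_ml_h: float
) -> tuple[float, float]:
    """VE/VO2 and VE/VCO2 on matched time support, both sides in mL/min."""
    vo2_ml_min = vo2_ml_h / 60.0
    vco2_ml_min = vco2_ml_h / 60.0
    if vo2_ml_min <= 0 or vco2_ml_min <= 0:
        warnings.warn("non-positive metabolic rate; coupling ratio missing", stacklevel=2)
        return float("nan"), float("nan")
    return ve_ml_min / vo2_ml_min, ve_ml_min / vco2_ml_min


def summarize_recording(
    rec: Recording,
    flow_rate_ml_h: float,
    lights_on: tuple[float, float] | None = None,
) -> MetabolicSummary:
    """VO2/VCO2/RER summary of a recording's gas-fraction channels."""
    chans = {}
    for role in (
        ChannelRole.FIO2_IN,
        ChannelRole.FIO2_OUT,
        ChannelRole.FICO2_IN,
        ChannelRole.FICO2_OUT,
    ):
        chans[role] = rec.get(role)
    fs = chans[ChannelRole.FIO2_IN].sample_rate
    vo2, vco2 = open_circuit_rates(
        chans[ChannelRole.FIO2_IN].samples,
        chans[ChannelRole.FIO2_OUT].samples,
        chans[ChannelRole.FICO2_IN].samples,
        chans[ChannelRole.FICO2_OUT].samples,
        flow_rate_ml_h,
    )
    # gas channels are already on the 11-min grid when fs == 1/GRID_S
    if abs(fs - 1.0 / GRID_S) < 1e-12:
        vo2_bins, light = vo2, np.ones(vo2.size, dtype=bool)
        vco2_bins = vco2
        if lights_on is not None:
            mid = (np.arange(vo2.size) + 0.5) * GRID_S
            day = np.mod(mid, 86400.0)
            light = (day >= lights_on[0]) & (day < lights_on[1])
    else:
        vo2_bins, light = sample_grid(vo2, fs, lights_on=lights_on)
        vco2_bins, _ = sample_grid(vco2, fs, lights_on=lights_on)
    with np.errstate(divide="ignore", invalid="ignore"):
        rer_bins = np.where(vo2_bins > 0, vco2_bins / vo2_bins, np.nan)
    activity_total = float("nan")
    if ChannelRole.ACTIVITY in rec:
        act = rec.get(ChannelRole.ACTIVITY)
        _, activity_total = activity_counts(act.samples, act.sample_rate)
    mean_vo2 = float(vo2_bins.mean())
    mean_vco2 = float(vco2_bins.mean())
    return MetabolicSummary(
        vo2_ml_h=mean_vo2,
        vco2_ml_h=mean_vco2,
        rer=mean_vco2 / mean_vo2 if mean_vo2 > 0 else float("nan"),
        activity_total=activity_total,
        vo2_bins=vo2_bins,
        vco2_bins=vco2_bins,
        rer_bins=rer_bins,
        light_bins=light,
    )
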