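"""Barometric (whole-body plethysmography) tidal-volume calibration.

Chamber-pressure fluctuations caused by the warming and humidification of
inspired air are converted to tidal volume with the classical barometric
relation of Drorbaugh and Fenn.  Writing ``T_B`` for body (rectal)
temperature, ``T_C`` for chamber temperature (both Kelvin), ``P_B`` for
barometric pressure and ``P_H2O(T)`` for water-vapor pressure (mm Hg), the
dimensionless conversion factor is

    F = T_B (P_B - P_H2O_TC) / [ T_B (P_B - P_H2O_TC) - T_C (P_B - P_H2O_TB) ]

where ``P_H2O_TB`` is the saturated vapor pressure at body temperature and
``P_H2O_TC`` the (humidity-scaled) vapor pressure at chamber temperature.
Volume then follows from the pressure deflection ``P_K`` of a known-volume
injection ``V_K``:

    V(t) = P(t) / P_K * V_K * F

Saturated vapor pressure uses the Antoine equation for water with constants
A = 8.07131, B = 1730.63, C = 233.426 (P in mm Hg, T in deg C; valid
1-100 deg C), which reproduces steam-table values to within ~0.5% over the
physiological range (47.07 mm Hg at 37 deg C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ConfigurationError, ChannelRole, Recording, TimeSeriesChannel

__all__ = [
    "CalibrationContext",
    "DegenerateConditionsError",
    "saturated_vapor_pressure",
    "drorbaugh_fenn_factor",
    "pressure_to_volume",
    "volume_to_pressure",
    "differentiate_volume",
    "calibrate_recording",
]

# Antoine constants for water, P in mm Hg, T in Celsius (1-100 degC range).
_ANTOINE_A = 8.07131
_ANTOINE_B = 1730.63
_ANTOINE_C = 233.426

_T_MIN_K = 270.0
_T_MAX_K = 320.0


class DegenerateConditionsError(ConfigurationError):
    """Body and chamber conditions make the barometric factor singular."""


def saturated_vapor_pressure(temp_k: float) -> float:
    """Saturated water-vapor pressure in mm Hg at temperature ``temp_k`` (K).

    Valid only over the physiological range (270, 320) K; out-of-range
    temperatures raise :class:`ConfigurationError`.
    """
    if not (_T_MIN_K < temp_k < _T_MAX_K):
        raise ConfigurationError(
            f"temperature {temp_k} K outside validated range ({_T_MIN_K}, {_T_MAX_K}) K"
        )
    t_c = temp_k - 273.15
    return float(10.0 ** (_ANTOINE_A - _ANTOINE_B / (_ANTOINE_C + t_c)))


@dataclass
class CalibrationContext:
    """Everything needed for the pressure-to-volume conversion.

    Parameters
    ----------
    v_k : float
        Injected calibration volume, mL.
    p_k : float
        Pressure deflection produced by ``v_k``, in pressure-channel units.
    t_body_k, t_chamber_k, t_room_k : float
        Body (rectal), chamber and room temperatures in Kelvin.
    humidity : float
        Chamber relative humidity as a fraction of saturation.
    p_baro_mmhg : float
        Barometric pressure, mm Hg.
    """

    v_k: float
    p_k: float
    t_body_k: float
    t_chamber_k: float
    t_room_k: float
    humidity: float
    p_baro_mmhg: float

    def __post_init__(self) -> None:
        for name, t in (
            ("body", self.t_body_k),
            ("chamber", self.t_chamber_k),
            ("room", self.t_room_k),
        ):
            if not (_T_MIN_K < t < _T_MAX_K):
                raise ConfigurationError(
                    f"{name} temperature {t} K outside ({_T_MIN_K}, {_T_MAX_K}) K"
                )
        if not (500.0 < self.p_baro_mmhg < 800.0):
            raise ConfigurationError(
                f"barometric pressure {self.p_baro_mmhg} mm Hg outside (500, 800)"
            )
        if self.v_k <= 0 or self.p_k <= 0:
            raise ConfigurationError("calibration volume and deflection must be > 0")
        if not (0.0 <= self.humidity <= 1.0):
            raise ConfigurationError("humidity must be a fraction in [0, 1]")

    @property
    def p_h2o_body(self) -> float:
        """Saturated vapor pressure at body temperature, mm Hg."""
        return saturated_vapor_pressure(self.t_body_k)

    @property
    def p_h2o_chamber(self) -> float:
        """Humidity-scaled vapor pressure at chamber temperature, mm Hg."""
        return self.humidity * saturated_vapor_pressure(self.t_chamber_k)

    @classmethod
    def from_meta(cls, meta) -> "CalibrationContext":
        """Build a context from :class:`~somnoresp.core.RecordingMeta`."""
        required = {
            "body_temp_c": meta.body_temp_c,
            "chamber_temp_c": meta.chamber_temp_c,
            "room_temp_c": meta.room_temp_c,
            "humidity": meta.humidity,
            "barometric_mmhg": meta.barometric_mmhg,
            "calibration_volume_ml": meta.calibration_volume_ml,
            "calibration_deflection": meta.calibration_deflection,
        }
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ConfigurationError(
                "tidal-volume conversion requires metadata field(s): " + ", ".join(missing)
            )
        return cls(
            v_k=meta.calibration_volume_ml,
            p_k=meta.calibration_deflection,
            t_body_k=meta.body_temp_c + 273.15,
            t_chamber_k=meta.chamber_temp_c + 273.15,
            t_room_k=meta.room_temp_c + 273.15,
            humidity=meta.humidity,
            p_baro_mmhg=meta.barometric_mmhg,
        )


def drorbaugh_fenn_factor(ctx: CalibrationContext) -> float:
    """Dimensionless barometric conversion factor F (see module docstring).

    F > 1 for physiological inputs (body warmer and wetter than the chamber).
    A zero or negative denominator (body and chamber in equilibrium) raises
    :class:`DegenerateConditionsError`.
    """
    num = ctx.t_body_k * (ctx.p_baro_mmhg - ctx.p_h2o_chamber)
    den = num - ctx.t_chamber_k * (ctx.p_baro_mmhg - ctx.p_h2o_body)
    if den <= 0:
        raise DegenerateConditionsError(
            "barometric factor denominator is non-positive: body and chamber "
            "temperature/humidity are too close for a pressure signal to carry "
            "tidal-volume information"
        )
    return float(num / den)


def pressure_to_volume(pressure: np.ndarray, ctx: CalibrationContext) -> np.ndarray:
    """Convert a chamber-pressure trace to tidal volume (mL).

    Exactly linear in the pressure signal: V(t) = P(t)/P_K * V_K * F.
    """
    factor = drorbaugh_fenn_factor(ctx)
    return np.asarray(pressure, dtype=float) * (ctx.v_k * factor / ctx.p_k)


def volume_to_pressure(volume: np.ndarray, ctx: CalibrationContext) -> np.ndarray:
    """Inverse of :func:`pressure_to_volume`; used to simulate chamber pressure."""
    factor = drorbaugh_fenn_factor(ctx)
    return np.asarray(volume, dtype=float) * (ctx.p_k / (ctx.v_k * factor))


def differentiate_volume(
    volume: np.ndarray,
    sample_rate: float,
    lowpass_hz: float | None = None,
) -> np.ndarray:
    """Differentiate a volume trace to airflow (mL/s).

    Second-order central differences in the interior, one-sided differences
    at the edges (``numpy.gradient``).  If ``lowpass_hz`` is given, the flow
    is smoothed with a zero-phase 4th-order Butterworth low-pass at that
    cutoff (breathing is well below 20 Hz); smoothing is off by default.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size < 3:
        raise ConfigurationError("differentiation needs at least 3 samples")
    flow = np.gradient(volume, 1.0 / sample_rate)
    if lowpass_hz is not None:
        sos = butter(4, lowpass_hz, btype="low", fs=sample_rate, output="sos")
        flow = sosfiltfilt(sos, flow)
    return flow


def calibrate_recording(rec: Recording, lowpass_hz: float | None = None) -> Recording:
    """Derive volume and flow channels from a chamber-pressure channel in place.

    Requires complete calibration metadata on the recording; raises at this
    point (not at read time) when a required field is missing.
    """
    pressure = rec.get(ChannelRole.CHAMBER_PRESSURE)
    ctx = CalibrationContext.from_meta(rec.meta)
    volume = pressure_to_volume(pressure.samples, ctx)
    flow = differentiate_volume(volume, pressure.sample_rate, lowpass_hz=lowpass_hz)
    rec.add(TimeSeriesChannel("volume", ChannelRole.VOLUME, "mL", pressure.sample_rate, volume))
    rec.add(TimeSeriesChannel("flow", ChannelRole.FLOW, "mL/s", pressure.sample_rate, flow))
    return rec
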