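"""Core in-memory containers for multichannel physiological recordings.

A :class:`Recording` holds a set of named :class:`TimeSeriesChannel` objects
(chamber pressure, airflow, EEG, EMG, SpO2, respiratory effort, gas
fractions, activity) together with the environmental metadata required for
barometric tidal-volume calibration.  Time is expressed in seconds from
recording start and every interval is half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterator

import numpy as np

__all__ = [
    "ChannelRole",
    "Stage",
    "BreathLabel",
    "TimeSeriesChannel",
    "RecordingMeta",
    "Recording",
    "BreathRecord",
    "RespiratoryEvent",
    "ConfigurationError",
    "IntegrityError",
]


class ConfigurationError(ValueError):
    """Raised when inputs or configuration violate a documented precondition."""


class IntegrityError(ValueError):
    """Raised when stored or supplied data are internally inconsistent."""


class ChannelRole(str, Enum):
    CHAMBER_PRESSURE = "chamber_pressure"
    FLOW = "flow"
    VOLUME = "volume"
    EEG = "eeg"
    EMG = "emg"
    SPO2 = "spo2"
    EFFORT = "effort"
    FIO2_IN = "fio2_in"
    FIO2_OUT = "fio2_out"
    FICO2_IN = "fico2_in"
    FICO2_OUT = "fico2_out"
    FICO2_INSPIRED = "fico2_inspired"
    ACTIVITY = "activity"
    OTHER = "other"


class Stage(str, Enum):
    WAKE = "W"
    NREM = "NREM"
    REM = "REM"
    UNKNOWN = "unknown"


class BreathLabel(str, Enum):
    NORMAL = "normal"
    SNIFF = "sniff"
    FLOW_LIMITED = "flow_limited"


@dataclass
class TimeSeriesChannel:
    """One uniformly sampled signal.

    Parameters
    ----------
    name : str
        Free-form channel name.
    role : ChannelRole
        Semantic role used by the analysis stages to locate channels.
    unit : str
        Physical unit of the samples (e.g. ``"mL/s"``, ``"%"``, ``"a.u."``).
    sample_rate : float
        Sampling frequency in Hz; must be positive.
    samples : ndarray
        1-D array of finite sample values.
    """

    name: str
    role: ChannelRole
    unit: str
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ConfigurationError(f"channel {self.name!r}: sample_rate must be > 0")
        if not self.unit:
            raise ConfigurationError(f"channel {self.name!r}: unit must be nonempty")
        if self.samples.ndim != 1:
            raise ConfigurationError(f"channel {self.name!r}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise IntegrityError(f"channel {self.name!r}: non-finite samples")
        if not isinstance(self.role, ChannelRole):
            self.role = ChannelRole(self.role)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds covered by this channel."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.sample_rate

    def slice_seconds(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open interval [t_start, t_end)."""
        i0 = max(0, int(np.ceil(t_start * self.sample_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(t_end * self.sample_rate - 1e-9)))
        return self.samples[i0:i1]


@dataclass
class RecordingMeta:
    """Environmental and calibration metadata for one session.

    Temperatures are in degrees Celsius, humidity as a fraction of
    saturation, barometric pressure in mm Hg.  ``calibration_volume`` (mL)
    and ``calibration_deflection`` (pressure-channel units) describe the
    known-volume injection used to calibrate the plethysmography chamber.
    Any field may be ``None``; stages that need a missing field raise at the
    point of use, not at read time.
    """

    body_temp_c: float | None = None
    chamber_temp_c: float | None = None
    room_temp_c: float | None = None
    humidity: float | None = None
    barometric_mmhg: float | None = None
    calibration_volume_ml: float | None = None
    calibration_deflection: float | None = None
    animal_mass_g: float | None = None
    start_time: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        known = {f: d.get(f) for f in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class Recording:
    """A multichannel session: channels keyed by role, plus metadata."""

    channels: dict[ChannelRole, TimeSeriesChannel] = field(default_factory=dict)
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def add(self, channel: TimeSeriesChannel) -> None:
        self.channels[channel.role] = channel

    def __contains__(self, role: ChannelRole) -> bool:
        return role in self.channels

    def __iter__(self) -> Iterator[TimeSeriesChannel]:
        return iter(self.channels.values())

    def get(self, role: ChannelRole) -> TimeSeriesChannel:
        if role not in self.channels:
            raise KeyError(f"recording has no channel with role {ChannelRole(role).value!r}")
        return self.channels[ChannelRole(role)]

    @property
    def duration(self) -> float:
        if not self.channels:
            return 0.0
        return max(ch.duration for ch in self.channels.values())

    def validate(self) -> None:
        """Check that all channels span the same duration to within one sample."""
        if not self.channels:
            return
        durations = [(ch, ch.duration) for ch in self.channels.values()]
        ref = durations[0][1]
        for ch, d in durations:
            tol = 1.0 / ch.sample_rate + 1e-9
            if abs(d - ref) > tol:
                raise IntegrityError(
                    f"channel {ch.name!r} spans {d:.3f} s but {durations[0][0].name!r} "
                    f"spans {ref:.3f} s (difference exceeds one sample)"
                )


@dataclass
class BreathRecord:
    """Per-breath timing, volume and inspiratory flow landmarks.

    ``V_Imax1`` / ``V_I50`` / ``V_Imax2`` are the peak inspiratory flows over
    the first half of inspiration, at its midpoint, and over its second half;
    ``V_I_max`` is the overall maximum.  ``mean_insp_flow`` is VT/Ti and
    ``inst_VE`` the instantaneous minute ventilation VT * 60/Ttot.
    """

    index: int
    t_start: float
    t_insp_end: float
    t_end: float
    vt_ml: float
    v_i_max: float
    v_imax1: float
    v_i50: float
    v_imax2: float
    stage: Stage = Stage.UNKNOWN
    label: BreathLabel = BreathLabel.NORMAL

    @property
    def ti(self) -> float:
        return self.t_insp_end - self.t_start

    @property
    def te(self) -> float:
        return self.t_end - self.t_insp_end

    @property
    def ttot(self) -> float:
        return self.t_end - self.t_start

    @property
    def mean_insp_flow(self) -> float:
        return self.vt_ml / self.ti if self.ti > 0 else float("nan")

    @property
    def inst_rr(self) -> float:
        """Instantaneous respiratory rate, breaths/min."""
        return 60.0 / self.ttot if self.ttot > 0 else float("nan")

    @property
    def inst_ve(self) -> float:
        """Instantaneous minute ventilation, mL/min."""
        return self.vt_ml * self.inst_rr


@dataclass
class RespiratoryEvent:
    """A scored apnea or oxygen desaturation with sleep-stage context."""

    kind: str  # "apnea" | "desaturation"
    t_start: float
    duration: float
    stage: Stage
    magnitude: float  # % flow reduction (apnea) or % SpO2 drop (desaturation)

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration
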