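"""Synthetic whole-body-plethysmography polysomnography recordings.

Generates multichannel recordings (airflow, volume, respiratory effort,
EEG, EMG, SpO2, gas fractions, activity, chamber pressure) with complete
ground truth, emulating the statistical structure the analysis pipeline
assumes: periodic breathing with occasional sniffs, REM-predominant
inspiratory flow-limited breaths (mid-inspiratory plateau with continued
effort), obstructive apneas with preserved effort followed by >=4% SpO2
desaturations, 5-s-epoch sleep architecture with stage-specific EEG bands
and EMG tone, graded CO2-challenge ventilatory responses, and open-circuit
calorimetry traces on an 11-min sampling grid.

Breath template
---------------
Inspiration is a half-sine of peak flow ``A = pi*VT/(2*Ti)`` (so the
inspired volume is exactly VT); expiration is an exponential decay whose
area returns the volume to baseline.  A flow-limited breath clips the
inspiratory flow at ``L = A*(1 - severity*(1 - sin(0.2*pi)))`` — the level
the half-sine reaches at 20% of Ti — so at severity 1 the flow is exactly
constant from 20% to 80% of inspiration.  Clipped area is *not*
re-normalized: flow-limited breaths lose volume, as in obstruction.  The
effort channel of a flow-limited breath is a monotonically rising quarter-
sine drive scaled by ``effort_gain`` (effort continues to increase through
the plateau); normal breaths mirror their unclipped inspiratory flow.

Determinism: a single ``numpy.random.Generator`` seeded from
``SynthConfig.seed`` is consumed by the sub-generators in a fixed,
documented order (hypnogram, breath train, apneas, SpO2, EEG/EMG,
metabolic traces), so identical configurations yield bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .calibration import CalibrationContext, volume_to_pressure
from .core import (
    BreathLabel,
    ChannelRole,
    ConfigurationError,
    Recording,
    RecordingMeta,
    Stage,
    TimeSeriesChannel,
)
from .staging import EPOCH_LEN_S, Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "TrueBreath",
    "generate_hypnogram",
    "generate_breath_train",
    "inject_apneas",
    "generate_spo2",
    "generate_eeg_emg",
    "generate_metabolic_traces",
    "generate_recording",
]

AMBIENT_FIO2 = 0.2093
AMBIENT_FICO2 = 0.0004

#: EEG generation band (Hz) and RMS amplitude (a.u.) per stage; EMG RMS per
#: stage.  Generation bands are inset ~10% inside the nominal analysis bands
#: (Wake 10-20, NREM 2-5, REM 5-10 Hz) so that filter roll-off keeps the
#: emitted power inside the band the stager integrates.
EEG_BANDS = {Stage.WAKE: (11.0, 19.0), Stage.NREM: (2.3, 4.6), Stage.REM: (5.5, 9.5)}
EEG_AMPLITUDE = {Stage.WAKE: 0.7, Stage.NREM: 2.0, Stage.REM: 0.7}
EMG_RMS = {Stage.WAKE: 1.0, Stage.NREM: 0.3, Stage.REM: 0.1}


# --------------------------------------------------------------------------
# configuration


@dataclass
class BreathParams:
    rate_bpm: float = 150.0          # breaths per minute
    rate_cv: float = 0.08            # fractional breath-to-breath period CV
    tidal_volume_ml: float = 0.15
    ti_fraction: float = 0.4         # inspiratory fraction of the cycle
    amplitude_noise_sd: float = 0.05  # per-breath multiplicative amplitude jitter
    signal_noise_sd: float = 0.01    # additive white noise, fraction of nominal peak flow


@dataclass
class SniffParams:
    probability: float = 0.02        # per breath
    ti_scale: float = 0.4            # sniff Ti (and Te) relative to a normal breath


@dataclass
class FlowLimitationParams:
    probability: float = 0.4         # per REM breath
    plateau_severity: float = 0.85   # in [0, 1]; degree of mid-inspiratory flattening
    effort_gain: float = 1.3         # > 1; effort keeps rising through the plateau
    rem_only: bool = True


@dataclass
class ApneaParams:
    #: events per hour in each stage
    rate_per_h: dict = field(default_factory=lambda: {"W": 0.0, "NREM": 2.0, "REM": 15.0})
    duration_mean_s: float = 1.2
    duration_sd_s: float = 0.3
    duration_min_s: float = 0.8
    flow_suppression: float = 0.02   # residual flow amplitude during an event
    effort_boost: float = 1.2        # obstructive: effort preserved/increased
    min_gap_s: float = 5.0           # enforced spacing between events
    max_retries: int = 200


@dataclass
class Spo2Params:
    baseline_pct: float = 97.0
    desat_depth_mean_pct: float = 6.0
    desat_depth_sd_pct: float = 1.0
    desat_lag_s: float = 2.0
    desat_hold_s: float = 4.0        # extra time the dip persists past the apnea
    tau_s: float = 1.5               # first-order SpO2 response time constant
    noise_sd_pct: float = 0.2
    independent_desat_rate_per_h: float = 0.0
    independent_desat_duration_s: float = 8.0


@dataclass
class HypnogramParams:
    #: mean bout durations (s) per stage
    bout_mean_s: dict = field(default_factory=lambda: {"W": 120.0, "NREM": 180.0, "REM": 60.0})
    #: transition weights from each stage to the others; REM is only entered
    #: from NREM regardless of weights (convention)
    transition_weights: dict = field(
        default_factory=lambda: {
            "W": {"NREM": 1.0, "REM": 0.0},
            "NREM": {"W": 0.35, "REM": 0.65},
            "REM": {"W": 0.5, "NREM": 0.5},
        }
    )
    initial_stage: str = "W"


@dataclass
class MetabolismParams:
    vo2_ml_h: float = 60.0
    rer: float = 0.85
    activity_rate_per_min: float = 2.0
    chamber_flow_ml_h: float = 30000.0  # 0.5 L/min bias flow
    fraction_noise_sd: float = 0.0      # additive noise on gas fractions


@dataclass
class EnvironmentParams:
    body_temp_c: float = 36.5
    chamber_temp_c: float = 29.0
    room_temp_c: float = 23.0
    humidity: float = 0.9
    barometric_mmhg: float = 760.0
    calibration_volume_ml: float = 0.05
    calibration_deflection: float = 1.0
    animal_mass_g: float = 45.0


@dataclass
class SynthConfig:
    """Full parameterization of one synthetic recording.

    Defaults describe a diet-induced-obese mouse daytime sleep study:
    150 breaths/min, 0.15 mL tidal volume, apneas concentrated in REM,
    ~6% desaturations, VO2 60 mL/h at RER 0.85, chamber at 29 degC with a
    humidified atmosphere at 760 mm Hg.
    """

    seed: int = 0
    duration_s: float = 600.0
    sample_rate: float = 1000.0
    breath: BreathParams = field(default_factory=BreathParams)
    sniff: SniffParams = field(default_factory=SniffParams)
    flow_limitation: FlowLimitationParams = field(default_factory=FlowLimitationParams)
    apnea: ApneaParams = field(default_factory=ApneaParams)
    spo2: Spo2Params = field(default_factory=Spo2Params)
    hypnogram: HypnogramParams = field(default_factory=HypnogramParams)
    #: list of (inspired CO2 %, duration s) segments; empty = no CO2 challenge
    co2_protocol: list = field(default_factory=list)
    hcvr_gain: float = 7.5           # mL/min of VE per % inspired CO2
    hcvr_tau_s: float = 15.0         # first-order VE transition time constant
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.breath.rate_bpm <= 0:
            raise ConfigurationError("breath rate must be positive")
        for name, p in (
            ("sniff.probability", self.sniff.probability),
            ("flow_limitation.probability", self.flow_limitation.probability),
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if not (0.0 <= self.flow_limitation.plateau_severity <= 1.0):
            raise ConfigurationError("plateau_severity must be in [0, 1]")
        if not (0.0 < self.breath.ti_fraction < 1.0):
            raise ConfigurationError("ti_fraction must be in (0, 1)")
        if self.metabolism.rer <= 0:
            raise ConfigurationError("rer must be positive")
        if not (80.0 < self.spo2.baseline_pct <= 100.0):
            raise ConfigurationError("SpO2 baseline must be in (80, 100]")

    def calibration_context(self) -> CalibrationContext:
        env = self.environment
        return CalibrationContext(
            v_k=env.calibration_volume_ml,
            p_k=env.calibration_deflection,
            t_body_k=env.body_temp_c + 273.15,
            t_chamber_k=env.chamber_temp_c + 273.15,
            t_room_k=env.room_temp_c + 273.15,
            humidity=env.humidity,
            p_baro_mmhg=env.barometric_mmhg,
        )

    def meta(self) -> RecordingMeta:
        env = self.environment
        return RecordingMeta(
            body_temp_c=env.body_temp_c,
            chamber_temp_c=env.chamber_temp_c,
            room_temp_c=env.room_temp_c,
            humidity=env.humidity,
            barometric_mmhg=env.barometric_mmhg,
            calibration_volume_ml=env.calibration_volume_ml,
            calibration_deflection=env.calibration_deflection,
            animal_mass_g=env.animal_mass_g,
        )


# --------------------------------------------------------------------------
# ground truth


@dataclass
class TrueBreath:
    """One generated breath as recorded in the ground-truth table."""

    t_start: float
    t_insp_end: float
    t_end: float
    label: BreathLabel
    stage: Stage
    vt_ml: float       # inspired volume actually emitted (after any clipping)
    peak_flow: float   # emitted V_I_max


@dataclass
class GroundTruth:
    """Generator-side truth used only by tests and validation."""

    breath_table: list[TrueBreath] = field(default_factory=list)
    apnea_events: list[tuple[float, float, Stage]] = field(default_factory=list)
    desat_events: list[tuple[float, float]] = field(default_factory=list)  # (t_start, depth %)
    hypnogram_true: Hypnogram | None = None
    hcvr_gain_true: float = 0.0
    rer_true: float = float("nan")
    vo2_true_ml_h: float = float("nan")
    ve_baseline_ml_min: float = float("nan")


# --------------------------------------------------------------------------
# hypnogram


def generate_hypnogram(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[Hypnogram, list[tuple[Stage, float]]]:
    """Semi-Markov sleep architecture on a 5-s epoch grid.

    Bout durations are exponential with the configured per-stage means
    (rounded up to whole epochs); transitions follow the configured weights
    except that REM is only entered from NREM.
    """
    hp = config.hypnogram
    for stage, mean in hp.bout_mean_s.items():
        if mean <= EPOCH_LEN_S:
            raise ConfigurationError(f"bout mean for {stage} must exceed one epoch (5 s)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_epochs = int(round(config.duration_s / EPOCH_LEN_S))
    stages: list[Stage] = []
    bouts: list[tuple[Stage, float]] = []
    current = Stage(hp.initial_stage)
    while len(stages) < n_epochs:
        mean = hp.bout_mean_s[current.value]
        bout_s = max(EPOCH_LEN_S, rng.exponential(mean))
        n = max(1, int(round(bout_s / EPOCH_LEN_S)))
        n = min(n, n_epochs - len(stages))
        stages.extend([current] * n)
        bouts.append((current, n * EPOCH_LEN_S))
        weights = dict(hp.transition_weights[current.value])
        if current != Stage.NREM:
            weights.pop(Stage.REM.value, None)  # REM entered only from NREM
        targets = [s for s, w in weights.items() if w > 0]
        if not targets:
            # absorbing stage (e.g. weights forcing Wake-only)
            if len(stages) < n_epochs:
                stages.extend([current] * (n_epochs - len(stages)))
            break
        w = np.array([weights[s] for s in targets], dtype=float)
        current = Stage(rng.choice(targets, p=w / w.sum()))
    return Hypnogram(stages[:n_epochs], source="external"), bouts


# --------------------------------------------------------------------------
# breath train

_PLATEAU_REF_FRACTION = 0.2  # clip level referenced to the flow at 20% of Ti


def _expiration(n_te: int, vt: float, dt: float) -> np.ndarray:
    """Exponential-decay expiratory flow whose area is exactly -vt."""
    if n_te <= 0:
        return np.zeros(0)
    te = n_te * dt
    tau = te / 4.0
    t = np.arange(n_te) * dt
    shape = np.exp(-t / tau)
    area = np.trapezoid(shape, dx=dt)
    if area <= 0:
        return np.zeros(n_te)
    return -(vt / area) * shape


def generate_breath_train(
    config: SynthConfig,
    hypnogram: Hypnogram,
    rng: np.random.Generator | None = None,
    ve_multiplier: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Generate flow (mL/s), volume (mL), effort (a.u.) and the truth table.

    ``ve_multiplier``, when given, is a per-sample minute-ventilation scale
    (used for CO2 challenges); each breath's amplitude is scaled by its
    value at breath onset.  The volume channel is the running trapezoidal
    integral of the flow channel.
    """
    config.validate()
    if config.duration_s < 10.0:
        raise ConfigurationError("breath-train generation requires duration >= 10 s")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    dt = 1.0 / fs
    n_total = int(round(config.duration_s * fs))
    flow = np.zeros(n_total)
    effort = np.zeros(n_total)
    br = config.breath
    truth = GroundTruth(hypnogram_true=hypnogram)
    ttot_nom = 60.0 / br.rate_bpm
    a_nom = math.pi * br.tidal_volume_ml / (2.0 * br.ti_fraction * ttot_nom)

    i = 0
    breath_index = 0
    while True:
        # draws per breath, in fixed order: period jitter, amplitude jitter,
        # sniff uniform, flow-limitation uniform
        jitter = rng.normal() if br.rate_cv > 0 else 0.0
        amp_jitter = rng.normal() if br.amplitude_noise_sd > 0 else 0.0
        u_sniff = rng.uniform()
        u_fl = rng.uniform()

        ttot = ttot_nom * max(0.3, 1.0 + br.rate_cv * jitter)
        t_start = i * dt
        stage = hypnogram.stage_at(t_start) if len(hypnogram) else Stage.UNKNOWN

        label = BreathLabel.NORMAL
        if u_sniff < config.sniff.probability:
            label = BreathLabel.SNIFF
            ttot *= config.sniff.ti_scale
        elif (
            u_fl < config.flow_limitation.probability
            and (stage == Stage.REM or not config.flow_limitation.rem_only)
        ):
            label = BreathLabel.FLOW_LIMITED

        n_ti = max(4, int(round(br.ti_fraction * ttot * fs)))
        n_te = max(4, int(round((1.0 - br.ti_fraction) * ttot * fs)))
        if i + n_ti + n_te > n_total:
            break  # final partial breath does not fit; leave trailing zeros

        amp = a_nom * max(0.1, 1.0 + br.amplitude_noise_sd * amp_jitter)
        if label == BreathLabel.SNIFF:
            # same drive amplitude over a compressed cycle -> smaller VT
            pass
        if ve_multiplier is not None:
            amp *= float(ve_multiplier[i])

        phase = np.arange(n_ti) * (math.pi / n_ti)
        insp = amp * np.sin(phase)
        drive = insp.copy()
        if label == BreathLabel.FLOW_LIMITED:
            sev = config.flow_limitation.plateau_severity
            clip = amp * (1.0 - sev * (1.0 - math.sin(math.pi * _PLATEAU_REF_FRACTION)))
            insp = np.minimum(insp, clip)
            # effort keeps rising through inspiration (quarter-sine drive)
            drive = (
                config.flow_limitation.effort_gain
                * amp
                * np.sin(0.5 * math.pi * np.arange(n_ti) / n_ti)
            )
        vt = float(np.trapezoid(insp, dx=dt))
        exp_flow = _expiration(n_te, vt, dt)

        flow[i : i + n_ti] = insp
        flow[i + n_ti : i + n_ti + n_te] = exp_flow
        effort[i : i + n_ti] = drive
        # effort relaxes during expiration
        effort[i + n_ti : i + n_ti + n_te] = drive[-1] * np.exp(
            -np.arange(n_te) / (0.15 * n_te + 1)
        )

        truth.breath_table.append(
            TrueBreath(
                t_start=t_start,
                t_insp_end=(i + n_ti) * dt,
                t_end=(i + n_ti + n_te) * dt,
                label=label,
                stage=stage,
                vt_ml=vt,
                peak_flow=float(insp.max()),
            )
        )
        i += n_ti + n_te
        breath_index += 1

    if br.signal_noise_sd > 0:
        flow = flow + rng.normal(0.0, br.signal_noise_sd * a_nom, n_total)
    volume = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    return flow, volume, effort, truth


# --------------------------------------------------------------------------
# apneas


def inject_apneas(
    flow: np.ndarray,
    effort: np.ndarray,
    truth: GroundTruth,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Suppress flow (>=95% amplitude reduction) while preserving effort.

    Event counts per stage are Poisson at the configured per-hour rates;
    start times are drawn uniformly within that stage's runs.  Overlapping
    or out-of-bounds draws are redrawn up to ``max_retries`` times, after
    which a :class:`ConfigurationError` is raised.
    """
    ap = config.apnea
    if ap.duration_min_s <= 0:
        raise ConfigurationError("apnea minimum duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    flow = np.array(flow, dtype=float, copy=True)
    effort = np.array(effort, dtype=float, copy=True)
    hyp = truth.hypnogram_true
    if hyp is None:
        raise ConfigurationError("apnea injection needs the true hypnogram")

    placed: list[tuple[float, float, Stage]] = []
    for stage in (Stage.WAKE, Stage.NREM, Stage.REM):
        rate = float(ap.rate_per_h.get(stage.value, 0.0))
        stage_runs = [(t0, t1) for s, t0, t1 in hyp.runs() if s == stage]
        stage_h = sum(t1 - t0 for t0, t1 in stage_runs) / 3600.0
        if rate <= 0 or stage_h <= 0:
            continue
        n_events = int(rng.poisson(rate * stage_h))
        lengths = np.array([t1 - t0 for t0, t1 in stage_runs])
        for _ in range(n_events):
            for attempt in range(ap.max_retries + 1):
                dur = max(ap.duration_min_s, rng.normal(ap.duration_mean_s, ap.duration_sd_s))
                ridx = int(rng.choice(len(stage_runs), p=lengths / lengths.sum()))
                r0, r1 = stage_runs[ridx]
                if r1 - r0 <= dur:
                    continue
                t0 = r0 + rng.uniform(0.0, (r1 - r0) - dur)
                ok = all(
                    t0 + dur + ap.min_gap_s <= e0 or e0 + ed + ap.min_gap_s <= t0
                    for e0, ed, _ in placed
                )
                if ok:
                    placed.append((t0, dur, stage))
                    break
            else:
                raise ConfigurationError(
                    "could not place a non-overlapping apnea within "
                    f"{ap.max_retries} retries (stage {stage.value})"
                )

    for t0, dur, stage in sorted(placed):
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        flow[i0:i1] *= ap.flow_suppression
        effort[i0:i1] *= ap.effort_boost
        truth.apnea_events.append((t0, dur, stage))
    return flow, effort, truth


# --------------------------------------------------------------------------
# SpO2


def generate_spo2(
    truth: GroundTruth,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """SpO2 (%) as a first-order low-pass response to per-event dips.

    Each apnea (and each independent desaturation event) drives, after
    ``desat_lag_s``, a step of drawn depth lasting the event duration plus
    ``desat_hold_s``; the trace relaxes with time constant ``tau_s`` and
    stays within (0, 100].  Truth depths are recorded in
    ``truth.desat_events``.
    """
    sp = config.spo2
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    if n_samples is None:
        n_samples = int(round(config.duration_s * fs))
    target = np.zeros(n_samples)

    events: list[tuple[float, float]] = [
        (t0, dur + sp.desat_hold_s) for t0, dur, _ in truth.apnea_events
    ]
    n_indep = (
        int(rng.poisson(sp.independent_desat_rate_per_h * config.duration_s / 3600.0))
        if sp.independent_desat_rate_per_h > 0
        else 0
    )
    for _ in range(n_indep):
        t0 = rng.uniform(0.0, max(0.0, config.duration_s - sp.independent_desat_duration_s))
        events.append((t0, sp.independent_desat_duration_s))

    for t0, dur in sorted(events):
        depth = max(0.5, rng.normal(sp.desat_depth_mean_pct, sp.desat_depth_sd_pct))
        i0 = int(round((t0 + sp.desat_lag_s) * fs))
        i1 = min(n_samples, int(round((t0 + sp.desat_lag_s + dur) * fs)))
        if i0 >= n_samples:
            continue
        target[i0:i1] = np.minimum(target[i0:i1], -depth)
        truth.desat_events.append((t0, depth))

    # first-order low-pass: y[k] = y[k-1] + alpha (target[k] - y[k-1])
    alpha = 1.0 / (sp.tau_s * fs)
    from scipy.signal import lfilter

    dip = lfilter([alpha], [1.0, -(1.0 - alpha)], target)
    spo2 = sp.baseline_pct + dip
    if sp.noise_sd_pct > 0:
        # pulse-oximeter-like bounded noise: clipped at 3 SD so the
        # event-free floor stays within baseline - 3*noise_sd
        noise = rng.normal(0.0, sp.noise_sd_pct, n_samples)
        np.clip(noise, -3 * sp.noise_sd_pct, 3 * sp.noise_sd_pct, out=noise)
        spo2 = spo2 + noise
    return np.clip(spo2, 1e-6, 100.0)


# --------------------------------------------------------------------------
# EEG / EMG


def generate_eeg_emg(
    hypnogram: Hypnogram,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-dependent band-limited EEG and EMG noise (a.u.).

    Per same-stage run, the EEG is white noise band-passed to the stage's
    characteristic band and scaled to the stage's RMS amplitude; the EMG is
    white noise at the stage's tone level (Wake > NREM >= REM).
    """
    if len(hypnogram) == 0:
        raise ConfigurationError("hypnogram must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    from scipy.signal import butter, sosfiltfilt

    fs = config.sample_rate
    n_total = int(round(hypnogram.duration * fs))
    eeg = np.zeros(n_total)
    emg = np.zeros(n_total)
    sos_cache: dict[Stage, np.ndarray] = {}
    for stage, t0, t1 in hypnogram.runs():
        if stage not in EEG_BANDS:
            raise ConfigurationError(f"unknown stage label {stage!r}")
        i0, i1 = int(round(t0 * fs)), min(n_total, int(round(t1 * fs)))
        n = i1 - i0
        if n <= 0:
            continue
        if stage not in sos_cache:
            lo, hi = EEG_BANDS[stage]
            sos_cache[stage] = butter(4, (lo, hi), btype="band", fs=fs, output="sos")
        white = rng.normal(0.0, 1.0, n)
        band = sosfiltfilt(sos_cache[stage], white)
        rms = np.sqrt(np.mean(band**2))
        if rms > 0:
            band *= EEG_AMPLITUDE[stage] / rms
        eeg[i0:i1] = band
        emg[i0:i1] = rng.normal(0.0, EMG_RMS[stage], n)
    return eeg, emg


# --------------------------------------------------------------------------
# metabolic traces

METABOLIC_GRID_S = 660.0  # gas samples collected every 11 min


def generate_metabolic_traces(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> dict[ChannelRole, TimeSeriesChannel]:
    """Gas-fraction channels on the 11-min grid plus a 1-Hz activity channel.

    Outflow O2/CO2 fractions are constructed so that the Haldane-corrected
    open-circuit equations recover exactly the configured VO2 and
    VCO2 = RER * VO2 at the configured chamber flow.  Activity is a Poisson
    impulse stream at the configured beam-break rate.
    """
    mb = config.metabolism
    if mb.vo2_ml_h <= 0:
        raise ConfigurationError("vo2 must be positive")
    if not (0.5 < mb.rer < 1.5):
        logger.warning("RER %.3f outside the physiological range (0.5, 1.5)", mb.rer)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_bins = max(1, int(math.ceil(config.duration_s / METABOLIC_GRID_S)))
    q = mb.chamber_flow_ml_h
    vo2 = mb.vo2_ml_h
    vco2 = mb.rer * vo2
    n_in = 1.0 - AMBIENT_FIO2 - AMBIENT_FICO2
    # inert-gas balance gives the outflow inert fraction in closed form
    n_out = q * n_in / (q - vo2 + vco2)
    fio2_out = (q * AMBIENT_FIO2 - vo2) * n_out / (q * n_in)
    fico2_out = (q * AMBIENT_FICO2 + vco2) * n_out / (q * n_in)

    def chan(role: ChannelRole, value: float) -> TimeSeriesChannel:
        samples = np.full(n_bins, value)
        if mb.fraction_noise_sd > 0:
            samples = samples + rng.normal(0.0, mb.fraction_noise_sd, n_bins)
        return TimeSeriesChannel(role.value, role, "fraction", 1.0 / METABOLIC_GRID_S, samples)

    channels = {
        ChannelRole.FIO2_IN: chan(ChannelRole.FIO2_IN, AMBIENT_FIO2),
        ChannelRole.FIO2_OUT: chan(ChannelRole.FIO2_OUT, fio2_out),
        ChannelRole.FICO2_IN: chan(ChannelRole.FICO2_IN, AMBIENT_FICO2),
        ChannelRole.FICO2_OUT: chan(ChannelRole.FICO2_OUT, fico2_out),
    }
    n_seconds = max(1, int(round(config.duration_s)))
    lam = mb.activity_rate_per_min / 60.0
    counts = rng.poisson(lam, n_seconds) if lam > 0 else np.zeros(n_seconds, dtype=int)
    channels[ChannelRole.ACTIVITY] = TimeSeriesChannel(
        "activity", ChannelRole.ACTIVITY, "breaks", 1.0, counts.astype(float)
    )
    return channels


# --------------------------------------------------------------------------
# composition


def _ve_multiplier(config: SynthConfig, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample VE scale and inspired-CO2 trace for a CO2-challenge protocol.

    The scale moves as a first-order response (tau = ``hcvr_tau_s``) toward
    ``1 + gain * CO2% / VE_baseline`` in each protocol segment, settling
    within the 60-s window that analysis excludes.
    """
    fs = config.sample_rate
    co2 = np.zeros(n_samples)
    cursor = 0
    for pct, dur in config.co2_protocol:
        n = int(round(dur * fs))
        co2[cursor : cursor + n] = pct
        cursor += n
        if cursor >= n_samples:
            break
    if cursor < n_samples and config.co2_protocol:
        co2[cursor:] = config.co2_protocol[-1][0]
    ve0 = config.breath.tidal_volume_ml * config.breath.rate_bpm  # mL/min
    target = 1.0 + config.hcvr_gain * co2 / ve0
    alpha = 1.0 / (config.hcvr_tau_s * fs)
    from scipy.signal import lfilter

    mult = lfilter([alpha], [1.0, -(1.0 - alpha)], target - 1.0, zi=[0.0])[0] + 1.0
    return mult, co2


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Compose a full multichannel recording with ground truth.

    Sub-generators consume a single seeded random stream in this fixed
    order: hypnogram, breath train, apneas, SpO2, EEG/EMG, metabolic
    traces.  All channels share the time base; metadata is copied from the
    environment configuration; chamber pressure is derived from the volume
    channel by inverting the barometric calibration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n_total = int(round(config.duration_s * fs))

    hyp, _bouts = generate_hypnogram(config, rng)
    mult, co2 = (None, None)
    if config.co2_protocol:
        mult, co2 = _ve_multiplier(config, n_total)
    flow, _vol, effort, truth = generate_breath_train(config, hyp, rng, ve_multiplier=mult)
    flow, effort, truth = inject_apneas(flow, effort, truth, config, rng)
    volume = cumulative_trapezoid(flow, dx=1.0 / fs, initial=0.0)
    spo2 = generate_spo2(truth, config, rng, n_samples=n_total)
    eeg, emg = generate_eeg_emg(hyp, config, rng)
    metab = generate_metabolic_traces(config, rng)

    ctx = config.calibration_context()
    pressure = volume_to_pressure(volume, ctx)

    rec = Recording(meta=config.meta())
    rec.add(TimeSeriesChannel("flow", ChannelRole.FLOW, "mL/s", fs, flow))
    rec.add(TimeSeriesChannel("volume", ChannelRole.VOLUME, "mL", fs, volume))
    rec.add(TimeSeriesChannel("effort", ChannelRole.EFFORT, "a.u.", fs, effort))
    rec.add(TimeSeriesChannel("chamber_pressure", ChannelRole.CHAMBER_PRESSURE, "a.u.", fs, pressure))
    rec.add(TimeSeriesChannel("spo2", ChannelRole.SPO2, "%", fs, spo2))
    rec.add(TimeSeriesChannel("eeg", ChannelRole.EEG, "a.u.", fs, eeg))
    rec.add(TimeSeriesChannel("emg", ChannelRole.EMG, "a.u.", fs, emg))
    if co2 is not None:
        rec.add(
            TimeSeriesChannel("fico2_inspired", ChannelRole.FICO2_INSPIRED, "%", fs, co2)
        )
    for role, ch in metab.items():
        rec.add(ch)
    rec.validate()

    truth.hcvr_gain_true = config.hcvr_gain if config.co2_protocol else 0.0
    truth.rer_true = config.metabolism.rer
    truth.vo2_true_ml_h = config.metabolism.vo2_ml_h
    truth.ve_baseline_ml_min = config.breath.tidal_volume_ml * config.breath.rate_bpm
    return rec, truth
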