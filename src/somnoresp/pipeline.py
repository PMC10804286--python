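"""End-to-end orchestration: recording -> tables, indices and summaries.

``run_pipeline`` takes a :class:`PipelineConfig` (YAML-serializable), either
synthesizes a recording or loads one from the native container, then runs
staging, breath analysis, flow-limitation classification, apnea/ODI
scoring, HCVR and calorimetry as enabled, writing delimited tables plus a
JSON run manifest into the output directory.  Every output table carries
the configuration hash in a leading comment line, and a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .breaths import aggregate_ventilation, analyze_flow, breaths_in_windows, select_analysis_windows
from .calibration import calibrate_recording
from .core import ChannelRole, ConfigurationError, Stage
from .events import ApneaScoringConfig, DesatScoringConfig, apnea_index, detect_apneas, detect_desaturations
from .flowlimit import FlowLimitConfig, classify_breaths
from .hcvr import run_hcvr
from .metabolism import summarize_recording
from .staging import Hypnogram, architecture_summary, stage_recording
from .synth import SynthConfig, generate_recording

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_mapping(cls, data: dict):
    """Build a (possibly nested) dataclass from a plain mapping."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
            v = _from_mapping(f.type, v)
        elif isinstance(v, dict) and f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            probe = f.default_factory()  # type: ignore[misc]
            if dataclasses.is_dataclass(probe):
                v = _from_mapping(type(probe), v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    output_dir: str = "somnoresp_out"
    input_recording: str | None = None      # native container path; None -> synthesize
    synth: SynthConfig = field(default_factory=SynthConfig)
    hypnogram_path: str | None = None       # externally scored hypnogram (CSV)
    use_automatic_staging: bool = True      # stage from EEG/EMG when no external file
    calibrate_from_pressure: bool = False   # derive flow/volume from chamber pressure
    run_classification: bool = True
    run_events: bool = True
    run_odi: bool = True
    run_hcvr_stage: bool = False
    run_metabolism: bool = True
    flow_limit: FlowLimitConfig = field(default_factory=FlowLimitConfig)
    apnea_scoring: ApneaScoringConfig = field(default_factory=ApneaScoringConfig)
    desat_scoring: DesatScoringConfig = field(default_factory=DesatScoringConfig)
    hcvr_protocol: list = field(default_factory=list)  # [(CO2 %, duration s), ...]
    metabolic_flow_ml_h: float = 30000.0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_to_plain(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return _from_mapping(cls, data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        ``output_dir`` and ``log_level`` do not affect results and are
        excluded, so runs of one configuration into different directories
        produce identical tables.
        """
        plain = _to_plain(self)
        plain.pop("output_dir", None)
        plain.pop("log_level", None)
        canonical = json.dumps(plain, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    output_dir: Path
    config_hash: str
    summary: dict
    outputs: dict[str, str] = field(default_factory=dict)


def _write_table(df_writer, path: Path, config_hash: str) -> None:
    """Write a table with a leading config-hash comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df_writer(fh)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every enabled stage; partial outputs are kept on stage failure."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict = {"config_hash": chash}
    outputs: dict[str, str] = {}
    run_log: list[str] = []

    try:
        # --- acquire recording -------------------------------------------
        if config.input_recording:
            rec = sio.read_recording(config.input_recording)
            truth = None
            run_log.append(f"loaded recording from {config.input_recording}")
        else:
            rec, truth = generate_recording(config.synth)
            run_log.append(f"synthesized recording (seed={config.synth.seed})")

        if config.calibrate_from_pressure or ChannelRole.FLOW not in rec:
            calibrate_recording(rec)
            run_log.append("derived volume/flow from chamber pressure")

        # --- hypnogram ----------------------------------------------------
        if config.hypnogram_path:
            hyp = sio.read_hypnogram(config.hypnogram_path)
            run_log.append("using externally scored hypnogram")
        elif config.use_automatic_staging and ChannelRole.EEG in rec and ChannelRole.EMG in rec:
            hyp, _ = stage_recording(rec)
            run_log.append("scored hypnogram from EEG/EMG")
        elif truth is not None and truth.hypnogram_true is not None:
            hyp = truth.hypnogram_true
            run_log.append("using generator hypnogram")
        else:
            hyp = Hypnogram([], source="external")
            run_log.append("no hypnogram available; stage-resolved outputs disabled")
        if len(hyp):
            hdf = pd.DataFrame(
                {
                    "epoch_start_s": [i * hyp.epoch_len for i in range(len(hyp))],
                    "stage": [s.value for s in hyp.stages],
                }
            )
            _write_table(lambda fh: hdf.to_csv(fh, index=False), out / "hypnogram.csv", chash)
            outputs["hypnogram"] = "hypnogram.csv"
            arch = architecture_summary(hyp)
            summary["architecture"] = {
                "total_sleep_s": arch.total_sleep_s,
                "stage_seconds": arch.stage_seconds,
                "bout_counts": arch.bout_counts,
                "bout_mean_s": arch.bout_mean_s,
            }

        # --- breaths ------------------------------------------------------
        flow = rec.get(ChannelRole.FLOW)
        breaths = analyze_flow(flow.samples, flow.sample_rate, hypnogram=hyp if len(hyp) else None)
        run_log.append(f"segmented {len(breaths)} breaths")

        if config.run_classification and breaths:
            effort = rec.get(ChannelRole.EFFORT).samples if ChannelRole.EFFORT in rec else None
            cls = classify_breaths(breaths, flow.samples, flow.sample_rate, config.flow_limit, effort=effort)
            summary["flow_limited_fraction"] = cls.flow_limited_fraction
            summary["breath_labels"] = cls.n_by_label

        bdf = sio.breaths_to_frame(breaths)
        _write_table(lambda fh: bdf.to_csv(fh, index=False, float_format="%.10g"),
                     out / "breaths.csv", chash)
        outputs["breaths"] = "breaths.csv"

        if len(hyp):
            windows = select_analysis_windows(hyp)
            vent = {}
            for stage, wins in (("REM", windows.rem), ("NREM", windows.nrem)):
                sel = breaths_in_windows(breaths, wins)
                s = aggregate_ventilation(sel, Stage(stage))
                vent[stage] = {
                    "n_breaths": s.n_breaths, "vt_ml": s.vt_ml, "rr_bpm": s.rr_bpm,
                    "ve_ml_min": s.ve_ml_min, "v_i_max": s.v_i_max,
                    "mean_insp_flow": s.mean_insp_flow, "missing": s.missing,
                }
            summary["ventilation"] = vent

        # --- events -------------------------------------------------------
        events = []
        if config.run_events and breaths:
            events = detect_apneas(
                flow.samples, flow.sample_rate, breaths,
                hypnogram=hyp if len(hyp) else None, cfg=config.apnea_scoring,
            )
            if len(hyp):
                summary["apnea_index"] = {
                    s.value: apnea_index(events, hyp, s)
                    for s in (Stage.NREM, Stage.REM)
                    if hyp.stage_seconds(s) > 0
                }
        if config.run_odi and len(hyp):
            if ChannelRole.SPO2 not in rec:
                raise ConfigurationError(
                    "ODI requested but the recording has no channel with role 'spo2'"
                )
            sp = rec.get(ChannelRole.SPO2)
            odi = detect_desaturations(sp.samples, sp.sample_rate, hyp, breaths, config.desat_scoring)
            events = events + odi.events
            summary["odi_per_h"] = odi.odi_per_h
        if config.run_events or config.run_odi:
            edf = pd.DataFrame(
                [
                    {"kind": e.kind, "t_start": e.t_start, "duration": e.duration,
                     "stage": e.stage.value, "magnitude": e.magnitude}
                    for e in events
                ],
                columns=["kind", "t_start", "duration", "stage", "magnitude"],
            )
            _write_table(lambda fh: edf.to_csv(fh, index=False, float_format="%.10g"),
                         out / "events.csv", chash)
            outputs["events"] = "events.csv"

        # --- HCVR ---------------------------------------------------------
        protocol = config.hcvr_protocol or config.synth.co2_protocol
        if config.run_hcvr_stage and protocol:
            res = run_hcvr(rec, [tuple(p) for p in protocol], hypnogram=hyp if len(hyp) else None)
            summary["hcvr"] = {
                "slope_ml_min_per_pct": res.slope, "intercept_ml_min": res.intercept,
                "r_squared": res.r_squared, "levels_pct": res.levels_pct,
                "ve_ml_min": res.ve_ml_min,
            }

        # --- metabolism ---------------------------------------------------
        if config.run_metabolism and ChannelRole.FIO2_IN in rec:
            ms = summarize_recording(rec, config.metabolic_flow_ml_h)
            summary["metabolism"] = {
                "vo2_ml_h": ms.vo2_ml_h, "vco2_ml_h": ms.vco2_ml_h, "rer": ms.rer,
                "activity_total": ms.activity_total,
            }
    finally:
        manifest = {
            "config_hash": chash,
            "config": _to_plain(config),
            "run_log": run_log,
            "outputs": outputs,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return PipelineResult(output_dir=out, config_hash=chash, summary=summary, outputs=outputs)
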