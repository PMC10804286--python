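"""Read/write recordings and derived tables in a versioned text container.

A recording is stored as a directory: a ``recording.json`` sidecar with
the format version, metadata and a channel manifest, plus one delimited
single-column file per channel.  Sample values are written with 17
significant digits, so the native round trip is exact for metadata and
bit-faithful (<=1e-12 relative) for samples.  Derived tables (breaths,
events, hypnograms) are plain CSV; the hypnogram exchange format is the
two-column ``epoch_start_s,stage`` table.

Format versioning: ``FORMAT_VERSION`` is written on every save and checked
on load; older minor versions of the same major remain readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BreathRecord,
    ChannelRole,
    IntegrityError,
    Recording,
    RecordingMeta,
    RespiratoryEvent,
    Stage,
    TimeSeriesChannel,
)
from .staging import EPOCH_LEN_S, Hypnogram

__all__ = [
    "FORMAT_VERSION",
    "write_recording",
    "read_recording",
    "write_breath_table",
    "read_breath_table",
    "write_events",
    "read_events",
    "write_hypnogram",
    "read_hypnogram",
]

FORMAT_VERSION = "1.0"


class SchemaError(IntegrityError):
    """The on-disk container violates the documented schema."""


def _check_version(version: str) -> None:
    try:
        major, _minor = (int(x) for x in version.split("."))
    except Exception as exc:
        raise SchemaError(f"unparseable format version {version!r}") from exc
    ours = int(FORMAT_VERSION.split(".")[0])
    if major > ours:
        raise SchemaError(f"container format {version} is newer than supported {FORMAT_VERSION}")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to a container directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ch in rec:
        fname = f"channel_{ch.role.value}.csv"
        np.savetxt(path / fname, ch.samples, fmt="%.17g", header=ch.name, comments="# ")
        manifest.append(
            {
                "name": ch.name,
                "role": ch.role.value,
                "unit": ch.unit,
                "sample_rate": ch.sample_rate,
                "n_samples": ch.n_samples,
                "file": fname,
            }
        )
    sidecar = {
        "format_version": FORMAT_VERSION,
        "meta": rec.meta.to_dict(),
        "channels": manifest,
    }
    (path / "recording.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a container directory back into a schema-validated Recording.

    Unknown channel roles are preserved under role ``other``.  Missing
    metadata does not fail here; conversion stages raise at point of use.
    """
    path = Path(path)
    sidecar_path = path / "recording.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no recording.json under {path}")
    sidecar = json.loads(sidecar_path.read_text())
    for field in ("format_version", "meta", "channels"):
        if field not in sidecar:
            raise SchemaError(f"recording.json is missing required field {field!r}")
    _check_version(sidecar["format_version"])
    rec = Recording(meta=RecordingMeta.from_dict(sidecar["meta"]))
    for entry in sidecar["channels"]:
        for field in ("role", "unit", "sample_rate", "n_samples", "file"):
            if field not in entry:
                raise SchemaError(f"channel manifest entry is missing field {field!r}")
        samples = np.loadtxt(path / entry["file"], comments="#", ndmin=1)
        if samples.size != entry["n_samples"]:
            raise IntegrityError(
                f"channel file {entry['file']}: {samples.size} samples on disk, "
                f"{entry['n_samples']} expected"
            )
        try:
            role = ChannelRole(entry["role"])
        except ValueError:
            role = ChannelRole.OTHER
        rec.add(
            TimeSeriesChannel(
                entry.get("name", entry["role"]), role, entry["unit"],
                entry["sample_rate"], samples,
            )
        )
    rec.validate()
    return rec


def breaths_to_frame(breaths: list[BreathRecord]) -> pd.DataFrame:
    rows = [
        {
            "index": b.index,
            "t_start": b.t_start,
            "t_insp_end": b.t_insp_end,
            "t_end": b.t_end,
            "ti": b.ti,
            "te": b.te,
            "ttot": b.ttot,
            "vt_ml": b.vt_ml,
            "v_i_max": b.v_i_max,
            "v_imax1": b.v_imax1,
            "v_i50": b.v_i50,
            "v_imax2": b.v_imax2,
            "mean_insp_flow": b.mean_insp_flow,
            "inst_rr": b.inst_rr,
            "inst_ve": b.inst_ve,
            "stage": b.stage.value,
            "label": b.label.value,
        }
        for b in breaths
    ]
    columns = [
        "index", "t_start", "t_insp_end", "t_end", "ti", "te", "ttot", "vt_ml",
        "v_i_max", "v_imax1", "v_i50", "v_imax2", "mean_insp_flow", "inst_rr",
        "inst_ve", "stage", "label",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_breath_table(breaths: list[BreathRecord], path: str | Path) -> Path:
    path = Path(path)
    breaths_to_frame(breaths).to_csv(path, index=False, float_format="%.10g")
    return path


def read_breath_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: list[RespiratoryEvent], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "kind": e.kind,
            "t_start": e.t_start,
            "duration": e.duration,
            "stage": e.stage.value,
            "magnitude": e.magnitude,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["kind", "t_start", "duration", "stage", "magnitude"]).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def read_events(path: str | Path) -> list[RespiratoryEvent]:
    df = pd.read_csv(path)
    return [
        RespiratoryEvent(
            kind=r.kind, t_start=r.t_start, duration=r.duration,
            stage=Stage(r.stage), magnitude=r.magnitude,
        )
        for r in df.itertuples()
    ]


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    """Two-column exchange format: epoch_start_s, stage."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_start_s": [i * hyp.epoch_len for i in range(len(hyp))],
            "stage": [s.value for s in hyp.stages],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise SchemaError("hypnogram table must have a 'stage' column")
    epoch_len = EPOCH_LEN_S
    if len(df) > 1 and "epoch_start_s" in df.columns:
        epoch_len = float(df.epoch_start_s.iloc[1] - df.epoch_start_s.iloc[0])
    return Hypnogram([Stage(s) for s in df.stage], epoch_len=epoch_len, source="external")
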