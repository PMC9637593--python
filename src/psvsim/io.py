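"""Reading and writing: parameter configs, waveform records, sidecars.

Parameter sets are serialized as human-readable YAML, one file per
archetype instance, with the symbol names used throughout the package and
an explicit unit string per entry.  Waveform records are long-format
delimited text (time, pao, flow, volume, pmus, phase) plus a JSON sidecar
holding events, per-breath annotations, induction settings and the full
configuration -- the dataset stays inspectable with a text editor.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .circuit import CircuitParameters, LimbParameters, VentilatorConfig
from .lung import LungParameters

__all__ = [
    "save_lung_parameters",
    "load_lung_parameters",
    "record_to_csv",
    "write_record",
    "read_record",
]

#: unit strings per parameter symbol
_UNITS = {
    "Au": "cmH2O.s/L", "Ku": "cmH2O.s2/L2", "Kc": "cmH2O.s/L", "Vcmax": "L",
    "As": "cmH2O.s/L", "Ks": "-", "Bs": "cmH2O.s/L", "Vstar": "L",
    "RV": "L", "TLC": "L", "Ac": "1/cmH2O", "Bc": "cmH2O", "Dc": "-",
    "Acw": "cmH2O", "Bcw": "cmH2O", "Al": "L", "Bl": "1/cmH2O", "Dl": "cmH2O",
    "Cve": "L/cmH2O", "Rve": "cmH2O.s/L", "Rd": "cmH2O.s/L",
}


def save_lung_parameters(params: LungParameters, path) -> None:
    """Write one parameter set as YAML (symbol: {value, unit})."""
    doc = {"archetype": params.archetype}
    for name in _UNITS:
        doc[name] = {"value": float(getattr(params, name)), "unit": _UNITS[name]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_lung_parameters(path) -> LungParameters:
    """Read a parameter set written by :func:`save_lung_parameters`."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    kwargs = {"archetype": doc.get("archetype", "healthy")}
    for name in _UNITS:
        entry = doc[name]
        kwargs[name] = float(entry["value"] if isinstance(entry, dict) else entry)
    return LungParameters(**kwargs)


# ---------------------------------------------------------------------------
# waveform records


def record_to_csv(record, pao=None, flow=None, volume=None) -> str:
    """Render the sensor channels as deterministic delimited text.

    Optional overrides let the caller substitute noisy sensor channels
    while the record itself keeps the noiseless ground truth.
    """
    pao = record.pao if pao is None else pao
    flow = record.flow if flow is None else flow
    volume = record.volume if volume is None else volume
    cols = np.column_stack([record.t, pao, flow, volume, record.pmus, record.phase])
    buf = _io.StringIO()
    buf.write("time,pao,flow,volume,pmus,phase\n")
    np.savetxt(buf, cols, fmt=["%.4f", "%.6f", "%.6f", "%.6f", "%.6f", "%d"],
               delimiter=",")
    return buf.getvalue()


def _annotation_rows(annotations, breaths):
    rows = []
    for i, ann in enumerate(annotations):
        b = breaths[i]
        markers = {k: list(v) for k, v in ann.markers.items()}
        rows.append(
            {
                "index": i,
                "intended_class": b.profile.intended_class,
                "label": ann.label.label,
                "start_delay": ann.label.start_delay,
                "end_delay": ann.label.end_delay,
                "markers": markers,
                "induction": {
                    "trigger_drop": b.trigger_drop,
                    "cycle_fraction": b.cycle_fraction,
                },
                "amplitude": b.profile.amplitude,
                "rise_time": b.profile.rise_time,
                "fall_time": b.profile.fall_time,
            }
        )
    return rows


def write_record(
    record,
    base_path,
    annotations=None,
    anomalies=None,
    pao=None,
    flow=None,
    volume=None,
    meta: Optional[dict] = None,
) -> tuple:
    """Write ``<base>.csv`` and ``<base>.json`` for one record.

    The sidecar carries events, per-breath annotations (classified from
    noiseless ground truth), the full configuration and any extra
    metadata (seeds, realized SNRs).  Returns the two paths.
    """
    base = Path(base_path)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    csv_path.write_text(record_to_csv(record, pao=pao, flow=flow, volume=volume),
                        encoding="utf-8")
    sidecar = {
        "fs": record.fs,
        "events": {k: [float(x) for x in v] for k, v in record.events.items()},
        "lung": dataclasses.asdict(record.lung) if record.lung else None,
        "circuit": dataclasses.asdict(record.circuit) if record.circuit else None,
        "vent": dataclasses.asdict(record.vent) if record.vent else None,
        "meta": meta or {},
    }
    if annotations is not None and record.schedule is not None:
        sidecar["breaths"] = _annotation_rows(annotations, record.schedule.breaths)
    if anomalies is not None:
        sidecar["auto_trigger_anomalies"] = [float(x) for x in anomalies]
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True),
                         encoding="utf-8")
    return csv_path, json_path


def read_record(base_path):
    """Read back a written record as ``(DataFrame, sidecar dict)``."""
    import pandas as pd

    base = Path(base_path)
    frame = pd.read_csv(base.with_suffix(".csv"))
    sidecar = json.loads(base.with_suffix(".json").read_text(encoding="utf-8"))
    return frame, sidecar
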