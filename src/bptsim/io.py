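"""File-format plumbing: HDF5 raw container, CSV traces, run manifests.

Container schema
----------------
``/raw/data``        complex [lines x coils x samples]
``/raw/dwell_time``  scalar, s
``/raw/line_times``  [lines], s
``/raw/meta``        JSON string attribute (center frequency, image band,
                     tone offsets, provenance)
``/sim/flux/<id>``   complex flux series with ``axis`` dataset and attrs
``/traces/<name>``   real/complex trace with ``sample_rate``/``units`` attrs
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .em_bore import FluxSeries
from .kspace import BptSeries, RawAcquisition
from .sigproc import MotionTrace

__all__ = [
    "RunManifest",
    "save_raw",
    "load_raw",
    "save_flux_series",
    "load_flux_series",
    "save_trace",
    "load_trace",
    "flux_to_csv",
    "bpt_series_to_csv",
    "bpt_series_from_csv",
    "trace_to_csv",
]


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output directory."""

    command: str
    config_hash: str
    seed: int
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, out_dir: str | Path) -> "RunManifest":
        d = json.loads((Path(out_dir) / "manifest.json").read_text())
        return cls(**d)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_raw(path: str | Path, raw: RawAcquisition) -> None:
    with h5py.File(path, "a") as f:
        if "raw" in f:
            del f["raw"]
        g = f.create_group("raw")
        g.create_dataset("data", data=raw.data)
        g.create_dataset("dwell_time", data=raw.dwell_time)
        g.create_dataset("line_times", data=raw.line_times)
        meta = {"center_frequency": raw.center_frequency,
                "image_band": list(raw.image_band), **_json_safe(raw.meta)}
        g.attrs["meta"] = json.dumps(meta)


def load_raw(path: str | Path) -> RawAcquisition:
    with h5py.File(path, "r") as f:
        if "raw" not in f:
            raise ValueError(f"{path} is not a raw acquisition container "
                             "(missing /raw group)")
        g = f["raw"]
        meta = json.loads(g.attrs["meta"])
        return RawAcquisition(
            data=g["data"][()],
            dwell_time=float(g["dwell_time"][()]),
            line_times=g["line_times"][()],
            center_frequency=float(meta.pop("center_frequency", 127.8e6)),
            image_band=tuple(meta.pop("image_band", (-40e3, 40e3))),
            meta=meta)


def save_flux_series(path: str | Path, series: list[FluxSeries]) -> None:
    with h5py.File(path, "a") as f:
        if "sim/flux" in f:
            del f["sim/flux"]
        g = f.require_group("sim/flux")
        for i, fs in enumerate(series):
            sg = g.create_group(f"{i:03d}_{fs.coil_id}")
            sg.create_dataset("flux", data=fs.flux)
            sg.create_dataset("axis", data=fs.axis)
            sg.attrs["coil_id"] = fs.coil_id
            sg.attrs["frequency_hz"] = fs.frequency
            sg.attrs["axis_name"] = fs.axis_name


def load_flux_series(path: str | Path) -> list[FluxSeries]:
    out = []
    with h5py.File(path, "r") as f:
        g = f["sim/flux"]
        for key in sorted(g):
            sg = g[key]
            out.append(FluxSeries(str(sg.attrs["coil_id"]),
                                  float(sg.attrs["frequency_hz"]),
                                  sg["axis"][()], sg["flux"][()],
                                  str(sg.attrs["axis_name"])))
    return out


def save_trace(path: str | Path, trace: MotionTrace) -> None:
    with h5py.File(path, "a") as f:
        key = f"traces/{trace.name}"
        if key in f:
            del f[key]
        d = f.create_dataset(key, data=trace.values)
        d.attrs["sample_rate"] = trace.sample_rate
        d.attrs["units"] = trace.units
        d.attrs["meta"] = json.dumps(_json_safe(trace.meta))


def load_trace(path: str | Path, name: str) -> MotionTrace:
    with h5py.File(path, "r") as f:
        d = f[f"traces/{name}"]
        return MotionTrace(name, float(d.attrs["sample_rate"]), d[()],
                           str(d.attrs["units"]),
                           json.loads(d.attrs.get("meta", "{}")))


def flux_to_csv(path: str | Path, series: list[FluxSeries]) -> None:
    """FluxSeries table: coil_id, frequency_hz, <axis>, flux_real, flux_imag."""
    rows = []
    for fs in series:
        for ax, val in zip(fs.axis, fs.flux):
            rows.append({"coil_id": fs.coil_id, "frequency_hz": fs.frequency,
                         fs.axis_name: ax, "flux_real": val.real,
                         "flux_imag": val.imag})
    pd.DataFrame(rows).to_csv(path, index=False)


def bpt_series_to_csv(path: str | Path, series: BptSeries) -> None:
    """Long-format table (line_time_s, coil_id, real, imag); full float precision."""
    n_lines, n_coils = series.values.shape
    df = pd.DataFrame({
        "line_time_s": np.repeat(series.line_times, n_coils),
        "coil_id": np.tile(np.arange(n_coils), n_lines),
        "real": series.values.real.ravel(),
        "imag": series.values.imag.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    with open(path, "a") as f:
        f.write(f"# tone_label={series.tone_label} "
                f"frequency_offset={series.frequency_offset!r}\n")


def bpt_series_from_csv(path: str | Path) -> BptSeries:
    label, offset = "tone", 0.0
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                parts = dict(kv.split("=", 1) for kv in line[1:].split())
                label = parts.get("tone_label", label)
                offset = float(parts.get("frequency_offset", offset))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    n_coils = int(df["coil_id"].max()) + 1
    times = df["line_time_s"].to_numpy()[::n_coils]
    vals = (df["real"].to_numpy() + 1j * df["imag"].to_numpy()).reshape(-1, n_coils)
    return BptSeries(label, offset, vals, times)


def preamp_sweep_to_csv(path: str | Path, input_dbm, fundamental_dbm,
                        imd_dbm) -> None:
    """Two-tone sweep table (input_dbm, fundamental_dbm, imd_dbm)."""
    pd.DataFrame({"input_dbm": input_dbm, "fundamental_dbm": fundamental_dbm,
                  "imd_dbm": imd_dbm}).to_csv(path, index=False,
                                              float_format="%.17g")


def preamp_sweep_from_csv(path: str | Path):
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("input_dbm", "fundamental_dbm", "imd_dbm"):
        if col not in df:
            raise ValueError(f"sweep table missing column {col!r}")
    return (df["input_dbm"].to_numpy(), df["fundamental_dbm"].to_numpy(),
            df["imd_dbm"].to_numpy())


def trace_to_csv(path: str | Path, trace: MotionTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "value": np.real(trace.values)}
                 ).to_csv(path, index=False, float_format="%.17g")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
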