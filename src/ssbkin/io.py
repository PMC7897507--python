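"""Trace, protocol and manifest file formats.

Traces are CSV with the fixed header ``time_s,compaction_nm_per_nt`` and a
JSON sidecar (<name>.json) carrying protocol, parameters, noise model and
seed, so every artifact can be regenerated exactly.  Protocols and
parameter sets are JSON (YAML also accepted for protocols); a dataset
manifest lists every trace of a generated series with its provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ParameterSet, load_parameters, save_parameters
from .protocols import Protocol, Trace
from .synthetic_data import ConcentrationSeries

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "read_protocol",
    "write_protocol",
    "write_series",
    "read_manifest",
]

TRACE_COLUMNS = ("time_s", "compaction_nm_per_nt")


class TraceFormatError(ValueError):
    pass


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({TRACE_COLUMNS[0]: trace.time, TRACE_COLUMNS[1]: trace.compaction})
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "noisy": trace.noisy,
        "seed": trace.seed,
        "protocol": trace.protocol.to_dict() if trace.protocol else None,
        "meta": trace.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_trace(path) -> Trace:
    """Read a trace CSV (and sidecar if present); lossless round-trip."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"missing column {col!r} in {path}")
    protocol = None
    noisy, seed, meta = False, None, {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        noisy = bool(d.get("noisy", False))
        seed = d.get("seed")
        meta = d.get("meta", {})
        if d.get("protocol"):
            protocol = Protocol.from_dict(d["protocol"])
    return Trace(
        time=df[TRACE_COLUMNS[0]].to_numpy(float),
        compaction=df[TRACE_COLUMNS[1]].to_numpy(float),
        protocol=protocol, noisy=noisy, seed=seed, meta=meta,
    )


def write_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2) + "\n")


def read_protocol(path) -> Protocol:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml
        return Protocol.from_dict(yaml.safe_load(text))
    return Protocol.from_dict(json.loads(text))


def write_series(series: ConcentrationSeries, outdir) -> Path:
    """Write every trace of a series plus a manifest JSON; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for (c, rep), tr in sorted(series.traces.items()):
        name = f"trace_c{c:g}nM_rep{rep}.csv"
        write_trace(tr, outdir / name)
        entries.append({
            "file": name, "concentration_nM": c, "replicate": rep,
            "seed": tr.seed,
        })
    manifest = {
        "kind": "concentration_series",
        "concentrations_nM": list(series.concentrations),
        "n_rep": series.n_rep,
        "params": series.params.to_dict(),
        "noise": {"sigma": series.noise.sigma,
                  "drift_rate_per_100s": series.noise.drift_rate,
                  "seed": series.noise.seed},
        "traces": entries,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath


def read_manifest(path) -> tuple[dict, dict]:
    """Load a series manifest; returns (manifest dict, {(c, rep): Trace})."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    traces = {}
    for e in manifest["traces"]:
        traces[(float(e["concentration_nM"]), int(e["replicate"]))] = \
            read_trace(path.parent / e["file"])
    return manifest, traces
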