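"""Raw trace file I/O: binary sample streams with JSON sidecars.

Analog (simulation-rate) traces are stored as raw little-endian float64
volts; digitized traces as raw little-endian uint16 ADC codes.  Each binary
file ``<name>.bin`` is described by a ``<name>.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .semg_synth import EMGTrace
from .signal_chain import DigitalTrace

__all__ = ["write_trace", "read_trace", "write_digital", "read_digital"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: EMGTrace, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(trace.samples.astype("<f8").tobytes())
    _sidecar(path).write_text(
        json.dumps(
            {
                "kind": "analog_trace",
                "dtype": "<f8",
                "fs_sim": trace.fs_sim,
                "n_samples": len(trace.samples),
                "components": list(trace.components),
            },
            indent=2,
        )
    )
    return path


def read_trace(path: str | Path) -> EMGTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    samples = np.frombuffer(path.read_bytes(), dtype="<f8").copy()
    return EMGTrace(samples, meta["fs_sim"], tuple(meta.get("components", ("emg",))))


def write_digital(dt: DigitalTrace, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(dt.codes.astype("<u2").tobytes())
    _sidecar(path).write_text(
        json.dumps(
            {
                "kind": "digital_trace",
                "dtype": "<u2",
                "fs": dt.fs,
                "bits": dt.bits,
                "vref": dt.vref,
                "n_samples": len(dt.codes),
            },
            indent=2,
        )
    )
    return path


def read_digital(path: str | Path) -> DigitalTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    codes = np.frombuffer(path.read_bytes(), dtype="<u2").copy()
    return DigitalTrace(codes, fs=meta["fs"], bits=meta["bits"], vref=meta["vref"])
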