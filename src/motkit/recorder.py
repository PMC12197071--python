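"""Host-side frame consumption and the on-disk recording format.

The host reassembles per-channel sample streams from the serial frame
stream and persists a session as one little-endian binary file of 16-bit
codes per channel plus a single JSON sidecar carrying the metadata the
format requires: a signal description, channel names, the per-channel
session QoS (lost-packet count), the sampling frequency and the ADC
resolution.  One file per channel — rather than an interleaved layout —
keeps partial sessions readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .central_hub import SerialFrame, decode_frame_stream
from .errors import CorruptFileError, SchemaError

__all__ = ["FORMAT_VERSION", "REQUIRED_META", "Recording", "assemble",
           "assemble_bytes", "write_recording", "read_recording"]

FORMAT_VERSION = 1

#: metadata fields every sidecar must carry
REQUIRED_META = (
    "description",
    "channel_names",
    "qos",
    "sampling_frequency_hz",
    "adc_bits",
)

_SIDECAR = "recording.json"


@dataclass
class Recording:
    """Per-channel digitized streams plus JSON-serializable metadata."""

    channels: dict[int, np.ndarray]
    meta: dict

    def __post_init__(self) -> None:
        self.channels = {
            int(ch): np.asarray(codes, dtype=np.uint16)
            for ch, codes in self.channels.items()
        }
        missing = [k for k in REQUIRED_META if k not in self.meta]
        if missing:
            raise SchemaError(f"metadata missing required fields: {missing}")
        bits = int(self.meta["adc_bits"])
        for ch, codes in self.channels.items():
            if len(codes) and codes.max() > 2**bits - 1:
                raise CorruptFileError(
                    f"channel {ch} holds codes above the {bits}-bit range"
                )

    @property
    def fs(self) -> float:
        return float(self.meta["sampling_frequency_hz"])

    @property
    def bits(self) -> int:
        return int(self.meta["adc_bits"])

    def qos(self) -> dict[int, int]:
        return {int(ch): int(v) for ch, v in self.meta["qos"].items()}


def assemble(
    frames: Iterable[SerialFrame],
    fs: float = 1000.0,
    bits: int = 12,
    description: str = "",
    extra_meta: dict | None = None,
) -> Recording:
    """Reassemble per-channel streams from a frame sequence.

    Payloads are concatenated in frame order per channel and the per-frame
    QoS snapshots are summed into the session lost-packet count.
    """
    streams: dict[int, list] = {}
    qos: dict[int, int] = {}
    for frame in frames:
        for ch, lost, codes in frame.entries:
            streams.setdefault(ch, []).append(np.asarray(codes, dtype=np.uint16))
            qos[ch] = qos.get(ch, 0) + lost
    channels = {
        ch: (np.concatenate(parts) if parts else np.empty(0, dtype=np.uint16))
        for ch, parts in sorted(streams.items())
    }
    meta = {
        "format_version": FORMAT_VERSION,
        "description": description,
        "channel_names": {str(ch): f"CH{ch}" for ch in channels},
        "qos": {str(ch): int(qos.get(ch, 0)) for ch in channels},
        "sampling_frequency_hz": fs,
        "adc_bits": bits,
    }
    if extra_meta:
        meta.update(extra_meta)
    return Recording(channels, meta)


def assemble_bytes(data: bytes, **kwargs) -> tuple[Recording, int]:
    """Reassemble a recording straight from a serial byte stream.

    Corrupted stretches are skipped via end-marker resynchronization —
    acquisition continues past a framing error — and the number of such
    events is returned alongside the recording.
    """
    frames, errors = decode_frame_stream(data)
    return assemble(frames, **kwargs), errors


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording directory: channel_<id>.bin files + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    for ch, codes in sorted(rec.channels.items()):
        name = f"channel_{ch}.bin"
        (path / name).write_bytes(codes.astype("<u2").tobytes())
        files[str(ch)] = name
    sidecar = dict(rec.meta)
    sidecar["files"] = files
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory; inverse of :func:`write_recording`.

    Raises
    ------
    SchemaError
        If the sidecar is missing a required metadata field.
    CorruptFileError
        If a binary stream's length is not a whole number of 16-bit codes
        or holds codes above the stated resolution.
    """
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise SchemaError(f"no {_SIDECAR} in {path}")
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise SchemaError(f"sidecar missing required fields: {missing}")
    files = meta.pop("files", None)
    if files is None:
        files = {
            p.stem.split("_", 1)[1]: p.name for p in sorted(path.glob("channel_*.bin"))
        }
    channels = {}
    for ch, name in files.items():
        raw = (path / name).read_bytes()
        if len(raw) % 2 != 0:
            raise CorruptFileError(f"{name}: length {len(raw)} is not a multiple of 2")
        channels[int(ch)] = np.frombuffer(raw, dtype="<u2").copy()
    return Recording(channels, meta)
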