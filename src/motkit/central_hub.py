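"""Central-hub logic: channel activity, queue synchronization, QoS, framing.

The hub receives packets from up to six sensor nodes, tracks which channels
are active (a channel that stays silent for 1 s is deactivated), counts lost
packets per channel from gaps in the packet counters,

    QoS = sum_k (cont[k] - cont[k-1] - 1),

synchronizes channels with one queue each, and emits serial frames towards
the host only when every active channel has a payload queued (a barrier, so
all channels advance in lock step).

Serial frame layout (repo convention; the original protocol defines the
fields but not the byte encoding):

    offset  size        field
    0       2           BpC: bytes per active channel (uint16 LE)
    2       1           N_C: number of active channels (uint8)
    3       N_C*(3+BpC) per channel: id (uint8), QoS snapshot (uint16 LE),
                        payload (BpC bytes of uint16-LE sample words)
    -2      2           end marker 0x55 0xAA

The QoS snapshot carried by a frame is the number of packets detected lost
immediately before the payload in that entry; the host reconstructs the
session total per channel by summation.
"""

from __future__ import annotations

import struct
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DuplicatePacketError,
    FramingError,
    MalformedFrameError,
)
from .transport import COUNTER_MOD, PACKET_SAMPLES, DeliveredPacket, SamplePacket
from .errors import ReorderingError

__all__ = [
    "END_MARKER",
    "DEFAULT_TIMEOUT",
    "ChannelState",
    "SerialFrame",
    "Hub",
    "qos_update",
    "encode_frame",
    "decode_frame",
    "decode_frame_stream",
]

END_MARKER = b"\x55\xaa"
DEFAULT_TIMEOUT = 1.0  # seconds of silence before a channel is deactivated
PAYLOAD_BYTES = 2 * PACKET_SAMPLES  # 240

_FRAME_HEADER = struct.Struct("<HB")
_ENTRY_HEADER = struct.Struct("<BH")


@dataclass
class ChannelState:
    """Per-channel bookkeeping held by the hub."""

    channel_id: int
    active: bool = False
    last_seen: float = -float("inf")
    last_counter: int | None = None
    qos_cum: int = 0  # running lost-packet total for the session

    def __post_init__(self) -> None:
        if not (1 <= self.channel_id <= 6):
            raise ValueError("channel_id must be in 1..6")


def qos_update(state: ChannelState, counter: int) -> int:
    """Fold one packet counter into a channel's lost-packet count.

    The first packet of a session initialises ``last_counter`` and adds
    nothing; thereafter the gap ``(counter - last_counter - 1) mod 2**32``
    is added to ``qos_cum``.  Returns the number of packets newly counted
    as lost.

    Raises
    ------
    DuplicatePacketError
        If the counter repeats the previous one (gap of -1).
    ReorderingError
        If the modular gap exceeds 2**31, i.e. the counter went backwards.
    """
    counter = int(counter) % COUNTER_MOD
    if state.last_counter is None:
        state.last_counter = counter
        return 0
    diff = (counter - state.last_counter) % COUNTER_MOD
    if diff == 0:
        raise DuplicatePacketError(
            f"channel {state.channel_id}: counter {counter} repeated"
        )
    if diff > 2**31:
        raise ReorderingError(
            f"channel {state.channel_id}: counter stepped back ({state.last_counter} -> {counter})"
        )
    lost = diff - 1
    state.qos_cum += lost
    state.last_counter = counter
    return lost


@dataclass(frozen=True)
class SerialFrame:
    """One hub->host message covering every active channel."""

    bpc: int
    n_c: int
    entries: tuple[tuple[int, int, tuple[int, ...]], ...]  # (id, qos, codes)

    def __post_init__(self) -> None:
        if len(self.entries) != self.n_c:
            raise ValueError("entries length must equal n_c")
        for ch, qos, codes in self.entries:
            if not (1 <= ch <= 6):
                raise ValueError("entry channel id must be in 1..6")
            if qos < 0:
                raise ValueError("QoS snapshot must be non-negative")
            if 2 * len(codes) != self.bpc:
                raise ValueError("payload length inconsistent with bpc")


class Hub:
    """Stateful hub: ingest packets, expire silent channels, emit frames.

    ``now`` is always an injected simulation clock so behaviour is
    deterministic; the hub never reads wall time.
    """

    def __init__(self, timeout: float = DEFAULT_TIMEOUT):
        self.timeout = timeout
        self.states: dict[int, ChannelState] = {}
        self.queues: dict[int, deque] = {}
        self.rejected: list[tuple[object, str]] = []

    # -- ingestion ----------------------------------------------------------

    def ingest(self, item: SamplePacket | DeliveredPacket, now: float) -> None:
        """Fold one received packet into the hub state.

        Marks the channel active, updates its QoS from the counter, and
        enqueues the payload together with the gap it revealed.  Malformed,
        duplicate or reordered packets are rejected and logged; the state is
        left unchanged.
        """
        packet = item.packet if isinstance(item, DeliveredPacket) else item
        if not isinstance(packet, SamplePacket):
            self.rejected.append((item, "not a packet"))
            return
        ch = packet.channel_id
        state = self.states.get(ch)
        if state is None:
            state = ChannelState(ch)
            self.states[ch] = state
            self.queues[ch] = deque()
        try:
            lost = qos_update(state, packet.counter)
        except (DuplicatePacketError, ReorderingError) as exc:
            self.rejected.append((item, str(exc)))
            return
        state.active = True
        state.last_seen = now
        self.queues[ch].append((packet.samples, lost))

    # -- activity -----------------------------------------------------------

    def expire(self, now: float, timeout: float | None = None) -> None:
        """Deactivate channels silent for longer than the timeout.

        Queues are retained; a channel that resumes sending reactivates and
        its pending payloads are framed again.
        """
        timeout = self.timeout if timeout is None else timeout
        for state in self.states.values():
            if state.active and now - state.last_seen > timeout:
                state.active = False

    def active_channels(self) -> list[int]:
        return sorted(ch for ch, s in self.states.items() if s.active)

    # -- framing ------------------------------------------------------------

    def build_frame(self, now: float | None = None) -> SerialFrame | None:
        """Emit one frame if every active channel has a payload queued.

        The synchronization barrier: if any active channel's queue is empty,
        nothing is emitted.  When ``now`` is given, an active channel whose
        queue is empty and which has been silent for longer than the timeout
        is expired first, so one stalled channel cannot block the others
        indefinitely (and queues cannot grow without bound).
        """
        if now is not None:
            stalled = [
                ch
                for ch in self.active_channels()
                if not self.queues[ch] and now - self.states[ch].last_seen > self.timeout
            ]
            for ch in stalled:
                self.states[ch].active = False
        active = self.active_channels()
        if not active:
            return None
        if any(not self.queues[ch] for ch in active):
            return None
        entries = []
        for ch in active:
            codes, lost = self.queues[ch].popleft()
            entries.append((ch, lost, codes))
        return SerialFrame(PAYLOAD_BYTES, len(active), tuple(entries))

    def flush(self) -> list[SerialFrame]:
        """Drain remaining queues at end of session.

        Channels are progressively dropped from the active set as their
        queues empty, so every ingested payload ends up in a frame.
        """
        frames = []
        while True:
            pending = sorted(ch for ch, q in self.queues.items() if q)
            if not pending:
                break
            entries = []
            for ch in pending:
                codes, lost = self.queues[ch].popleft()
                entries.append((ch, lost, codes))
            frames.append(SerialFrame(PAYLOAD_BYTES, len(pending), tuple(entries)))
        return frames

    def qos_totals(self) -> dict[int, int]:
        """Session lost-packet count per channel seen so far."""
        return {ch: s.qos_cum for ch, s in sorted(self.states.items())}


# ---------------------------------------------------------------------------
# frame codec


def encode_frame(f: SerialFrame) -> bytes:
    """Serialize a frame to the documented byte layout."""
    parts = [_FRAME_HEADER.pack(f.bpc, f.n_c)]
    for ch, qos, codes in f.entries:
        parts.append(_ENTRY_HEADER.pack(ch, min(qos, 0xFFFF)))
        parts.append(np.asarray(codes, dtype="<u2").tobytes())
    parts.append(END_MARKER)
    return b"".join(parts)


def frame_length(bpc: int, n_c: int) -> int:
    return _FRAME_HEADER.size + n_c * (_ENTRY_HEADER.size + bpc) + len(END_MARKER)


def decode_frame(data: bytes) -> SerialFrame:
    """Parse exactly one frame; inverse of :func:`encode_frame`.

    Raises
    ------
    MalformedFrameError
        If the length is inconsistent with the header or a field is invalid.
    FramingError
        If the end marker is absent where the header says the frame ends.
    """
    if len(data) < _FRAME_HEADER.size + len(END_MARKER):
        raise MalformedFrameError("frame shorter than header + end marker")
    bpc, n_c = _FRAME_HEADER.unpack_from(data, 0)
    if bpc % 2 != 0:
        raise MalformedFrameError(f"bpc={bpc} is not a whole number of sample words")
    if n_c > 6:
        raise MalformedFrameError(f"n_c={n_c} exceeds the six-channel design")
    expected = frame_length(bpc, n_c)
    if len(data) != expected:
        raise MalformedFrameError(
            f"frame length {len(data)} inconsistent with header (expected {expected})"
        )
    if data[-2:] != END_MARKER:
        raise FramingError("end marker missing")
    entries = []
    pos = _FRAME_HEADER.size
    for _ in range(n_c):
        ch, qos = _ENTRY_HEADER.unpack_from(data, pos)
        pos += _ENTRY_HEADER.size
        if not (1 <= ch <= 6):
            raise MalformedFrameError(f"entry channel id {ch} outside 1..6")
        codes = np.frombuffer(data, dtype="<u2", offset=pos, count=bpc // 2)
        if codes.max(initial=0) > 4095:
            raise MalformedFrameError("payload word exceeds 12-bit range")
        pos += bpc
        entries.append((ch, qos, tuple(int(c) for c in codes)))
    return SerialFrame(bpc, n_c, tuple(entries))


def decode_frame_stream(data: bytes) -> tuple[list[SerialFrame], int]:
    """Decode a concatenated frame stream, resynchronizing after corruption.

    On a parse failure the decoder skips to just past the next end-marker
    occurrence and tries again, so one corrupted frame costs at most the
    bytes up to the following marker.  Returns the recovered frames and the
    number of resynchronization events.
    """
    frames: list[SerialFrame] = []
    errors = 0
    pos = 0
    n = len(data)
    while pos < n:
        ok = False
        if pos + _FRAME_HEADER.size <= n:
            bpc, n_c = _FRAME_HEADER.unpack_from(data, pos)
            expected = frame_length(bpc, n_c)
            if pos + expected <= n:
                try:
                    frames.append(decode_frame(data[pos : pos + expected]))
                    pos += expected
                    ok = True
                except (MalformedFrameError, FramingError):
                    pass
        if not ok:
            errors += 1
            idx = data.find(END_MARKER, pos + 1)
            if idx < 0:
                break
            pos = idx + len(END_MARKER)
    return frames, errors
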