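"""Node-to-hub wire format and a seeded lossy-link simulator.

Each sensor node blocks its ADC codes into 120-sample packets carrying a
channel identifier (1-6) and an incrementing 32-bit counter, the basis of
the hub's lost-packet accounting.  The byte layout is a repo convention
(the real radio protocol only bounds messages at 250 bytes):

    offset  size  field
    0       1     channel_id (uint8, 1..6)
    1       4     counter (uint32, little-endian, wraps at 2**32)
    5       240   120 sample words (uint16 little-endian, 12-bit value
                  in the low bits)
    -- total 245 bytes, under the 250-byte radio bound --

The link simulator stands in for the 2.45 GHz broadcast radio: per-packet
drops from a two-state Gilbert-Elliott chain (degenerate, i.i.d., by
default), optional distance-driven loss through a monotone logistic curve,
and sampled delivery latency.  Every drop is logged so downstream QoS
accounting can be checked against ground truth.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import MalformedPacketError

__all__ = [
    "PACKET_SAMPLES",
    "PACKET_BYTES",
    "COUNTER_MOD",
    "SamplePacket",
    "LinkParams",
    "DeliveredPacket",
    "TransmissionResult",
    "packetize",
    "encode_packet",
    "decode_packet",
    "transmit",
    "loss_from_distance",
]

PACKET_SAMPLES = 120
PACKET_BYTES = 1 + 4 + 2 * PACKET_SAMPLES  # 245, under the 250-byte bound
MAX_MESSAGE_BYTES = 250
COUNTER_MOD = 2**32

_HEADER = struct.Struct("<BI")


@dataclass(frozen=True)
class SamplePacket:
    """One node->hub message: channel id, counter, 120 ADC codes."""

    channel_id: int
    counter: int
    samples: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counter", int(self.counter) % COUNTER_MOD)
        object.__setattr__(self, "samples", tuple(int(s) for s in self.samples))
        if not (1 <= self.channel_id <= 6):
            raise ValueError("channel_id must be in 1..6")
        if len(self.samples) != PACKET_SAMPLES:
            raise ValueError(f"packet must carry exactly {PACKET_SAMPLES} samples")
        if any(not (0 <= s <= 4095) for s in self.samples):
            raise ValueError("samples must be 12-bit codes in [0, 4095]")


def packetize(
    channel_id: int, codes: Sequence[int] | np.ndarray, start_counter: int = 0
) -> list[SamplePacket]:
    """Block a code stream into consecutive 120-sample packets.

    Counters run consecutively from ``start_counter`` (mod 2**32).  A final
    partial block is withheld, mirroring a node that only transmits full
    buffers.
    """
    if not (1 <= channel_id <= 6):
        raise ValueError("channel_id must be in 1..6")
    codes = np.asarray(codes)
    n_full = len(codes) // PACKET_SAMPLES
    packets = []
    for i in range(n_full):
        block = codes[i * PACKET_SAMPLES : (i + 1) * PACKET_SAMPLES]
        packets.append(
            SamplePacket(channel_id, (start_counter + i) % COUNTER_MOD, tuple(int(c) for c in block))
        )
    return packets


def encode_packet(p: SamplePacket) -> bytes:
    """Serialize a packet to its fixed 245-byte layout."""
    payload = np.asarray(p.samples, dtype="<u2").tobytes()
    return _HEADER.pack(p.channel_id, p.counter) + payload


def decode_packet(data: bytes) -> SamplePacket:
    """Parse a 245-byte message; inverse of :func:`encode_packet`.

    Raises
    ------
    MalformedPacketError
        On wrong length, channel id outside 1..6, or a sample word whose
        value exceeds the 12-bit range.
    """
    if len(data) != PACKET_BYTES:
        raise MalformedPacketError(
            f"expected {PACKET_BYTES} bytes, got {len(data)}"
        )
    channel_id, counter = _HEADER.unpack_from(data, 0)
    if not (1 <= channel_id <= 6):
        raise MalformedPacketError(f"channel_id {channel_id} outside 1..6")
    samples = np.frombuffer(data, dtype="<u2", offset=_HEADER.size)
    if samples.max(initial=0) > 4095:
        raise MalformedPacketError("sample word exceeds 12-bit range")
    return SamplePacket(channel_id, counter, tuple(int(s) for s in samples))


# ---------------------------------------------------------------------------
# lossy link


def loss_from_distance(
    distance: float,
    max_loss: float = 0.01,
    d50: float = 70.0,
    width: float = 15.0,
) -> float:
    """Monotone logistic distance -> per-packet loss probability.

    Purely a simulation knob standing in for real propagation: loss rises
    smoothly from ~0 near the hub towards ``max_loss`` beyond ``d50`` metres.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return max_loss / (1.0 + np.exp(-(distance - d50) / width))


@dataclass(frozen=True)
class LinkParams:
    """Lossy-link configuration.

    Either set ``loss_prob`` directly or give a ``distance`` in metres, which
    is mapped through :func:`loss_from_distance`.  Burst losses use a
    two-state Gilbert-Elliott chain: in the bad state packets drop with
    ``loss_prob_bad``; the default transition probabilities make the chain
    degenerate (i.i.d. drops at ``loss_prob``).
    """

    loss_prob: float = 0.0
    distance: float | None = None
    p_good_to_bad: float = 0.0
    p_bad_to_good: float = 1.0
    loss_prob_bad: float = 1.0
    latency_mean: float = 0.002
    latency_jitter: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_prob", "p_good_to_bad", "p_bad_to_good", "loss_prob_bad"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.latency_mean < 0 or self.latency_jitter < 0:
            raise ValueError("latencies must be non-negative")

    @property
    def effective_loss_prob(self) -> float:
        """Good-state drop probability, from distance when given."""
        if self.distance is not None:
            return float(loss_from_distance(self.distance))
        return self.loss_prob


@dataclass(frozen=True)
class DeliveredPacket:
    """A packet that made it across the link, with its timestamps."""

    packet: SamplePacket
    send_time: float
    recv_time: float

    def __post_init__(self) -> None:
        if self.recv_time < self.send_time:
            raise ValueError("recv_time must be >= send_time")


@dataclass
class TransmissionResult:
    """Outcome of a simulated session.

    ``delivered`` preserves per-channel send order; ``drop_log`` records every
    dropped counter so that delivered + dropped = sent, exactly, per channel.
    """

    delivered: dict[int, list[DeliveredPacket]]
    drop_log: dict[int, list[int]]
    sent: dict[int, int]

    def dropped_counts(self) -> dict[int, int]:
        """All drops per channel (ground truth, includes trailing drops)."""
        return {ch: len(v) for ch, v in self.drop_log.items()}

    def observable_losses(self) -> dict[int, int]:
        """Drops detectable by counter-gap accounting.

        A drop is observable only if it sits between two delivered packets
        of its channel: packets lost before the first delivery or after the
        final one leave no counter gap for the hub to see.
        """
        out: dict[int, int] = {}
        for ch, drops in self.drop_log.items():
            delivered = self.delivered.get(ch, [])
            if not delivered:
                out[ch] = 0
                continue
            first = delivered[0].packet.counter
            last = delivered[-1].packet.counter
            out[ch] = sum(1 for c in drops if first < c < last)
        return out


def transmit(
    packets_by_channel: Mapping[int, Sequence[SamplePacket]],
    link: LinkParams,
    period: float = 0.120,
) -> TransmissionResult:
    """Simulate one session over the lossy link.

    Packets of each channel are sent every ``period`` seconds (120 samples at
    1 kS/s -> 0.120 s).  Each is dropped or delivered according to the
    Gilbert-Elliott chain; delivered packets receive
    ``send_time + max(0, N(latency_mean, latency_jitter))`` arrival times,
    nudged to be non-decreasing per channel so in-order delivery holds.
    Deterministic for a fixed ``link.seed``.
    """
    rng = np.random.default_rng(link.seed)
    p_loss_good = link.effective_loss_prob
    delivered: dict[int, list[DeliveredPacket]] = {}
    drop_log: dict[int, list[int]] = {}
    sent: dict[int, int] = {}
    for ch in sorted(packets_by_channel):
        packets = packets_by_channel[ch]
        delivered[ch] = []
        drop_log[ch] = []
        sent[ch] = len(packets)
        bad = False
        prev_recv = -np.inf
        for i, p in enumerate(packets):
            if p.channel_id != ch:
                raise ValueError("packet channel_id does not match its stream")
            # state transition, then loss draw in the current state
            if bad:
                if rng.random() < link.p_bad_to_good:
                    bad = False
            else:
                if rng.random() < link.p_good_to_bad:
                    bad = True
            p_loss = link.loss_prob_bad if bad else p_loss_good
            send_time = i * period
            if rng.random() < p_loss:
                drop_log[ch].append(p.counter)
                continue
            latency = max(
                0.0, link.latency_mean + link.latency_jitter * rng.standard_normal()
            )
            recv = max(send_time + latency, prev_recv + 1e-9)
            prev_recv = recv
            delivered[ch].append(DeliveredPacket(p, send_time, recv))
    return TransmissionResult(delivered, drop_log, sent)
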