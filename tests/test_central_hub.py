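"""Hub logic: QoS accounting, activity, queue barrier, frame codec."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motkit import (
    ChannelState,
    Hub,
    SamplePacket,
    SerialFrame,
    decode_frame,
    decode_frame_stream,
    encode_frame,
    qos_update,
)
from motkit.central_hub import END_MARKER, PAYLOAD_BYTES
from motkit.errors import (
    DuplicatePacketError,
    FramingError,
    MalformedFrameError,
    ReorderingError,
)
from motkit.transport import COUNTER_MOD


def packet(ch=1, counter=0, fill=0):
    return SamplePacket(ch, counter, tuple([fill] * 120))


class TestQosUpdate:
    def test_consecutive_counters_add_nothing(self):
        s = ChannelState(1)
        assert qos_update(s, 5) == 0  # first packet initializes
        assert qos_update(s, 6) == 0
        assert s.qos_cum == 0

    def test_gap_counts_lost_packets(self):
        s = ChannelState(1)
        qos_update(s, 5)
        assert qos_update(s, 9) == 3
        assert s.qos_cum == 3

    def test_gap_across_counter_wraparound(self):
        s = ChannelState(1)
        qos_update(s, COUNTER_MOD - 2)
        assert qos_update(s, 1) == 2  # lost: 2**32-1 and 0
        assert s.qos_cum == 2

    def test_duplicate_counter_raises(self):
        s = ChannelState(1)
        qos_update(s, 5)
        with pytest.raises(DuplicatePacketError):
            qos_update(s, 5)

    def test_backwards_counter_raises_reordering(self):
        s = ChannelState(1)
        qos_update(s, 100)
        with pytest.raises(ReorderingError):
            qos_update(s, 50)

    def test_seeded_drop_session_sums_exactly(self):
        # 1000 counters with 75 removed: session QoS equals the removal count
        rng = np.random.default_rng(0)
        dropped = set(rng.choice(np.arange(1, 999), size=75, replace=False))
        s = ChannelState(2)
        for c in range(1000):
            if c not in dropped:
                qos_update(s, c)
        assert s.qos_cum == 75


class TestIngestAndActivity:
    def test_first_packet_activates_channel(self):
        hub = Hub()
        hub.ingest(packet(ch=3), now=0.0)
        assert hub.states[3].active
        assert hub.active_channels() == [3]

    def test_payloads_queue_up(self):
        hub = Hub()
        hub.ingest(packet(counter=0), now=0.0)
        hub.ingest(packet(counter=1), now=0.1)
        assert len(hub.queues[1]) == 2

    def test_invalid_channel_rejected_without_state_change(self):
        hub = Hub()
        with pytest.raises(ValueError):
            packet(ch=7)
        hub.ingest("garbage", now=0.0)
        assert hub.states == {}
        assert len(hub.rejected) == 1

    def test_duplicate_packet_rejected_logged(self):
        hub = Hub()
        hub.ingest(packet(counter=4), now=0.0)
        hub.ingest(packet(counter=4), now=0.1)
        assert len(hub.rejected) == 1
        assert len(hub.queues[1]) == 1

    def test_silent_channel_deactivates_after_timeout(self):
        hub = Hub(timeout=1.0)
        hub.ingest(packet(ch=1), now=0.0)
        hub.ingest(packet(ch=2), now=1.0)
        hub.expire(now=1.5)
        assert not hub.states[1].active  # silent for 1.5 s > 1 s
        assert hub.states[2].active  # silent for only 0.5 s

    def test_half_second_silence_keeps_channel_active(self):
        hub = Hub()
        hub.ingest(packet(), now=0.0)
        hub.expire(now=0.5)
        assert hub.states[1].active

    def test_infinite_timeout_never_deactivates(self):
        hub = Hub(timeout=float("inf"))
        hub.ingest(packet(), now=0.0)
        hub.expire(now=1e9)
        assert hub.states[1].active


class TestFrameBarrier:
    def test_frame_emitted_when_all_active_queues_filled(self):
        hub = Hub()
        hub.ingest(packet(ch=1, fill=10), now=0.0)
        hub.ingest(packet(ch=2, fill=20), now=0.0)
        frame = hub.build_frame()
        assert frame is not None
        assert frame.n_c == 2
        assert [e[0] for e in frame.entries] == [1, 2]

    def test_no_active_channels_no_frame(self):
        assert Hub().build_frame() is None

    def test_barrier_holds_when_one_queue_empty(self):
        hub = Hub()
        for i in range(3):
            hub.ingest(packet(ch=1, counter=i), now=0.0)
        hub.ingest(packet(ch=2, counter=0), now=0.0)
        hub.ingest(packet(ch=3, counter=0), now=0.0)
        frames = []
        while (f := hub.build_frame()) is not None:
            frames.append(f)
        # frames emitted = min over active channels of queued payload counts
        assert len(frames) == 1
        assert len(hub.queues[1]) == 2

    def test_stalled_channel_expired_before_framing(self):
        hub = Hub(timeout=1.0)
        hub.ingest(packet(ch=1, counter=0), now=0.0)
        hub.ingest(packet(ch=2, counter=0), now=0.0)
        assert hub.build_frame() is not None
        # channel 2 goes silent while channel 1 keeps streaming
        hub.ingest(packet(ch=1, counter=1), now=2.0)
        frame = hub.build_frame(now=2.0)
        assert frame is not None and frame.n_c == 1
        assert not hub.states[2].active

    def test_flush_drains_unbalanced_queues(self):
        hub = Hub()
        for i in range(3):
            hub.ingest(packet(ch=1, counter=i), now=0.0)
        hub.ingest(packet(ch=2, counter=0), now=0.0)
        frames = hub.flush()
        assert [f.n_c for f in frames] == [2, 1, 1]
        assert all(len(q) == 0 for q in hub.queues.values())


frames_strategy = st.integers(1, 6).flatmap(
    lambda n: st.builds(
        lambda ids, qos, payloads: SerialFrame(
            PAYLOAD_BYTES,
            n,
            tuple((i, q, p) for i, q, p in zip(ids, qos, payloads)),
        ),
        ids=st.permutations(list(range(1, 7))).map(lambda l: sorted(l[:n])),
        qos=st.lists(st.integers(0, 65535), min_size=n, max_size=n),
        payloads=st.lists(
            st.lists(st.integers(0, 4095), min_size=120, max_size=120).map(tuple),
            min_size=n,
            max_size=n,
        ),
    )
)


class TestFrameCodec:
    @settings(derandomize=True, max_examples=30)
    @given(frames_strategy)
    def test_round_trip_identity(self, frame):
        assert decode_frame(encode_frame(frame)) == frame

    def test_layout_ends_with_marker(self):
        frame = SerialFrame(PAYLOAD_BYTES, 1, ((1, 0, tuple([0] * 120)),))
        raw = encode_frame(frame)
        assert raw[-2:] == END_MARKER
        assert raw.count(END_MARKER) >= 1
        assert len(raw) == 3 + 1 * (3 + PAYLOAD_BYTES) + 2

    def test_header_entry_mismatch_is_malformed(self):
        with pytest.raises(ValueError):
            SerialFrame(PAYLOAD_BYTES, 6, ((1, 0, tuple([0] * 120)),) * 5)
        # encoded stream claiming 2 entries but carrying 1
        frame = SerialFrame(PAYLOAD_BYTES, 1, ((1, 0, tuple([0] * 120)),))
        raw = bytearray(encode_frame(frame))
        raw[2] = 2
        with pytest.raises(MalformedFrameError):
            decode_frame(bytes(raw))

    def test_missing_end_marker_is_framing_error(self):
        frame = SerialFrame(PAYLOAD_BYTES, 1, ((1, 0, tuple([0] * 120)),))
        raw = bytearray(encode_frame(frame))
        raw[-2:] = b"\x00\x00"
        with pytest.raises(FramingError):
            decode_frame(bytes(raw))

    def test_stream_decoder_resynchronizes_after_corruption(self):
        good = SerialFrame(PAYLOAD_BYTES, 2, ((1, 3, tuple([7] * 120)), (2, 0, tuple([9] * 120))))
        raw_good = encode_frame(good)
        corrupted = bytearray(raw_good)
        corrupted[0] ^= 0xFF  # wreck the header of the first frame
        stream = bytes(corrupted) + raw_good
        frames, errors = decode_frame_stream(stream)
        assert frames == [good]
        assert errors >= 1

    def test_clean_stream_decodes_fully(self):
        frames_in = [
            SerialFrame(PAYLOAD_BYTES, 1, ((ch, ch, tuple([ch] * 120)),))
            for ch in (1, 2, 3)
        ]
        data = b"".join(encode_frame(f) for f in frames_in)
        frames_out, errors = decode_frame_stream(data)
        assert frames_out == frames_in
        assert errors == 0
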