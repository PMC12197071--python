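# Methods

This note documents the models behind `motkit`, the defaults and why they
were chosen, the numerical choices, and what the simulations do and do not
establish about real hardware.

## Synthetic sEMG process

Surface EMG is modelled as amplitude-modulated shaped noise: white Gaussian
noise is multiplied in the frequency domain by the square root of

    S(f) ∝ f² f_h⁴ / ((f² + f_l²)(f² + f_h²)²),

a classical rational sEMG spectrum shape, hard-limited to the 20–500 Hz
passband, normalised to unit RMS, then multiplied in the time domain by
`rms_rest + (rms_max − rms_rest)·e(t)` with a piecewise-linear envelope
`e(t) ∈ [0, 1]`. With `f_l = 60 Hz`, `f_h = 120 Hz` the spectrum peaks
below 100 Hz; 93 % of the power of a default trace lies in 20–250 Hz
(periodogram estimate, pinned in the unit tests), matching the stylised
fact that sEMG energy concentrates below ~250 Hz.

Defaults and rationale:

* `rms_rest = 2 µV`, `rms_max = 200 µV`. Physiological sEMG spans µV to
  ~10 mV, but the front-end's total gain of 927 V/V and 0–3.3 V rails bound
  the largest undistorted input at roughly ±1.7 mV peak (~0.5 mV RMS); 200 µV
  RMS at full contraction keeps ±3σ excursions comfortably inside the rails,
  which is how such hardware is operated in practice. Both values are
  conventions, not reproductions of any particular subject.
* `fs_sim = 10 kHz`: the analog chain is emulated well above the 1 kS/s
  acquisition rate so the 500 Hz stage and the decimating quantizer behave
  like their continuous-time counterparts. Chain-consistency tests use
  20 kHz, where bilinear frequency-axis warping at 1 kHz is ≤1.6 %.
* One RNG per generated trace, seeded from the spec; session orchestration
  derives per-channel seeds from the session seed and records them in the
  recording metadata for replay.

The generator does **not** model motor-unit action-potential trains,
electrode–skin impedance, inter-electrode correlation, or fatigue-related
spectral compression. Tests passing on this process therefore certify the
*signal path* (filtering, quantization, telemetry, bookkeeping), not
physiological fidelity.

Disturbance injectors are additive and order-preserving: mains interference
is a sum of sinusoids accumulated one term at a time (so sequential and
combined calls are bit-identical — the linearity property is exact, not
approximate); motion artifact is band-limited noise below the high-pass
corner plus Hann-windowed broadband bursts at given impact times.

## Analog front-end

The chain is gain 100 → HP(20 Hz, two cascaded identical first-order
sections) → LP(500 Hz, second order, gain 9.27, Q configurable, default
1/√2) → +1.65 V offset → clip to [0, 3.3] V.

* **High-pass topology.** Two cascaded real poles are fixed by design: that
  topology's half-power point for corner f_c is f_c·√(1/(√2−1)), i.e.
  31.08 Hz for 20 Hz — the designed low cutoff of this class of front-end.
* **Low-pass Q exposed.** Measured units of such hardware show mild peaking
  before roll-off, which depends on unpublished component values; rather
  than hard-coding a resonance the Q is a parameter with a Butterworth
  default.
* **Cutoff extraction.** `extract_cutoffs` finds the frequencies 3 dB
  (10·log₁₀ 2) below the curve maximum by linear interpolation of dB against
  log-frequency between bracketing grid points; the default grid has 300
  points/decade. The estimate is invariant to constant dB offsets.
  Note a subtlety: on the *full* chain the 500 Hz stage pulls the curve
  maximum ~0.18 dB below the mid-band asymptote, which moves the
  −3 dB-from-max low cutoff to ≈30.0 Hz; the 31.1 Hz design value is the
  property of the high-pass stage alone, so stage-wise responses
  (`highpass_response`, `lowpass_response`) are provided and used wherever a
  corner is attributed to its stage.
* **Discretization.** Each section is mapped by the bilinear transform with
  its corner prewarped (`ω = 2 f_s tan(π f_c/f_s)`), so digital corners land
  exactly on the analog ones. Steady-state assertions discard the first half
  of a one-second record, far beyond five time constants of the slowest
  (20 Hz) pole. Zero input produces exactly the offset voltage.
* **Tolerance Monte Carlo.** Every first-order section owns one RC pair;
  the second-order low-pass owns two, its natural frequency scaling as the
  inverse square root of the product of the four component factors. Per
  draw, δR ~ U(±1 %) and δC ~ U(±10 %) scale each corner by
  1/((1+δR)(1+δC)) — capacitors at the −10 % edge alone give the 1/0.9 ≈ 1.11
  corner factor. The low cutoff is extracted from the perturbed high-pass
  stage and the high cutoff from the perturbed low-pass stage (stage-wise
  attribution): a full-chain "−3 dB from max" reference would couple the
  low-pass draw into the low cutoff and break the clean interval-arithmetic
  bound [1/(1.1·1.01), 1/(0.9·0.99)] that the draws provably satisfy.
* **Quantizer.** Truncating mid-tread ADC, `⌊v/v_ref·2^bits⌋` clamped to
  [0, 2^bits−1]; decimation picks every k-th sample and requires an integer
  rate ratio (the 500 Hz analog stage is the anti-alias filter).
  Reconstruction `(code+0.5)·v_ref/2^bits` is within half an LSB for
  in-range inputs.

## Telemetry and hub

* **Packet layout** (repo convention; the radio protocol itself only bounds
  messages at 250 bytes): uint8 channel id ∈ 1..6, uint32-LE counter
  (wraps at 2³²), 120 uint16-LE sample words with the 12-bit code in the low
  bits — 245 bytes. 12-bit bit-packing was rejected for inspectability.
* **Link model.** Two-state Gilbert–Elliott drops (degenerate/i.i.d. by
  default — field reports of loss concentrating on one channel motivate
  keeping the burst machinery available), optional logistic distance→loss
  curve (a pure simulation knob), Gaussian latency with per-channel
  non-decreasing arrival times. Every drop is logged, so
  delivered + dropped = sent holds exactly.
* **QoS accounting.** Counter gaps `(cont[k] − cont[k−1] − 1) mod 2³²`
  accumulate per channel; a zero gap is a duplicate error, a gap above 2³¹
  a reordering error. The metric is *structurally blind* to packets lost
  before a channel's first delivered packet or after its last one (no
  bracketing counters exist), so ground-truth comparisons use the
  *observable* drop count — drops strictly between the first and last
  delivered counters — for which hub QoS is exact for every seed.
* **Queue barrier.** One queue per channel; a frame pops one payload from
  every active channel or nothing at all. Channels silent for over 1 s are
  deactivated (queues retained); a stalled-but-active channel blocking the
  barrier beyond the timeout is expired first, preventing unbounded queue
  growth. Frame building is serviced on a 20 ms tick, emulating the
  periodic serial task of such firmware; without the tick, per-packet
  servicing at cold start would emit a one-channel frame before the other
  channels' first packets (a few ms later) arrive. End-of-session `flush`
  drains unbalanced queues so every ingested payload is framed.
* **Frame layout**: uint16-LE bytes-per-channel, uint8 active-channel
  count, then per channel uint8 id, uint16-LE QoS snapshot (losses detected
  since that channel's previous frame), payload; trailer `0x55 0xAA`. The
  end marker is a repo convention chosen for resynchronization: the stream
  decoder skips to just past the next marker after a parse failure, so one
  corrupted frame costs at most the bytes up to the following marker.
  (Payload bytes may contain the marker; resynchronization is best-effort
  and is exercised with header-level corruption.)
* **Recording format**: one `<u2` binary file per channel plus a versioned
  JSON sidecar with description, channel names, per-channel session QoS,
  sampling frequency, and ADC resolution. Per-channel files keep partial
  sessions readable.

## Evaluation methodology

* **Spectra**: Welch averaged periodograms, Hann window, 50 % overlap,
  default 1024-sample segments (512 at 1 kS/s for the interference metric,
  trading resolution for ~30 averages on an 8 s record), density scaling,
  no detrending; the integrated one-sided PSD matches the signal variance
  within 1 % at this averaging depth.
* **Interference margin** (`mains_delta`): dB difference between the
  contraction and rest spectra at the grid bin nearest 60 Hz, no
  interpolation. The designed-recovery experiment holds the envelope at 0
  (rest) and 1 (contraction) with contraction RMS 100× rest, so the designed
  margin is exactly 40 dB at every in-band bin; a single-seed Welch estimate
  scatters with ≈1.3 dB SD, and the 20-seed mean recovers the design within
  ±1 dB. Shared low-level 60 Hz pickup cancels in the difference.
* **QoS sweep**: full link simulation per (distance, channel-count) cell,
  0–100 m in 10 m steps × 1–6 channels by default; totals equal the drop
  logs by construction.
* **Timing raster**: arrival times re-referenced to each channel's first
  message; a lossless 120-sample / 1 kS/s stream has a 0.120 s modal
  inter-arrival, one dropped packet doubles a single interval.
* **Power budget**: autonomy = capacity/draw; 180 mAh at 100 mA gives 1.8 h.
* **End-to-end sessions** for the bookkeeping guarantee run at desk scale:
  1.2 s × 1–6 channels × 100 seeds (10 packets per channel each), with
  losses drawn from 0–20 %. A lossless session's recording is bit-identical
  to the quantizer output up to the packetization floor (trailing partial
  blocks are never transmitted).

## Known limitations

* No SPICE-level front-end effects (slew rate, CMRR vs frequency, input
  impedance, component-value-specific peaking); measured hardware corners
  (e.g. a 19 Hz / 690 Hz unit) are hardware properties outside this model.
* The distance→loss curve is not a propagation model; field packet-loss
  figures are not claimed reproducible.
* Counter width, byte packings, the QoS field scope and the end-marker
  value are documented conventions where the original protocol leaves them
  unspecified.
* Real-time concerns (UART timing at 921,600 baud, task scheduling) are
  recorded as metadata only.
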