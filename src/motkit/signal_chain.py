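"""Parametric model of the sensor node's analog front-end and digitizer.

The front-end is an AD8232-style biopotential chain:

* instrumentation amplifier, fixed gain 100 V/V;
* second-order high-pass at 20 Hz, realised as two cascaded identical
  first-order real-pole sections (the AD8232 DC-blocking architecture) —
  this is the only topology whose -3 dB-from-passband point lands at
  20 * sqrt(1/(sqrt(2)-1)) ~ 31.1 Hz for a 20 Hz design value;
* second-order low-pass at 500 Hz with gain 9.27 and configurable quality
  factor (default Butterworth, Q = 1/sqrt(2));
* a DC offset of half the 3.3 V supply so the bipolar biopotential fits a
  unipolar ADC input, hard-clipped at the supply rails;
* a 12-bit SAR ADC sampling at 1 kS/s over a 3.3 V reference.

Small-signal frequency responses are evaluated analytically; time-domain
conditioning discretises each section with the bilinear transform, corner
frequencies prewarped so the digital corners land exactly on the analog ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import MotkitError

__all__ = [
    "ChainParams",
    "FrequencyResponse",
    "ToleranceSpec",
    "ToleranceResult",
    "DigitalTrace",
    "frequency_response",
    "highpass_response",
    "lowpass_response",
    "extract_cutoffs",
    "apply_chain",
    "tolerance_monte_carlo",
    "corner_scale",
    "quantize",
    "default_freq_grid",
]

#: -3 dB in the half-power sense, 10*log10(2)
_HALF_POWER_DB = 10.0 * math.log10(2.0)


@dataclass(frozen=True)
class ChainParams:
    """Component-level description of the analog chain.

    All gains in V/V, corners in Hz, voltages in volts.
    """

    ia_gain: float = 100.0
    hp_fc: float = 20.0
    lp_fc: float = 500.0
    lp_gain: float = 9.27
    lp_q: float = 1.0 / math.sqrt(2.0)
    v_offset: float = 1.65
    v_rail_lo: float = 0.0
    v_rail_hi: float = 3.3

    def __post_init__(self) -> None:
        if self.ia_gain <= 0 or self.lp_gain <= 0:
            raise ValueError("gains must be positive")
        if not (0 < self.hp_fc < self.lp_fc):
            raise ValueError("need 0 < hp_fc < lp_fc")
        if self.lp_q <= 0:
            raise ValueError("lp_q must be positive")
        if not (self.v_rail_lo < self.v_offset < self.v_rail_hi):
            raise ValueError("v_offset must lie strictly between the rails")

    @property
    def midband_gain(self) -> float:
        """Product of the stage gains (V/V)."""
        return self.ia_gain * self.lp_gain

    @property
    def midband_gain_db(self) -> float:
        return 20.0 * math.log10(self.midband_gain)


@dataclass(frozen=True)
class FrequencyResponse:
    """Magnitude response sampled on a frequency grid."""

    freqs: np.ndarray
    magnitude_db: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        mags = np.asarray(self.magnitude_db, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "magnitude_db", mags)
        if freqs.shape != mags.shape or freqs.ndim != 1:
            raise ValueError("freqs and magnitude_db must be 1-D of equal length")
        if len(freqs) and (freqs[0] <= 0 or np.any(np.diff(freqs) <= 0)):
            raise ValueError("freqs must be strictly increasing and positive")


@dataclass(frozen=True)
class ToleranceSpec:
    """Component tolerance model: 1% resistors, 10% capacitors by default."""

    r_tol: float = 0.01
    c_tol: float = 0.10
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_tol < 0.5 and 0.0 <= self.c_tol < 0.5):
            raise ValueError("tolerances must lie in [0, 0.5)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class ToleranceResult:
    """Per-draw extracted cutoff frequencies (Hz)."""

    f_low: np.ndarray
    f_high: np.ndarray
    nominal_f_low: float
    nominal_f_high: float


@dataclass(frozen=True)
class DigitalTrace:
    """ADC output: integer codes at the acquisition rate."""

    codes: np.ndarray
    fs: float = 1000.0
    bits: int = 12
    vref: float = 3.3

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if not np.issubdtype(codes.dtype, np.integer):
            codes = codes.astype(np.uint16)
        object.__setattr__(self, "codes", codes)
        if len(codes) and (codes.min() < 0 or codes.max() > 2**self.bits - 1):
            raise ValueError(f"codes must lie in [0, {2**self.bits - 1}]")

    def to_volts(self) -> np.ndarray:
        """Mid-tread reconstruction ``(code + 0.5) * vref / 2**bits``."""
        return (self.codes.astype(np.float64) + 0.5) * self.vref / 2**self.bits


# ---------------------------------------------------------------------------
# analytic small-signal response


def _complex_response(
    freqs: np.ndarray,
    hp_fcs: Sequence[float],
    lp_fc: float | None,
    lp_q: float,
    gain: float,
) -> np.ndarray:
    f = np.asarray(freqs, dtype=np.float64)
    h = np.full(f.shape, gain, dtype=np.complex128)
    for fc in hp_fcs:
        jr = 1j * f / fc
        h *= jr / (1.0 + jr)
    if lp_fc is not None:
        r = f / lp_fc
        h /= 1.0 - r**2 + 1j * r / lp_q
    return h


def default_freq_grid(
    fmin: float = 1.0, fmax: float = 10_000.0, points_per_decade: int = 300
) -> np.ndarray:
    """Logarithmic frequency grid dense enough for cutoff extraction."""
    decades = math.log10(fmax / fmin)
    n = max(2, int(round(decades * points_per_decade)) + 1)
    return np.logspace(math.log10(fmin), math.log10(fmax), n)


def _validate_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    return freqs


def frequency_response(
    params: ChainParams, freqs: np.ndarray | None = None
) -> FrequencyResponse:
    """Small-signal magnitude of the full chain (offset and rails ignored)."""
    if freqs is None:
        freqs = default_freq_grid()
    freqs = _validate_freqs(freqs)
    h = _complex_response(
        freqs,
        hp_fcs=(params.hp_fc, params.hp_fc),
        lp_fc=params.lp_fc,
        lp_q=params.lp_q,
        gain=params.ia_gain * params.lp_gain,
    )
    return FrequencyResponse(freqs, 20.0 * np.log10(np.abs(h)))


def highpass_response(
    params: ChainParams, freqs: np.ndarray | None = None
) -> FrequencyResponse:
    """Magnitude of the high-pass stage alone (two cascaded sections, unity
    passband gain).  Useful for attributing the low cutoff to its stage."""
    if freqs is None:
        freqs = default_freq_grid()
    freqs = _validate_freqs(freqs)
    h = _complex_response(freqs, (params.hp_fc, params.hp_fc), None, 1.0, 1.0)
    return FrequencyResponse(freqs, 20.0 * np.log10(np.abs(h)))


def lowpass_response(
    params: ChainParams, freqs: np.ndarray | None = None
) -> FrequencyResponse:
    """Magnitude of the second-order low-pass stage alone (gain included)."""
    if freqs is None:
        freqs = default_freq_grid()
    freqs = _validate_freqs(freqs)
    h = _complex_response(freqs, (), params.lp_fc, params.lp_q, params.lp_gain)
    return FrequencyResponse(freqs, 20.0 * np.log10(np.abs(h)))


def extract_cutoffs(fr: FrequencyResponse) -> tuple[float, float]:
    """Locate the half-power (-3 dB from maximum) corner frequencies.

    Returns ``(f_low, f_high)``; a side on which the response never falls
    3 dB below the maximum is reported as ``nan``.  Crossings are located by
    linear interpolation of dB versus log-frequency between the bracketing
    grid points, so the grid should be dense (>= 200 points per decade) near
    the corners.
    """
    mags = fr.magnitude_db
    freqs = fr.freqs
    if len(freqs) < 2:
        raise ValueError("response grid too short")
    peak_idx = int(np.argmax(mags))
    target = mags[peak_idx] - _HALF_POWER_DB

    logf = np.log10(freqs)

    def _interp(i_out: int, i_in: int) -> float:
        # linear in (log f, dB) between the outside and inside points
        m0, m1 = mags[i_out], mags[i_in]
        if m1 == m0:
            return float(freqs[i_in])
        frac = (target - m0) / (m1 - m0)
        return float(10.0 ** (logf[i_out] + frac * (logf[i_in] - logf[i_out])))

    f_low = math.nan
    for i in range(peak_idx, -1, -1):
        if mags[i] < target:
            f_low = _interp(i, i + 1)
            break

    f_high = math.nan
    for i in range(peak_idx, len(mags)):
        if mags[i] < target:
            f_high = _interp(i, i - 1)
            break

    return f_low, f_high


# ---------------------------------------------------------------------------
# time-domain conditioning


def _prewarped(fc: float, fs: float) -> float:
    """Analog corner (rad/s) prewarped so the bilinear corner lands on fc."""
    return 2.0 * fs * math.tan(math.pi * fc / fs)


def _chain_sections(params: ChainParams, fs: float) -> list[tuple[np.ndarray, np.ndarray]]:
    wc = _prewarped(params.hp_fc, fs)
    hp_b, hp_a = sps.bilinear([1.0, 0.0], [1.0, wc], fs)
    w0 = _prewarped(params.lp_fc, fs)
    lp_b, lp_a = sps.bilinear(
        [params.lp_gain * w0**2], [1.0, w0 / params.lp_q, w0**2], fs
    )
    return [(hp_b, hp_a), (hp_b, hp_a), (lp_b, lp_a)]


def apply_chain(trace, params: ChainParams):
    """Run a trace through the front-end in the time domain.

    Filters the signal through the discretized HP/LP sections, applies the
    instrumentation-amplifier gain, shifts by the DC offset and hard-clips to
    the supply rails.  The returned object is a new trace at the same
    simulation rate.

    Raises
    ------
    ValueError
        If ``trace.fs_sim < 10 * lp_fc`` (too coarse to emulate the chain).
    """
    fs = trace.fs_sim
    if fs < 10.0 * params.lp_fc:
        raise ValueError(
            f"fs_sim={fs} too low; need at least 10 x lp_fc = {10 * params.lp_fc} Hz"
        )
    x = trace.samples
    for b, a in _chain_sections(params, fs):
        x = sps.lfilter(b, a, x)
    x = params.ia_gain * x + params.v_offset
    np.clip(x, params.v_rail_lo, params.v_rail_hi, out=x)
    return trace.with_samples(x, ("chain",))


# ---------------------------------------------------------------------------
# component-tolerance Monte Carlo


def corner_scale(delta_r: float, delta_c: float) -> float:
    """Corner-frequency factor for an RC pair off-nominal by the deltas.

    A first-order corner is 1/(2*pi*R*C), so relative errors delta_r and
    delta_c scale the corner by ``1 / ((1 + delta_r) * (1 + delta_c))`` —
    capacitors at -10% push a corner to 1/0.9 ~ 1.11x its design value.
    """
    return 1.0 / ((1.0 + delta_r) * (1.0 + delta_c))


def tolerance_monte_carlo(
    params: ChainParams, tol: ToleranceSpec, freqs: np.ndarray | None = None
) -> ToleranceResult:
    """Monte Carlo of the cutoff frequencies under component tolerances.

    Each first-order high-pass section owns one RC pair; the second-order
    low-pass owns two, scaling its natural frequency by the inverse square
    root of the product of the four component factors.  Per draw, the low
    cutoff is extracted from the (perturbed) high-pass stage response and the
    high cutoff from the low-pass stage response, attributing each corner to
    the filter that sets it.  Reproducible for a fixed ``tol.seed``.
    """
    if freqs is None:
        freqs = default_freq_grid()
    freqs = _validate_freqs(freqs)
    rng = np.random.default_rng(tol.seed)

    f_lows = np.empty(tol.n_draws)
    f_highs = np.empty(tol.n_draws)
    for i in range(tol.n_draws):
        # high-pass: one RC pair per section
        hp_fcs = []
        for _ in range(2):
            dr = rng.uniform(-tol.r_tol, tol.r_tol)
            dc = rng.uniform(-tol.c_tol, tol.c_tol)
            hp_fcs.append(params.hp_fc * corner_scale(dr, dc))
        # low-pass: two RC pairs set the natural frequency
        factor = 1.0
        for _ in range(2):
            dr = rng.uniform(-tol.r_tol, tol.r_tol)
            dc = rng.uniform(-tol.c_tol, tol.c_tol)
            factor *= (1.0 + dr) * (1.0 + dc)
        lp_fc = params.lp_fc / math.sqrt(factor)

        h_hp = _complex_response(freqs, hp_fcs, None, 1.0, 1.0)
        f_lows[i], _ = extract_cutoffs(
            FrequencyResponse(freqs, 20.0 * np.log10(np.abs(h_hp)))
        )
        h_lp = _complex_response(freqs, (), lp_fc, params.lp_q, params.lp_gain)
        _, f_highs[i] = extract_cutoffs(
            FrequencyResponse(freqs, 20.0 * np.log10(np.abs(h_lp)))
        )

    nominal_low, _ = extract_cutoffs(highpass_response(params, freqs))
    _, nominal_high = extract_cutoffs(lowpass_response(params, freqs))
    return ToleranceResult(f_lows, f_highs, nominal_low, nominal_high)


# ---------------------------------------------------------------------------
# digitization


def quantize(
    trace, fs: float = 1000.0, bits: int = 12, vref: float = 3.3
) -> DigitalTrace:
    """Decimate and quantize a conditioned trace.

    The simulation rate must be an integer multiple of ``fs``; every k-th
    sample is kept (the analog chain's low-pass is the anti-alias filter).
    Codes are ``clamp(floor(v / vref * 2**bits), 0, 2**bits - 1)``.
    """
    ratio = trace.fs_sim / fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"fs_sim={trace.fs_sim} is not an integer multiple of fs={fs}"
        )
    v = trace.samples[::k]
    codes = np.floor(v / vref * 2**bits)
    codes = np.clip(codes, 0, 2**bits - 1).astype(np.uint16)
    return DigitalTrace(codes, fs=fs, bits=bits, vref=vref)
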