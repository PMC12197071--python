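"""Synthetic surface-EMG traces with contraction envelopes and disturbances.

Surface EMG is a zero-mean stochastic interference signal of motor-unit
action potentials, with amplitudes from a few microvolts at rest up to the
millivolt range under strong contraction, and spectral content roughly in
the 10-500 Hz band with most of the energy below ~250 Hz.  The generator
here models it as white Gaussian noise shaped by a band-limited power
spectral density and amplitude-modulated by a contraction envelope; it makes
every downstream stage (front-end filtering, digitization, telemetry,
recording) testable without any acquisition hardware.

The PSD shape is the classical two-parameter rational form

    S(f)  proportional to  f^2 * fh^4 / ((f^2 + fl^2) * (f^2 + fh^2)^2)

hard-limited to the requested passband.  With the defaults fl = 60 Hz and
fh = 120 Hz the spectrum peaks below 100 Hz and concentrates its mass well
under 250 Hz, which is what real sEMG looks like after electrode pickup.

Two disturbance injectors mirror what field recordings contain: additive
power-line (mains) sinusoids with optional harmonics, and motion artifacts
(slow baseline drift plus short broadband impact bursts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EMGTrace",
    "SynthSpec",
    "generate_semg",
    "add_mains",
    "add_motion_artifact",
]

#: default contraction profile: 1 s rest, 0.5 s ramp-up, 2 s hold, ramp-down
DEFAULT_ENVELOPE: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (1.0, 0.0),
    (1.5, 1.0),
    (3.5, 1.0),
    (4.0, 0.0),
)

# PSD shape parameters (Hz); chosen so spectral mass concentrates below 250 Hz
_SHAPE_F_LOW = 60.0
_SHAPE_F_HIGH = 120.0


@dataclass(frozen=True)
class EMGTrace:
    """A densely sampled electrode-referred voltage signal.

    Parameters
    ----------
    samples
        Voltage samples in volts.  Typical magnitudes are 1e-6 to 1e-2 V.
    fs_sim
        Simulation sampling rate in Hz.  This is the *analog emulation* rate
        (default 10 kHz elsewhere), deliberately far above the 1 kS/s
        acquisition rate so the front-end can be emulated before decimation.
    components
        Tags describing what was injected ("emg", "mains", "drift", "impact").
    """

    samples: np.ndarray
    fs_sim: float
    components: tuple[str, ...] = ("emg",)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.fs_sim <= 0:
            raise ValueError("fs_sim must be positive")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.fs_sim

    def times(self) -> np.ndarray:
        """Sample times in seconds starting at 0."""
        return np.arange(len(self.samples)) / self.fs_sim

    def with_samples(self, samples: np.ndarray, extra: Iterable[str] = ()) -> "EMGTrace":
        """Copy of this trace with new samples and extra component tags."""
        return EMGTrace(samples, self.fs_sim, self.components + tuple(extra))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic sEMG process.

    ``envelope`` is a piecewise-linear contraction intensity in [0, 1] given
    as (time_s, intensity) breakpoints; outside the breakpoint span the edge
    value is held.  The instantaneous RMS of the generated trace is
    ``rms_rest + (rms_max - rms_rest) * intensity(t)``.
    """

    envelope: tuple[tuple[float, float], ...] = DEFAULT_ENVELOPE
    band: tuple[float, float] = (20.0, 500.0)
    rms_rest: float = 2e-6
    rms_max: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        env = tuple((float(t), float(v)) for t, v in self.envelope)
        object.__setattr__(self, "envelope", env)
        lo, hi = self.band
        if not (0.0 <= lo < hi):
            raise ValueError("band lower edge must be >= 0 and below upper edge")
        if not (0.0 <= self.rms_rest <= self.rms_max):
            raise ValueError("need rms_max >= rms_rest >= 0")
        if any(not (0.0 <= v <= 1.0) for _, v in env):
            raise ValueError("envelope intensities must lie in [0, 1]")

    def envelope_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear envelope intensity evaluated at times ``t``."""
        pts = np.asarray(self.envelope, dtype=float)
        return np.interp(t, pts[:, 0], pts[:, 1])

    # -- plain-dict serialization (YAML/JSON friendly) ----------------------

    def to_dict(self) -> dict:
        return {
            "envelope": [list(p) for p in self.envelope],
            "band": list(self.band),
            "rms_rest": self.rms_rest,
            "rms_max": self.rms_max,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        kwargs = dict(d)
        if "envelope" in kwargs:
            kwargs["envelope"] = tuple(tuple(p) for p in kwargs["envelope"])
        if "band" in kwargs:
            kwargs["band"] = tuple(kwargs["band"])
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SynthSpec":
        return cls.from_dict(json.loads(s))


def _psd_shape(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Unnormalised PSD of the EMG process, zero outside the passband."""
    lo, hi = band
    f2 = freqs**2
    shape = (
        f2
        * _SHAPE_F_HIGH**4
        / ((f2 + _SHAPE_F_LOW**2) * (f2 + _SHAPE_F_HIGH**2) ** 2)
    )
    shape[(freqs < lo) | (freqs > hi)] = 0.0
    return shape


def generate_semg(
    spec: SynthSpec, duration: float, fs_sim: float = 10_000.0
) -> EMGTrace:
    """Generate a synthetic sEMG trace.

    White Gaussian noise is shaped in the frequency domain by the band-limited
    PSD above, normalised to unit RMS, then amplitude-modulated by the
    contraction envelope.  Reproducible for a fixed ``spec.seed``.

    Raises
    ------
    ValueError
        If ``duration`` is not positive or ``fs_sim`` does not satisfy the
        Nyquist precondition ``fs_sim > 2 * band_high``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    lo, hi = spec.band
    if fs_sim <= 2.0 * hi:
        raise ValueError(
            f"fs_sim={fs_sim} must exceed twice the band upper edge ({hi} Hz)"
        )
    n = int(round(duration * fs_sim))
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_sim)
    spectrum *= np.sqrt(_psd_shape(freqs, spec.band))
    shaped = np.fft.irfft(spectrum, n=n)
    rms = float(np.sqrt(np.mean(shaped**2)))
    if rms > 0.0:
        shaped /= rms
    t = np.arange(n) / fs_sim
    amplitude = spec.rms_rest + (spec.rms_max - spec.rms_rest) * spec.envelope_at(t)
    return EMGTrace(shaped * amplitude, fs_sim, ("emg",))


def add_mains(
    trace: EMGTrace,
    amplitude: float,
    f0: float = 60.0,
    harmonics: Sequence[tuple[float, float]] = (),
) -> EMGTrace:
    """Add power-line interference: a sinusoid at ``f0`` plus harmonics.

    ``harmonics`` is a sequence of ``(order, relative_amplitude)`` pairs; each
    contributes ``relative_amplitude * amplitude`` at ``order * f0``.  The
    input trace is never modified.  The sinusoids are accumulated one at a
    time, in order, so splitting one call into several sequential calls
    performs the identical floating-point operation sequence.

    Raises
    ------
    ValueError
        If ``f0`` or any harmonic frequency reaches the Nyquist rate.
    """
    nyq = trace.fs_sim / 2.0
    if f0 >= nyq:
        raise ValueError(f"f0={f0} Hz is not below Nyquist ({nyq} Hz)")
    for order, _rel in harmonics:
        if order * f0 >= nyq:
            raise ValueError(f"harmonic at {order * f0} Hz is not below Nyquist")
    out = trace.samples.copy()
    t = trace.times()
    out = out + amplitude * np.sin(2.0 * np.pi * f0 * t)
    for order, rel in harmonics:
        out = out + (rel * amplitude) * np.sin(2.0 * np.pi * (order * f0) * t)
    injected = amplitude != 0.0 or any(rel != 0.0 for _, rel in harmonics)
    return trace.with_samples(out, ("mains",) if injected else ())


def add_motion_artifact(
    trace: EMGTrace,
    drift_amp: float = 0.0,
    drift_band: tuple[float, float] = (0.5, 8.0),
    impact_times: Sequence[float] = (),
    impact_amp: float = 0.0,
    impact_duration: float = 0.020,
    seed: int = 0,
) -> EMGTrace:
    """Add motion artifacts: slow baseline drift and/or impact bursts.

    Drift is band-limited Gaussian noise confined to ``drift_band`` (below the
    front-end's 20 Hz corner by default) with RMS ``drift_amp``.  Each impact
    is a Hann-windowed broadband burst of length ``impact_duration`` and RMS
    ``impact_amp`` centred at the given time, emulating the short
    high-frequency noise that electrode shifts on ground impact produce.

    Raises
    ------
    ValueError
        If an impact time lies outside the trace span.
    """
    duration = trace.duration
    for t0 in impact_times:
        if not (0.0 <= t0 <= duration):
            raise ValueError(f"impact time {t0}s outside trace span [0, {duration}]s")
    rng = np.random.default_rng(seed)
    out = trace.samples.copy()
    tags: list[str] = []
    n = len(out)
    fs = trace.fs_sim

    if drift_amp != 0.0:
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        mask = (freqs >= drift_band[0]) & (freqs <= drift_band[1])
        spectrum[~mask] = 0.0
        drift = np.fft.irfft(spectrum, n=n)
        rms = float(np.sqrt(np.mean(drift**2)))
        if rms > 0.0:
            drift *= drift_amp / rms
        out = out + drift
        tags.append("drift")

    if impact_amp != 0.0 and len(impact_times) > 0:
        m = max(2, int(round(impact_duration * fs)))
        window = np.hanning(m)
        for t0 in impact_times:
            burst = rng.standard_normal(m) * window
            rms = float(np.sqrt(np.mean(burst**2)))
            if rms > 0.0:
                burst *= impact_amp / rms
            start = int(round(t0 * fs))
            stop = min(start + m, n)
            out[start:stop] += burst[: stop - start]
        tags.append("impact")

    return trace.with_samples(out, tags)
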