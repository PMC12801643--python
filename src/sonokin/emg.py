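"""EMG envelope extraction chains and FES stimulation-artifact suppression.

Three envelope chains produce normalized kinematic estimates from surface
EMG: the Teager-Kaiser energy operator (band-pass 15-380 Hz → TKEO →
rectify → low-pass 7 Hz), the Hilbert analytic-signal magnitude (band-pass
20-450 Hz → |analytic| → low-pass 7 Hz), and a moving RMS (200-sample
window, full overlap).  All filters are 4th-order Butterworth cascades
applied forward-backward (zero net phase), and every chain min-max
normalizes its output over the trial.

Under FES, the stimulation artifact is a periodic pulse train; its
fundamental is estimated from the Welch power spectrum by a harmonic-comb
score and suppressed by a cascade of notch filters at the fundamental and
its harmonics, applied before any envelope chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import signal

from .streams import TimedStream

__all__ = [
    "CombFilterSpec",
    "EnvelopeSignal",
    "estimate_stim_frequency",
    "comb_filter",
    "teager_kaiser",
    "tkeo_envelope",
    "hilbert_envelope",
    "rms_envelope",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CombFilterSpec:
    """Notch cascade at a stimulation fundamental and its harmonics."""

    fundamental: float                 # Hz
    rate: float                        # Hz, stream sampling rate
    bandwidth: float = 2.0             # Hz at −3 dB per notch
    harmonics: tuple = field(default=None)

    def __post_init__(self):
        if self.fundamental <= 0:
            raise ConfigurationError("fundamental must be positive")
        nyq = self.rate / 2.0
        if self.harmonics is None:
            ks = np.arange(1, int(np.floor((nyq - 1e-9) / self.fundamental)) + 1)
            object.__setattr__(
                self, "harmonics", tuple(float(k * self.fundamental) for k in ks)
            )
        for f in self.harmonics:
            if f >= nyq:
                raise ConfigurationError(
                    f"notch frequency {f} Hz at or above Nyquist ({nyq} Hz)"
                )


def _line_power(freqs, psd, f, half=1.0, annulus=(1.5, 3.5)):
    """Band power in f ± half, minus the local broadband background.

    The ON/OFF gating of the stimulation spreads each harmonic into ~1 Hz
    sidebands, so a narrow band (not a single bin) is integrated; the
    background is the median spectral density in a surrounding annulus.
    """
    df = freqs[1] - freqs[0]
    sel = (freqs >= f - half) & (freqs <= f + half)
    ann = ((freqs >= f - annulus[1]) & (freqs < f - annulus[0])) | (
        (freqs > f + annulus[0]) & (freqs <= f + annulus[1])
    )
    if not np.any(sel) or not np.any(ann):
        return 0.0
    return float(psd[sel].sum() * df - psd[sel].size * df * np.median(psd[ann]))


def estimate_stim_frequency(
    x: TimedStream,
    search_band=(20.0, 60.0),
    grid_step: float = 0.25,
    max_harmonic_hz: float = 450.0,
    score_ratio: float = 5.0,
) -> Optional[float]:
    """Estimate the FES stimulation fundamental from the raw EMG spectrum.

    A Welch spectrum is scanned over candidate fundamentals on a
    ``grid_step`` grid within ``search_band``; each candidate is scored by
    its summed background-subtracted line power over every harmonic up to
    ``max_harmonic_hz`` (clipped at zero per harmonic, so absent lines do
    not reward a candidate).  Scoring whole-band harmonic stacks rather
    than a fixed low harmonic count avoids the octave ambiguity of a
    biphasic pulse train, whose even harmonics dominate.  The best
    candidate is returned only if its score exceeds ``score_ratio`` times
    the median candidate score — otherwise ``None`` (no comb structure,
    e.g. a volitional FES-OFF recording).
    """
    fs = x.rate
    v = np.asarray(x.values, dtype=float)
    if v.size < 5 * fs:
        raise ValueError("need at least 5 s of signal to estimate the fundamental")
    nperseg = min(int(round(8 * fs)), v.size)
    freqs, psd = signal.welch(v, fs=fs, nperseg=nperseg)

    candidates = np.arange(search_band[0], search_band[1] + 1e-9, grid_step)
    top = min(max_harmonic_hz, 0.95 * fs / 2)
    scores = np.empty(candidates.size)
    for i, f0 in enumerate(candidates):
        hs = f0 * np.arange(1, int(top / f0) + 1)
        scores[i] = sum(max(_line_power(freqs, psd, h), 0.0) for h in hs)
    best = int(np.argmax(scores))
    med = float(np.median(scores))
    if med > 0 and scores[best] > score_ratio * med:
        return float(candidates[best])
    return None


def comb_filter(x: TimedStream, spec: CombFilterSpec) -> TimedStream:
    """Suppress a periodic artifact with zero-phase notches at each harmonic.

    Second-order IIR notches at every harmonic below Nyquist, cascaded and
    applied forward-backward; output length equals input length.
    """
    if abs(spec.rate - x.rate) > 1e-9:
        raise ConfigurationError("comb spec designed for a different rate")
    sections = []
    for f in spec.harmonics:
        b, a = signal.iirnotch(f, f / spec.bandwidth, fs=x.rate)
        sections.append(np.hstack([b, a]))
    sos = np.vstack(sections)
    y = signal.sosfiltfilt(sos, np.asarray(x.values, dtype=float))
    return TimedStream(values=y, rate=x.rate, t0=x.t0,
                       stream_id=x.stream_id, pulse_channel=x.pulse_channel)


def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator Ψ[x[n]] = x[n]² − x[n−1]·x[n+1].

    Interior samples follow the definition; the endpoints replicate the
    nearest interior value so the output length matches the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("TKEO requires at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


@dataclass
class EnvelopeSignal:
    """Normalized nonnegative envelope of an EMG recording."""

    times: np.ndarray
    values: np.ndarray
    rate: float
    method: str
    normalized: bool = True
    degenerate: bool = False           # constant input; values all zero
    comb: Optional[CombFilterSpec] = None

    def as_prediction(self):
        from .streams import MethodPrediction
        return MethodPrediction(times=self.times, values=self.values,
                                method=f"emg_{self.method}")


def _normalize(values: np.ndarray):
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo <= 0:
        return np.zeros_like(values), True
    return (values - lo) / (hi - lo), False


def _lowpass(values, cutoff, fs, order=4):
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, values)


def _bandpass(values, lo, hi, fs, order=4):
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, values)


def _prefilter(x: TimedStream, fes_spec) -> np.ndarray:
    if fes_spec is not None:
        x = comb_filter(x, fes_spec)
    return np.asarray(x.values, dtype=float)


def tkeo_envelope(
    x: TimedStream, fes_spec: Optional[CombFilterSpec] = None,
    normalize: bool = True,
) -> EnvelopeSignal:
    """Teager-Kaiser chain: [comb] → band-pass 15-380 Hz → TKEO →
    half-wave rectify → low-pass 7 Hz → min-max normalize."""
    if x.rate < 1000:
        raise ValueError("TKEO chain expects a sampling rate >= 1000 Hz")
    v = _prefilter(x, fes_spec)
    v = _bandpass(v, 15.0, min(380.0, 0.45 * x.rate), x.rate)
    v = teager_kaiser(v)
    v = np.maximum(v, 0.0)             # Ψ can dip negative on noise
    v = _lowpass(v, 7.0, x.rate)
    degenerate = False
    if normalize:
        v, degenerate = _normalize(v)
    return EnvelopeSignal(times=x.times, values=v, rate=x.rate,
                          method="tkeo", normalized=normalize,
                          degenerate=degenerate, comb=fes_spec)


def hilbert_envelope(
    x: TimedStream, fes_spec: Optional[CombFilterSpec] = None,
    normalize: bool = True,
) -> EnvelopeSignal:
    """Hilbert chain: [comb] → band-pass 20-450 Hz → |analytic signal| →
    low-pass 7 Hz → min-max normalize."""
    if x.rate <= 900:
        raise ValueError("Hilbert chain expects a sampling rate > 900 Hz")
    v = _prefilter(x, fes_spec)
    v = _bandpass(v, 20.0, min(450.0, 0.45 * x.rate), x.rate)
    v = np.abs(signal.hilbert(v))
    v = _lowpass(v, 7.0, x.rate)
    degenerate = False
    if normalize:
        v, degenerate = _normalize(v)
    return EnvelopeSignal(times=x.times, values=v, rate=x.rate,
                          method="hilbert", normalized=normalize,
                          degenerate=degenerate, comb=fes_spec)


def moving_rms(values: np.ndarray, window: int = 200) -> np.ndarray:
    """Centered moving RMS with stride 1; edge windows shrink to fit."""
    v = np.asarray(values, dtype=float)
    if v.size < window:
        raise ValueError(f"need at least {window} samples")
    sq = v * v
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    n = v.size
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    total = csum[hi + 1] - csum[lo]
    return np.sqrt(total / (hi - lo + 1))


def rms_envelope(
    x: TimedStream, fes_spec: Optional[CombFilterSpec] = None,
    window: int = 200, normalize: bool = True,
) -> EnvelopeSignal:
    """RMS chain: [comb] → centered 200-sample moving RMS (full overlap,
    0.1 s at 2000 Hz) → min-max normalize."""
    v = _prefilter(x, fes_spec)
    v = moving_rms(v, window=window)
    degenerate = False
    if normalize:
        v, degenerate = _normalize(v)
    return EnvelopeSignal(times=x.times, values=v, rate=x.rate,
                          method="rms", normalized=normalize,
                          degenerate=degenerate, comb=fes_spec)


ENVELOPE_CHAINS = {
    "tkeo": tkeo_envelope,
    "hilbert": hilbert_envelope,
    "rms": rms_envelope,
}


def decode_envelope(
    x: TimedStream, method: str,
    fes_spec: Optional[CombFilterSpec] = None,
):
    """Run one named envelope chain and return it as a MethodPrediction."""
    if method not in ENVELOPE_CHAINS:
        raise ValueError(f"unknown envelope method {method!r}")
    return ENVELOPE_CHAINS[method](x, fes_spec).as_prediction()
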