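"""Zero-phase frequency-domain filtering for oscillatory-potential isolation.

The OPs ride on the b-wave rising limb at roughly 50–180 Hz.  They are
separated from the P2 by taking the discrete Fourier transform of the
P3-subtracted trace and applying a zero-phase band-pass whose half-power
(−3 dB) points sit exactly at the band corners.  The realization uses
raised-cosine (in power) transition skirts: the amplitude response is

    |H(f)| = 0                      f <= fc - T
    |H(f)| = sqrt(0.5*(1 - cos(pi*(f - fc + T)/(2T))))   fc - T < f < fc + T
    |H(f)| = 1                      f >= fc + T

around the low corner fc (mirrored at the high corner), so |H(fc)| = 1/sqrt(2)
= −3.01 dB.  The response is purely real, hence exactly zero-phase.
"""

from __future__ import annotations

import numpy as np

from ..waveform import Waveform

__all__ = ["bandpass_gain", "apply_gain", "bandpass_ops", "extract_p2", "lowpass"]

OP_BAND_HZ = (50.0, 180.0)
#: transition half-widths (Hz) of the raised-cosine skirts at the two corners
DEFAULT_TRANSITION_HZ = (20.0, 30.0)


def _rising_skirt(f: np.ndarray, corner: float, half_width: float) -> np.ndarray:
    """Amplitude 0→1 around ``corner`` with half-power exactly at the corner."""
    x = np.clip((f - (corner - half_width)) / (2.0 * half_width), 0.0, 1.0)
    return np.sqrt(0.5 * (1.0 - np.cos(np.pi * x)))


def _falling_skirt(f: np.ndarray, corner: float, half_width: float) -> np.ndarray:
    """Amplitude 1→0 around ``corner`` with half-power exactly at the corner."""
    x = np.clip((f - (corner - half_width)) / (2.0 * half_width), 0.0, 1.0)
    return np.sqrt(0.5 * (1.0 + np.cos(np.pi * x)))


def bandpass_gain(
    freqs: np.ndarray,
    low: float = OP_BAND_HZ[0],
    high: float = OP_BAND_HZ[1],
    transition: tuple[float, float] = DEFAULT_TRANSITION_HZ,
) -> np.ndarray:
    """Real amplitude response of the OP band-pass on the given frequency grid."""
    if high <= low:
        raise ValueError("band-pass corners must satisfy low < high")
    t_lo, t_hi = transition
    if low - t_lo <= 0:
        raise ValueError("low transition skirt must not reach DC")
    return _rising_skirt(freqs, low, t_lo) * _falling_skirt(freqs, high, t_hi)


def apply_gain(w: Waveform, gain_fn) -> Waveform:
    """Apply a real (zero-phase) frequency-domain gain to a waveform."""
    n = w.amplitudes.size
    freqs = np.fft.rfftfreq(n, d=1.0 / w.sample_rate)
    spec = np.fft.rfft(w.amplitudes)
    out = np.fft.irfft(spec * gain_fn(freqs), n=n)
    return w.with_amplitudes(out)


def bandpass_ops(
    w: Waveform,
    low: float = OP_BAND_HZ[0],
    high: float = OP_BAND_HZ[1],
    transition: tuple[float, float] = DEFAULT_TRANSITION_HZ,
) -> Waveform:
    """Band-pass a trace to the OP band (−3 dB at ``low`` and ``high``)."""
    nyq = w.sample_rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"high corner {high} Hz must lie below Nyquist ({nyq:.0f} Hz)"
        )
    if high + transition[1] >= nyq:
        raise ValueError("upper transition skirt must lie below Nyquist")
    return apply_gain(w, lambda f: bandpass_gain(f, low, high, transition))


def extract_p2(
    w_p2op: Waveform,
    low: float = OP_BAND_HZ[0],
    high: float = OP_BAND_HZ[1],
    transition: tuple[float, float] = DEFAULT_TRANSITION_HZ,
) -> Waveform:
    """Complement of :func:`bandpass_ops`: the smooth b-wave with OPs removed.

    By construction ``bandpass_ops(w) + extract_p2(w) == w`` sample for sample.
    """
    ops = bandpass_ops(w_p2op, low, high, transition)
    return w_p2op.with_amplitudes(w_p2op.amplitudes - ops.amplitudes)


def lowpass(w: Waveform, cutoff: float, half_width: float = 10.0) -> Waveform:
    """Zero-phase low-pass with half-power at ``cutoff`` Hz.

    Used as pre-measurement noise control before reading peak amplitudes of
    smooth components (P2, pSTR), whose physiological content lies well below
    the cutoff.
    """
    return apply_gain(w, lambda f: _falling_skirt(f, cutoff, half_width))
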