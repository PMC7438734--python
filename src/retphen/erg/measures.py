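"""Peak measurements of the separated ERG components.

These read amplitudes and implicit times (flash onset → peak) from the
component traces produced upstream: the P2 b-wave after P3 subtraction and
OP removal, the band-passed OP burst, and the dim-flash positive scotopic
threshold response (pSTR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ..waveform import LuminanceSeries, Waveform

__all__ = [
    "OPResult",
    "STRResult",
    "measure_p2_amplitude",
    "measure_ops",
    "measure_str",
    "STR_ENERGIES",
]

#: dim-flash energies averaged for the scotopic threshold response (log cd·s/m²)
STR_ENERGIES = (-4.90, -5.01, -5.31)

P2_WINDOW_MS = (20.0, 150.0)
OP_WINDOW_MS = (10.0, 60.0)
PSTR_WINDOW_MS = (60.0, 130.0)


@dataclass(frozen=True)
class OPResult:
    """Oscillatory-potential summary: sum of positive peak amplitudes and
    the implicit time of the largest peak."""

    amplitude: float  # μV, sum over positive peaks above the noise floor
    implicit_time: float  # ms, NaN when no peak found
    per_peak: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.implicit_time)


@dataclass(frozen=True)
class STRResult:
    """pSTR amplitude/implicit time averaged over the three dim energies."""

    pstr_amplitude: float  # μV
    pstr_implicit_time: float  # ms
    energies_used: tuple[float, float, float]


def measure_p2_amplitude(
    w_p2: Waveform, window: tuple[float, float] = P2_WINDOW_MS
) -> tuple[float, float]:
    """Baseline-to-positive-peak amplitude and implicit time of the b-wave.

    Ties break to the earliest peak.  A trace with no positive excursion in
    the window reports amplitude 0 and NaN implicit time.
    """
    m = (w_p2.times >= window[0]) & (w_p2.times <= window[1])
    if not m.any():
        raise ValueError(f"no samples in search window {window} ms")
    a, t = w_p2.amplitudes[m], w_p2.times[m]
    i = int(np.argmax(a))  # argmax returns the first maximum: earliest tie-break
    if a[i] <= 0:
        return 0.0, float("nan")
    return float(a[i]), float(t[i])


def measure_ops(
    w_op: Waveform,
    search_window: tuple[float, float] = OP_WINDOW_MS,
    noise_floor: float = 5.0,
) -> OPResult:
    """Sum positive OP peaks above ``noise_floor`` μV inside the window.

    The summary amplitude is the sum of individual positive peak amplitudes
    (monotone in burst energy); the implicit time is that of the largest
    peak, earliest on ties.
    """
    m = (w_op.times >= search_window[0]) & (w_op.times <= search_window[1])
    if not m.any():
        raise ValueError(f"no samples in search window {search_window} ms")
    a, t = w_op.amplitudes[m], w_op.times[m]
    idx, props = find_peaks(a, height=noise_floor)
    if idx.size == 0:
        return OPResult(0.0, float("nan"))
    heights = props["peak_heights"]
    per_peak = tuple((float(t[i]), float(h)) for i, h in zip(idx, heights))
    imax = int(np.argmax(heights))
    return OPResult(float(heights.sum()), float(t[idx[imax]]), per_peak)


def measure_str(
    series: LuminanceSeries,
    str_energies=STR_ENERGIES,
    window: tuple[float, float] = PSTR_WINDOW_MS,
    energy_tol: float = 0.01,
) -> STRResult:
    """Average the positive STR over the three dim flashes.

    Each required energy must be present in the series (within
    ``energy_tol`` log units); the pSTR amplitude/implicit time are the means
    of the per-trace positive-peak measurements inside ``window``.
    """
    if len(str_energies) != 3:
        raise ValueError("the STR is averaged over exactly three energies")
    missing = [e for e in str_energies if series.nearest(e, energy_tol) is None]
    if missing:
        raise ValueError(
            f"series lacks required STR energies {missing} log cd·s/m²"
        )
    amps, times = [], []
    for e in str_energies:
        w = series.nearest(e, energy_tol)
        amp, it = measure_p2_amplitude(w, window=window)
        amps.append(amp)
        times.append(it)
    return STRResult(
        pstr_amplitude=float(np.mean(amps)),
        pstr_implicit_time=float(np.mean(times)),
        energies_used=tuple(float(e) for e in str_energies),
    )
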