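"""Containers for full-field ERG recordings.

A :class:`Waveform` is one corneal voltage trace elicited by a single flash,
uniformly sampled from a pre-stimulus baseline (t < 0) through the
post-stimulus response, tagged with the flash strength in log10 cd·s/m².
A :class:`LuminanceSeries` is the ordered set of such traces recorded from
one eye over an ascending ladder of flash energies — the unit of analysis
for dark-adapted ERG decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "LuminanceSeries",
    "baseline_correct",
    "read_waves_csv",
    "series_to_frame",
]

#: column order of the long-format waveform interchange table
WAVES_COLUMNS = [
    "subject_id",
    "genotype",
    "age_months",
    "eye",
    "energy_log_cd_s_m2",
    "time_ms",
    "amplitude_uV",
]

MIN_SAMPLE_RATE_HZ = 1000.0


@dataclass(frozen=True)
class Waveform:
    """One ERG trace.

    Parameters
    ----------
    times : ndarray
        Sample times in ms, strictly increasing with a constant step;
        flash onset is at t = 0 and the trace must start before it.
    amplitudes : ndarray
        Corneal potential in μV, same length as ``times``.
    energy : float
        Flash energy in log10 cd·s/m².
    subject_ref : str
        Opaque subject/eye identifier.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    energy: float
    subject_ref: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("waveform needs at least two samples")
        if a.shape != t.shape:
            raise ValueError("times and amplitudes must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be strictly increasing with constant step")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitudes must be finite")
        sr = 1000.0 / dt[0]
        if sr < MIN_SAMPLE_RATE_HZ:
            raise ValueError(
                f"sample rate {sr:.0f} Hz < {MIN_SAMPLE_RATE_HZ:.0f} Hz minimum "
                "(oscillatory-potential band must sit below Nyquist)"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def dt_ms(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt_ms

    @property
    def energy_linear(self) -> float:
        """Flash energy in linear cd·s/m²."""
        return float(10.0 ** self.energy)

    def with_amplitudes(self, amplitudes: np.ndarray) -> "Waveform":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=float))

    def same_time_base(self, other: "Waveform") -> bool:
        return self.times.shape == other.times.shape and np.allclose(
            self.times, other.times
        )


@dataclass
class LuminanceSeries:
    """Ascending-energy set of waveforms from one eye/session."""

    waveforms: list[Waveform]
    subject_id: str = ""
    genotype: str = ""
    age_months: float = float("nan")
    eye: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waveforms = sorted(self.waveforms, key=lambda w: w.energy)
        energies = [w.energy for w in self.waveforms]
        if len(set(np.round(energies, 6))) != len(energies):
            raise ValueError("energies in a luminance series must be unique")
        if self.waveforms:
            ref = self.waveforms[0]
            for w in self.waveforms[1:]:
                if not ref.same_time_base(w):
                    raise ValueError("all waveforms must share one time base")

    @property
    def energies(self) -> np.ndarray:
        return np.array([w.energy for w in self.waveforms])

    def nearest(self, energy: float, tol: float = 0.01) -> Waveform | None:
        """Waveform whose log-energy is within ``tol`` of ``energy``."""
        if not self.waveforms:
            return None
        idx = int(np.argmin(np.abs(self.energies - energy)))
        w = self.waveforms[idx]
        return w if abs(w.energy - energy) <= tol else None

    def __len__(self) -> int:
        return len(self.waveforms)

    def __iter__(self):
        return iter(self.waveforms)


def baseline_correct(w: Waveform, prestim_window: tuple[float, float] = (-np.inf, 0.0)) -> Waveform:
    """Subtract the mean pre-stimulus level from a trace.

    ``prestim_window`` is a closed ms interval that must lie entirely before
    flash onset (t = 0); the default uses every pre-stimulus sample.
    """
    lo, hi = prestim_window
    if hi > 0:
        raise ValueError("pre-stimulus window must end at or before flash onset (t = 0)")
    mask = (w.times >= lo) & (w.times <= hi)
    if not mask.any():
        raise ValueError(
            f"no samples in pre-stimulus window [{lo}, {hi}] ms; "
            "recording must include a baseline segment before t = 0"
        )
    return w.with_amplitudes(w.amplitudes - float(w.amplitudes[mask].mean()))


def read_waves_csv(path) -> list[LuminanceSeries]:
    """Read the long-format waveform table into luminance series (one per eye)."""
    df = pd.read_csv(path)
    missing = [c for c in WAVES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"waveform table missing columns: {missing}")
    out: list[LuminanceSeries] = []
    for (sid, gen, age, eye), g in df.groupby(
        ["subject_id", "genotype", "age_months", "eye"], sort=True
    ):
        waves = []
        for energy, ge in g.groupby("energy_log_cd_s_m2", sort=True):
            ge = ge.sort_values("time_ms")
            waves.append(
                Waveform(
                    times=ge["time_ms"].to_numpy(float),
                    amplitudes=ge["amplitude_uV"].to_numpy(float),
                    energy=float(energy),
                    subject_ref=f"{sid}/{eye}",
                )
            )
        out.append(
            LuminanceSeries(
                waveforms=waves,
                subject_id=str(sid),
                genotype=str(gen),
                age_months=float(age),
                eye=str(eye),
            )
        )
    return out


def series_to_frame(series: LuminanceSeries) -> pd.DataFrame:
    """Long-format table for one series (inverse of :func:`read_waves_csv`)."""
    rows = []
    for w in series:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": series.subject_id,
                    "genotype": series.genotype,
                    "age_months": series.age_months,
                    "eye": series.eye,
                    "energy_log_cd_s_m2": w.energy,
                    "time_ms": w.times,
                    "amplitude_uV": w.amplitudes,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[WAVES_COLUMNS]
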