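"""Synthetic dark-adapted ERG waveforms with known component truths.

Each waveform is the sum of four analytically defined components plus white
Gaussian noise:

* P3: the delayed-Gaussian photoreceptoral component (negative);
* P2: a gamma-density b-wave template scaled by a Naka-Rushton
  intensity-response at the flash energy;
* OPs: a Gabor packet (~115 Hz, σ = 8 ms) on the b-wave rising limb,
  scaled by the same intensity-response fraction;
* pSTR: a Gaussian bump (~110 ms, σ = 15 ms) present only at the dim
  STR-range flashes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..erg.naka_rushton import naka_rushton
from ..erg.p3 import P3Params, p3_model
from ..waveform import LuminanceSeries, Waveform
from .config import ENERGY_LADDER

__all__ = ["ErgTruth", "erg_components", "simulate_erg_waveform", "simulate_series"]

#: flashes at or below this log-energy carry the pSTR bump
PSTR_MAX_ENERGY = -4.5


@dataclass(frozen=True)
class ErgTruth:
    """Ground-truth component parameters for one eye."""

    rm_p3: float = 400.0  # μV
    s: float = 2.0e-3  # (cd·s/m²)⁻¹·ms⁻²
    td: float = 4.0  # ms
    vmax: float = 500.0  # μV
    k: float = 0.05  # cd·s/m², semi-saturation
    b_onset_ms: float = 15.0  # synaptic delay before bipolar depolarization
    b_peak_ms: float = 95.0
    b_alpha: float = 4.0  # gamma template shape
    op_envelope_uv: float = 40.0  # Gabor envelope peak
    op_center_ms: float = 40.0
    op_onset_ms: float = 20.0  # smooth gate: OPs absent before this time
    op_freq_hz: float = 115.0
    op_sigma_ms: float = 8.0
    pstr_uv: float = 25.0
    pstr_time_ms: float = 110.0
    pstr_sigma_ms: float = 15.0

    def to_dict(self) -> dict:
        return asdict(self)


def _gamma_template(
    t: np.ndarray, onset_ms: float, peak_ms: float, alpha: float
) -> np.ndarray:
    """Unit-peak gamma-density b-wave shape, zero before the synaptic onset."""
    tau = np.clip(t - onset_ms, 0.0, None) / (peak_ms - onset_ms)
    return np.where(t > onset_ms, tau**alpha * np.exp(alpha * (1.0 - tau)), 0.0)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def erg_components(truth: ErgTruth, energy: float, times: np.ndarray) -> dict:
    """Noiseless component traces (μV) at log-energy ``energy``."""
    i_lin = 10.0**energy
    p3 = p3_model(i_lin, times, P3Params(truth.rm_p3, truth.s, truth.td))
    frac = float(naka_rushton(i_lin, 1.0, truth.k))
    p2 = truth.vmax * frac * _gamma_template(
        times, truth.b_onset_ms, truth.b_peak_ms, truth.b_alpha
    )
    env = truth.op_envelope_uv * frac * np.exp(
        -((times - truth.op_center_ms) ** 2) / (2.0 * truth.op_sigma_ms**2)
    )
    env *= _smoothstep((times - truth.op_onset_ms) / 6.0)
    ops = env * np.cos(2.0 * np.pi * truth.op_freq_hz * (times - truth.op_center_ms) / 1000.0)
    ops[times <= 0] = 0.0
    if energy <= PSTR_MAX_ENERGY:
        pstr = truth.pstr_uv * np.exp(
            -((times - truth.pstr_time_ms) ** 2) / (2.0 * truth.pstr_sigma_ms**2)
        )
        pstr[times <= 0] = 0.0
    else:
        pstr = np.zeros_like(times)
    return {"p3": p3, "p2": p2, "ops": ops, "pstr": pstr}


def _time_base(span_ms=(-20.0, 250.0), sample_rate_hz: float = 4000.0) -> np.ndarray:
    dt = 1000.0 / sample_rate_hz
    n = int(round((span_ms[1] - span_ms[0]) / dt)) + 1
    return span_ms[0] + dt * np.arange(n)


def simulate_erg_waveform(
    truth: ErgTruth,
    energy: float,
    seed_or_rng=0,
    noise_sd: float = 5.0,
    span_ms=(-20.0, 250.0),
    sample_rate_hz: float = 4000.0,
    subject_ref: str = "",
) -> Waveform:
    """One seeded noisy waveform at the given log-energy."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    times = _time_base(span_ms, sample_rate_hz)
    comps = erg_components(truth, energy, times)
    clean = comps["p3"] + comps["p2"] + comps["ops"] + comps["pstr"]
    noise = rng.normal(0.0, noise_sd, times.size) if noise_sd > 0 else 0.0
    return Waveform(times, clean + noise, energy=energy, subject_ref=subject_ref)


def simulate_series(
    truth: ErgTruth,
    energies=ENERGY_LADDER,
    seed_or_rng=0,
    noise_sd: float = 5.0,
    span_ms=(-20.0, 250.0),
    sample_rate_hz: float = 4000.0,
    subject_id: str = "",
    genotype: str = "",
    age_months: float = float("nan"),
    eye: str = "OD",
) -> LuminanceSeries:
    """A full seeded luminance series for one eye."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    waves = [
        simulate_erg_waveform(
            truth, e, rng, noise_sd, span_ms, sample_rate_hz,
            subject_ref=f"{subject_id}/{eye}",
        )
        for e in energies
    ]
    return LuminanceSeries(
        waveforms=waves,
        subject_id=subject_id,
        genotype=genotype,
        age_months=age_months,
        eye=eye,
    )
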