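"""Delayed-Gaussian model of the photoreceptoral (P3) ERG component.

The leading electronegative limb of the dark-adapted ERG (the a-wave) is
driven by rod photocurrent suppression.  It is modelled here by the standard
delayed-Gaussian saturation function

    P3(i, t) = -RmP3 * (1 - exp(-i * S * (t - td)^2))   for t > td, else 0

with ``i`` the flash energy in linear cd·s/m², ``RmP3`` the saturated
amplitude (μV), ``S`` the phototransduction sensitivity/amplification
((cd·s·m⁻²)⁻¹·ms⁻²; time enters in ms) and ``td`` a short transduction delay
(ms).  A single (RmP3, S, td) triple is fitted as an ensemble across the
leading edges of the brightest flashes, where the raw waveform is
P3-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ..waveform import LuminanceSeries, Waveform

__all__ = ["P3Params", "p3_model", "DelayedGaussianP3Model", "fit_p3"]


@dataclass(frozen=True)
class P3Params:
    """Fitted delayed-Gaussian parameters for one eye."""

    rm_p3: float  # saturated amplitude magnitude, μV (>= 0)
    s: float  # sensitivity, (cd·s/m²)⁻¹·ms⁻²
    td: float  # delay, ms
    converged: bool = True
    residual_norm: float = float("nan")
    fit_window: tuple[float, float] = (0.0, 0.0)  # ms span actually used
    energies_used: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rm_p3 < 0:
            raise ValueError("RmP3 must be non-negative")
        if self.td < 0:
            raise ValueError("td must be non-negative")


def p3_model(energy: float, t, params: P3Params) -> np.ndarray:
    """Evaluate the delayed-Gaussian P3 at time(s) ``t`` (ms).

    ``energy`` is in linear cd·s/m².  Returns μV, in [-RmP3, 0]; zero for
    t <= td.
    """
    if energy < 0:
        raise ValueError("flash energy must be non-negative (linear cd·s/m²)")
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - params.td, 0.0, None)
    # exponent can overflow harmlessly toward saturation; clip for tidiness
    expo = np.clip(energy * params.s * dt * dt, 0.0, 700.0)
    return -params.rm_p3 * (1.0 - np.exp(-expo))


def _leading_edge_segments(
    series: LuminanceSeries,
    n_bright: int,
    trough_window: tuple[float, float],
    max_leading_ms: float,
):
    """(energy_linear, times, amplitudes) segments from flash onset to the
    a-wave trough (capped at ``max_leading_ms``) of the brightest
    ``n_bright`` traces with a detectable negative trough.  The cap keeps the
    ensemble inside the P3-dominated epoch before post-receptoral intrusion."""
    segs = []
    for w in sorted(series.waveforms, key=lambda w: -w.energy)[:n_bright]:
        m = (w.times >= trough_window[0]) & (w.times <= trough_window[1])
        if not m.any():
            continue
        tt, aa = w.times[m], w.amplitudes[m]
        imin = int(np.argmin(aa))
        if aa[imin] >= 0:  # no negative deflection: not P3-dominated
            continue
        keep = tt <= min(tt[imin], trough_window[0] + max_leading_ms)
        if keep.sum() < 4:
            continue
        segs.append((w.energy_linear, tt[keep], aa[keep], w.energy))
    return segs


@dataclass
class P3FitResults:
    """Results of the ensemble delayed-Gaussian fit."""

    params: P3Params

    @property
    def converged(self) -> bool:
        return self.params.converged

    def predict(self, energy_linear: float, t) -> np.ndarray:
        return p3_model(energy_linear, t, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Delayed-Gaussian P3 fit",
            "-----------------------",
            f"RmP3        {p.rm_p3:10.3f} μV",
            f"S           {p.s:10.6f} (cd·s/m²)⁻¹·ms⁻²",
            f"td          {p.td:10.3f} ms",
            f"converged   {p.converged}",
            f"resid. norm {p.residual_norm:10.4f}",
            f"fit window  {p.fit_window[0]:.2f}–{p.fit_window[1]:.2f} ms",
            f"energies    {', '.join(f'{e:.2f}' for e in p.energies_used)} log cd·s/m²",
        ]
        return "\n".join(lines)


class DelayedGaussianP3Model:
    """Ensemble fit of the delayed-Gaussian P3 to bright-flash leading edges.

    Parameters
    ----------
    series : LuminanceSeries
        Baseline-corrected luminance series.
    n_bright : int
        Number of brightest flashes pooled into the ensemble fit.
    trough_window : (float, float)
        ms window searched for each trace's a-wave trough; the fit uses
        onset→trough (the P3-dominated leading edge) of each trace.
    max_leading_ms : float
        Hard cap on each leading-edge segment, keeping the fit clear of
        post-receptoral (b-wave/OP) intrusion on slower dim-flash troughs.
    """

    def __init__(
        self,
        series: LuminanceSeries,
        n_bright: int = 3,
        trough_window: tuple[float, float] = (0.0, 50.0),
        max_leading_ms: float = 20.0,
    ):
        self.series = series
        self.n_bright = n_bright
        self.trough_window = trough_window
        self.max_leading_ms = max_leading_ms

    def fit(self) -> P3FitResults:
        segs = _leading_edge_segments(
            self.series, self.n_bright, self.trough_window, self.max_leading_ms
        )
        if len(segs) < 2:
            # degenerate: no a-wave to model; flag, report zero amplitude
            return P3FitResults(
                P3Params(0.0, 1e-6, 0.0, converged=False, residual_norm=np.nan)
            )
        energies = [s[0] for s in segs]
        logs = tuple(s[3] for s in segs)
        t_all = np.concatenate([s[1] for s in segs])
        a_all = np.concatenate([s[2] for s in segs])
        amp0 = float(-a_all.min())

        # coarse grid over (S, td) with RmP3 profiled out (model is linear in it)
        s_grid = np.logspace(-5, 1.2, 40)
        td_grid = np.linspace(0.0, 12.0, 25)
        best = (np.inf, amp0, 1e-3, 2.0)
        for td in td_grid:
            for s in s_grid:
                g = self._shape(energies, segs, s, td)
                denom = float(g @ g)
                if denom <= 0:
                    continue
                rm = max(0.0, float(-(a_all @ g) / denom))
                r = a_all + rm * g
                sse = float(r @ r)
                if sse < best[0]:
                    best = (sse, rm, s, td)
        _, rm0, s0, td0 = best

        def resid(x):
            rm, log10s, td = x
            g = self._shape(energies, segs, 10.0 ** log10s, td)
            return a_all + rm * g

        sol = least_squares(
            resid,
            x0=[rm0, np.log10(s0), td0],
            bounds=([0.0, -8.0, 0.0], [np.inf, 2.0, 20.0]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rm, log10s, td = sol.x
        res_norm = float(np.linalg.norm(sol.fun))
        window = (float(min(s[1][0] for s in segs)), float(max(s[1][-1] for s in segs)))
        params = P3Params(
            rm_p3=float(rm),
            s=float(10.0 ** log10s),
            td=float(td),
            converged=bool(sol.success and rm > 0),
            residual_norm=res_norm,
            fit_window=window,
            energies_used=logs,
        )
        return P3FitResults(params)

    @staticmethod
    def _shape(energies, segs, s, td) -> np.ndarray:
        """Unit-amplitude model shape 1-exp(-i·S·(t-td)²) stacked over segments."""
        parts = []
        for (i_lin, tt, _aa, _log) in segs:
            dt = np.clip(tt - td, 0.0, None)
            parts.append(1.0 - np.exp(-np.clip(i_lin * s * dt * dt, 0.0, 700.0)))
        return np.concatenate(parts)


def fit_p3(
    series: LuminanceSeries,
    n_bright: int = 3,
    trough_window: tuple[float, float] = (0.0, 50.0),
    max_leading_ms: float = 20.0,
) -> P3Params:
    """Functional wrapper: fit the ensemble delayed-Gaussian, return params."""
    return (
        DelayedGaussianP3Model(series, n_bright, trough_window, max_leading_ms)
        .fit()
        .params
    )


def isolate_p2_op(w: Waveform, params: P3Params) -> Waveform:
    """Subtract the modelled P3 from a trace, exposing the P2–OP complex."""
    model = p3_model(w.energy_linear, w.times, params)
    return w.with_amplitudes(w.amplitudes - model)
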