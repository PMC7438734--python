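"""Naka-Rushton intensity–response fitting.

Component amplitudes grow with flash energy following the hyperbolic
saturation function

    V(i) = Vmax * i^n / (i^n + K^n)

with ``Vmax`` the saturated amplitude (μV), ``K`` the semi-saturation energy
(linear cd·s/m²; V(K) = Vmax/2) and ``n`` a slope exponent, fixed at 1 by
default for stability on short luminance ladders.  The reported sensitivity
is -log10(K) (log (cd·s/m²)⁻¹): higher sensitivity means half-saturation at
a dimmer flash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["NakaRushtonFit", "NakaRushtonModel", "naka_rushton", "fit_naka_rushton"]


def naka_rushton(i, vmax: float, k: float, n: float = 1.0) -> np.ndarray:
    """Evaluate V(i) at linear energy/energies ``i``."""
    i = np.asarray(i, dtype=float)
    ip = np.power(i, n)
    return vmax * ip / (ip + k**n)


@dataclass(frozen=True)
class NakaRushtonFit:
    """Fitted intensity-response parameters."""

    vmax: float  # μV
    k: float  # semi-saturation energy, linear cd·s/m²
    n: float  # exponent
    converged: bool = True
    residual_norm: float = float("nan")

    @property
    def sensitivity(self) -> float:
        """-log10(K), in log (cd·s/m²)⁻¹."""
        return -np.log10(self.k)

    def predict(self, i) -> np.ndarray:
        return naka_rushton(i, self.vmax, self.k, self.n)

    def summary(self) -> str:
        return "\n".join(
            [
                "Naka-Rushton fit",
                "----------------",
                f"Vmax         {self.vmax:10.3f} μV",
                f"K            {self.k:10.6g} cd·s/m²",
                f"n            {self.n:10.3f}",
                f"sensitivity  {self.sensitivity:10.3f} log (cd·s/m²)⁻¹",
                f"converged    {self.converged}",
            ]
        )


class NakaRushtonModel:
    """Fit V(i) = Vmax·iⁿ/(iⁿ+Kⁿ) to (energy, amplitude) points.

    Parameters
    ----------
    energies : array-like
        Linear flash energies (cd·s/m²), at least 3 distinct values.
    amplitudes : array-like
        Component amplitudes (μV).
    fix_n : float or None
        Exponent held fixed (default 1.0); pass None to fit it freely.
    """

    def __init__(self, energies, amplitudes, fix_n: float | None = 1.0):
        self.energies = np.asarray(energies, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.fix_n = fix_n
        if self.energies.shape != self.amplitudes.shape:
            raise ValueError("energies and amplitudes must have equal length")
        if np.any(self.energies <= 0):
            raise ValueError("energies must be positive (linear cd·s/m²)")

    def fit(self) -> NakaRushtonFit:
        x, y = self.energies, self.amplitudes
        if np.unique(x).size < 3 or not np.any(y > 0):
            return NakaRushtonFit(
                max(float(y.max(initial=0.0)), 0.0), 1.0, 1.0, converged=False
            )

        n0 = self.fix_n if self.fix_n is not None else 1.0
        # profile Vmax (linear parameter) over a log-spaced K grid
        k_grid = np.logspace(np.log10(x.min()) - 2, np.log10(x.max()) + 1, 120)
        best = (np.inf, float(y.max()), float(np.median(x)))
        for k in k_grid:
            g = x**n0 / (x**n0 + k**n0)
            denom = float(g @ g)
            if denom <= 0:
                continue
            vm = float(y @ g) / denom
            r = y - vm * g
            sse = float(r @ r)
            if sse < best[0] and vm > 0:
                best = (sse, vm, k)
        _, vm0, k0 = best

        if self.fix_n is not None:

            def resid(p):
                return y - naka_rushton(x, p[0], 10.0 ** p[1], self.fix_n)

            x0 = [vm0, np.log10(k0)]
            lb, ub = [0.0, -12.0], [np.inf, 6.0]
        else:

            def resid(p):
                return y - naka_rushton(x, p[0], 10.0 ** p[1], p[2])

            x0 = [vm0, np.log10(k0), 1.0]
            lb, ub = [0.0, -12.0, 0.2], [np.inf, 6.0, 5.0]

        sol = least_squares(resid, x0=x0, bounds=(lb, ub), xtol=1e-13, ftol=1e-13)
        vm = float(sol.x[0])
        k = float(10.0 ** sol.x[1])
        n = float(self.fix_n if self.fix_n is not None else sol.x[2])
        ok = bool(sol.success and vm > 0 and np.isfinite(k))
        return NakaRushtonFit(vm, k, n, converged=ok,
                              residual_norm=float(np.linalg.norm(sol.fun)))


def fit_naka_rushton(points, fix_n: float | None = 1.0) -> NakaRushtonFit:
    """Functional wrapper over :class:`NakaRushtonModel`.

    ``points`` is an iterable of (linear energy, amplitude μV) pairs.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        return NakaRushtonFit(0.0, 1.0, 1.0, converged=False)
    return NakaRushtonModel(pts[:, 0], pts[:, 1], fix_n=fix_n).fit()
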