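"""Plate-reader quantification: BCA total protein and Aβ ELISA.

Standard wells of known concentration define a standard curve; sample
signals are inverted through the curve, corrected for their dilution chain,
and the Aβ read-out is expressed as pg of Aβ per mg of total protein.

Curve forms
-----------
``linear``     y = a + b·x
``quadratic``  y = a + b·x + c·x², required monotone over the standard range
               (the usual BCA choice: slight downward curvature)
``4pl``        y = d + (a - d) / (1 + (x/c)^b), the four-parameter logistic
               conventional for immunoassays (default for ELISA)

All curves refuse extrapolation: sample signals outside the standard signal
range are flagged below-detection / above-range rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "StandardSeries",
    "StandardCurve",
    "StandardCurveModel",
    "AssaySample",
    "NormalizedAbeta",
    "fit_standard_curve",
    "interpolate_concentration",
    "insoluble_dilution_chain",
    "normalize_abeta",
    "detection_limit",
    "INSOLUBLE_CHAIN",
]

#: the insoluble-fraction dilution chain: formic acid 1:4, Tris 1:20, PBS/casein 1:5
INSOLUBLE_CHAIN = ((1, 4), (1, 20), (1, 5))


@dataclass
class StandardSeries:
    """Known (concentration, signal) pairs for one assay's standards."""

    concentrations: np.ndarray
    signals: np.ndarray
    assay: str = "BCA"  # or "ELISA"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if c.shape != s.shape:
            raise ValueError("concentrations and signals must have equal length")
        if np.any(c < 0) or not np.all(np.isfinite(s)):
            raise ValueError("concentrations must be >= 0 and signals finite")
        if np.unique(c).size < 3:
            raise ValueError("need at least 3 distinct standard levels")
        # replicate standards at the same level are averaged before fitting
        levels, inv = np.unique(c, return_inverse=True)
        means = np.bincount(inv, weights=s) / np.bincount(inv)
        self.concentrations, self.signals = levels, means


def _4pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class StandardCurve:
    """Invertible fitted signal–concentration map over the standard range."""

    form: str
    coefficients: tuple
    conc_range: tuple[float, float]
    signal_range: tuple[float, float]
    increasing: bool
    r_squared: float
    assay: str = ""
    curve_id: str = ""

    def signal(self, conc):
        x = np.asarray(conc, dtype=float)
        if self.form == "linear":
            a, b = self.coefficients
            return a + b * x
        if self.form == "quadratic":
            a, b, c = self.coefficients
            return a + b * x + c * x * x
        if self.form == "4pl":
            return _4pl(x, *self.coefficients)
        raise ValueError(f"unknown curve form {self.form!r}")

    def concentration(self, signal: float) -> float:
        """Invert one signal to concentration; raises outside the range."""
        lo, hi = self.signal_range
        if not (min(lo, hi) <= signal <= max(lo, hi)):
            raise ValueError("signal outside the standard curve's signal range")
        if self.form == "linear":
            a, b = self.coefficients
            return (signal - a) / b
        if self.form == "4pl":
            a, b, c, d = self.coefficients
            # closed-form inverse of the logistic
            ratio = (a - d) / (signal - d) - 1.0
            return float(c * ratio ** (1.0 / b))
        c0, c1 = self.conc_range
        lo_c = c0 - 1e-12 * max(1.0, abs(c0))
        hi_c = c1 + 1e-12 * max(1.0, abs(c1))
        return float(brentq(lambda x: float(self.signal(x)) - signal, lo_c, hi_c))


class StandardCurveModel:
    """Fit a standard curve of the requested form to averaged standards."""

    def __init__(self, series: StandardSeries, form: str = "linear"):
        self.series = series
        self.form = form

    def fit(self) -> StandardCurve:
        x, y = self.series.concentrations, self.series.signals
        if self.form == "linear":
            b, a = np.polyfit(x, y, 1)
            coeffs: tuple = (float(a), float(b))
        elif self.form == "quadratic":
            c, b, a = np.polyfit(x, y, 2)
            coeffs = (float(a), float(b), float(c))
        elif self.form == "4pl":
            a0 = float(y[np.argmin(x)])
            d0 = float(y[np.argmax(x)])
            c0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
            # relative (1/Y²) weighting: read noise on plate readers scales
            # with signal, and it keeps the lower asymptote anchored
            sigma = np.maximum(np.abs(y), 1e-12 * max(1.0, float(np.abs(y).max())))
            popt, _ = curve_fit(
                _4pl, x, y, p0=[a0, 1.0, c0, d0], sigma=sigma,
                bounds=([-np.inf, 1e-6, 1e-12, -np.inf],
                        [np.inf, 50.0, np.inf, np.inf]),
                maxfev=20000,
            )
            coeffs = tuple(float(v) for v in popt)
        else:
            raise ValueError(f"unknown curve form {self.form!r}")

        curve = StandardCurve(
            form=self.form,
            coefficients=coeffs,
            conc_range=(float(x.min()), float(x.max())),
            signal_range=(0.0, 0.0),  # placeholder, set below
            increasing=True,
            r_squared=0.0,
            assay=self.series.assay,
        )
        grid = np.linspace(x.min(), x.max(), 512)
        vals = curve.signal(grid)
        d = np.diff(vals)
        if np.all(d > 0):
            inc = True
        elif np.all(d < 0):
            inc = False
        else:
            raise ValueError(
                "fitted standard curve is non-monotone over the standard range "
                "(assay failure)"
            )
        yhat = curve.signal(x)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return StandardCurve(
            form=self.form,
            coefficients=coeffs,
            conc_range=(float(x.min()), float(x.max())),
            signal_range=(float(vals[0]), float(vals[-1])),
            increasing=inc,
            r_squared=r2,
            assay=self.series.assay,
        )


def fit_standard_curve(series: StandardSeries, form: str = "linear") -> StandardCurve:
    return StandardCurveModel(series, form).fit()


@dataclass
class AssaySample:
    """One assayed sample: replicate signals plus its dilution bookkeeping."""

    signals: tuple  # replicate raw signals (duplicates typical)
    dilution_factor: float = 1.0
    fraction: str = "soluble"  # or "insoluble"
    tissue: str = "brain"  # or "retina"
    pooled_n: int = 1  # retina pools 6-8 eyes into one sample
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.pooled_n < 1:
            raise ValueError("pooled_n must be >= 1")
        self.signals = tuple(float(s) for s in self.signals)

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.signals))

    @property
    def cv(self) -> float:
        """Coefficient of variation of the replicates (0 for singletons)."""
        if len(self.signals) < 2:
            return 0.0
        m = self.mean_signal
        return float(np.std(self.signals, ddof=1) / m) if m != 0 else float("nan")


def interpolate_concentration(curve: StandardCurve, sample: AssaySample) -> dict:
    """Invert the mean replicate signal and undo the dilution.

    Returns a dict with the concentration (same units as the standards,
    multiplied by the dilution factor) and a flag: 'ok', 'below_detection'
    (signal beyond the low-concentration end) or 'above_range'.
    """
    sig = sample.mean_signal
    lo_sig, hi_sig = curve.signal_range
    low_end, high_end = (lo_sig, hi_sig) if curve.increasing else (hi_sig, lo_sig)
    if (curve.increasing and sig < low_end) or (not curve.increasing and sig > low_end):
        return {"concentration": float("nan"), "flag": "below_detection",
                "cv": sample.cv, "sample_id": sample.sample_id}
    if (curve.increasing and sig > high_end) or (not curve.increasing and sig < high_end):
        return {"concentration": float("nan"), "flag": "above_range",
                "cv": sample.cv, "sample_id": sample.sample_id}
    conc = curve.concentration(sig) * sample.dilution_factor
    return {"concentration": float(conc), "flag": "ok",
            "cv": sample.cv, "sample_id": sample.sample_id}


def insoluble_dilution_chain(ratios=INSOLUBLE_CHAIN) -> float:
    """Composite dilution factor of a chain of (part : whole) steps.

    Each step (p, w) dilutes p parts into a total of w, a factor of w / p;
    the composite is the product.  The default chain is the insoluble-Aβ
    workup: formic acid 1:4, then 1 M Tris 1:20, then PBS/casein 1:5,
    i.e. 4 × 20 × 5 = 400.
    """
    factor = 1.0
    for part, whole in ratios:
        if part <= 0 or whole <= 0:
            raise ValueError("dilution ratio parts must be positive")
        factor *= whole / part
    return float(factor)


@dataclass(frozen=True)
class NormalizedAbeta:
    """Aβ expressed per mg of total protein, with provenance."""

    pg_per_mg: float
    provenance: dict = field(default_factory=dict)


def normalize_abeta(
    abeta_pg_per_ml: float, protein_mg_per_ml: float, provenance: dict | None = None
) -> NormalizedAbeta:
    """Aβ (pg/ml) ÷ total protein (mg/ml) → pg per mg, same-volume basis."""
    if protein_mg_per_ml <= 0:
        raise ValueError("total protein concentration must be positive")
    if abeta_pg_per_ml < 0:
        raise ValueError("Aβ concentration must be non-negative")
    return NormalizedAbeta(
        pg_per_mg=abeta_pg_per_ml / protein_mg_per_ml,
        provenance=dict(provenance or {}),
    )


def detection_limit(control_signals, k: float = 3.0) -> float:
    """Reliable detection limit from control-tissue signals: mean + k·SD."""
    s = np.asarray(list(control_signals), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 control signals")
    return float(s.mean() + k * s.std(ddof=1))
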