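"""Synthetic plate-reader tables for BCA and ELISA quantification.

Standards and duplicate sample wells are generated from a known curve truth
plus multiplicative read noise, in the same long CSV layout the assay
module consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..assay import StandardCurve

__all__ = ["simulate_plate", "linear_curve_truth", "fourpl_curve_truth"]

PLATE_COLUMNS = [
    "well",
    "role",
    "known_concentration",
    "signal",
    "dilution_factor",
    "sample_id",
    "fraction",
    "tissue",
    "pooled_n",
]


def linear_curve_truth(intercept: float = 0.05, slope: float = 0.4,
                       conc_max: float = 2.0, assay: str = "BCA") -> StandardCurve:
    return StandardCurve(
        form="linear",
        coefficients=(intercept, slope),
        conc_range=(0.0, conc_max),
        signal_range=(intercept, intercept + slope * conc_max),
        increasing=True,
        r_squared=1.0,
        assay=assay,
        curve_id="truth",
    )


def fourpl_curve_truth(a: float = 50.0, b: float = 1.2, c: float = 500.0,
                       d: float = 60000.0, conc_range=(7.8, 4000.0),
                       assay: str = "ELISA") -> StandardCurve:
    curve = StandardCurve(
        form="4pl",
        coefficients=(a, b, c, d),
        conc_range=conc_range,
        signal_range=(0.0, 0.0),
        increasing=True,
        r_squared=1.0,
        assay=assay,
        curve_id="truth",
    )
    lo = float(curve.signal(conc_range[0]))
    hi = float(curve.signal(conc_range[1]))
    return StandardCurve(
        form="4pl", coefficients=(a, b, c, d), conc_range=conc_range,
        signal_range=(lo, hi), increasing=hi > lo, r_squared=1.0,
        assay=assay, curve_id="truth",
    )


def simulate_plate(
    curve_truth: StandardCurve,
    sample_truths,
    seed_or_rng=0,
    cv: float = 0.02,
    standards=None,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """One plate: standards plus duplicate sample wells.

    ``sample_truths`` is a list of dicts with keys ``sample_id``,
    ``concentration`` (undiluted, in standard units), ``dilution_factor``
    and optional metadata (``fraction``, ``tissue``, ``pooled_n``).  The
    signal of each sample well is the curve evaluated at
    concentration / dilution_factor, times multiplicative read noise.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if standards is None:
        lo, hi = curve_truth.conc_range
        standards = np.linspace(lo, hi, 6)

    def noisy(x: float) -> float:
        return float(x * (1.0 + rng.normal(0.0, cv))) if cv > 0 else float(x)

    rows = []
    well = 0
    for conc in standards:
        for _ in range(n_replicates):
            rows.append(
                {
                    "well": f"S{well:02d}", "role": "standard",
                    "known_concentration": float(conc),
                    "signal": noisy(float(curve_truth.signal(conc))),
                    "dilution_factor": 1.0, "sample_id": "",
                    "fraction": "", "tissue": "", "pooled_n": 1,
                }
            )
            well += 1
    well = 0
    for s in sample_truths:
        at_well = s["concentration"] / s.get("dilution_factor", 1.0)
        for _ in range(n_replicates):
            rows.append(
                {
                    "well": f"U{well:02d}", "role": "sample",
                    "known_concentration": float("nan"),
                    "signal": noisy(float(curve_truth.signal(at_well))),
                    "dilution_factor": float(s.get("dilution_factor", 1.0)),
                    "sample_id": s["sample_id"],
                    "fraction": s.get("fraction", ""),
                    "tissue": s.get("tissue", ""),
                    "pooled_n": int(s.get("pooled_n", 1)),
                }
            )
            well += 1
    return pd.DataFrame(rows)[PLATE_COLUMNS]
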