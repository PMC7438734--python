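"""Synthetic OCT boundary traces for the central B-scan.

The generator lays four boundary curves over a lateral extent matching the
acquisition geometry (1.4 mm, 1000 A-scans, ONH-centred).  A common-mode
sinusoidal undulation mimics retinal curvature without changing any layer
thickness; independent axial noise per boundary mimics manual tracing
jitter.  With zero noise the per-layer mean thicknesses equal the
programmed truths exactly.
"""

from __future__ import annotations

import numpy as np

from ..oct import BoundarySet

__all__ = ["simulate_oct_boundaries"]


def simulate_oct_boundaries(
    thicknesses: dict,
    seed_or_rng=0,
    n_ascans: int = 1000,
    lateral_extent_um: float = 1400.0,
    undulation_amp_um: float = 15.0,
    undulation_period_um: float = 700.0,
    axial_noise_sd_um: float = 2.0,
    axial_scale_um: float = 2.8,
    subject_id: str = "",
    genotype: str = "",
    age_months: float = float("nan"),
    eye: str = "OD",
) -> BoundarySet:
    """Boundary traces from truth thicknesses {'rnfl', 'ipl', 'ort'} in μm.

    GCC and TRT follow from the identities gcc = rnfl + ipl and
    trt = gcc + ort.
    """
    rnfl, ipl, ort = (float(thicknesses[k]) for k in ("rnfl", "ipl", "ort"))
    if min(rnfl, ipl, ort) < 0:
        raise ValueError("thickness truths must be non-negative")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    lateral = np.linspace(0.0, lateral_extent_um, n_ascans)
    # common-mode curvature: shifts all boundaries, leaves thicknesses intact
    ilm = 50.0 + undulation_amp_um * np.sin(2.0 * np.pi * lateral / undulation_period_um)

    def jitter():
        if axial_noise_sd_um <= 0:
            return 0.0
        return rng.normal(0.0, axial_noise_sd_um, n_ascans)

    rnfl_post = ilm + rnfl + jitter()
    gcc_post = ilm + rnfl + ipl + jitter()
    retina_post = ilm + rnfl + ipl + ort + jitter()
    # enforce the physical ordering sample-wise (noise must not invert layers)
    rnfl_post = np.maximum(rnfl_post, ilm + 0.5)
    gcc_post = np.maximum(gcc_post, rnfl_post)
    retina_post = np.maximum(retina_post, gcc_post + 0.5)
    return BoundarySet(
        lateral_um=lateral,
        ilm_um=ilm,
        rnfl_post_um=rnfl_post,
        gcc_post_um=gcc_post,
        retina_post_um=retina_post,
        axial_scale_um=axial_scale_um,
        subject_id=subject_id,
        genotype=genotype,
        age_months=age_months,
        eye=eye,
    )
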