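"""OCT layer morphometry: boundary traces → thickness endpoints.

The central horizontal B-scan is segmented (upstream, by a masked human
grader or a simulator) into four axial boundaries per A-scan: the inner
limiting membrane (ILM), the posterior edge of the retinal nerve fiber
layer (RNFL), the posterior edge of the ganglion cell complex (GCC) and the
posterior retinal boundary.  This module converts those depths into the five
thickness endpoints:

    RNFL = RNFL_post − ILM
    GCC  = GCC_post − ILM
    IPL  = GCC − RNFL          (inner plexiform layer, by definition)
    TRT  = retina_post − ILM   (total retinal thickness)
    ORT  = TRT − GCC           (outer retinal thickness)

All depths are μm, positive downward from the ILM; a configurable exclusion
half-width drops A-scans around the optic nerve head, where the layered
retina is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BoundarySet",
    "ThicknessProfile",
    "derive_thicknesses",
    "normalize_profiles",
    "read_boundaries_csv",
    "derive_thickness_table",
]

BOUNDARY_COLUMNS = [
    "subject_id",
    "genotype",
    "age_months",
    "eye",
    "ascan_index",
    "lateral_um",
    "ilm_um",
    "rnfl_post_um",
    "gcc_post_um",
    "retina_post_um",
]

THICKNESS_ENDPOINTS = ["rnfl", "ipl", "gcc", "ort", "trt"]


@dataclass
class BoundarySet:
    """Per-A-scan boundary depths (μm) of one central B-scan."""

    lateral_um: np.ndarray
    ilm_um: np.ndarray
    rnfl_post_um: np.ndarray
    gcc_post_um: np.ndarray
    retina_post_um: np.ndarray
    axial_scale_um: float = 1.0  # μm per axial pixel of the source image
    subject_id: str = ""
    genotype: str = ""
    age_months: float = float("nan")
    eye: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrs = [self.lateral_um, self.ilm_um, self.rnfl_post_um,
                self.gcc_post_um, self.retina_post_um]
        arrs = [np.asarray(a, dtype=float) for a in arrs]
        n = arrs[0].size
        if any(a.size != n for a in arrs):
            raise ValueError("all boundary arrays must have equal length")
        (self.lateral_um, self.ilm_um, self.rnfl_post_um,
         self.gcc_post_um, self.retina_post_um) = arrs
        if self.axial_scale_um <= 0:
            raise ValueError("axial scale must be positive")
        self._check_ordering()

    def _check_ordering(self) -> None:
        bad = ~(
            (self.ilm_um < self.rnfl_post_um)
            & (self.rnfl_post_um <= self.gcc_post_um)
            & (self.gcc_post_um < self.retina_post_um)
        )
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"boundary ordering violated at A-scan index {idx}: "
                "require ILM < RNFL_post <= GCC_post < retina_post"
            )


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-eye mean layer thicknesses (μm) with the derivation identities
    ipl = gcc - rnfl and ort = trt - gcc holding exactly."""

    rnfl: float
    ipl: float
    gcc: float
    ort: float
    trt: float
    n_ascans_used: int
    subject_id: str = ""
    genotype: str = ""
    age_months: float = float("nan")
    eye: str = ""

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "genotype": self.genotype,
            "age_months": self.age_months,
            "eye": self.eye,
            "rnfl": self.rnfl,
            "ipl": self.ipl,
            "gcc": self.gcc,
            "ort": self.ort,
            "trt": self.trt,
            "n_ascans_used": self.n_ascans_used,
        }


def derive_thicknesses(
    b: BoundarySet,
    exclusion_zone_um: float = 100.0,
    onh_center_um: float | None = None,
) -> ThicknessProfile:
    """Average per-A-scan thicknesses over the included B-scan extent.

    A-scans within ``exclusion_zone_um`` laterally of the optic nerve head
    (default: the lateral midpoint of the scan, which is ONH-centred in this
    protocol) are excluded.  Derived layers are computed from the averaged
    primary layers so the identities hold to machine precision.
    """
    center = (
        onh_center_um
        if onh_center_um is not None
        else float((b.lateral_um.min() + b.lateral_um.max()) / 2.0)
    )
    keep = np.abs(b.lateral_um - center) > exclusion_zone_um
    if not keep.any():
        raise ValueError("exclusion zone removes every A-scan")
    rnfl = float(np.mean(b.rnfl_post_um[keep] - b.ilm_um[keep]))
    gcc = float(np.mean(b.gcc_post_um[keep] - b.ilm_um[keep]))
    trt = float(np.mean(b.retina_post_um[keep] - b.ilm_um[keep]))
    return ThicknessProfile(
        rnfl=rnfl,
        ipl=gcc - rnfl,
        gcc=gcc,
        ort=trt - gcc,
        trt=trt,
        n_ascans_used=int(keep.sum()),
        subject_id=b.subject_id,
        genotype=b.genotype,
        age_months=b.age_months,
        eye=b.eye,
    )


def normalize_profiles(
    table: pd.DataFrame,
    reference: tuple[str, float] = ("WT", 6),
    endpoints=THICKNESS_ENDPOINTS,
) -> pd.DataFrame:
    """Express each thickness as a percentage of the reference-group mean.

    ``reference`` is (genotype, age_months); the reference group's mean maps
    to exactly 100 for every endpoint.
    """
    gen, age = reference
    ref = table[(table["genotype"] == gen) & (table["age_months"] == age)]
    if ref.empty:
        raise ValueError(f"empty reference group {gen} at {age} months")
    out = table.copy()
    for ep in endpoints:
        mean = ref[ep].mean()
        if mean == 0:
            raise ValueError(f"reference mean for {ep!r} is zero")
        out[ep] = 100.0 * table[ep] / mean
    return out


def read_boundaries_csv(path, axial_scale_um: float = 1.0) -> list[BoundarySet]:
    """Read the boundary interchange table into per-eye boundary sets."""
    df = pd.read_csv(path)
    missing = [c for c in BOUNDARY_COLUMNS if c not in df.columns and c != "lateral_um"]
    if missing:
        raise ValueError(f"boundary table missing columns: {missing}")
    out = []
    for (sid, gen, age, eye), g in df.groupby(
        ["subject_id", "genotype", "age_months", "eye"], sort=True
    ):
        g = g.sort_values("ascan_index")
        lateral = (
            g["lateral_um"].to_numpy(float)
            if "lateral_um" in g.columns
            else g["ascan_index"].to_numpy(float)
        )
        out.append(
            BoundarySet(
                lateral_um=lateral,
                ilm_um=g["ilm_um"].to_numpy(float),
                rnfl_post_um=g["rnfl_post_um"].to_numpy(float),
                gcc_post_um=g["gcc_post_um"].to_numpy(float),
                retina_post_um=g["retina_post_um"].to_numpy(float),
                axial_scale_um=axial_scale_um,
                subject_id=str(sid),
                genotype=str(gen),
                age_months=float(age),
                eye=str(eye),
            )
        )
    return out


def derive_thickness_table(
    boundary_sets, exclusion_zone_um: float = 100.0
) -> pd.DataFrame:
    """Thickness profiles for many eyes as a tidy one-row-per-eye table."""
    return pd.DataFrame(
        [derive_thicknesses(b, exclusion_zone_um).to_row() for b in boundary_sets]
    )
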