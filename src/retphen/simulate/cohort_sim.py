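"""Whole-cohort simulation: every study input family from one seed.

``simulate_cohort`` draws per-subject biological truths from the effect
configuration, renders ERG luminance series, OCT boundary traces, stained
section images and assay plates, and records every truth in a manifest so
each analysis stage can be validated round-trip.  The entire bundle is a
pure function of (design, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..waveform import series_to_frame
from .config import CohortDesign, EffectConfig, default_effect_config
from .erg_sim import ErgTruth, simulate_series
from .ihc_sim import simulate_ihc_image
from .oct_sim import simulate_oct_boundaries
from .plate_sim import fourpl_curve_truth, linear_curve_truth, simulate_plate

__all__ = ["SimulatedCohort", "simulate_cohort", "simulate_endpoint_table"]

_TISSUE_ABETA_FACTOR = {("brain", "soluble"): 1.0, ("retina", "soluble"): 0.9,
                        ("brain", "insoluble"): 1.0, ("retina", "insoluble"): 0.3}
_SOLUBLE_DILUTION = {"brain": 20.0, "retina": 10.0}
INSOLUBLE_FACTOR = 400.0  # formic 1:4 × Tris 1:20 × PBS/casein 1:5


def _draw(rng: np.random.Generator, value: float, sd: float,
          relative: bool) -> float:
    """Biological variation: additive SD (homoscedastic) or, for endpoints
    spanning orders of magnitude, a multiplicative spread; truncated
    positive."""
    if sd <= 0:
        return value
    if relative:
        return float(value * max(0.05, 1.0 + rng.normal(0.0, sd)))
    return float(max(0.05 * value, value + rng.normal(0.0, sd)))


def _subject_truths(cfg: EffectConfig, genotype: str, age: int,
                    rng: np.random.Generator) -> dict:
    out = {}
    for name, eff in cfg.endpoints.items():
        out[name] = _draw(rng, eff.truth(genotype, age), eff.sd, eff.relative)
    return out


@dataclass
class SimulatedCohort:
    """In-memory bundle of all simulated inputs plus ground truth."""

    design: CohortDesign
    config: EffectConfig
    seed: int
    erg_series: list = field(default_factory=list)
    boundary_sets: list = field(default_factory=list)
    ihc_images: list = field(default_factory=list)  # (manifest row dict, array)
    plates: dict = field(default_factory=dict)  # name -> DataFrame
    truth: dict = field(default_factory=dict)  # subject_id -> truths

    def waves_frame(self) -> pd.DataFrame:
        return pd.concat(
            [series_to_frame(s) for s in self.erg_series], ignore_index=True
        )

    def boundaries_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.boundary_sets:
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": b.subject_id,
                        "genotype": b.genotype,
                        "age_months": b.age_months,
                        "eye": b.eye,
                        "ascan_index": np.arange(b.lateral_um.size),
                        "lateral_um": b.lateral_um,
                        "ilm_um": b.ilm_um,
                        "rnfl_post_um": b.rnfl_post_um,
                        "gcc_post_um": b.gcc_post_um,
                        "retina_post_um": b.retina_post_um,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def truth_endpoint_table(self, endpoints=("pstr", "rm_p3", "vmax", "op")) -> pd.DataFrame:
        rows = []
        for sid, t in self.truth.items():
            for ep in endpoints:
                if ep in t["endpoints"]:
                    rows.append(
                        {
                            "subject_id": sid,
                            "genotype": t["genotype"],
                            "age_months": t["age_months"],
                            "endpoint": ep,
                            "value": t["endpoints"][ep],
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> dict:
        """Write the bundle in the documented interchange formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        if self.erg_series:
            p = out / "waves.csv"
            self.waves_frame().to_csv(p, index=False)
            paths["waves"] = str(p)
        if self.boundary_sets:
            p = out / "boundaries.csv"
            self.boundaries_frame().to_csv(p, index=False)
            paths["boundaries"] = str(p)
        if self.ihc_images:
            import tifffile

            sec_dir = out / "sections"
            sec_dir.mkdir(exist_ok=True)
            rows = []
            for row, img in self.ihc_images:
                path = sec_dir / f"{row['image_id']}.tiff"
                tifffile.imwrite(path, img)
                rows.append({**row, "path": str(path)})
            p = out / "sections.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            paths["sections"] = str(p)
        for name, plate in self.plates.items():
            p = out / f"plate_{name}.csv"
            plate.to_csv(p, index=False)
            paths[f"plate_{name}"] = str(p)
        p = out / "truth.json"
        with open(p, "w") as fh:
            json.dump({"seed": self.seed, "subjects": self.truth}, fh, indent=1)
        paths["truth"] = str(p)
        return paths


def simulate_cohort(
    design: CohortDesign | None = None,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    modalities=("erg", "oct", "ihc", "assay"),
    n_ascans: int = 1000,
    ihc_image_shape: tuple[int, int] = (128, 128),
) -> SimulatedCohort:
    """Generate the full synthetic study from one seed."""
    design = design or CohortDesign()
    cfg = cfg or default_effect_config()
    root = np.random.SeedSequence([seed, 202309])
    bundle = SimulatedCohort(design=design, config=cfg, seed=seed)

    def record(sid, genotype, age, truths, modality):
        entry = bundle.truth.setdefault(
            sid,
            {"genotype": genotype, "age_months": age, "modalities": [],
             "endpoints": {}},
        )
        entry["modalities"].append(modality)
        entry["endpoints"].update(truths)

    if "erg" in modalities:
        for (genotype, age), n in design.cells("erg").items():
            for j in range(n):
                sid = f"ERG-{genotype}-{age}m-{j:02d}"
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 1, age, int(genotype == "5xFAD"), j])
                )
                t = _subject_truths(cfg, genotype, age, rng)
                truth = ErgTruth(
                    rm_p3=t["rm_p3"], s=t["s"], td=t["td"], vmax=t["vmax"],
                    k=t["k"], op_envelope_uv=t["op"], pstr_uv=t["pstr"],
                )
                series = simulate_series(
                    truth, cfg.energies, rng, cfg.waveform_noise_uv,
                    cfg.time_span_ms, cfg.sample_rate_hz,
                    subject_id=sid, genotype=genotype, age_months=age,
                )
                bundle.erg_series.append(series)
                record(sid, genotype, age,
                       {k: t[k] for k in ("rm_p3", "s", "td", "vmax", "k", "op", "pstr")},
                       "erg")

    if "oct" in modalities:
        for (genotype, age), n in design.cells("oct").items():
            for j in range(n):
                sid = f"OCT-{genotype}-{age}m-{j:02d}"
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 2, age, int(genotype == "5xFAD"), j])
                )
                t = _subject_truths(cfg, genotype, age, rng)
                th = {k: t[k] for k in ("rnfl", "ipl", "ort")}
                b = simulate_oct_boundaries(
                    th, rng, n_ascans=n_ascans,
                    axial_noise_sd_um=cfg.oct_axial_noise_um,
                    subject_id=sid, genotype=genotype, age_months=age,
                )
                bundle.boundary_sets.append(b)
                th["gcc"] = th["rnfl"] + th["ipl"]
                th["trt"] = th["gcc"] + th["ort"]
                record(sid, genotype, age, th, "oct")

    if "ihc" in modalities:
        for (genotype, age), n in design.cells("ihc").items():
            for j in range(n):
                sid = f"IHC-{genotype}-{age}m-{j:02d}"
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 3, age, int(genotype == "5xFAD"), j])
                )
                t = _subject_truths(cfg, genotype, age, rng)
                frac = min(t["stain_fraction"], 0.5)
                fractions = {}
                for location in ("cortex", "hippocampus"):
                    for section in range(3):
                        f_sec = min(1.0, frac * max(0.05, 1.0 + rng.normal(0, 0.1)))
                        img, count = simulate_ihc_image(
                            f_sec, rng, shape=ihc_image_shape,
                            stain_rgb=cfg.ihc_stain_rgb,
                            background_rgb=cfg.ihc_background_rgb,
                        )
                        image_id = f"{sid}-{location}-s{section}"
                        row = {
                            "image_id": image_id, "subject_id": sid,
                            "genotype": genotype, "age_months": age,
                            "location": location, "section_id": section,
                            "true_stained_pixels": count,
                            "true_fraction": count / img[..., 0].size,
                        }
                        bundle.ihc_images.append((row, img))
                        fractions[image_id] = count / img[..., 0].size
                record(sid, genotype, age,
                       {"stain_fraction": frac, "section_fractions": fractions},
                       "ihc")

    if "assay" in modalities:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        bca_samples, elisa_samples = [], []
        for (genotype, age) in design.cells("erg"):
            t = _subject_truths(cfg, genotype, age, rng)
            for tissue in ("brain", "retina"):
                for fraction in ("soluble", "insoluble"):
                    abeta = (
                        t[f"abeta_{fraction}"]
                        * _TISSUE_ABETA_FACTOR[(tissue, fraction)]
                    )
                    dil = (
                        _SOLUBLE_DILUTION[tissue]
                        if fraction == "soluble"
                        else INSOLUBLE_FACTOR
                    )
                    sid = f"{genotype}-{age}m-{tissue}-{fraction}"
                    protein = t["protein_mg_per_ml"]
                    pooled = 7 if tissue == "retina" else 1
                    bca_samples.append(
                        {"sample_id": sid, "concentration": protein,
                         "dilution_factor": _SOLUBLE_DILUTION[tissue],
                         "fraction": fraction, "tissue": tissue, "pooled_n": pooled}
                    )
                    elisa_samples.append(
                        {"sample_id": sid, "concentration": abeta,
                         "dilution_factor": dil, "fraction": fraction,
                         "tissue": tissue, "pooled_n": pooled}
                    )
                    bundle.truth.setdefault(
                        sid,
                        {"genotype": genotype, "age_months": age,
                         "modalities": ["assay"], "endpoints": {}},
                    )["endpoints"].update(
                        {"abeta_pg_per_ml": abeta, "protein_mg_per_ml": protein,
                         "abeta_pg_per_mg": abeta / protein}
                    )
        bca_truth = linear_curve_truth(conc_max=2.0)
        elisa_truth = fourpl_curve_truth()
        # dedupe BCA protein wells (same sample measured once per fraction)
        seen, bca_unique = set(), []
        for s in bca_samples:
            key = s["sample_id"].rsplit("-", 1)[0]
            if key not in seen:
                seen.add(key)
                bca_unique.append({**s, "sample_id": key})
        bundle.plates["bca"] = simulate_plate(
            bca_truth,
            [{**s, "concentration": min(s["concentration"],
                                        bca_truth.conc_range[1] * s["dilution_factor"])}
             for s in bca_unique],
            rng, cv=cfg.plate_cv,
        )
        elisa_in_range = []
        for s in elisa_samples:
            at_well = s["concentration"] / s["dilution_factor"]
            lo, hi = elisa_truth.conc_range
            at_well = min(max(at_well, lo), hi)
            elisa_in_range.append(
                {**s, "concentration": at_well * s["dilution_factor"]}
            )
        bundle.plates["elisa"] = simulate_plate(
            elisa_truth, elisa_in_range, rng, cv=cfg.plate_cv
        )
    return bundle


def simulate_endpoint_table(
    design: CohortDesign | None = None,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    endpoints=("pstr", "rm_p3", "vmax", "op"),
    modality: str = "erg",
) -> pd.DataFrame:
    """Endpoint-level cohort table drawn directly from the effect config.

    Skips waveform/image rendering; used for fast calibration studies
    (e.g. null false-positive rates) where only the biological layer
    matters.
    """
    design = design or CohortDesign()
    cfg = cfg or default_effect_config()
    rows = []
    for (genotype, age), n in design.cells(modality).items():
        for j in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 9, age, int(genotype == "5xFAD"), j])
            )
            t = _subject_truths(cfg, genotype, age, rng)
            sid = f"{modality.upper()}-{genotype}-{age}m-{j:02d}"
            for ep in endpoints:
                rows.append(
                    {"subject_id": sid, "genotype": genotype,
                     "age_months": age, "endpoint": ep, "value": t[ep]}
                )
    return pd.DataFrame(rows)
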