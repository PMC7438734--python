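"""Pipeline orchestration: validated I/O, configuration and full-study runs.

Stages (any subset, or the full simulate → analyse → statistics chain) are
driven by a :class:`RunConfig` that round-trips losslessly through YAML;
every run writes its resolved configuration and a manifest (seed, config
hash, outputs) next to the results so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay as assay_mod
from . import cohort as cohort_mod
from . import histology as histo_mod
from . import oct as oct_mod
from .erg import DecomposeConfig, decompose_cohort
from .simulate import CohortDesign, default_effect_config, simulate_cohort
from .waveform import read_waves_csv

__all__ = ["RunConfig", "validate_table", "run_pipeline", "TABLE_SCHEMAS"]

log = logging.getLogger("retphen")

TABLE_SCHEMAS = {
    "waves": {
        "required": ["subject_id", "genotype", "age_months", "eye",
                     "energy_log_cd_s_m2", "time_ms", "amplitude_uV"],
        "numeric": ["age_months", "energy_log_cd_s_m2", "time_ms", "amplitude_uV"],
    },
    "boundaries": {
        "required": ["subject_id", "genotype", "age_months", "eye", "ascan_index",
                     "ilm_um", "rnfl_post_um", "gcc_post_um", "retina_post_um"],
        "numeric": ["age_months", "ascan_index", "ilm_um", "rnfl_post_um",
                    "gcc_post_um", "retina_post_um"],
    },
    "sections": {
        "required": ["path", "subject_id", "genotype", "age_months",
                     "location", "section_id"],
        "numeric": ["age_months"],
    },
    "plate": {
        "required": ["well", "role", "known_concentration", "signal",
                     "dilution_factor", "sample_id"],
        "numeric": ["known_concentration", "signal", "dilution_factor"],
    },
    "cohort": {
        "required": ["subject_id", "genotype", "age_months", "endpoint", "value"],
        "numeric": ["age_months", "value"],
        "unique": ["subject_id", "endpoint"],
    },
}


def validate_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the documented schemas.

    Errors name the file, the offending column and (for cell-level
    problems) the first offending row.
    """
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path)
    problems = []
    for col in spec["required"]:
        if col not in df.columns:
            problems.append(f"{path}: missing required column {col!r}")
    if problems:
        raise ValueError("; ".join(problems))
    for col in spec.get("numeric", []):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            problems.append(
                f"{path}: column {col!r} row {row} has non-numeric value "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = coerced
    if "unique" in spec:
        dup = df.duplicated(subset=spec["unique"])
        if dup.any():
            row = int(dup.idxmax())
            problems.append(
                f"{path}: duplicated {spec['unique']} at row {row}"
            )
    if problems:
        raise ValueError("; ".join(problems))
    return df


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    stages: list = field(default_factory=lambda: ["simulate", "erg", "oct",
                                                  "ihc", "assay", "stats"])
    seed: int = 0
    out_dir: str = "retphen_out"
    # input paths (ignored for stages fed by an in-run simulate)
    waves: str | None = None
    boundaries: str | None = None
    sections: str | None = None
    plate_bca: str | None = None
    plate_elisa: str | None = None
    # stage parameters
    erg: dict = field(default_factory=dict)  # DecomposeConfig overrides
    oct_exclusion_um: float = 100.0
    ihc_threshold: dict = field(default_factory=lambda: {
        "hue": [10.0, 50.0], "saturation": [0.15, 1.0], "intensity": [0.0, 0.85]})
    bca_form: str = "linear"
    elisa_form: str = "4pl"
    reference: list = field(default_factory=lambda: ["WT", 6])
    alpha: float = 0.05
    sim_n_per_cell: int | None = None  # None -> the study's group sizes
    sim_n_ascans: int = 200
    sim_image_px: int = 96

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                      "outputs": {}}
    cohort_frames: list[pd.DataFrame] = []
    try:
        paths = {"waves": cfg.waves, "boundaries": cfg.boundaries,
                 "sections": cfg.sections, "plate_bca": cfg.plate_bca,
                 "plate_elisa": cfg.plate_elisa}

        if "simulate" in cfg.stages:
            log.info("stage simulate: seed=%d", cfg.seed)
            design = (
                CohortDesign.uniform(cfg.sim_n_per_cell)
                if cfg.sim_n_per_cell
                else CohortDesign()
            )
            bundle = simulate_cohort(
                design, default_effect_config(), seed=cfg.seed,
                n_ascans=cfg.sim_n_ascans,
                ihc_image_shape=(cfg.sim_image_px, cfg.sim_image_px),
            )
            written = bundle.write(out / "inputs")
            paths.update(
                {
                    "waves": written.get("waves"),
                    "boundaries": written.get("boundaries"),
                    "sections": written.get("sections"),
                    "plate_bca": written.get("plate_bca"),
                    "plate_elisa": written.get("plate_elisa"),
                }
            )
            manifest["outputs"]["inputs"] = written

        if "erg" in cfg.stages and paths["waves"]:
            log.info("stage erg: %s", paths["waves"])
            validate_table(paths["waves"], "waves")
            series = read_waves_csv(paths["waves"])
            dcfg = DecomposeConfig(**_tuplify(cfg.erg)) if cfg.erg else DecomposeConfig()
            erg_table = decompose_cohort(series, dcfg)
            p = out / "erg_params.csv"
            erg_table.to_csv(p, index=False)
            manifest["outputs"]["erg"] = str(p)
            long = erg_table.melt(
                id_vars=["subject_id", "genotype", "age_months", "eye"],
                value_vars=[c for c in erg_table.columns if c in (
                    "rm_p3", "p3_sensitivity", "vmax", "p2_sensitivity",
                    "op_amplitude", "op_implicit_time",
                    "pstr_amplitude", "pstr_implicit_time")],
                var_name="endpoint", value_name="value",
            )
            cohort_frames.append(long)

        if "oct" in cfg.stages and paths["boundaries"]:
            log.info("stage oct: %s", paths["boundaries"])
            validate_table(paths["boundaries"], "boundaries")
            bsets = oct_mod.read_boundaries_csv(paths["boundaries"])
            thick = oct_mod.derive_thickness_table(bsets, cfg.oct_exclusion_um)
            pct = oct_mod.normalize_profiles(thick, tuple(cfg.reference))
            merged = thick.merge(
                pct, on=["subject_id", "genotype", "age_months", "eye"],
                suffixes=("", "_pct"),
            )
            p = out / "thickness.csv"
            merged.to_csv(p, index=False)
            manifest["outputs"]["oct"] = str(p)
            long = thick.melt(
                id_vars=["subject_id", "genotype", "age_months", "eye"],
                value_vars=oct_mod.THICKNESS_ENDPOINTS,
                var_name="endpoint", value_name="value",
            )
            cohort_frames.append(long)

        if "ihc" in cfg.stages and paths["sections"]:
            log.info("stage ihc: %s", paths["sections"])
            manifest_df = validate_table(paths["sections"], "sections")
            thr = histo_mod.HsiThreshold(**_tuplify(cfg.ihc_threshold))
            per_image = []
            for _, row in manifest_df.iterrows():
                img = _read_image(row["path"])
                res = histo_mod.threshold_stain(img, thr)
                per_image.append(
                    {**row.to_dict(), "stained_pixels": res.stained_pixels,
                     "total_pixels": res.total_pixels,
                     "percent_area": res.percent_area}
                )
            per_image = pd.DataFrame(per_image)
            per_animal = (
                per_image.groupby(
                    ["subject_id", "genotype", "age_months", "location"]
                )["percent_area"].mean().reset_index()
            )
            p = out / "ihc_area.csv"
            per_image.to_csv(p, index=False)
            pa = out / "ihc_area_per_animal.csv"
            per_animal.to_csv(pa, index=False)
            tg = per_animal[per_animal["genotype"] == "5xFAD"]
            reg = (
                histo_mod.regress_burden_on_age(
                    tg[["age_months", "percent_area"]].to_numpy()
                )
                if len(tg) >= 3 and tg["age_months"].nunique() >= 2
                else None
            )
            with open(out / "ihc_regression.json", "w") as fh:
                json.dump(reg, fh, indent=1)
            manifest["outputs"]["ihc"] = str(p)

        if "assay" in cfg.stages and paths["plate_bca"] and paths["plate_elisa"]:
            log.info("stage assay")
            abeta = _assay_stage(paths, cfg)
            p = out / "abeta.csv"
            abeta.to_csv(p, index=False)
            manifest["outputs"]["assay"] = str(p)

        if "stats" in cfg.stages and cohort_frames:
            log.info("stage stats")
            cohort = pd.concat(cohort_frames, ignore_index=True)
            pc = out / "endpoints.csv"
            cohort.to_csv(pc, index=False)
            report = {}
            for ep in sorted(cohort["endpoint"].unique()):
                try:
                    report[ep] = cohort_mod.cohort_report(
                        cohort, alpha=cfg.alpha, endpoints=[ep]
                    )[ep]
                except ValueError as err:
                    report[ep] = {"error": str(err)}
            normalized = cohort_mod.normalize_to_baseline(
                cohort.dropna(subset=["value"]),
                (cfg.reference[0], cfg.reference[1]),
            )
            normalized.to_csv(out / "endpoints_percent.csv", index=False)
            p = out / "stats.json"
            with open(p, "w") as fh:
                json.dump(report, fh, indent=1, default=float)
            manifest["outputs"]["stats"] = str(p)
    finally:
        log.removeHandler(handler)
        handler.close()

    cfg.to_yaml(out / "resolved_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _read_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def _assay_stage(paths: dict, cfg: RunConfig) -> pd.DataFrame:
    bca = validate_table(paths["plate_bca"], "plate")
    elisa = validate_table(paths["plate_elisa"], "plate")

    def curve_from(plate: pd.DataFrame, form: str, assay: str):
        std = plate[plate["role"] == "standard"]
        series = assay_mod.StandardSeries(
            std["known_concentration"].to_numpy(float),
            std["signal"].to_numpy(float),
            assay=assay,
        )
        return assay_mod.fit_standard_curve(series, form)

    def samples_from(plate: pd.DataFrame, curve) -> pd.DataFrame:
        rows = []
        for sid, g in plate[plate["role"] == "sample"].groupby("sample_id"):
            s = assay_mod.AssaySample(
                signals=tuple(g["signal"]),
                dilution_factor=float(g["dilution_factor"].iloc[0]),
                fraction=str(g["fraction"].iloc[0]) if "fraction" in g else "",
                tissue=str(g["tissue"].iloc[0]) if "tissue" in g else "",
                pooled_n=int(g["pooled_n"].iloc[0]) if "pooled_n" in g else 1,
                sample_id=str(sid),
            )
            rows.append(assay_mod.interpolate_concentration(curve, s))
        return pd.DataFrame(rows)

    bca_curve = curve_from(bca, cfg.bca_form, "BCA")
    elisa_curve = curve_from(elisa, cfg.elisa_form, "ELISA")
    protein = samples_from(bca, bca_curve).rename(
        columns={"concentration": "protein_mg_per_ml", "flag": "protein_flag",
                 "cv": "protein_cv"}
    )
    abeta = samples_from(elisa, elisa_curve).rename(
        columns={"concentration": "abeta_pg_per_ml", "flag": "abeta_flag",
                 "cv": "abeta_cv"}
    )
    # ELISA sample ids carry the fraction; BCA protein is per tissue sample
    abeta["bca_key"] = abeta["sample_id"].str.rsplit("-", n=1).str[0]
    merged = abeta.merge(
        protein, left_on="bca_key", right_on="sample_id",
        suffixes=("", "_bca"), how="left",
    )
    out_rows = []
    for _, r in merged.iterrows():
        if r["abeta_flag"] == "ok" and r.get("protein_flag") == "ok":
            norm = assay_mod.normalize_abeta(
                r["abeta_pg_per_ml"], r["protein_mg_per_ml"],
                provenance={"elisa_curve": elisa_curve.form,
                            "bca_curve": bca_curve.form},
            ).pg_per_mg
        else:
            norm = float("nan")
        out_rows.append(
            {"sample_id": r["sample_id"], "abeta_pg_per_ml": r["abeta_pg_per_ml"],
             "abeta_flag": r["abeta_flag"],
             "protein_mg_per_ml": r.get("protein_mg_per_ml", float("nan")),
             "protein_flag": r.get("protein_flag", "missing"),
             "abeta_pg_per_mg": norm}
        )
    return pd.DataFrame(out_rows)
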