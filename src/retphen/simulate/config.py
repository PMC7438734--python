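"""Effect configuration for the synthetic study cohort.

The generator emulates a 5xFAD vs wild-type ageing study (6/12/17 months)
with programmable per-endpoint effects.  Each endpoint has a 6-month WT
baseline, a multiplicative genotype factor per age (applied to transgenics),
a multiplicative age factor per age (applied to everyone) and a biological
noise SD in the endpoint's units (between-animal spread, homoscedastic
across cells as the ANOVA assumes).  The frozen defaults encode the study
pattern this package is designed around:

* pSTR amplitude −30% in 5xFAD at every age (the earliest deficit);
* P3 (RmP3), P2 (Vmax) and OP amplitudes −20% in 5xFAD at 17 months only;
* a 10%-per-period age decline of ERG amplitudes in both genotypes;
* RNFL −8% in 5xFAD at every age; IPL +6% at 6 months; ORT/sensitivities
  unaffected.

Biological SDs (≈8–10% of baseline for ERG amplitudes, ≈3% for layer
thicknesses) and the measurement-noise levels are fixed study conditions,
chosen once from the power the real study evidently had (it resolved these
effect sizes at n ≈ 8–16 per cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EndpointEffect", "EffectConfig", "CohortDesign", "default_effect_config"]

AGES = (6, 12, 17)

#: default stimulus ladder, log cd·s/m²: includes exactly the dim STR triple
#: and reaches the protocol maximum of 2.07
ENERGY_LADDER = (-5.31, -5.01, -4.90, -3.81, -2.81, -1.81, -0.81, 0.15, 1.15, 2.07)


@dataclass(frozen=True)
class EndpointEffect:
    baseline: float  # 6-month WT value
    genotype_factor: dict = field(default_factory=dict)  # age -> multiplier (5xFAD)
    age_factor: dict = field(default_factory=dict)  # age -> multiplier (both)
    sd: float = 0.0  # between-animal biological noise SD (endpoint units)
    relative: bool = False  # True: sd acts as a CV (multiplicative spread),
    # used for endpoints spanning orders of magnitude (stain area, Aβ)

    def truth(self, genotype: str, age: int) -> float:
        v = self.baseline * self.age_factor.get(age, 1.0)
        if genotype not in ("WT", "5xFAD"):
            raise ValueError(f"unknown genotype {genotype!r}")
        if genotype == "5xFAD":
            v *= self.genotype_factor.get(age, 1.0)
        return v


def _flat(x: float) -> dict:
    return {a: x for a in AGES}


_ERG_AGE_DECLINE = {6: 1.0, 12: 0.9, 17: 0.81}  # 10% per examination period
_LATE_ONLY = {6: 1.0, 12: 1.0, 17: 0.80}


@dataclass
class EffectConfig:
    """All programmable truths of the synthetic study."""

    ages: tuple = AGES
    energies: tuple = ENERGY_LADDER
    endpoints: dict = field(default_factory=dict)
    # measurement-layer noise (distinct from biological CV)
    waveform_noise_uv: float = 5.0
    oct_axial_noise_um: float = 2.0
    plate_cv: float = 0.02
    sample_rate_hz: float = 4000.0
    time_span_ms: tuple = (-20.0, 250.0)
    ihc_stain_rgb: tuple = (150, 90, 40)  # DAB brown, inside the default gamut
    ihc_background_rgb: tuple = (130, 120, 180)  # haematoxylin blue

    def endpoint(self, name: str) -> EndpointEffect:
        return self.endpoints[name]


def default_effect_config() -> EffectConfig:
    cfg = EffectConfig()
    cfg.endpoints = {
        # --- ERG component truths (SDs ≈ 8–10% of the 6-month WT baseline)
        "rm_p3": EndpointEffect(400.0, dict(_LATE_ONLY), dict(_ERG_AGE_DECLINE), 32.0),
        "s": EndpointEffect(2.0e-3, _flat(1.0), _flat(1.0), 1.6e-4),
        "td": EndpointEffect(4.0, _flat(1.0), _flat(1.0), 0.2),
        "vmax": EndpointEffect(500.0, dict(_LATE_ONLY), dict(_ERG_AGE_DECLINE), 40.0),
        "k": EndpointEffect(0.05, _flat(1.0), _flat(1.0), 0.005),
        "op": EndpointEffect(40.0, dict(_LATE_ONLY), dict(_ERG_AGE_DECLINE), 3.2),
        "pstr": EndpointEffect(25.0, _flat(0.70), dict(_ERG_AGE_DECLINE), 2.5),
        # --- OCT layer truths, μm (SDs ≈ 3% of baseline)
        "rnfl": EndpointEffect(20.0, _flat(0.92), _flat(1.0), 0.6),
        "ipl": EndpointEffect(60.0, {6: 1.06, 12: 1.0, 17: 1.0}, _flat(1.0), 1.8),
        "ort": EndpointEffect(140.0, _flat(1.0), _flat(1.0), 4.2),
        # --- IHC stain area fraction (cortex/hippocampus composite); spans
        # orders of magnitude between genotypes, so the spread is relative
        "stain_fraction": EndpointEffect(
            0.0005,  # WT background
            {6: 20.0, 12: 50.0, 17: 80.0},  # 5xFAD burden grows with age
            _flat(1.0),
            0.25, relative=True,
        ),
        # --- assay truths (pg/ml Aβ at the well; mg/ml protein)
        "protein_mg_per_ml": EndpointEffect(2.0, _flat(1.0), _flat(1.0), 0.2),
        "abeta_soluble": EndpointEffect(
            1.0, {6: 400.0, 12: 600.0, 17: 800.0}, _flat(1.0), 0.15, relative=True
        ),
        "abeta_insoluble": EndpointEffect(
            1.0, {6: 1500.0, 12: 2500.0, 17: 2000.0}, _flat(1.0), 0.15, relative=True
        ),
    }
    return cfg


@dataclass(frozen=True)
class CohortDesign:
    """Per-cell sample sizes, keyed (genotype, age) -> n eyes.

    Defaults mirror the source study's reported group sizes: ERG 5xFAD
    n = 8/12/12 and WT n = 11/12/15 at 6/12/17 months; OCT 5xFAD 8/12/14 and
    WT 13/13/16.
    """

    erg_n: tuple = ((("5xFAD", 6), 8), (("5xFAD", 12), 12), (("5xFAD", 17), 12),
                    (("WT", 6), 11), (("WT", 12), 12), (("WT", 17), 15))
    oct_n: tuple = ((("5xFAD", 6), 8), (("5xFAD", 12), 12), (("5xFAD", 17), 14),
                    (("WT", 6), 13), (("WT", 12), 13), (("WT", 17), 16))
    ihc_n: tuple = ((("5xFAD", 6), 3), (("5xFAD", 12), 3), (("5xFAD", 17), 3),
                    (("WT", 6), 1), (("WT", 12), 1), (("WT", 17), 1))

    def cells(self, modality: str):
        return dict(getattr(self, f"{modality}_n"))

    @staticmethod
    def uniform(n: int, modalities=("erg", "oct", "ihc")) -> "CohortDesign":
        cells = tuple(
            ((g, a), n) for g in ("5xFAD", "WT") for a in AGES
        )
        kw = {f"{m}_n": cells for m in modalities}
        return CohortDesign(**kw)
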