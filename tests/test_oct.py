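import numpy as np
import pandas as pd
import pytest

from retphen.oct import (
    BoundarySet,
    derive_thicknesses,
    derive_thickness_table,
    normalize_profiles,
)
from retphen.simulate import simulate_oct_boundaries

TRUTH = {"rnfl": 20.0, "ipl": 60.0, "ort": 140.0}


def _flat_boundaries(rnfl=20.0, gcc=80.0, trt=220.0, n=200):
    lateral = np.linspace(0, 1400.0, n)
    ilm = np.full(n, 50.0)
    return BoundarySet(
        lateral_um=lateral,
        ilm_um=ilm,
        rnfl_post_um=ilm + rnfl,
        gcc_post_um=ilm + gcc,
        retina_post_um=ilm + trt,
    )


class TestDeriveThicknesses:
    def test_flat_bands_subtraction_identities(self):
        p = derive_thicknesses(_flat_boundaries())
        assert (p.rnfl, p.ipl, p.gcc, p.ort, p.trt) == (20.0, 60.0, 80.0, 140.0, 220.0)

    def test_coincident_boundaries_zero_ipl(self):
        p = derive_thicknesses(_flat_boundaries(rnfl=20.0, gcc=20.0))
        assert p.ipl == 0.0

    def test_ordering_violation_names_ascan(self):
        b = _flat_boundaries()
        b.gcc_post_um[17] = b.retina_post_um[17] + 5.0
        with pytest.raises(ValueError, match="17"):
            b._check_ordering()

    def test_identities_machine_precision_on_simulated(self):
        for seed in range(5):
            b = simulate_oct_boundaries(TRUTH, seed_or_rng=seed, n_ascans=300)
            p = derive_thicknesses(b)
            assert p.ipl == p.gcc - p.rnfl
            assert p.ort == p.trt - p.gcc

    def test_zero_noise_recovers_truth_exactly(self):
        b = simulate_oct_boundaries(TRUTH, axial_noise_sd_um=0.0, n_ascans=500)
        p = derive_thicknesses(b)
        assert p.rnfl == pytest.approx(20.0, abs=1e-9)
        assert p.ipl == pytest.approx(60.0, abs=1e-9)
        assert p.trt == pytest.approx(220.0, abs=1e-9)

    def test_noise_recovery_within_sem(self):
        b = simulate_oct_boundaries(TRUTH, seed_or_rng=11, axial_noise_sd_um=2.0,
                                    n_ascans=1000)
        p = derive_thicknesses(b)
        # SEM of a 2 μm-noise mean over ~850 included A-scans << 0.2 μm
        assert p.rnfl == pytest.approx(20.0, abs=0.3)
        assert p.trt == pytest.approx(220.0, abs=0.3)

    def test_sinusoidal_thickness_undulation_mean_recovered(self):
        n = 1000
        lateral = np.linspace(0, 1400.0, n)
        ilm = np.full(n, 50.0)
        # RNFL thickness undulates ±4 μm over full periods: mean stays 20
        rnfl = 20.0 + 4.0 * np.sin(2 * np.pi * lateral / 350.0)
        b = BoundarySet(lateral, ilm, ilm + rnfl, ilm + 80.0, ilm + 220.0)
        p = derive_thicknesses(b, exclusion_zone_um=0.0)
        assert p.rnfl == pytest.approx(20.0, abs=1.4)  # half the 2.8 μm axial scale

    def test_inflating_posterior_boundary_shifts_trt_and_ort_only(self):
        b = _flat_boundaries()
        base = derive_thicknesses(b)
        b2 = BoundarySet(b.lateral_um, b.ilm_um, b.rnfl_post_um, b.gcc_post_um,
                         b.retina_post_um + 10.0)
        inflated = derive_thicknesses(b2)
        assert inflated.trt == base.trt + 10.0
        assert inflated.ort == base.ort + 10.0
        assert inflated.rnfl == base.rnfl and inflated.gcc == base.gcc


class TestNormalizeProfiles:
    def _table(self):
        rows = []
        for i, (gen, age, rnfl) in enumerate(
            [("WT", 6, 20.0), ("WT", 6, 22.0), ("5xFAD", 6, 10.5),
             ("WT", 12, 42.0)]
        ):
            rows.append({"subject_id": f"s{i}", "genotype": gen, "age_months": age,
                         "eye": "OD", "rnfl": rnfl, "ipl": 60.0, "gcc": 80.0,
                         "ort": 140.0, "trt": 220.0})
        return pd.DataFrame(rows)

    def test_reference_mean_maps_to_100(self):
        out = normalize_profiles(self._table())
        ref = out[(out["genotype"] == "WT") & (out["age_months"] == 6)]
        assert ref["rnfl"].mean() == pytest.approx(100.0)

    def test_half_reference_is_50(self):
        out = normalize_profiles(self._table())
        assert out.loc[2, "rnfl"] == pytest.approx(50.0)

    def test_double_reference_is_200(self):
        out = normalize_profiles(self._table())
        assert out.loc[3, "rnfl"] == pytest.approx(200.0)

    def test_idempotent_on_reference_mean(self):
        once = normalize_profiles(self._table())
        twice = normalize_profiles(once)
        ref = twice[(twice["genotype"] == "WT") & (twice["age_months"] == 6)]
        assert ref["rnfl"].mean() == pytest.approx(100.0)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_profiles(self._table(), reference=("WT", 17))

    def test_programmed_genotype_effect_recovered(self):
        from retphen.simulate import CohortDesign, default_effect_config, simulate_cohort

        bundle = simulate_cohort(
            CohortDesign.uniform(12), default_effect_config(), seed=5,
            modalities=("oct",), n_ascans=200,
        )
        thick = derive_thickness_table(bundle.boundary_sets)
        pct = normalize_profiles(thick)
        fad = pct[pct["genotype"] == "5xFAD"]["rnfl"].mean()
        assert fad == pytest.approx(92.0, abs=2.5)  # programmed −8%
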