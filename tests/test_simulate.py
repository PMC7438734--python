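import numpy as np
import pytest

from retphen.erg import measure_str
from retphen.simulate import (
    CohortDesign,
    ErgTruth,
    default_effect_config,
    erg_components,
    simulate_cohort,
    simulate_endpoint_table,
    simulate_erg_waveform,
    simulate_ihc_image,
    simulate_oct_boundaries,
    simulate_series,
)
from retphen.waveform import LuminanceSeries


class TestSeededDeterminism:
    def test_waveform_bitwise(self):
        t = ErgTruth()
        w1 = simulate_erg_waveform(t, 2.07, seed_or_rng=42)
        w2 = simulate_erg_waveform(t, 2.07, seed_or_rng=42)
        assert np.array_equal(w1.amplitudes, w2.amplitudes)

    def test_boundaries_bitwise(self):
        kw = dict(n_ascans=200)
        b1 = simulate_oct_boundaries({"rnfl": 20, "ipl": 60, "ort": 140},
                                     seed_or_rng=5, **kw)
        b2 = simulate_oct_boundaries({"rnfl": 20, "ipl": 60, "ort": 140},
                                     seed_or_rng=5, **kw)
        assert np.array_equal(b1.rnfl_post_um, b2.rnfl_post_um)

    def test_image_bitwise(self):
        i1, _ = simulate_ihc_image(0.1, seed_or_rng=3, shape=(64, 64))
        i2, _ = simulate_ihc_image(0.1, seed_or_rng=3, shape=(64, 64))
        assert np.array_equal(i1, i2)

    def test_cohort_truth_reproducible(self):
        d = CohortDesign.uniform(2)
        b1 = simulate_cohort(d, seed=8, modalities=("erg",))
        b2 = simulate_cohort(d, seed=8, modalities=("erg",))
        assert b1.truth == b2.truth


class TestDesignAndEffects:
    def test_manifest_counts_match_design(self):
        d = CohortDesign.uniform(3)
        bundle = simulate_cohort(d, seed=1, modalities=("erg", "oct"), n_ascans=50)
        assert len(bundle.erg_series) == 3 * 6
        assert len(bundle.boundary_sets) == 3 * 6
        for (gen, age), n in d.cells("erg").items():
            got = [s for s in bundle.erg_series
                   if s.genotype == gen and s.age_months == age]
            assert len(got) == n

    def test_programmed_pstr_ratio_recovered(self):
        ratios = []
        for seed in range(10):
            t = simulate_endpoint_table(CohortDesign.uniform(12), seed=seed,
                                        endpoints=("pstr",))
            by = t.groupby("genotype")["value"].mean()
            ratios.append(by["5xFAD"] / by["WT"])
        assert np.mean(ratios) == pytest.approx(0.70, abs=0.03)

    def test_null_config_rarely_significant(self):
        from retphen.cohort import two_way_anova

        cfg = default_effect_config()
        cfg.endpoint("vmax").genotype_factor.update({6: 1.0, 12: 1.0, 17: 1.0})
        hits = 0
        for seed in range(60):
            t = simulate_endpoint_table(CohortDesign(), cfg, seed=seed,
                                        endpoints=("vmax",))
            hits += two_way_anova(t, "vmax").effects["genotype"]["p"] < 0.05
        assert hits / 60 < 0.15


class TestComponentTruths:
    def test_dim_flash_pstr_measured_exactly(self):
        t = ErgTruth(pstr_uv=25.0, pstr_time_ms=110.0)
        s = simulate_series(t, energies=(-5.31, -5.01, -4.90), seed_or_rng=0,
                            noise_sd=0.0)
        res = measure_str(s)
        assert res.pstr_amplitude == pytest.approx(25.0, rel=1e-3)
        assert res.pstr_implicit_time == pytest.approx(110.0, abs=0.3)

    def test_pstr_absent_at_bright_flashes(self):
        t = ErgTruth()
        times = np.linspace(-20, 250, 1081)
        comps = erg_components(t, 2.07, times)
        assert np.all(comps["pstr"] == 0.0)

    def test_components_sum_to_waveform(self):
        t = ErgTruth()
        w = simulate_erg_waveform(t, 0.15, seed_or_rng=0, noise_sd=0.0)
        comps = erg_components(t, 0.15, w.times)
        total = sum(comps.values())
        assert np.allclose(w.amplitudes, total, atol=1e-12)

    def test_infeasible_area_fraction_errors(self):
        with pytest.raises(ValueError):
            simulate_ihc_image(1.5)


class TestOctGenerator:
    def test_zero_noise_exact(self):
        from retphen.oct import derive_thicknesses

        b = simulate_oct_boundaries({"rnfl": 18.4, "ipl": 63.6, "ort": 140.0},
                                    axial_noise_sd_um=0.0, n_ascans=400)
        p = derive_thicknesses(b)
        assert p.rnfl == pytest.approx(18.4, abs=1e-9)
        assert p.ipl == pytest.approx(63.6, abs=1e-9)
        assert p.ort == pytest.approx(140.0, abs=1e-9)

    def test_noisy_mean_within_sem(self):
        from retphen.oct import derive_thicknesses

        devs = [
            derive_thicknesses(
                simulate_oct_boundaries({"rnfl": 20.0, "ipl": 60.0, "ort": 140.0},
                                        seed_or_rng=s, axial_noise_sd_um=2.0,
                                        n_ascans=1000)
            ).rnfl - 20.0
            for s in range(10)
        ]
        assert np.max(np.abs(devs)) < 0.3  # ~4 SEM of 2 μm / sqrt(850)


class TestSeriesStructure:
    def test_series_shares_time_base(self):
        s = simulate_series(ErgTruth(), seed_or_rng=0, noise_sd=1.0)
        assert isinstance(s, LuminanceSeries)
        assert len(s) == 10
        assert all(w.same_time_base(s.waveforms[0]) for w in s)
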