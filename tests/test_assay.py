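import numpy as np
import pytest

from retphen.assay import (
    AssaySample,
    StandardSeries,
    detection_limit,
    fit_standard_curve,
    insoluble_dilution_chain,
    interpolate_concentration,
    normalize_abeta,
)
from retphen.simulate import fourpl_curve_truth, linear_curve_truth, simulate_plate


class TestStandardCurves:
    def test_linear_standards_recovered_exactly(self):
        conc = np.array([0.0, 0.5, 1.0, 2.0])
        series = StandardSeries(conc, 0.05 + 0.4 * conc)
        curve = fit_standard_curve(series, "linear")
        assert curve.coefficients[0] == pytest.approx(0.05, abs=1e-9)
        assert curve.coefficients[1] == pytest.approx(0.4, abs=1e-9)

    def test_interpolation_identity_at_standard_level(self):
        conc = np.array([0.0, 0.5, 1.0, 2.0])
        series = StandardSeries(conc, 0.05 + 0.4 * conc)
        curve = fit_standard_curve(series, "linear")
        assert curve.concentration(float(curve.signal(0.5))) == pytest.approx(0.5)

    def test_quadratic_round_trip(self):
        conc = np.linspace(0, 2, 6)
        series = StandardSeries(conc, 0.02 + 0.5 * conc - 0.05 * conc**2)
        curve = fit_standard_curve(series, "quadratic")
        for c in (0.3, 1.1, 1.9):
            assert curve.concentration(float(curve.signal(c))) == pytest.approx(
                c, abs=1e-6
            )

    def test_non_monotone_curve_errors(self):
        conc = np.linspace(0, 2, 6)
        series = StandardSeries(conc, 1.0 * conc - 0.4 * conc**2)  # peaks inside
        with pytest.raises(ValueError, match="monotone"):
            fit_standard_curve(series, "quadratic")

    def test_4pl_parameter_recovery_over_seeds(self):
        """4PL standards with 2% read noise: median recovered parameters
        within 1% of truth over 50 seeds.  The ladder includes a zero well
        and a saturating top standard so both asymptotes are anchored."""
        truth = fourpl_curve_truth()
        ladder = np.concatenate([[0.0], np.geomspace(15.6, 32000.0, 9)])
        recovered = []
        for seed in range(50):
            plate = simulate_plate(truth, [], seed_or_rng=seed, cv=0.02,
                                   standards=ladder)
            std = plate[plate["role"] == "standard"]
            series = StandardSeries(std["known_concentration"].to_numpy(),
                                    std["signal"].to_numpy(), assay="ELISA")
            curve = fit_standard_curve(series, "4pl")
            recovered.append(curve.coefficients)
        rec = np.array(recovered)
        for j, true_val in enumerate(truth.coefficients):
            med = np.median(rec[:, j])
            assert abs(med - true_val) / abs(true_val) < 0.01


class TestInterpolation:
    def _curve(self):
        conc = np.array([0.0, 0.5, 1.0, 2.0])
        return fit_standard_curve(StandardSeries(conc, 0.05 + 0.4 * conc), "linear")

    def test_dilution_correction(self):
        curve = self._curve()
        sig = float(curve.signal(0.5))
        res = interpolate_concentration(
            curve, AssaySample(signals=(sig, sig), dilution_factor=10.0)
        )
        assert res["flag"] == "ok"
        assert res["concentration"] == pytest.approx(5.0)

    def test_signal_at_top_standard(self):
        curve = self._curve()
        sig = float(curve.signal(2.0))
        res = interpolate_concentration(
            curve, AssaySample(signals=(sig,), dilution_factor=4.0)
        )
        assert res["concentration"] == pytest.approx(8.0)

    def test_below_detection_flag(self):
        curve = self._curve()
        res = interpolate_concentration(
            curve, AssaySample(signals=(0.01,), dilution_factor=1.0)
        )
        assert res["flag"] == "below_detection"
        assert np.isnan(res["concentration"])

    def test_dilution_linearity(self):
        curve = self._curve()
        sig = float(curve.signal(0.8))
        c1 = interpolate_concentration(
            curve, AssaySample(signals=(sig,), dilution_factor=1.0)
        )["concentration"]
        c20 = interpolate_concentration(
            curve, AssaySample(signals=(sig,), dilution_factor=20.0)
        )["concentration"]
        assert c20 == pytest.approx(20.0 * c1)


class TestDilutionAndNormalization:
    @pytest.mark.parametrize("chain,expected", [
        ([(1, 4)], 4.0),
        ([(1, 4), (1, 20), (1, 5)], 400.0),
        ([], 1.0),
    ])
    def test_dilution_chain(self, chain, expected):
        assert insoluble_dilution_chain(chain) == expected

    def test_insoluble_chain_matches_stated_volumes(self):
        # 5 μl into 20 (1:4), then 1:20, then 1:5 -> ×400 overall
        assert insoluble_dilution_chain() == 400.0

    def test_invalid_ratio_errors(self):
        with pytest.raises(ValueError):
            insoluble_dilution_chain([(0, 4)])

    def test_pg_per_mg(self):
        assert normalize_abeta(500.0, 0.5).pg_per_mg == pytest.approx(1000.0)
        assert normalize_abeta(0.0, 0.5).pg_per_mg == 0.0

    def test_ratio_invariance(self):
        a = normalize_abeta(500.0, 0.5).pg_per_mg
        b = normalize_abeta(1000.0, 1.0).pg_per_mg
        assert a == b

    def test_nonpositive_protein_errors(self):
        with pytest.raises(ValueError):
            normalize_abeta(500.0, 0.0)

    def test_detection_limit_rule(self):
        sig = [1.0, 1.2, 0.8, 1.0]
        expected = np.mean(sig) + 3 * np.std(sig, ddof=1)
        assert detection_limit(sig) == pytest.approx(expected)


class TestPlateRoundTrip:
    def test_zero_noise_round_trip(self):
        truth = linear_curve_truth()
        samples = [
            {"sample_id": "a", "concentration": 5.0, "dilution_factor": 10.0},
            {"sample_id": "b", "concentration": 12.0, "dilution_factor": 20.0},
        ]
        plate = simulate_plate(truth, samples, cv=0.0)
        std = plate[plate["role"] == "standard"]
        curve = fit_standard_curve(
            StandardSeries(std["known_concentration"].to_numpy(),
                           std["signal"].to_numpy()),
            "linear",
        )
        for s in samples:
            g = plate[plate["sample_id"] == s["sample_id"]]
            res = interpolate_concentration(
                curve,
                AssaySample(signals=tuple(g["signal"]),
                            dilution_factor=s["dilution_factor"]),
            )
            assert res["concentration"] == pytest.approx(s["concentration"], abs=1e-6)

    def test_noisy_median_recovery_within_5pct(self):
        truth = linear_curve_truth()
        errs = []
        for seed in range(50):
            plate = simulate_plate(
                truth,
                [{"sample_id": "a", "concentration": 8.0, "dilution_factor": 10.0}],
                seed_or_rng=seed, cv=0.02,
            )
            std = plate[plate["role"] == "standard"]
            curve = fit_standard_curve(
                StandardSeries(std["known_concentration"].to_numpy(),
                               std["signal"].to_numpy()),
                "linear",
            )
            g = plate[plate["sample_id"] == "a"]
            res = interpolate_concentration(
                curve, AssaySample(signals=tuple(g["signal"]), dilution_factor=10.0)
            )
            errs.append(abs(res["concentration"] - 8.0) / 8.0)
        assert np.median(errs) < 0.05

    def test_same_seed_identical_plate(self):
        truth = linear_curve_truth()
        p1 = simulate_plate(truth, [], seed_or_rng=9, cv=0.02)
        p2 = simulate_plate(truth, [], seed_or_rng=9, cv=0.02)
        assert p1.equals(p2)
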