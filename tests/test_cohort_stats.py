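import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retphen.cohort import (
    GenotypeAgeAnova,
    bonferroni_posthoc,
    ks_normality,
    normalize_to_baseline,
    two_way_anova,
)
from retphen.simulate import CohortDesign, default_effect_config, simulate_endpoint_table


def _table(cells: dict, endpoint="e") -> pd.DataFrame:
    rows, k = [], 0
    for (gen, age), vals in cells.items():
        for v in vals:
            rows.append({"subject_id": f"s{k}", "genotype": gen,
                         "age_months": age, "endpoint": endpoint,
                         "value": float(v)})
            k += 1
    return pd.DataFrame(rows)


def _balanced_ss_oracle(cells: dict):
    """Classical balanced two-way sums of squares from cell means."""
    gens = sorted({g for g, _ in cells})
    ages = sorted({a for _, a in cells})
    n = len(next(iter(cells.values())))
    allv = np.concatenate([np.asarray(v, float) for v in cells.values()])
    gm = allv.mean()
    gmean = {g: np.mean([np.mean(cells[(g, a)]) for a in ages]) for g in gens}
    amean = {a: np.mean([np.mean(cells[(g, a)]) for g in gens]) for a in ages}
    ss_g = n * len(ages) * sum((gmean[g] - gm) ** 2 for g in gens)
    ss_a = n * len(gens) * sum((amean[a] - gm) ** 2 for a in ages)
    ss_i = n * sum(
        (np.mean(cells[(g, a)]) - gmean[g] - amean[a] + gm) ** 2
        for g in gens for a in ages
    )
    ss_r = sum(
        float(np.sum((np.asarray(v, float) - np.mean(v)) ** 2))
        for v in cells.values()
    )
    return ss_g, ss_a, ss_i, ss_r


INTEGER_TOY = {
    ("WT", 6): [10, 12, 14], ("WT", 12): [11, 13, 15], ("WT", 17): [9, 11, 13],
    ("5xFAD", 6): [8, 10, 12], ("5xFAD", 12): [7, 9, 11], ("5xFAD", 17): [4, 6, 8],
}


class TestTwoWayAnova:
    def test_matches_hand_computed_ss_on_integer_toy(self):
        res = two_way_anova(_table(INTEGER_TOY), "e")
        ss_g, ss_a, ss_i, ss_r = _balanced_ss_oracle(INTEGER_TOY)
        assert res.effects["genotype"]["ss"] == pytest.approx(ss_g, rel=1e-8)
        assert res.effects["age"]["ss"] == pytest.approx(ss_a, rel=1e-8)
        assert res.effects["interaction"]["ss"] == pytest.approx(ss_i, rel=1e-8)
        assert res.residual_ss == pytest.approx(ss_r, rel=1e-8)
        assert res.effects["genotype"]["df"] == 1
        assert res.effects["age"]["df"] == 2
        assert res.effects["interaction"]["df"] == 2
        assert res.residual_df == 12

    def test_f_statistics_from_ss(self):
        res = two_way_anova(_table(INTEGER_TOY), "e")
        ss_g, _, _, ss_r = _balanced_ss_oracle(INTEGER_TOY)
        f_expected = (ss_g / 1) / (ss_r / 12)
        assert res.effects["genotype"]["F"] == pytest.approx(f_expected, rel=1e-8)
        p_expected = sps.f.sf(f_expected, 1, 12)
        assert res.effects["genotype"]["p"] == pytest.approx(p_expected, rel=1e-8)

    def test_equal_genotype_means_zero_genotype_ss(self):
        cells = {
            ("WT", 6): [10, 12], ("WT", 12): [14, 16],
            ("5xFAD", 6): [10, 12], ("5xFAD", 12): [14, 16],
        }
        res = two_way_anova(_table(cells), "e")
        assert res.effects["genotype"]["ss"] == pytest.approx(0.0, abs=1e-10)

    def test_additive_shift_zero_interaction(self):
        cells = {
            ("WT", 6): [10, 12], ("WT", 12): [14, 16], ("WT", 17): [18, 20],
            ("5xFAD", 6): [5, 7], ("5xFAD", 12): [9, 11], ("5xFAD", 17): [13, 15],
        }
        res = two_way_anova(_table(cells), "e")
        assert res.effects["interaction"]["ss"] == pytest.approx(0.0, abs=1e-9)

    def test_row_permutation_invariance(self):
        t = _table(INTEGER_TOY)
        shuffled = t.sample(frac=1.0, random_state=7).reset_index(drop=True)
        r1, r2 = two_way_anova(t, "e"), two_way_anova(shuffled, "e")
        for eff in ("genotype", "age", "interaction"):
            assert r1.effects[eff]["F"] == pytest.approx(r2.effects[eff]["F"])

    def test_total_ss_decomposition_balanced(self):
        res = two_way_anova(_table(INTEGER_TOY), "e")
        t = _table(INTEGER_TOY)
        total = float(np.sum((t["value"] - t["value"].mean()) ** 2))
        parts = sum(res.effects[e]["ss"] for e in res.effects) + res.residual_ss
        assert parts == pytest.approx(total, rel=1e-8)

    def test_empty_cell_named_in_error(self):
        cells = {("WT", 6): [1, 2], ("WT", 12): [3, 4], ("5xFAD", 6): [5, 6]}
        with pytest.raises(ValueError, match="5xFAD.*12|12.*5xFAD"):
            two_way_anova(_table(cells), "e")


class TestBonferroniPosthoc:
    def test_adjustment_rule_and_cap(self):
        rng = np.random.default_rng(4)
        cells = {(g, a): rng.normal(10 if g == "WT" else 9, 1, 8)
                 for g in ("WT", "5xFAD") for a in (6, 12, 17)}
        ph = bonferroni_posthoc(_table(cells), "e")
        assert ph.m == 3
        for _, r in ph.comparisons.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, 3 * r["p_raw"]))
            assert r["p_adj"] >= r["p_raw"]

    def test_two_age_family_uses_m2(self):
        rng = np.random.default_rng(5)
        cells = {(g, a): rng.normal(10, 1, 6)
                 for g in ("WT", "5xFAD") for a in (6, 12)}
        ph = bonferroni_posthoc(_table(cells), "e")
        assert ph.m == 2
        for _, r in ph.comparisons.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, 2 * r["p_raw"]))

    def test_monotone_in_family_size(self):
        # same raw p adjusted with larger m never shrinks
        for p_raw in (0.001, 0.02, 0.5):
            assert min(1.0, 3 * p_raw) >= min(1.0, 2 * p_raw)

    def test_uses_pooled_residual_t(self):
        ph = bonferroni_posthoc(_table(INTEGER_TOY), "e")
        res = two_way_anova(_table(INTEGER_TOY), "e")
        mse = res.residual_ss / res.residual_df
        row = ph.comparisons[ph.comparisons["age_months"] == 6].iloc[0]
        diff = np.mean(INTEGER_TOY[("5xFAD", 6)]) - np.mean(INTEGER_TOY[("WT", 6)])
        t_expected = diff / np.sqrt(mse * (1 / 3 + 1 / 3))
        assert row["t"] == pytest.approx(t_expected, rel=1e-9)
        assert row["df"] == res.residual_df


class TestKsNormality:
    def test_d_matches_ecdf_scan_oracle(self):
        x = np.array([2.1, -0.3, 0.8, 1.5, -1.2, 0.1, 0.6, -0.9, 1.9, 0.3])
        res = ks_normality(x)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        cdf = sps.norm.cdf(z)
        n = len(z)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res["D"] == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_null_pass_rate_near_95pct(self):
        passed = 0
        reps = 200
        for seed in range(reps):
            x = np.random.default_rng(seed).normal(3.0, 2.0, 200)
            passed += ks_normality(x)["normal"]
        assert passed / reps == pytest.approx(0.95, abs=0.05)

    def test_constant_sample_degenerate(self):
        res = ks_normality(np.full(10, 3.0))
        assert res["degenerate"]

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestNormalizeToBaseline:
    def test_reference_mean_is_100(self):
        t = _table(INTEGER_TOY)
        out = normalize_to_baseline(t)
        ref = out[(out["genotype"] == "WT") & (out["age_months"] == 6)]
        assert ref["value"].mean() == pytest.approx(100.0)

    def test_linearity(self):
        t = _table(INTEGER_TOY)
        doubled = t.assign(value=t["value"] * 2)
        o1, o2 = normalize_to_baseline(t), normalize_to_baseline(doubled)
        assert np.allclose(o1["value"], o2["value"])

    def test_empty_reference_errors(self):
        t = _table({("WT", 12): [1, 2], ("5xFAD", 12): [3, 4]})
        with pytest.raises(ValueError, match="reference"):
            normalize_to_baseline(t)

    def test_programmed_pstr_effect_recovered(self):
        table = simulate_endpoint_table(
            CohortDesign.uniform(12), default_effect_config(), seed=21,
            endpoints=("pstr",),
        )
        out = normalize_to_baseline(table)
        fad6 = out[(out["genotype"] == "5xFAD") & (out["age_months"] == 6)]
        assert fad6["value"].mean() == pytest.approx(70.0, abs=5.0)


class TestNullCalibration:
    def test_false_positive_rate_near_alpha(self):
        """All-null effect config: genotype effect significant in ~5% of
        seeded replicates (binomial tolerance around α = 0.05)."""
        cfg = default_effect_config()
        null_eff = cfg.endpoint("pstr")
        null_eff.genotype_factor.update({a: 1.0 for a in (6, 12, 17)})
        null_eff.age_factor.update({a: 1.0 for a in (6, 12, 17)})
        hits, reps = 0, 200
        for seed in range(reps):
            t = simulate_endpoint_table(CohortDesign(), cfg, seed=seed,
                                        endpoints=("pstr",))
            res = two_way_anova(t, "pstr")
            hits += res.effects["genotype"]["p"] < 0.05
        assert 0.01 <= hits / reps <= 0.10
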