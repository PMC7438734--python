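"""Genotype × age cohort statistics.

Every endpoint in the study — ERG amplitudes/sensitivities, layer
thicknesses, stain burden, Aβ levels — is analysed the same way: a two-way
ANOVA with genotype (5xFAD vs WT) and age (6/12/17 months) as factors,
Type III sums of squares with sum-to-zero contrasts (group sizes are
unbalanced), Bonferroni-corrected genotype contrasts within each age as the
post hoc family, Kolmogorov-Smirnov (Lilliefors) normality screening, and
percent-of-baseline normalization against the 6-month WT group.  α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "GenotypeAgeAnova",
    "two_way_anova",
    "bonferroni_posthoc",
    "ks_normality",
    "normalize_to_baseline",
    "cohort_report",
    "ALPHA",
]

ALPHA = 0.05
COHORT_COLUMNS = ["subject_id", "genotype", "age_months", "endpoint", "value"]


def _check_cohort(df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    sub = df[df["endpoint"] == endpoint].dropna(subset=["value"]).copy()
    if sub.empty:
        raise ValueError(f"no rows for endpoint {endpoint!r}")
    dup = sub.duplicated(subset=["subject_id", "endpoint"])
    if dup.any():
        raise ValueError(
            f"duplicate subject×endpoint rows for endpoint {endpoint!r}"
        )
    genos = sorted(sub["genotype"].unique())
    ages = sorted(sub["age_months"].unique())
    if len(genos) < 2 or len(ages) < 2:
        raise ValueError("ANOVA needs both genotypes and at least 2 ages")
    for g in genos:
        for a in ages:
            n = ((sub["genotype"] == g) & (sub["age_months"] == a)).sum()
            if n == 0:
                raise ValueError(f"empty design cell: genotype={g}, age={a}")
            if n < 2:
                raise ValueError(
                    f"cell genotype={g}, age={a} has {n} subject(s); need >= 2"
                )
    return sub


@dataclass
class AnovaResult:
    """Type III two-way ANOVA effects with cell summaries."""

    endpoint: str
    effects: dict  # name -> {df, df_resid, F, p, ss}
    residual_df: int
    residual_ss: float
    cell_stats: pd.DataFrame  # genotype × age: n, mean, sem

    def summary(self) -> str:
        lines = [
            f"Two-way ANOVA (Type III), endpoint: {self.endpoint}",
            f"{'effect':<16}{'df':>5}{'F':>12}{'p':>12}",
        ]
        for name, e in self.effects.items():
            lines.append(
                f"{name:<16}{e['df']:>5d}{e['F']:>12.4f}{e['p']:>12.4g}"
            )
        lines.append(f"residual df = {self.residual_df}")
        return "\n".join(lines)


@dataclass
class PosthocResult:
    """Genotype contrast at each age with Bonferroni adjustment (m = #ages)."""

    endpoint: str
    comparisons: pd.DataFrame  # age, diff, t, df, p_raw, p_adj, significant
    m: int
    alpha: float = ALPHA


class GenotypeAgeAnova:
    """Model object for one endpoint of a long-format cohort table.

    Parameters
    ----------
    table : DataFrame
        Columns subject_id, genotype, age_months, endpoint, value; one value
        per subject per endpoint (eyes/animals treated as independent).
    endpoint : str
        Endpoint name to analyse.
    """

    def __init__(self, table: pd.DataFrame, endpoint: str):
        self.data = _check_cohort(table, endpoint)
        self.endpoint = endpoint

    def fit(self) -> "GenotypeAgeAnovaResults":
        df = self.data.rename(columns={"age_months": "age"})
        df["age"] = df["age"].astype(str)
        model = smf.ols(
            "value ~ C(genotype, Sum) * C(age, Sum)", data=df
        ).fit()
        tab = anova_lm(model, typ=3)
        key = {
            "C(genotype, Sum)": "genotype",
            "C(age, Sum)": "age",
            "C(genotype, Sum):C(age, Sum)": "interaction",
        }
        resid_df = int(tab.loc["Residual", "df"])
        resid_ss = float(tab.loc["Residual", "sum_sq"])
        effects = {}
        for row, name in key.items():
            effects[name] = {
                "df": int(tab.loc[row, "df"]),
                "df_resid": resid_df,
                "F": float(tab.loc[row, "F"]),
                "p": float(tab.loc[row, "PR(>F)"]),
                "ss": float(tab.loc[row, "sum_sq"]),
            }
        cells = (
            self.data.groupby(["genotype", "age_months"])["value"]
            .agg(n="count", mean="mean", sem="sem")
            .reset_index()
        )
        anova = AnovaResult(
            endpoint=self.endpoint,
            effects=effects,
            residual_df=resid_df,
            residual_ss=resid_ss,
            cell_stats=cells,
        )
        return GenotypeAgeAnovaResults(self, anova)


@dataclass
class GenotypeAgeAnovaResults:
    """Fitted ANOVA plus the Bonferroni post hoc family."""

    model: GenotypeAgeAnova
    anova: AnovaResult
    _posthoc: PosthocResult | None = field(default=None, repr=False)

    def posthoc(self, alpha: float = ALPHA) -> PosthocResult:
        if self._posthoc is None or self._posthoc.alpha != alpha:
            self._posthoc = bonferroni_posthoc(
                self.model.data, self.model.endpoint, self.anova, alpha=alpha
            )
        return self._posthoc

    def summary(self) -> str:
        ph = self.posthoc()
        lines = [self.anova.summary(), "", "Bonferroni post hoc (genotype within age):"]
        for _, r in ph.comparisons.iterrows():
            star = "*" if r["significant"] else ""
            lines.append(
                f"  age {r['age_months']:>4g} mo: diff {r['diff']:>9.3f}, "
                f"t({r['df']:d}) = {r['t']:.3f}, p_adj = {r['p_adj']:.4g} {star}"
            )
        return "\n".join(lines)


def two_way_anova(table: pd.DataFrame, endpoint: str) -> AnovaResult:
    """Functional wrapper over :class:`GenotypeAgeAnova`."""
    return GenotypeAgeAnova(table, endpoint).fit().anova


def bonferroni_posthoc(
    table: pd.DataFrame,
    endpoint: str,
    anova: AnovaResult | None = None,
    alpha: float = ALPHA,
) -> PosthocResult:
    """Genotype difference at each age, t-tests on the pooled residual MS.

    The comparison family is the genotype contrast within each age level
    (m = number of ages); adjusted p = min(1, m · raw p).
    """
    sub = _check_cohort(table, endpoint)
    if anova is None:
        anova = two_way_anova(table, endpoint)
    mse = anova.residual_ss / anova.residual_df
    genos = sorted(sub["genotype"].unique())
    ages = sorted(sub["age_months"].unique())
    m = len(ages)
    rows = []
    for age in ages:
        a = sub[(sub["age_months"] == age) & (sub["genotype"] == genos[0])]["value"]
        b = sub[(sub["age_months"] == age) & (sub["genotype"] == genos[1])]["value"]
        diff = float(a.mean() - b.mean())
        se = float(np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b))))
        t = diff / se if se > 0 else float("inf")
        p_raw = float(2.0 * sps.t.sf(abs(t), anova.residual_df))
        p_adj = min(1.0, m * p_raw)
        rows.append(
            {
                "age_months": age,
                "comparison": f"{genos[0]} - {genos[1]}",
                "diff": diff,
                "t": t,
                "df": anova.residual_df,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return PosthocResult(
        endpoint=endpoint, comparisons=pd.DataFrame(rows), m=m, alpha=alpha
    )


def ks_normality(sample, alpha: float = ALPHA) -> dict:
    """One-sample KS against a normal with estimated mean/SD (Lilliefors).

    Returns the D statistic, the Lilliefors-corrected p, and whether the
    sample passes (fails to reject normality) at ``alpha``.  Samples with
    zero variance are flagged degenerate.
    """
    x = np.asarray(list(sample), dtype=float)
    if x.size < 5:
        raise ValueError("KS normality screen needs n >= 5")
    if np.std(x) == 0:
        return {"D": float("nan"), "p": float("nan"),
                "normal": False, "degenerate": True}
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    return {"D": float(d), "p": float(p), "normal": bool(p > alpha),
            "degenerate": False}


def normalize_to_baseline(
    table: pd.DataFrame, reference: tuple[str, float] = ("WT", 6)
) -> pd.DataFrame:
    """Express each value as a percentage of the reference-cell mean.

    Per endpoint: value → 100 · value / mean(values in the (genotype, age)
    reference cell).  The reference cell's mean maps to exactly 100.
    """
    gen, age = reference
    out = table.copy()
    for ep, g in table.groupby("endpoint"):
        ref = g[(g["genotype"] == gen) & (g["age_months"] == age)]["value"]
        if ref.empty:
            raise ValueError(
                f"empty reference cell ({gen}, {age} months) for endpoint {ep!r}"
            )
        mean = ref.mean()
        if mean == 0:
            raise ValueError(f"reference mean is zero for endpoint {ep!r}")
        out.loc[g.index, "value"] = 100.0 * g["value"] / mean
    return out


def cohort_report(
    table: pd.DataFrame, alpha: float = ALPHA, endpoints=None
) -> dict:
    """Full statistical report (ANOVA, post hoc, normality) per endpoint."""
    report = {}
    names = endpoints if endpoints is not None else sorted(table["endpoint"].unique())
    for ep in names:
        res = GenotypeAgeAnova(table, ep).fit()
        ph = res.posthoc(alpha=alpha)
        norm = {}
        sub = table[table["endpoint"] == ep].dropna(subset=["value"])
        for (g, a), cell in sub.groupby(["genotype", "age_months"]):
            if len(cell) >= 5:
                norm[f"{g}:{a:g}"] = ks_normality(cell["value"], alpha=alpha)
        report[ep] = {
            "anova": {
                name: {k: v for k, v in e.items()}
                for name, e in res.anova.effects.items()
            },
            "residual_df": res.anova.residual_df,
            "posthoc": ph.comparisons.to_dict(orient="records"),
            "normality": norm,
            "cell_stats": res.anova.cell_stats.to_dict(orient="records"),
        }
    return report
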