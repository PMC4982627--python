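"""Egg-to-adult viability and qPCR expression statistics.

The viability pipeline mirrors the standard proportion-data workflow: per-vial
emerged/total proportions, arcsine square-root transform, a Kolmogorov-
Smirnov (Lilliefors-style, estimated parameters) normality check, a rank
transform when normality is rejected, then a two-way fixed-effects ANOVA of
experimental condition (control vs cold stress) x insertion genotype
(with/without) with Type III sums of squares and partial eta-squared effect
sizes (small/medium/large at 0.01/0.06/0.14). Relative expression uses
efficiency-corrected ddCt-style normalization of a target gene against a
reference gene, with a Welch t-test between genotype groups on biological-
replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AnovaResult",
    "viability_proportions",
    "arcsine_transform",
    "normality_check",
    "rank_transform",
    "two_way_anova",
    "effect_size_class",
    "viability_pipeline",
    "relative_expression",
    "compare_expression",
]


def viability_proportions(table: pd.DataFrame) -> pd.Series:
    """Per-vial emerged/total proportions.

    ``table`` needs ``emerged`` and ``total`` columns; totals must be positive
    and emerged counts within [0, total].
    """
    total = table["total"].to_numpy(dtype=float)
    emerged = table["emerged"].to_numpy(dtype=float)
    if (total <= 0).any():
        raise ValueError("vial totals must be positive")
    if ((emerged < 0) | (emerged > total)).any():
        raise ValueError("emerged counts must lie in [0, total]")
    return pd.Series(emerged / total, index=table.index, name="proportion")


def arcsine_transform(p) -> np.ndarray | float:
    """Variance-stabilizing arcsin(sqrt(p)) transform, in radians."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


def normality_check(values, alpha: float = 0.05) -> dict:
    """Kolmogorov-Smirnov test against a normal with estimated parameters.

    Uses Lilliefors critical values (the parameters are estimated from the
    sample). Degenerate (zero-variance) samples are declared non-normal.
    Returns a dict with statistic, p_value and the boolean ``normal``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values for the normality check")
    if v.std() == 0:
        return {"statistic": np.inf, "p_value": 0.0, "normal": False}
    stat, p = lilliefors(v, dist="norm")
    return {"statistic": float(stat), "p_value": float(p), "normal": p >= alpha}


def rank_transform(values) -> np.ndarray:
    """Average (midrank-for-ties) ranks, order-preserving."""
    return stats.rankdata(np.asarray(values, dtype=float), method="average")


@dataclass(frozen=True)
class AnovaResult:
    """Per-term ANOVA table with partial eta-squared effect sizes."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, p_value,
    #                      partial_eta_sq, effect_class
    residual_ss: float
    residual_df: float

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def effect_size_class(partial_eta_sq: float) -> str:
    """Small/medium/large classification at 0.01 / 0.06 / 0.14."""
    if partial_eta_sq >= 0.14:
        return "large"
    if partial_eta_sq >= 0.06:
        return "medium"
    if partial_eta_sq >= 0.01:
        return "small"
    return "negligible"


def two_way_anova(
    response,
    condition,
    genotype,
    replicate=None,
) -> AnovaResult:
    """Full-factorial condition x genotype ANOVA (+ optional replicate).

    Least-squares fit with sum-to-zero contrasts and Type III sums of squares
    (these coincide with Type I/II on balanced designs). Replicate, when
    given, enters as a crossed fixed main effect. Partial eta-squared is
    SS_term / (SS_term + SS_residual).
    """
    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "condition": pd.Categorical(condition),
        "genotype": pd.Categorical(genotype),
    })
    if len(df["condition"].cat.categories) < 2 or len(df["genotype"].cat.categories) < 2:
        raise ValueError("each factor needs at least 2 levels")
    formula = "y ~ C(condition, Sum) * C(genotype, Sum)"
    if replicate is not None:
        df["replicate"] = pd.Categorical(replicate)
        if len(df["replicate"].cat.categories) > 1:
            formula += " + C(replicate, Sum)"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    aov = sm.stats.anova_lm(model, typ=3)
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    resid_df = float(aov.loc["Residual", "df"])
    rename = {
        "C(condition, Sum)": "condition",
        "C(genotype, Sum)": "genotype",
        "C(condition, Sum):C(genotype, Sum)": "interaction",
        "C(replicate, Sum)": "replicate",
    }
    rows = {}
    for raw, name in rename.items():
        if raw not in aov.index:
            continue
        ss = float(aov.loc[raw, "sum_sq"])
        peta = ss / (ss + resid_ss) if ss + resid_ss > 0 else 0.0
        rows[name] = {
            "sum_sq": ss,
            "df": float(aov.loc[raw, "df"]),
            "F": float(aov.loc[raw, "F"]),
            "p_value": float(aov.loc[raw, "PR(>F)"]),
            "partial_eta_sq": peta,
            "effect_class": effect_size_class(peta),
        }
    table = pd.DataFrame(rows).T
    for col in ("sum_sq", "df", "F", "p_value", "partial_eta_sq"):
        table[col] = table[col].astype(float)
    return AnovaResult(table, resid_ss, resid_df)


def viability_pipeline(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The full viability workflow on a vial-level count table.

    proportions -> arcsine -> KS normality check on model residual scale
    (the pooled transformed values) -> rank transform when non-normal ->
    two-way ANOVA. Returns the AnovaResult plus the branch taken.
    """
    props = viability_proportions(table)
    y = arcsine_transform(props.to_numpy())
    check = normality_check(y, alpha=alpha)
    ranked = not check["normal"]
    if ranked:
        y = rank_transform(y)
    replicate = table["replicate"] if table["replicate"].nunique() > 1 else None
    result = two_way_anova(y, table["condition"], table["genotype"], replicate)
    return {
        "anova": result,
        "normality": check,
        "rank_transformed": ranked,
        "transformed_response": y,
    }


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def relative_expression(
    ct_target,
    ct_reference,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> np.ndarray | float:
    """Efficiency-corrected expression of a target relative to a reference.

    E_t^(-Ct_target) / E_r^(-Ct_reference), with amplification factors E in
    (1, 2] (E = 1 + efficiency/100; a primer-pair efficiency of 99.1% gives
    E = 1.991; perfect doubling gives 2).
    """
    for e in (efficiency_target, efficiency_reference):
        if not 1 < e <= 2:
            raise ValueError("amplification factor must be in (1, 2]")
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    out = efficiency_target ** (-ct_t) / efficiency_reference ** (-ct_r)
    return float(out) if out.ndim == 0 else out


def compare_expression(samples: pd.DataFrame, efficiency_target: float = 1.991,
                       efficiency_reference: float = 2.0) -> dict:
    """Two-group comparison of normalized expression.

    ``samples`` columns: sample, group (with_insertion/without_insertion),
    replicate, ct_target, ct_reference. Biological replicates are averaged
    per sample before an unequal-variance (Welch) two-sided t-test between
    groups. Returns group means and the t-test p-value.
    """
    df = samples.copy()
    df["expression"] = relative_expression(
        df["ct_target"], df["ct_reference"], efficiency_target,
        efficiency_reference,
    )
    per_sample = df.groupby(["group", "sample"], observed=True)["expression"].mean()
    groups = per_sample.index.get_level_values("group").unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = per_sample.loc[groups[0]].to_numpy()
    b = per_sample.loc[groups[1]].to_numpy()
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "group_means": {g: float(per_sample.loc[g].mean()) for g in groups},
        "t_statistic": float(t),
        "p_value": float(p),
        "n_per_group": {groups[0]: int(a.size), groups[1]: int(b.size)},
    }
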