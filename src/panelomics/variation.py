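"""ANOVA screening and genotype-variation summaries.

The screening mirrors the classical diversity-panel workflow: a fixed-effect
two-way ANOVA (genotype, stage, genotype x stage) per trait, a one-way
genotype ANOVA within each stage, and a one-way ANOVA within each cross
(two parents plus their hybrid).  Summaries report per-stage genotype-mean
minima, maxima and max/min fold-change ratios with significance stars.

Type II sums of squares are used for the two-way model; on the nominally
balanced complete design they coincide with the classical sequential
decomposition, and with missing values they remain order-invariant.
P-values are raw (no multiple-testing correction gates any downstream
step); a Benjamini-Hochberg FDR column is emitted for reference only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .panel import CrossDesign, TraitTable

STAR_BANDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class TwoWayResult:
    p_stage: float
    p_genotype: float
    p_interaction: float
    table: pd.DataFrame | None = None  # statsmodels ANOVA table (sum_sq, df, F, PR(>F))

    def __iter__(self):
        return iter((self.p_stage, self.p_genotype, self.p_interaction))


def _trait_frame(table: TraitTable, trait_id: str) -> pd.DataFrame:
    s = table.values[trait_id]
    df = s.rename("value").reset_index()
    return df.dropna(subset=["value"])


def two_way_anova(table: TraitTable, trait_id: str) -> TwoWayResult:
    """Fixed-effect crossed genotype x stage ANOVA for one trait.

    Returns Type II p-values for the stage, genotype and interaction terms.
    A trait with no data yields an all-NaN result with a warning.
    """
    df = _trait_frame(table, trait_id)
    if df.empty:
        warnings.warn(f"trait {trait_id!r}: no non-missing values; ANOVA skipped")
        return TwoWayResult(math.nan, math.nan, math.nan)
    fit = ols("value ~ C(genotype) + C(stage) + C(genotype):C(stage)", data=df).fit()
    with warnings.catch_warnings():
        # zero residual variance (noise-free fixtures) triggers harmless 0/0
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = anova_lm(fit, typ=2)
    return TwoWayResult(
        p_stage=float(aov.loc["C(stage)", "PR(>F)"]),
        p_genotype=float(aov.loc["C(genotype)", "PR(>F)"]),
        p_interaction=float(aov.loc["C(genotype):C(stage)", "PR(>F)"]),
        table=aov,
    )


def one_way_anova_by_stage(table: TraitTable, trait_id: str, stage: str) -> float:
    """One-way genotype ANOVA p-value within a stage."""
    df = _trait_frame(table, trait_id)
    df = df[df["stage"] == stage]
    groups = [g["value"].to_numpy() for _, g in df.groupby("genotype") if len(g) > 0]
    return _f_oneway_p(groups)


def per_cross_anova(table: TraitTable, trait_id: str, cross, stage: str) -> float:
    """One-way ANOVA over exactly {hybrid, parent1, parent2} at a stage.

    ``cross`` is a (hybrid, parent1, parent2) triple.  A missing genotype
    yields NaN with a warning.
    """
    hybrid, p1, p2 = cross
    df = _trait_frame(table, trait_id)
    df = df[df["stage"] == stage]
    groups = []
    for g in (p1, p2, hybrid):
        vals = df.loc[df["genotype"] == g, "value"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"trait {trait_id!r} cross {hybrid}: genotype {g!r} missing at {stage}")
            return math.nan
        groups.append(vals)
    return _f_oneway_p(groups)


def _f_oneway_p(groups) -> float:
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or sum(len(g) for g in groups) <= len(groups):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    # identical group means with zero residual variance: F = 0/0 -> no evidence
    if math.isnan(p) and all(np.allclose(g, groups[0].mean()) for g in groups):
        return 1.0
    return float(p)


def significance_code(p: float) -> str:
    """Star code for a p-value: NS, *, **, or *** ('NA' when missing)."""
    if p is None or (isinstance(p, float) and math.isnan(p)) or pd.isna(p):
        return "NA"
    for cut, stars in STAR_BANDS:
        if p < cut:
            return stars
    return "NS"


def genotype_mean_summary(table: TraitTable, trait_id: str, stage: str):
    """(min, max, max/min) over per-genotype replicate means at a stage.

    The ratio is NaN when the minimum mean is not strictly positive, as a
    fold change is then meaningless.
    """
    means = table.genotype_means(stage=stage)[trait_id].dropna()
    if means.empty:
        return (math.nan, math.nan, math.nan)
    lo, hi = float(means.min()), float(means.max())
    ratio = hi / lo if lo > 0 else math.nan
    return (lo, hi, ratio)


def max_min_ratio(min_mean: float, max_mean: float) -> float:
    """Fold-change ratio max/min of genotype means; NaN when min <= 0."""
    if min_mean is None or max_mean is None or pd.isna(min_mean) or pd.isna(max_mean):
        return math.nan
    return max_mean / min_mean if min_mean > 0 else math.nan


def variation_table(table: TraitTable, stages=None) -> pd.DataFrame:
    """One summary row per trait: global two-way ANOVA plus per-stage detail.

    Columns mirror the classical variation table: stage/genotype/interaction
    stars from the two-way model, then per stage the genotype p-value and
    star, the min and max genotype means and their ratio.
    """
    stages = list(stages) if stages is not None else table.stages
    rows = []
    for trait in table.trait_ids:
        res = two_way_anova(table, trait)
        row = {
            "trait_id": trait,
            "level": table.traits.at[trait, "level"],
            "p_stage": res.p_stage, "star_stage": significance_code(res.p_stage),
            "p_genotype": res.p_genotype, "star_genotype": significance_code(res.p_genotype),
            "p_interaction": res.p_interaction,
            "star_interaction": significance_code(res.p_interaction),
        }
        for stage in stages:
            p_g = one_way_anova_by_stage(table, trait, stage)
            lo, hi, ratio = genotype_mean_summary(table, trait, stage)
            row[f"p_genotype_{stage}"] = p_g
            row[f"star_genotype_{stage}"] = significance_code(p_g)
            row[f"min_{stage}"] = lo
            row[f"max_{stage}"] = hi
            row[f"ratio_{stage}"] = ratio
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        ok = out["p_genotype"].notna()
        out["fdr_genotype"] = math.nan
        if ok.any():
            out.loc[ok, "fdr_genotype"] = multipletests(
                out.loc[ok, "p_genotype"], method="fdr_bh")[1]
    return out


def gated_traits(variation: pd.DataFrame, stage: str, alpha: float = 0.05) -> list:
    """Traits whose genotype effect is significant at the stage (raw p)."""
    col = f"p_genotype_{stage}"
    if col not in variation.columns:
        raise KeyError(f"variation table has no column {col!r}")
    keep = variation[col] < alpha
    return variation.loc[keep, "trait_id"].tolist()


def polymorphism_percent(n_polymorphic: int, n_total: int) -> float:
    """Percentage of polymorphic markers in a genotyping panel."""
    if n_total <= 0 or n_polymorphic < 0 or n_polymorphic > n_total:
        raise ValueError("need 0 <= n_polymorphic <= n_total with n_total > 0")
    return 100.0 * n_polymorphic / n_total
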