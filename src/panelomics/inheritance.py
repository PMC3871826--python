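"""Additive/dominance decomposition and inheritance-mode calling.

For a cross between inbred parent lines P1 and P2 with hybrid F1, and a
quantitative trait measured on replicate means:

    A = (mean(P1) - mean(P2)) / 2      additive component, parent1 first
    D = mean(F1) - (mean(P1) + mean(P2)) / 2   dominance component

The D/A ratio classifies the mode of inheritance into five bands:

    over-recessive   D/A < -1.2
    recessive        -1.2 <= D/A <= -0.8
    additive         -0.8 <  D/A <  0.8
    dominant          0.8 <= D/A <= 1.2
    overdominant      D/A > 1.2

Band boundaries are inclusive exactly as written above, so swapping the two
parents (which negates A and hence D/A) maps dominant to recessive and
overdominant to over-recessive, band for band.  When the parents are
indistinguishable (A ~ 0) the ratio is undefined and the call is
``undetermined`` rather than an arbitrary +/-inf artifact of noise.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .panel import CrossDesign, TraitTable
from .variation import per_cross_anova

MODES = ("over_recessive", "recessive", "additive", "dominant", "overdominant")
UNDETERMINED = "undetermined"


def additive_component(p1_mean: float, p2_mean: float) -> float:
    """Half the signed parental difference, parent1 first."""
    if _isna(p1_mean) or _isna(p2_mean):
        return math.nan
    return (p1_mean - p2_mean) / 2.0


def dominance_component(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Hybrid mean minus the midparent."""
    if _isna(f1_mean) or _isna(p1_mean) or _isna(p2_mean):
        return math.nan
    return f1_mean - (p1_mean + p2_mean) / 2.0


def classify_mode(A: float, D: float, rel_tol: float = 1e-6):
    """Map an (A, D) pair to its D/A ratio and inheritance mode.

    Returns ``(da_ratio, mode)``; ``(nan, "undetermined")`` when A is
    negligible relative to the pair's magnitude (parents indistinguishable).
    """
    if _isna(A) or _isna(D):
        return (math.nan, UNDETERMINED)
    if abs(A) <= rel_tol * (abs(A) + abs(D)) or A == 0.0:
        return (math.nan, UNDETERMINED)
    ratio = D / A
    if ratio < -1.2:
        mode = "over_recessive"
    elif ratio <= -0.8:
        mode = "recessive"
    elif ratio < 0.8:
        mode = "additive"
    elif ratio <= 1.2:
        mode = "dominant"
    else:
        mode = "overdominant"
    return (ratio, mode)


def inheritance_scan(table: TraitTable, design: CrossDesign, alpha: float = 0.05,
                     rel_tol: float = 1e-6, stages=None) -> pd.DataFrame:
    """Call inheritance modes for every (trait, cross, stage).

    A combination is emitted only when the within-cross one-way ANOVA over
    {parent1, parent2, hybrid} is significant at ``alpha`` (raw p); A and D
    are then computed on replicate means and classified.
    """
    stages = list(stages) if stages is not None else table.stages
    rows = []
    for stage in stages:
        means = table.genotype_means(stage=stage)
        for hybrid, p1, p2 in design:
            missing = [g for g in (hybrid, p1, p2) if g not in means.index]
            if missing:
                warnings.warn(f"cross {hybrid}: genotype(s) {missing} absent at {stage}; skipped")
                continue
            for trait in table.trait_ids:
                p_cross = per_cross_anova(table, trait, (hybrid, p1, p2), stage)
                if not (p_cross < alpha):
                    continue
                a = additive_component(means.at[p1, trait], means.at[p2, trait])
                d = dominance_component(means.at[hybrid, trait], means.at[p1, trait], means.at[p2, trait])
                ratio, mode = classify_mode(a, d, rel_tol)
                rows.append({
                    "trait_id": trait, "cross_id": hybrid, "stage": stage,
                    "p_cross": p_cross, "A": a, "D": d,
                    "da_ratio": ratio, "mode": mode,
                })
    cols = ["trait_id", "cross_id", "stage", "p_cross", "A", "D", "da_ratio", "mode"]
    return pd.DataFrame(rows, columns=cols)


def mode_distribution(results: pd.DataFrame) -> pd.DataFrame:
    """Count mode calls per (cross, stage), with per-group proportions."""
    if results.empty:
        return pd.DataFrame(columns=["cross_id", "stage", "mode", "count", "proportion"])
    counts = (
        results.groupby(["cross_id", "stage", "mode"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["cross_id", "stage"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def nonadditive_fraction(results: pd.DataFrame) -> float:
    """Pooled fraction of determinate calls that are not additive."""
    det = results[results["mode"] != UNDETERMINED]
    if det.empty:
        return math.nan
    return float((det["mode"] != "additive").mean())


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)
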