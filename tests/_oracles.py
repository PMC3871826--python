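"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid statsmodels/scipy ANOVA machinery: sums of squares
are accumulated straight from the textbook definitions on balanced complete
designs, and p-values come only from the F survival function.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def twoway_anova_oracle(genotype, stage, value):
    """Classical two-way crossed ANOVA on a balanced complete design.

    Returns (p_stage, p_genotype, p_interaction) from explicit sums of
    squares: SS_total = SS_G + SS_S + SS_GxS + SS_error.
    """
    genotype = np.asarray(genotype)
    stage = np.asarray(stage)
    y = np.asarray(value, dtype=float)
    gs = sorted(set(genotype))
    ss = sorted(set(stage))
    grand = y.mean()
    ss_g = sum(((y[genotype == g]).mean() - grand) ** 2 * (genotype == g).sum() for g in gs)
    ss_s = sum(((y[stage == s]).mean() - grand) ** 2 * (stage == s).sum() for s in ss)
    ss_cells = 0.0
    ss_err = 0.0
    for g in gs:
        for s in ss:
            cell = y[(genotype == g) & (stage == s)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_int = ss_cells - ss_g - ss_s
    df_g = len(gs) - 1
    df_s = len(ss) - 1
    df_int = df_g * df_s
    df_err = len(y) - len(gs) * len(ss)
    ms_err = ss_err / df_err
    p_g = float(stats.f.sf((ss_g / df_g) / ms_err, df_g, df_err))
    p_s = float(stats.f.sf((ss_s / df_s) / ms_err, df_s, df_err))
    p_int = float(stats.f.sf((ss_int / df_int) / ms_err, df_int, df_err))
    return p_s, p_g, p_int


def oneway_anova_oracle(group, value):
    """One-way ANOVA p-value from explicit between/within sums of squares."""
    group = np.asarray(group)
    y = np.asarray(value, dtype=float)
    gs = sorted(set(group))
    grand = y.mean()
    ss_b = sum((group == g).sum() * ((y[group == g]).mean() - grand) ** 2 for g in gs)
    ss_w = sum((((y[group == g]) - (y[group == g]).mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(y) - len(gs)
    f = (ss_b / df_b) / (ss_w / df_w)
    return float(stats.f.sf(f, df_b, df_w))


def pearson_p_oracle(r: float, n: int) -> float:
    """Two-sided p for a sample correlation via the t-transform, n-2 df."""
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))
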