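"""Thresholded Pearson correlation analysis within and between trait levels.

Correlations are computed on per-genotype means at one stage (n = number of
genotypes), restricted to traits whose genotype effect passed the variation
screen at that stage.  An association is an edge when it clears the dual
gate |r| > r_min AND p < alpha (defaults 0.7 and 0.01).  At n = 12 the
p < 0.01 gate is the binding constraint: it corresponds to |r| > 0.708,
slightly stricter than the 0.7 magnitude gate.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import Edge, TraitNetwork
from .panel import TraitTable


def pearson_with_p(x, y):
    """Sample Pearson r and two-sided p (t-transform, n-2 df).

    Pairs with a missing value in either vector are dropped; fewer than
    three complete pairs or a zero-variance vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def all_pairs_correlations(means: pd.DataFrame) -> pd.DataFrame:
    """Pearson r/p for every unordered trait pair of a means matrix.

    Returns one row per pair: trait_a, trait_b, n (complete pairs), r, p.
    """
    cols = list(means.columns)
    rows = []
    arr = means.to_numpy(dtype=float)
    for i, j in combinations(range(len(cols)), 2):
        x, y = arr[:, i], arr[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        r, p = pearson_with_p(x, y)
        rows.append({"trait_a": cols[i], "trait_b": cols[j],
                     "n": int(ok.sum()), "r": r, "p": p})
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "n", "r", "p"])


def significant_edges(means: pd.DataFrame, levels: Mapping[str, str],
                      gated: Iterable[str] | None = None,
                      r_min: float = 0.7, alpha: float = 0.01) -> TraitNetwork:
    """Build the dual-gate correlation network over gated traits.

    ``gated`` lists the traits admitted to the analysis (typically those
    significantly variable among genotypes at the stage); None admits all
    columns.  Edge weights are the signed correlations.
    """
    keep = [t for t in means.columns if gated is None or t in set(gated)]
    pairs = all_pairs_correlations(means[keep])
    edges = [
        Edge(row.trait_a, row.trait_b, row.r, "pearson")
        for row in pairs.itertuples(index=False)
        if not math.isnan(row.r) and abs(row.r) > r_min and row.p < alpha
    ]
    nodes = {t: levels.get(t, "unknown") for t in keep}
    return TraitNetwork(nodes=nodes, edges=edges)


def cross_level_summary(pairs: pd.DataFrame, levels: Mapping[str, str],
                        r_min: float = 0.7, alpha: float = 0.01) -> pd.DataFrame:
    """Per level-pair counts of significant correlations vs chance.

    For each unordered pair of expression levels: the number of trait pairs
    tested, the number passing the dual gate split by sign, the count
    expected by chance (alpha x tests) and a binomial exceedance probability
    P[X >= observed] with X ~ Binomial(n_tested, alpha).  The chance model
    treats tests as independent — a working definition, not an exact null.
    """
    recs = {}
    for row in pairs.itertuples(index=False):
        la, lb = levels.get(row.trait_a, "unknown"), levels.get(row.trait_b, "unknown")
        key = tuple(sorted((la, lb)))
        rec = recs.setdefault(key, {"n_tested": 0, "n_significant": 0,
                                    "n_positive": 0, "n_negative": 0})
        rec["n_tested"] += 1
        if not math.isnan(row.r) and abs(row.r) > r_min and row.p < alpha:
            rec["n_significant"] += 1
            rec["n_positive" if row.r > 0 else "n_negative"] += 1
    out = []
    for (la, lb), rec in sorted(recs.items()):
        expected = alpha * rec["n_tested"]
        p_exc = float(stats.binom.sf(rec["n_significant"] - 1, rec["n_tested"], alpha))
        out.append({"level_a": la, "level_b": lb, **rec,
                    "expected_by_chance": expected, "p_exceedance": p_exc})
    return pd.DataFrame(out, columns=["level_a", "level_b", "n_tested", "n_significant",
                                      "n_positive", "n_negative", "expected_by_chance",
                                      "p_exceedance"])


def activity_spot_correlation(table: TraitTable, mapping: Mapping[str, Sequence[str]],
                              stage: str) -> pd.DataFrame:
    """Correlate enzyme activities with their annotated protein spots.

    ``mapping`` sends an enzyme trait_id to the spot trait_ids annotated
    with the same function (a many-to-one map, since one gene product may
    appear as several 2-DE spots).  Enzymes or spots absent from the table
    are skipped.
    """
    means = table.genotype_means(stage=stage)
    rows = []
    for enzyme, spots in mapping.items():
        if enzyme not in means.columns:
            continue
        for spot in spots:
            if spot not in means.columns:
                continue
            r, p = pearson_with_p(means[enzyme], means[spot])
            rows.append({"enzyme": enzyme, "spot": spot, "stage": stage, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["enzyme", "spot", "stage", "r", "p"])


def strong_correlates(pairs: pd.DataFrame, targets: Sequence[str],
                      r_min: float = 0.78, alpha: float = 0.001) -> pd.DataFrame:
    """Traits very strongly correlated with given target traits.

    A stricter gate (default |r| >= 0.78, p < 0.001) used for headline
    tables of spots tracking integrative phenotypes such as fruit weight or
    dry matter content.
    """
    t = set(targets)
    rows = []
    for row in pairs.itertuples(index=False):
        if math.isnan(row.r) or abs(row.r) < r_min or not (row.p < alpha):
            continue
        if row.trait_a in t or row.trait_b in t:
            target = row.trait_a if row.trait_a in t else row.trait_b
            other = row.trait_b if row.trait_a in t else row.trait_a
            rows.append({"target": target, "trait": other, "r": row.r, "p": row.p})
    return pd.DataFrame(rows, columns=["target", "trait", "r", "p"])
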