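"""ANOVA screening checked against an independent sums-of-squares oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import panelomics as po
from panelomics import TraitTable, make_trait_meta
from _oracles import oneway_anova_oracle, twoway_anova_oracle


def _balanced_table(rng, n_genotypes=3, n_stages=2, n_reps=3, effects=None):
    idx = pd.MultiIndex.from_product(
        [[f"G{i}" for i in range(n_genotypes)], ["CE", "OR"][:n_stages], range(1, n_reps + 1)],
        names=("genotype", "stage", "replicate"))
    y = rng.normal(size=len(idx))
    if effects is not None:
        y = y + np.array([effects(g, s) for g, s, _ in idx])
    values = pd.DataFrame({"t": y}, index=idx)
    return TraitTable(values, make_trait_meta(["t"], "metabolite"))


class TestTwoWayAnova:
    def test_no_genotype_variance_gives_zero_ss(self, ):
        # same value for every genotype within a stage -> SS_G = SS_GxS = 0
        rng = np.random.default_rng(0)
        table = _balanced_table(rng, effects=lambda g, s: 5.0 if s == "OR" else 0.0)
        # rebuild with replicate noise only varying by replicate, constant per cell
        vals = table.values.copy()
        vals["t"] = [1.0 + (3.0 if s == "OR" else 0.0) + 0.1 * r
                     for g, s, r in vals.index]
        table = TraitTable(vals, table.traits)
        res = po.two_way_anova(table, "t")
        assert res.table.loc["C(genotype)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["C(genotype):C(stage)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ss_oracle_on_balanced_design(self, seed):
        rng = np.random.default_rng(seed)
        table = _balanced_table(rng, n_genotypes=4)
        res = po.two_way_anova(table, "t")
        df = table.values["t"].reset_index()
        p_s, p_g, p_i = twoway_anova_oracle(df["genotype"], df["stage"], df["t"])
        assert res.p_stage == pytest.approx(p_s, abs=1e-10)
        assert res.p_genotype == pytest.approx(p_g, abs=1e-10)
        assert res.p_interaction == pytest.approx(p_i, abs=1e-10)

    def test_planted_stage_effect_only(self):
        # stage effect >> noise, no genotype effect: p_stage tiny, p_genotype large
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            table = _balanced_table(rng, effects=lambda g, s: 6.0 if s == "OR" else 0.0)
            res = po.two_way_anova(table, "t")
            hits += (res.p_stage < 0.001) and (res.p_genotype > 0.05)
        assert hits >= 36  # >= 90% of seeds

    def test_all_missing_trait_warns_and_returns_nan(self, tiny_table):
        vals = tiny_table.values.copy()
        vals["glucose"] = np.nan
        table = TraitTable(vals, tiny_table.traits)
        with pytest.warns(UserWarning, match="no non-missing"):
            res = po.two_way_anova(table, "glucose")
        assert math.isnan(res.p_genotype)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        table = _balanced_table(rng, n_genotypes=5)
        res1 = po.two_way_anova(table, "t")
        scaled = TraitTable(table.values * 3.7 + 11.0, table.traits)
        res2 = po.two_way_anova(scaled, "t")
        for a, b in zip(res1, res2):
            assert a == pytest.approx(b, rel=1e-8)


class TestOneWayAnova:
    def test_equal_means_no_evidence(self):
        idx = pd.MultiIndex.from_product(
            [["A", "B", "C"], ["CE"], [1, 2, 3]], names=("genotype", "stage", "replicate"))
        vals = pd.DataFrame({"t": [1.0, 2.0, 3.0] * 3}, index=idx)
        table = TraitTable(vals, make_trait_meta(["t"], "enzyme"))
        assert po.one_way_anova_by_stage(table, "t", "CE") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ss_oracle(self, seed):
        rng = np.random.default_rng(50 + seed)
        table = _balanced_table(rng, n_genotypes=6)
        p = po.one_way_anova_by_stage(table, "t", "CE")
        df = table.values["t"].xs("CE", level="stage").reset_index()
        assert p == pytest.approx(oneway_anova_oracle(df["genotype"], df["t"]), abs=1e-10)

    def test_stage_specific_genotype_effect(self):
        # genotype effect planted at CE only -> significant at CE, not at OR
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(200 + seed)
            table = _balanced_table(
                rng, effects=lambda g, s: (4.0 * int(g[1:]) if s == "CE" else 0.0))
            p_ce = po.one_way_anova_by_stage(table, "t", "CE")
            p_or = po.one_way_anova_by_stage(table, "t", "OR")
            hits += (p_ce < 0.001) and (p_or > 0.05)
        assert hits >= 25


class TestPerCrossAnova:
    def test_separated_parent_and_hybrid_means_significant(self):
        # parents at 10 and 4, hybrid at midparent 7, sd 0.1, n=3
        rng = np.random.default_rng(9)
        idx = pd.MultiIndex.from_product(
            [["P1", "P2", "F1"], ["CE"], [1, 2, 3]], names=("genotype", "stage", "replicate"))
        mean = {"P1": 10.0, "P2": 4.0, "F1": 7.0}
        vals = pd.DataFrame({"t": [mean[g] + 0.1 * rng.standard_normal() for g, s, r in idx]},
                            index=idx)
        table = TraitTable(vals, make_trait_meta(["t"], "metabolite"))
        p = po.per_cross_anova(table, "t", ("F1", "P1", "P2"), "CE")
        assert p < 1e-6  # F is enormous at this separation

    def test_missing_genotype_warns_nan(self, tiny_table):
        with pytest.warns(UserWarning, match="missing"):
            p = po.per_cross_anova(tiny_table, "glucose", ("H1", "Levovil", "Ghost"), "CE")
        assert math.isnan(p)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_ss_oracle(self, seed, tiny_table):
        p = po.per_cross_anova(tiny_table, "glucose", ("H1", "Levovil", "Cervil"), "CE")
        df = tiny_table.values["glucose"].xs("CE", level="stage").reset_index()
        assert p == pytest.approx(oneway_anova_oracle(df["genotype"], df["glucose"]), abs=1e-10)


class TestSignificanceCode:
    @pytest.mark.parametrize("p,code", [
        (0.20, "NS"), (0.049, "*"), (0.005, "**"), (0.0005, "***"),
        (0.05, "NS"), (float("nan"), "NA"),
    ])
    def test_star_bands(self, p, code):
        assert po.significance_code(p) == code


class TestGenotypeMeanSummary:
    def test_reported_fold_changes(self):
        # genotype means fixed at published-style min/max; ratio to 2 d.p.
        assert po.max_min_ratio(68996.30, 193536.82) == pytest.approx(2.81, abs=0.01)
        assert po.max_min_ratio(3894.13, 30910.20) == pytest.approx(7.94, abs=0.01)

    def test_zero_minimum_gives_na_ratio(self):
        assert math.isnan(po.max_min_ratio(0.0, 12.75))

    def test_summary_from_table(self, tiny_table):
        lo, hi, ratio = po.genotype_mean_summary(tiny_table, "glucose", "CE")
        means = tiny_table.genotype_means(stage="CE")["glucose"]
        assert lo == pytest.approx(means.min())
        assert hi == pytest.approx(means.max())
        assert ratio == pytest.approx(means.max() / means.min())

    def test_ratio_scale_invariant_and_one_iff_equal(self, tiny_table):
        scaled = TraitTable(tiny_table.values * 2.5, tiny_table.traits)
        _, _, r1 = po.genotype_mean_summary(tiny_table, "glucose", "CE")
        _, _, r2 = po.genotype_mean_summary(scaled, "glucose", "CE")
        assert r1 == pytest.approx(r2, rel=1e-12)
        vals = tiny_table.values.copy()
        vals["glucose"] = 3.0
        const = TraitTable(vals, tiny_table.traits)
        assert po.genotype_mean_summary(const, "glucose", "CE")[2] == pytest.approx(1.0)


class TestVariationTable:
    def test_one_row_per_trait(self, small_panel):
        table, _, _ = small_panel
        var = po.variation_table(table)
        assert len(var) == len(table.trait_ids)
        assert {"star_interaction", "ratio_CE", "ratio_OR", "fdr_genotype"} <= set(var.columns)

    def test_constant_trait_ns_everywhere_ratio_one(self):
        idx = pd.MultiIndex.from_product(
            [["A", "B", "C"], ["CE", "OR"], [1, 2, 3]], names=("genotype", "stage", "replicate"))
        noise = np.random.default_rng(1).normal(scale=1e-9, size=len(idx))
        vals = pd.DataFrame({"t": 5.0 + noise}, index=idx)
        table = TraitTable(vals, make_trait_meta(["t"], "phenotype"))
        var = po.variation_table(table)
        assert var.loc[0, "star_genotype"] == "NS"
        assert var.loc[0, "ratio_CE"] == pytest.approx(1.0, abs=1e-6)


def test_polymorphism_percent_example():
    assert po.polymorphism_percent(133, 139) == pytest.approx(95.68, abs=0.01)
    assert round(po.polymorphism_percent(133, 139)) == 96
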