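"""ANOVA variation screen: which traits vary, where, and how much.

For every trait the screen reports two-way (genotype, stage, interaction)
significance stars, then per stage the one-way genotype p-value and the
min/max genotype means with their fold-change ratio — the classical
variation-table layout.
"""

import warnings

import panelomics as po

warnings.filterwarnings("ignore")

table, design, truth = po.generate_panel(po.PanelConfig(seed=1))
var = po.variation_table(table)

cols = ["trait_id", "level", "star_stage", "star_genotype", "star_interaction",
        "ratio_CE", "ratio_OR"]
print(var[cols].head(10).round(2).to_string(index=False))
print()

metphe = var[var["level"].isin(["metabolite", "phenotype"])]
pct = 100 * (metphe["p_interaction"] < 0.05).mean()
print(f"genotype-x-stage interaction significant for {pct:.0f}% of "
      f"{len(metphe)} metabolite/phenotype traits")
# A high interaction rate means genotype rankings change between stages, so
# downstream correlation and network analyses are run stage by stage.
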