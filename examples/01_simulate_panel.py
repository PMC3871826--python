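"""Generate a synthetic diversity panel and inspect its design.

The generator emulates a classic multi-omics fruit study: 8 inbred parents
paired into 4 crosses with F1 hybrids, two developmental stages (cell
expansion CE, orange-red OR), 3 biological replicates, and traits on four
expression levels.  Every inheritance mode, interaction flag and
correlation block is planted and returned as ground truth.
"""

import panelomics as po

table, design, truth = po.generate_panel(po.PanelConfig(seed=1))

print(f"samples x traits : {table.values.shape}")
print(f"genotypes        : {', '.join(table.genotypes)}")
print(f"crosses          : {[f'{h} = {p1} x {p2}' for h, p1, p2 in design]}")
print(f"traits per level : {table.traits['level'].value_counts().to_dict()}")
print()
planted = truth.modes["mode"].value_counts(normalize=True).round(3)
print("planted inheritance-mode frequencies (per trait x cross x stage):")
print(planted.to_string())
print()
print(f"planted correlation-block pairs: {len(truth.planted_edges)} "
      f"({int(truth.planted_edges['cross_level'].sum())} spanning two levels)")
# The mode frequencies sit near the configured 60% additive / 40% non-additive
# split; block pairs are the edges the correlation network should recover.
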