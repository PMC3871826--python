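"""PCA overview: stages dominate, then genotypes separate within stage.

Genotype means are autoscaled (centred, unit variance per trait) and
decomposed; a combined-stage run shows the developmental shift on PC1,
stage-wise runs show the genetic structure of the panel.
"""

import warnings

import panelomics as po

warnings.filterwarnings("ignore")

table, _, _ = po.generate_panel(po.PanelConfig(seed=1))

combined = po.pca(po.autoscale(table.genotype_means()))
print("combined-stage PCA, variance explained (%):",
      [round(float(v), 1) for v in combined.variance_explained[:4]])
pc1 = combined.scores["PC1"]
for stage in ("CE", "OR"):
    grp = pc1[pc1.index.get_level_values("stage") == stage]
    print(f"  PC1 mean at {stage}: {grp.mean():+.2f}")

ce = po.pca(po.autoscale(table.genotype_means(stage="CE")), n_components=3)
print("\nCE-stage PCA scores (first genotypes):")
print(ce.scores.head(5).round(2).to_string())
# Opposite PC1 means for CE and OR reproduce the familiar two-cloud picture
# of combined-stage runs; per-stage scores spread the 12 genotypes.
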