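"""Tumor-vs-healthy differential kinase activity by the fold-change rule.

Aggregates peptide AUC to upstream-kinase activity, contrasts tumor and
healthy organoid lines, and reports kinases whose average member-peptide
fold change exceeds 2 - the reporting rule used when group sizes are too
small for per-kinase hypothesis tests.
"""

import kinomescreen as ks

cfg = ks.SimulationConfig(
    planted_fold_changes={"KIN07": ("tumor", "healthy", 4.0)},
    seed=2,
)
signals, annotation, truth = ks.generate_kinome_dataset(cfg)
activity = ks.preprocess(signals).activity

groups = {}
for sample, label in truth.sample_groups.items():
    groups.setdefault(label, []).append(sample)

fc = ks.kinase_fold_change(
    activity, annotation, groups["tumor"], groups["healthy"],
    label_a="tumor", label_b="healthy",
)
print("top kinases by average member-peptide fold change (tumor vs healthy):")
print(fc.head(5).to_string(index=False))
print(f"\nkinases above the FC > 2 threshold: "
      f"{fc.loc[fc['above_threshold'], 'feature'].tolist()}")
# KIN07 carries a planted 4-fold activity difference; its estimate is
# attenuated below 4 by kinetic saturation and shared peptides but clears
# the threshold, while unplanted kinases stay near 1.

h, p = ks.kruskal_wallis_samples(activity)
print(f"\nKruskal-Wallis across all {activity.shape[0]} samples: "
      f"H = {h:.2f}, p = {p:.3g}")
# A small p says the per-line AUC distributions differ overall.

coords, evr, _ = ks.pca_samples(activity)
print(f"\nPCA: PC1 explains {evr[0]:.0%}, PC2 {evr[1]:.0%} of variance")
print(coords[["PC1", "PC2"]].round(2))
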