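"""Simulate a kinome-profiling run and reduce it to peptide activity.

Generates triplicate phosphorylation kinetics for a small peptide panel,
then applies the full preprocessing chain: drop the internal positive
control, clamp/filter on Vmax, integrate the 640-1840 s window, replace
zero AUC values, and normalize by the CD79A_181_193 control peptide.
"""

import kinomescreen as ks

cfg = ks.SimulationConfig(
    n_samples=4,
    group_labels=("tumor", "tumor", "healthy", "healthy"),
    n_peptides=12,
    n_kinases=4,
    planted_fold_changes={"KIN01": ("tumor", "healthy", 4.0)},
    seed=1,
)
signals, annotation, truth = ks.generate_kinome_dataset(cfg)
print(f"kinetic table: {len(signals)} wells "
      f"({signals['peptide_id'].nunique()} peptides x "
      f"{signals['sample_id'].nunique()} samples x "
      f"{signals['replicate'].nunique()} replicates)")

result = ks.preprocess(signals)
print("\nnormalized AUC activity (arbitrary units, control peptide = 1):")
print(result.activity.round(2))
print(f"\n{int(result.zero_replaced.to_numpy().sum())} zero-AUC cell(s) were "
      "replaced by their line's smallest positive AUC;")
print(f"peptides dropped by the Vmax filter: {result.dropped_peptides or 'none'}")
# Rows are organoid lines, columns surviving peptides. Values are areas
# under the signal-vs-time curve, each divided by that line's control-peptide
# AUC, so 2.0 means twice the phosphorylation signal of the control.
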