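"""How well does kinase gene expression predict kinase activity?

Generates expression with a chosen rank coupling to the planted kinase
activities, then correlates activity and expression across kinases within
each organoid line. With coupling 0 the per-line R^2 hovers at the
independence expectation 1/(n_kinases - 1), the situation observed for
real tumor organoids where transcript levels say little about enzyme
activity.
"""

import kinomescreen as ks

for rho in (0.0, 0.9):
    cfg = ks.SimulationConfig(rna_activity_correlation=rho, seed=3)
    signals, annotation, truth = ks.generate_kinome_dataset(cfg)
    activity = ks.preprocess(signals).activity
    kinase_act, _ = ks.kinase_activity(activity, annotation)
    expression = ks.generate_expression(truth, cfg)
    corr = ks.correlate_per_line(kinase_act, expression)
    print(f"\nactivity-expression coupling rho = {rho}:")
    print(corr[["sample_id", "r", "r2", "p", "p_adj"]].round(3).to_string(index=False))

n_kin = 37
print(f"\nindependence benchmark: E[R^2] = 1/({n_kin}-1) = {1/(n_kin-1):.3f}")
# At rho = 0 the per-line R^2 values scatter around 0.028 (pure chance);
# at rho = 0.9 they rise far above it - expression only predicts activity
# when the generative coupling is strong.
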