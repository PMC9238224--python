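# Methods

## Kinetic model and the AUC activity measure

The readout of a tyrosine-kinase substrate array is a fluorescence signal
per peptide that grows over the incubation as the peptide population is
phosphorylated. We model the noise-free well signal as a saturating
exponential

    S(t) = S_max * (1 - exp(-r t)),     r = rho0 * sum_k w[p,k] * a[s,k]

where `a[s,k]` is the activity of upstream kinase *k* in sample *s*,
`w[p,k] >= 0` are peptide–kinase weights, and `rho0` (`rate_scale`,
default 1.5e-5 /s) sets the overall kinetic scale. The saturating form
matches substrate-depletion enzyme kinetics; vendors do not document the
true curve family, so the family is a modeling choice, not an estimate. A
`kinetic_law="linear"` variant (`S = S_max * r * t`) is provided as the
degenerate small-`r` limit in which windowed AUC is exactly proportional to
the driving rate; it is what the exactness contract tests use.

Peptide activity is the trapezoidal AUC of the replicate-mean signal over
the 640–1840 s window, with linear interpolation onto the window edges when
the sampling grid misses them. This definition is deterministic and
grid-independent, and for curves sampled every 60 s it agrees with the
closed-form integral of the saturating law to well under 0.5% (measured
~0.013% worst-case). On a shared time grid, averaging replicates before
integration equals averaging per-replicate AUCs (trapezoid linearity); we
average first because the downstream unit is one AUC per sample × peptide.

The default `rate_scale` keeps `r*t` ≲ 0.5 over the window, i.e. the early,
near-linear part of the curve. This is a deliberate regime choice: activity
*ratios* survive onto the AUC scale only approximately once curves
saturate, and at this scale a 4-fold activity difference maps to a ~3.2–3.5
fold AUC difference rather than collapsing toward 1.

### Preprocessing rules

- **Internal positive control** (`ART_003_EAI(pY)AAPFAKKKXC`): removed
  before any statistics; its absence is a warning, not an error.
- **Vmax gate**: per replicate, Vmax is the OLS slope of the earliest
  timepoints (all points ≤ 640 s, minimum 3). Vmax serves only as a
  dead-substrate filter: negative values are clamped to 0 and peptides
  whose clamped average over *all* replicates and samples is 0 are dropped
  (`filter_scope` is dataset-wide; the array vendor's own Vmax algorithm is
  not public, so the slope estimator is ours, and the primary activity
  measure remains AUC).
- **Zero replacement**: per line, AUC values ≤ 0 are replaced by that
  line's smallest strictly positive AUC and flagged. The rule is applied to
  ≤ 0 rather than exactly 0 because the trapezoid of a noisy near-zero
  curve is routinely a small negative number; strict equality would be
  fragile. Idempotent by construction.
- **Control normalization**: every line is divided by its `CD79A_181_193`
  AUC (the control column becomes exactly 1 and is dropped). Whether the
  original analysis normalized Vmax, AUC or both is ambiguous; we normalize
  AUC by default (`normalize_auc=True`) since AUC is the quantity carried
  forward.

## Kinase aggregation and differential activity

Kinase activity is the unweighted arithmetic mean of member-peptide AUC
(median available). No peptide→kinase weighting is attempted beyond the
annotation table itself; orphan peptides (no curated kinase) stay in the
peptide matrix but never reach kinase level.

Group contrasts use fold changes, not p-values: with 1–3 lines per group
there is no power for per-kinase tests, so kinases are reported when the
*average member-peptide fold change* exceeds 2 (arithmetic mean of the
per-peptide meanA/meanB ratios, direction resolved after averaging;
geometric mean available). FC is always reported as a max/min ratio ≥ 1
plus the higher group's label, so FC(A,B) and FC(B,A) are the same record
with the direction flipped.

The global Kruskal–Wallis test treats each line's peptide-AUC vector as one
group (tie-corrected H, chi-square p with df = lines − 1). PCA is computed
from the SVD of the column-centered samples × peptides matrix with a fixed
sign convention (largest-|loading| positive per component). Hierarchical
clustering uses distance 1 − Pearson r with average linkage (flag for
complete/ward); zero-variance vectors get distance 1 with a warning, and
labels are sorted before linkage so leaf order is permutation-invariant.
Peptide classification cuts the peptide dendrogram (log10 AUC) into k = 3
clusters and labels them high / heterogeneous / low by mean log10 AUC.

## Expression integration

Expression is consumed as an already-normalized (TMM-scale) genes × samples
matrix; normalization itself is out of scope. Correlation is computed
across kinases *within* each line (one scatter per organoid line), because
with ~3 lines the per-gene-across-samples direction is powerless (it exists
behind `mode="per_gene"`). Under independence, E[R²] = 1/(n−1) with n the
number of paired points — 1/(n_kinases−1) per line, 1/(n_samples−1) per
gene — which is what the null-coupling generator reproduces. Both r and R²
are reported.

## Drug screen

Viability = mean(treated wells)/mean(vehicle wells), computed on the ATP
scale when a per-line standard curve is available (linear RLU vs
concentration over the 4× series from 20 µM to 4.9 nM; log-log option for
saturating luminescence) and on raw RLU otherwise. The ratio makes calls
scale-invariant in RLU. Efficacy in a line: viability strictly below
mean − 3·SD (sample SD, ddof = 1) of that line's vehicle wells — on the
worked micro-example wells (1.0, 0.95, 1.05, 1.0, 1.0) the threshold is
0.8939. Per dose (10 µM is the analysis default; 1 µM exists in the design)
drugs are classified pan-effective / selective / ineffective over the tumor
lines, plus a tumor-selective flag when no non-tumor line is hit. No
dose–response fitting: only two doses exist.

## Biomarker correlation screen

Per drug, response = clip(1 − viability, 0, 1) at the analysis dose is
correlated with each peptide's AUC across all lines carrying both assays
(tumor panels alone are too small for exact significance). Spearman rho
uses average ranks; for n ≤ 8 the two-sided p is the fraction of all n!
rank permutations with |rho| at least the observed (conditioning on the tie
pattern), vectorized by enumerating the response permutations once per drug.
Larger n falls back to the t-approximation. The BH family defaults to
peptides-within-one-drug (`family="global"` available); significant pairs
get the OLS R² of response on AUC.

**Power at n = 5.** The exact two-sided p of a perfect monotone pair is
2/120 ≈ 0.017 and |rho| takes only 11 values {0, 0.1, …, 1}. Consequences:
after BH over ~140 peptides nothing can clear α = 0.05, and with ~36
untargeted kinases whose activities are independent of a given drug's
target, the chance that *some* untargeted kinase's peptide set reaches a
median |rho| ≥ 0.9 is near 1 − (1 − 0.083)^36 ≈ 0.94. Recovery of a planted
target by top-ranking is therefore intrinsically noisy at this panel size
(~60% of drugs under the default noise settings), mirroring the empirical
observation that drug response often correlates with kinases the drug does
not target. This is a property of small panels, not of the estimator; the
null-FDR behavior of the screen is clean (empirical FDR ≈ 0 on null drugs).

## Synthetic-data generator

What it emulates: triplicate saturating kinetics for 144 peptides
(including both control peptides) across 8 lines (3 tumor / 2 adjacent / 3
healthy); a many-to-many annotation in which each peptide has one dominant
upstream kinase (weight U(0.85, 0.97)) and further kinases with probability
0.2 each (max 3), every kinase keeping at least one member peptide; ~5%
orphan peptides; group-structured activity folds; copula-linked expression;
drug responses that are logistic in the standardized target-kinase activity
(`beta` controls activity dependence; `beta = 0` is a flat 50% response,
`beta = inf` a hard switch) with vehicle-level noise; ATP standards on an
exact linear law with well noise.

Noise model: multiplicative Gaussian per well (`noise_cv`, default 0.1 — a
free parameter, the platform's true Lux noise is unpublished) plus an
additive sensor floor (`noise_floor_lux`, default 2 Lux) so near-zero
signals can dip negative and the clamp/zero-replacement paths are really
exercised; replicates carry no systematic offset. Not emulated: spatial
array artifacts, washing/exposure cycles, batch effects, plate-position
effects, correlated kinase programs (activities are independent across
kinases given group), or realistic annotation biology. Passing tests
therefore demonstrate rule fidelity and statistical behavior, not
biological validity on real arrays.

Key defaults, units, rationale:

| parameter | default | meaning |
|---|---|---|
| `n_peptides` / `n_kinases` | 144 / 37 | array design being emulated |
| `n_replicates` | 3 | technical triplicate |
| `timepoints` | 40…1840 s, 60 s steps | spans the AUC window |
| `noise_cv` | 0.1 | per-well multiplicative CV (free parameter) |
| `noise_floor_lux` | 2 Lux | additive sensor noise |
| `rate_scale` | 1.5e-5 /s | near-linear kinetics over the window |
| `activity_cv` | 0.2 | per-line lognormal activity spread |
| `vehicle_cv` | 0.05 | well-level viability noise |
| `vehicle_mean_rlu` | 1e5 | vehicle luminescence scale |
| `atp_slope_rlu_per_um` | 5000 | standards: RLU = slope·conc |

Determinism: all randomness flows from one integer seed through
`numpy.random.default_rng`; identical (config, seed) gives byte-identical
tables, and the end-to-end pipeline writes with fixed float formatting so
repeated runs are byte-identical (verified file-by-file).

## Problem sizes used in the checks

The test-suite and the acceptance script run at the sizes the package
treats as its reference study: 20 simulator seeds for fold-change recovery
(8 lines, 144 peptides, 37 kinases) and for biomarker recovery (5 lines),
200 seeds × 3 null drugs for FDR, 2000 replicates for the Kruskal–Wallis
type-I rate, and 50 random curves for the AUC oracle; the whole suite
completes in about a minute on one CPU.

## Known limitations

- The Vmax estimator is a stand-in for an undocumented vendor algorithm;
  only its gate role (clamp + average-above-zero filter) is contractual.
- Kinase scores ignore peptide multiplicity and specificity weights; a
  kinase annotated on one noisy peptide is as credible as one on eight.
- The FC > 2 rule carries no error control; it is a reporting convention
  for underpowered designs.
- Exact Spearman enumeration is factorial: n ≤ 8 by default (40320
  permutations); beyond that the t-approximation is used.
- Expression coupling at intermediate |rho| targets the copula correlation
  on standardized scales; the realized per-line Pearson r is attenuated by
  gene-level scale heterogeneity (exact only at rho ∈ {−1, 0, 1}).
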