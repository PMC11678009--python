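# Methods

This note records the statistical methods implemented in `chemotyper`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that matter
for reproducing results.

## Preprocessing

**Sample-median normalization.** Each sample's abundances are divided
by that sample's median over non-missing metabolites. This removes
multiplicative per-sample scale (extraction yield, injection volume);
it is exact for a lognormal per-sample scale factor up to the sampling
error of the median. The operation is idempotent and preserves
within-sample rank order. A practical consequence worth knowing: when
per-metabolite replicate noise is *smaller* than the sampling error of
the median, the residual normalization error becomes a shared
per-sample factor across all metabolites, which autoscaling can
amplify into an apparent common component. With realistic replicate
CVs (≥ 10%) the effect is negligible.

**Dixon outlier exclusion.** Within each (genotype × condition × day)
replicate group, each metabolite's most extreme value is tested with
the two-sided r10 ratio Q = gap/range, against the Rorabacher (1991)
critical values packaged as constants for n = 3..30 at α ∈
{0.10, 0.05, 0.01} (default 0.05). At most one value per metabolite
per group is removed (marked missing, hence eligible for imputation);
groups with fewer than 3 observed values or zero range are never
tested. The test assumes approximate normality within the group; on
strongly right-skewed (lognormal) replicate distributions its realised
false-positive rate runs one to two points above the nominal α — an
inherent property of applying the test on the linear scale, which is
the conventional order of operations (normalize → outlier test → log).

**Log + autoscaling.** Natural log, then each metabolite column is
centred and scaled to unit sample standard deviation (n − 1) over
non-missing entries. Zero-variance columns scale to all zeros rather
than being dropped, so column indices stay aligned across strata.

**Group-aware KNN imputation.** A missing cell (metabolite i, sample
j) is imputed only when metabolite i is observed in at least one other
replicate of j's group — the "technical error" rule; metabolites
absent from an entire group stay missing and are flagged. Donors are
the k = 10 metabolite rows nearest to row i by root-mean-square
difference over mutually observed samples (overlap-normalised
Euclidean distance, so rows with different overlaps compare fairly),
restricted to donors observed at sample j; the imputed value is the
unweighted donor mean. This is the classic expression-matrix KNN
scheme applied to metabolite rows. Its known failure mode is faithfully
reproduced rather than hidden: when an entire co-regulated block loses
the same sample (e.g. the outlier filter strikes a shared extreme),
no informative donors remain and the imputed value regresses to the
row neighbourhood mean, attenuating that block's correlations.

The pipeline order is normalize → Dixon → log/autoscale → impute; a
config flag (`impute_before_scale`) moves imputation before the
transform for sensitivity analysis.

## PCA and ellipses

PCA is computed by SVD of the column-centred matrix (no missing values
accepted — imputation precedes ordination). Variance fractions are
σᵢ²/Σσ² over all singular values. Component signs are fixed so each
component's largest-magnitude loading is positive. Group ellipses are
*data* ellipses: the contour at squared Mahalanobis radius χ²₂(level)
of the group's 2×2 sample covariance (default level 0.95), not
standard-error-of-mean ellipses.

## OPLS-DA

Two classes are encoded y = ±1 and centred; X is centred on the
modelled subset (columns are already unit-variance globally). The fit
is the standard O-PLS sequence: w ∝ Xᵀy (unit norm), t = Xw,
p = Xᵀt/tᵀt; the orthogonal weight w_o ∝ p − (wᵀp)w is normalised,
t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o, and X is deflated by t_o p_oᵀ; after
the configured number of orthogonal components (default 1) the
predictive component is recomputed on the deflated matrix. Deflation
guarantees w ⟂ w_o and t ⟂ t_o to machine precision.

Diagnostics: R²X(predictive) = ‖t pᵀ‖²_F/‖X₀‖²_F against the
pre-deflation centred matrix; R²Y = 1 − SS(y − tc)/SS(y);
Q²Y = 1 − PRESS/SS(y) from stratified k-fold cross-validation
(default 7 folds, deterministic given a fold seed; held-out samples
are passed through the training model's orthogonal filter before
projection). The permutation p-value permutes class labels and
recomputes Q²Y, with the add-one estimator
p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + n_perm), so p is never zero.

VIP for the single predictive component is √M·|w_j| (‖w‖ = 1), so
ΣVIP² = M exactly; the classic multi-component VIP is available
separately. DAM selection keeps metabolites with VIP ≥ 1 **and**
|loading| at or above the 0.75 quantile of |loadings|; an optional
absolute log₂ fold-change floor can be added (used in the
time-course DAM counting below, at 0.5 on the log₂ scale ≈ 1.4-fold,
floor 0.15 in the leveling analysis where genotype effects are small).
Thresholds are recorded on every DAM table. Fold changes are group
means on the *normalized* (pre-log) scale, because ratios of
autoscaled values are meaningless.

Loading comparisons between models use Spearman rank correlation over
the intersection of metabolite ids (≥ 10 required), ties mid-ranked,
p from the large-sample t approximation.

## Metabolite-set enrichment

Metabolites are ranked by predictive loading (descending; positive =
up under the positive class; ties broken lexicographically and
logged). The enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum (weight |score|^q, default q = 1;
misses decrement 1/(N − m)). Because the ranking derives from model
loadings rather than per-sample statistics, the null is random
same-size metabolite sets drawn from the ranked universe — the scheme
of loading-ranked GSEA tools — not sample-label permutation. NES
divides ES by the mean |null ES| of matching sign; the p-value is the
add-one fraction of same-sign null scores at least as extreme;
Benjamini–Hochberg adjusts across tested sets (minimum set size 3
after restriction to the ranked universe). The pathway-overlap graph
connects significant sets sharing at least one member within the
ranked universe; node attributes carry |NES|, adjusted p and
direction.

## Correlation networks

The default stratification is one network per genotype × condition,
pooling the three sampling days (n ≈ 12), because q < 0.05 edges are
statistically implausible from 4 replicates alone; a per-day mode
exists. Pearson r and two-sided p (exact t transform, df = n − 2) are
computed for all metabolite pairs; Benjamini–Hochberg q-values over
all M(M−1)/2 tests; edges where q < 0.05 carry the signed r.
Zero-variance metabolites are excluded from testing but remain in the
node universe at degree 0.

Metrics follow Cytoscape NetworkAnalyzer conventions: density
2E/(N(N−1)) over the full node universe; diameter on the largest
connected component, unweighted; heterogeneity = coefficient of
variation of the degree distribution (population variance);
centralization = (N/(N−2))(k_max/(N−1) − density). Edgeless networks
report diameter 0, heterogeneity 0 and an undefined (None)
positive:negative ratio.

Networks are compared by (a) Bray–Curtis dissimilarity Σ|u−v|/Σ(u+v)
on degree vectors aligned by metabolite id and (b) Jaccard distance on
sign-agnostic unordered edge sets (a metabolite pair counts once
regardless of correlation sign; a signed mode exists). Two edgeless
networks compare as 0 with a warning. Ward clustering uses Ward.D2
semantics (squared distances inside the Lance–Williams recurrence, as
in SciPy); dendrograms export as rooted Newick with branch lengths
from merge heights.

## Synthetic generator

The generator produces the full factorial design — 2 genotypes × 2
oxygen conditions × days {3, 5, 7} × 4 replicates, 370 metabolites —
with a log-scale additive model per metabolite and sample:

    log x = μ + α·[hypoxia] + β·g·shrink(day) + γ·(day − 5)·atten
            + Σ_f Λ_f(condition)·z_f + ε

exponentiated and then multiplied by a per-sample lognormal scale
factor, with multiplicative single-cell outliers and sparse missing
values (MCAR by default; an intensity-dependent left-censoring mode
exists). All randomness flows from one seeded generator.

Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `baseline_log_mean/sd` | 8.0 / 0.5 | lognormal abundance baseline |
| `condition_effect_sd` | 2.0 | log-effect scale of the 40 planted DAMs (≈ e² ≈ 7-fold); magnitudes are drawn near the scale and bounded away from zero so every planted DAM is genuinely differential |
| `condition_diffuse_sd` | 0.01 | diffuse hypoxia response on all non-DAM metabolites; sized to stay below the VIP ≥ 1 selection cutoff while still producing profile-wide loading similarity between genotypes |
| `genotype_effect_sd`, `n_genotype_dams` | 0.25, 60 | varietal differences on a dedicated metabolite subset, disjoint from DAMs and blocks so ground-truth attribution is unambiguous |
| `genotype_shrink_rate` | 0.55 | geometric decay of the genotype effect per sampling day under hypoxia only — the "leveling" of varietal differences during submergence |
| `age_effect_sd`, `age_attenuation_hypoxia` | 0.02, 0.3 | per-day developmental drift, attenuated under hypoxia (developmental arrest) |
| `n_latent_factors`, `block_size`, `factor_loading_sd` | 5, 12, 0.8 | co-regulation blocks driving network edges; pairwise within-block correlation ≈ λ²/(λ²+σ²) ≈ 0.98 before pipeline attenuation |
| `hypoxia_only_blocks`, `normoxia_only_blocks` | 3, 1 | condition-specific block activity (inactive blocks keep 0.25× loading): stress-induced hubs give hypoxia networks more active modules, a heavier degree tail and condition-separated Ward clustering |
| `sign_mixing_fraction` | {normoxia 0, hypoxia 0.3} | fraction of block members whose loading sign flips per condition; drives the positive:negative edge ratio contrast |
| `noise_sd` | 0.1 | replicate noise (≈ 10% CV) |
| `outlier_prob/multiplier` | 0.002 / 30 | sporadic technical spikes, large enough to be Dixon-detectable even inside high-variance blocks |
| `missing_prob` | 0.01 | sparse missingness |
| `sample_scale_sd` | 0.2 | per-sample lognormal scale |

Effect sizes interact through autoscaling: after per-metabolite
standardisation the *relative* sizes of condition, genotype, age and
factor variance decide which structure dominates the ordination, so
the defaults were chosen jointly — the condition axis (planted DAMs)
carries the largest between-group variance, genotype and age axes stay
clearly below it, and latent factors sit below both. The defaults
constitute the study conditions for all recovery tests; tests average
stochastic metrics over a small set of fixed generator seeds.

What the generator does **not** emulate: retention-index drift and
misannotation, batch/run-order effects, intensity-dependent
heteroscedasticity of GC-MS detectors, correlated missingness, and
dense pathway-level stoichiometric constraints. Recovery results on
synthetic data therefore demonstrate the correctness and calibration
of the algorithms under the stated statistical model, not performance
on raw instrument data.

## Numerical conventions and degenerate inputs

- Floats serialise at 6 significant digits; missing values as empty
  cells (also parsed from "NA"); written outputs are byte-deterministic.
- Dixon ties between the two extremes go to the upper end.
- All-zero or constant columns never produce NaNs: autoscaling maps
  them to zeros, correlation testing excludes them with a warning.
- Degenerate OPLS-DA contrasts (single class, zero-variance y,
  Xᵀy ≈ 0) raise errors rather than fitting noise.
- ES for a set spanning the whole list is exactly 1 (no miss
  decrements); all-zero hit weights fall back to unweighted
  increments.
- The permutation and fold assignments are deterministic given their
  seeds and are recorded in the run manifest.

## Problem sizes

The bundled analyses run at the study's natural scale (48 samples ×
370 metabolites); recovery statistics average over 3–8 generator
seeds, permutation tests use 199–2000 permutations and enrichment
nulls 1000–10000 draws. A full end-to-end run completes in seconds on
one CPU; the complete test suite in about a minute.

## Known limitations

- The Dixon critical table covers n ≤ 30; larger replicate groups are
  skipped with a warning (they are outside the method's intended
  regime anyway).
- Q²Y for very small strata (n = 8) is noisy; the pipeline reports it
  per model rather than pretending stability.
- The intervarietal "leveling" statistics at n = 8 carry a sizeable
  overfit floor in R²X(predictive); the decline across days is a
  property of seed-averaged means, and Q²Y shows it far more sharply
  than R²X.
- Correlation-network recovery is bounded by the imputation failure
  mode described above; with default settings the measured
  within-block edge recall is ≈ 0.85–0.9, not 1.
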