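# Methods

## The model and its assumptions

The pipeline estimates associations between sleep phenotypes (exposures) and
metabolite abundances (outcomes) in a complex survey sample. Metabolite
levels are modelled as survey-weighted linear regressions of the
rank-inverse-normalised abundance on the phenotype plus covariates. Two
nested covariate sets are used: Model 1 (batch, age, sex, centre,
background, BMI) and Model 2 (Model 1 plus alcohol, smoking, physical
activity, diet). Phenotypes come in three kinds:

- **continuous / binary** — one exposure coefficient; the estimate, SE and a
  t-type Wald p-value are reported;
- **circular** clock times in minutes past midnight, where 23:59 and 00:01
  are adjacent. They are encoded as (sin θ, cos θ), θ = 2π·t/1440 with
  midnight as the angular origin, and tested with a joint Wald test of the
  two coefficients. No single effect estimate exists for them.

Inference is design-based throughout: point estimates are weighted least
squares, and variances are Taylor-linearised between-PSU covariances within
strata. The estimator assumes every stratum contributes at least two PSUs
and that weights are inverse inclusion probabilities.

## Pre-processing

Stage order is fixed: (1) drop metabolites missing in more than 75% of
either batch (strict "more than"; a metabolite at exactly 75% in both is
kept — the threshold is configurable); (2) half-minimum imputation per batch
for xenobiotics, whose missingness is treated as below-detection-limit
censoring; (3) chained-equations multiple imputation with predictive-mean-
matching draws for the remaining metabolites, run separately per batch,
producing m = 5 completed datasets (statsmodels `MICEData`; each target's
imputation model uses the other metabolites plus age, sex and BMI, capped at
the 30 most correlated predictors for tractability); (4) rank-based
inverse-normal transform Φ⁻¹((rank − ½)/n), midranks for ties, per batch and
per completed dataset; (5) pairing of the k-th completed batch-1 dataset
with the k-th completed batch-2 dataset by row concatenation, columns
aligned by name.

The (rank − ½)/n offset is symmetric and finite at both extremes; a
constant column maps to all zeros. The transform makes each column's
empirical distribution standard normal, so downstream effect sizes are in SD
units of the transformed outcome (a planted raw-scale effect β appears
attenuated by the outcome's total SD — e.g. 0.3 → ≈0.283 under the default
noise model; validation tests account for this).

## Covariate functional forms

Continuous confounders (age, BMI, physical activity, diet) may act
nonlinearly. Per metabolite × covariate, five candidates are scored —
linear, and natural cubic splines with 1–4 interior knots at equal quantiles
(patsy `cr` basis; K interior knots contribute K+1 columns beyond the
intercept) — each adjusted for the baseline covariates, using individuals
with observed metabolite levels. AIC is −2·(weighted Gaussian
pseudo-log-likelihood, weights normalised to sum to n) + 2·(mean
parameters). The least complex form within 2 AIC points of the minimum is
selected; a tie at exactly +2 goes to the simpler form. Under a truly linear
relationship this rule keeps the linear form with probability ≈0.90 (the
four spline improvements behave as nested χ²₁ increments), which the test
suite checks against that oracle.

## Pooling and testing across imputations

- **Single coefficients**: Rubin's rules. T = W̄ + (1 + 1/m)B; the reference
  t distribution uses Barnard–Rubin degrees of freedom with the survey
  residual df as the complete-data df. When the completed datasets are
  numerically identical (missing-information fraction < 1e−9), pooling
  reproduces the single-dataset fit bit-for-bit — a deliberate degenerate-
  case rule so that "no missing data" is exactly equivalent to m = 1.
- **Circular phenotypes**: the sine/cosine covariance cannot be pooled
  across imputations, so the per-dataset joint Wald p-values are combined
  with the aggregated Cauchy association test (equal weights 1/m). ACAT is
  valid under the strong dependence between completed datasets; p-values
  below 1e−15 use the Cauchy tail approximation tan((0.5 − p)π) ≈ 1/(pπ),
  and the inverse map uses arctan(1/T)/π for T > 0 to avoid cancellation, so
  combining m identical p-values returns that p to machine precision.
- **FDR**: Benjamini–Hochberg step-up across metabolites within each
  (phenotype, model, stratum) family; Model-1 FDR p < 0.05 flags
  significance. Xenobiotics (single completion) are fitted once.

## Design-based variance conventions

The design df is d = #PSU − #strata. Two small-sample conventions are
adopted, both standard in survey regression software:

- the linearised meat carries the stratum factor n_h/(n_h − 1) **and** the
  cluster-regression dof factor (n − 1)/(n − p); in the equal-weight,
  one-observation-per-PSU limit the covariance is then exactly HC1
  (HC0 × n/(n − p)), which the oracle tests assert to 6+ significant digits;
- reference distributions inside the scan use the residual-df convention
  d − p + 1 (p = model parameter count): t(d − p + 1) for single
  coefficients (as the Barnard–Rubin complete-data df) and F(q, d − p + 1)
  for the joint circular test. Called directly with no model parameter
  count, `wald_joint` falls back to F(q, d − q + 1).

Without these factors the null rejection rate of the scan ran about half to
one percentage point above nominal at desk scale (≈200 PSUs, ~16 model
columns); with them the null is calibrated (see the acceptance checks).

## The synthetic cohort

`synthdata` emulates the structure of a multistage community cohort:

- **Design**: 20 strata × 20 PSUs by default. A real community survey
  samples hundreds of small clusters, and linearised variances need clusters
  to far outnumber model parameters; smaller PSU counts make every
  design-based test visibly anticonservative.
- **Weights**: inverse inclusion probabilities from a logistic selection
  model on standardised age plus a stratum effect. `weight_informativeness`
  scales the age coefficient; 0 gives weights uncorrelated with age.
- **Batches**: participants fall into batch 2 with probability
  `batch_fraction` (default 0.35); batch 2 is on average 8 years older
  (mirroring the two profiling waves) and its metabolites carry a +0.4 SD
  location shift, removed by per-batch normalisation and the batch
  covariate.
- **Phenotypes**: per-domain counts over Duration, HR, Insomnia, EDS, SDB,
  Timing. Non-timing phenotypes are Gaussian latents loading mildly on age;
  every second one is dichotomised at the median (prevalence ≈ 0.5). Timing
  phenotypes are von Mises clock times (κ = 2) around typical bed/wake
  times.
- **Metabolome**: unit-variance Gaussian baseline + 0.15·z_age + 0.10·z_BMI
  + planted effects + batch shift + noise. Circular effects act as
  A·sin(θ + φ). Xenobiotics are left-censored below the batch-specific
  `missing_rate_xeno` quantile (default 0.20); other metabolites get MAR
  gaps whose probability rises with age and BMI, averaging
  `missing_rate_other` (default 0.05).

What the generator does **not** emulate: the real phenotype definitions and
their correlation structure, LC-MS measurement error, household clustering
within PSUs, non-Gaussian abundance distributions (rank normalisation makes
the scan invariant to monotone distortions anyway), and missingness that is
not MAR given the modelled covariates. Passing tests therefore demonstrate
the statistical machinery is correct under a faithful design, not that any
particular biological finding replicates.

## Network summaries

The consolidated domain × subpathway count matrix defines a weighted
bipartite graph. "Cluster coefficient" is deliberately implemented as
connectance L/(n_rows·n_cols) — the ratio of realised to possible links —
not the standard bipartite clustering coefficient. Nestedness is NODF
(paired overlap with the strictly-decreasing-fill rule, ×100) and its
weighted extension on counts. Community structure is Barber's bipartite
modularity Q = (1/m)Σ(a_ij − k_i d_j/m)·1{g(i)=g(j)}. The exact optimiser
enumerates set partitions of the smaller node class and assigns each node of
the other class to its best-scoring module (or a fresh singleton) — this
conditional assignment is optimal, so the search is globally exact while
enumerating only Bell(min side) partitions; it is used whenever the graph is
small enough (≤12 total nodes or a smaller side of ≤9). Larger graphs use
seeded alternating label optimisation from 50 random starts, whose Q can
never exceed the exact optimum (asserted against the enumeration oracle on
small graphs). Layouts are seeded Fruchterman–Reingold (networkx) with
isolated nodes placed on a surrounding ring and a lone node at the origin.

## Numerical choices and degenerate inputs

- p-values are floored at 1e−15 end to end; ACAT inputs of exactly 0/1 are
  clipped with a warning, values outside [0,1] are errors.
- Singular design matrices raise an error naming the collinear columns
  (pivoted QR); a constant covariate in form selection yields the linear
  candidate only, with a warning (fitted by `lstsq`, tolerant of the rank
  deficiency).
- A stratum with one PSU is rejected at construction ("lonely PSU").
- Dice similarity of two empty sets is NaN with a warning, not 0.
- Ties at the top-10% connectivity cutoff are all included, so the list may
  exceed its nominal size.
- Binary-phenotype biomarker R² uses a weighted logistic fit with a
  variance-function pseudo-R² on the response scale — a documented
  approximation, not the linear-model adjusted R².

## Problem sizes

Desk-scale defaults keep the full pipeline and its validation fast while
preserving every structural feature: n = 1200–2000 participants, 60–104
metabolites, 5–11 phenotypes, m = 3–5 imputations. Null calibration uses
5 circular phenotypes × 104 metabolites (520 ACAT-pooled tests); parameter
recovery uses 20–50 replicate cohorts at n = 2000. These sizes are the
package's chosen simulation conditions; all of them are configurable.

## Known limitations

- The ACAT combination of per-dataset Wald tests (the only available route
  for circular exposures under multiple imputation) is slightly
  anticonservative for moderately correlated completed datasets — a
  property of the method itself, visible as a fraction of a percentage point
  at the null.
- The chained-equations imputer relies on numpy's global random state
  (seeded and restored around each call), a constraint inherited from the
  underlying implementation.
- The heuristic modularity optimiser reports the best Q found; only the
  enumeration path is guaranteed optimal.
- Survey-weighted logistic pseudo-R² values are not comparable to published
  likelihood-based R² variants.
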