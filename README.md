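# sleepatlas

A tested pipeline for building a sleep–metabolome association "atlas":
survey-weighted association scans between sleep phenotypes and untargeted
blood metabolomics, with the pooling, multiple-testing and network-summary
machinery such an atlas needs. The cohort data that motivated the design
(a multistage stratified community sample with two metabolomics batches) is
access-restricted, so the package ships a first-class synthetic-data module
that reproduces the *structure* of such data — strata, PSUs, unequal
sampling weights, batch contrasts, below-detection-limit missingness — with
known ground-truth effects, making every downstream stage verifiable.

## What it computes

For each sleep phenotype *x* (continuous, binary, or circular clock time)
and each metabolite *y* (rank-inverse-normalised within batch and imputed
dataset), the scan fits the survey-weighted linear model

> y = β·x + γ′z + ε  (weights w, strata h, PSUs j)

with Taylor-linearised stratified-cluster variance for β̂ and design df
d = #PSU − #strata. Circular phenotypes (bed/wake times, minutes past
midnight with 0 ≡ 1440) enter as sin θ, cos θ of θ = 2π·t/1440 and are
tested jointly with a multivariate Wald test. Missing metabolite values are
imputed — half-minimum per batch for xenobiotics (below-detection-limit
censoring), chained-equations multiple imputation (m = 5, predictive mean
matching) otherwise — and results are pooled across completed datasets with
Rubin's rules (single coefficients; Barnard–Rubin df) or the aggregated
Cauchy association test ACAT, T = Σᵢ wᵢ tan((0.5 − pᵢ)π), for the circular
Wald p-values whose sine/cosine covariance has no pooling rule.
Benjamini–Hochberg FDR is applied across metabolites within each
(phenotype, model, stratum) family; Model-1 FDR p < 0.05 defines a
significant association.

The significant pairs are then summarised as an atlas: a binary
phenotype × metabolite incidence matrix, consolidated domain × pathway
incidence/weight matrices, Dice similarity DSC = 2|X∩Y|/(|X|+|Y|) between
domain-level metabolite sets, top-connected metabolites, and bipartite
network properties (connectance, shared partners, NODF nestedness and its
weighted variant, Barber bipartite modularity Q, Fruchterman–Reingold
layout).

## Worked example

```python
import sleepatlas as sa

cfg = sa.SyntheticConfig(
    n_individuals=800, n_metabolites=20, n_xenobiotic=2,
    n_phenotypes_per_domain={"Duration": 1, "Timing": 1},
    effects={("duration_1", "met_001"): 0.4,
             ("timing_1", "met_002"): sa.CircularEffect(amplitude=0.5, phase=0.3)},
    seed=42)
cohort, phenotypes, matrix, truth = sa.simulate(cfg)
stack = sa.preprocess(matrix, cohort, m=5, seed=1)
design = sa.DesignInfo.from_cohort(cohort)
records = sa.scan(stack, phenotypes, cohort, design, model=1)
print(records[records.significant][["phenotype", "metabolite", "estimate", "p_fdr"]])
```

prints:

```
     phenotype metabolite  estimate         p_fdr
0   duration_1    met_001  0.381319  2.000000e-14
21    timing_1    met_002       NaN  2.000000e-14
33    timing_1    met_014       NaN  3.006169e-02
38    timing_1   xeno_001       NaN  3.006169e-02
```

The two planted associations are recovered overwhelmingly (p-values sit at
the pipeline's 1e−15 floor before BH adjustment). The duration estimate,
0.38, is the planted 0.4 SD effect attenuated by the rank-normalised
outcome's total SD. Circular timing associations carry no single estimate —
the sine/cosine pair is tested jointly and only the ACAT-pooled p is
reported. The two additional timing hits at p_fdr ≈ 0.03 are false
positives, a reminder that FDR 0.05 admits them by design.

The same flow is available from the shell:

```bash
sleepatlas all --config demo.yaml --out runs/demo
```

where `demo.yaml` holds a `synthdata:` block (or paths to the four input
tables), model/strata choices, `alpha`, and `m`. The run directory contains
the association table, incidence and consolidated matrices, the Dice matrix,
network properties and layout coordinates, all tab-delimited with a header
recording the package version, config hash and master seed; re-running the
same config reproduces the files byte-for-byte.

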