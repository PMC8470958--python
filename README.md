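# twinpath

Maximum-likelihood variance decomposition for the classical twin design:
univariate ACE/ADE models, multivariate **independent-pathway** models,
likelihood-ratio submodel selection, and a synthetic twin-cohort generator.

## The problem

Monozygotic (MZ) co-twins share all of their segregating genes; dizygotic
(DZ) co-twins share half on average.  Comparing how similar MZ pairs are to
how similar DZ pairs are identifies how much of a phenotype's variance is
**additive genetic (A)**, **shared environmental (C)** (or **dominance (D)**),
and **unique environmental (E)**.  With several phenotypes at once, the
independent-pathway model further splits each source into a *common* factor
loading on every trait (Ac, Cc, Ec) and *trait-specific* components
(As, Cs, Es) — so it can answer whether traits such as left-ventricular
systolic and diastolic function are driven by the same genes and exposures
or inherit independently (their co-heritability).

## The model

For p traits ordered (twin 1, twin 2), the model-implied pair covariance is

```
Sigma_z = [[V, W_z], [W_z, V]],   V = Σ_S  Sigma_S,   W_z = Σ_S κ(S, z) · Sigma_S
Sigma_S = λ_S λ_Sᵀ + diag(s_S²)
```

with cross-twin sharing coefficients κ: A → 1 (MZ) / ½ (DZ); C → 1 / 1;
D → 1 / ¼; E → 0 / 0.  λ_S are the common-factor loadings and s_S the
specific paths of source S; variances are squared paths, so the structure
is positive semidefinite for any real parameter values.  Means are modelled
per individual as `intercept + β_age·age + β_sex·sex`.  Parameters are
estimated by minimizing the exact −2 log-likelihood of the pair vectors
(quasi-Newton with analytic gradients, deterministic multi-start), and
submodels are compared by the likelihood-ratio χ² test: the most
parsimonious model without significant deterioration (α = 0.05) is kept.
Standardized shares (e.g. trait heritability `A = Ac + As`) are the squared
paths divided by the trait's total model variance.

## Worked example

Generate a cohort whose truth mirrors a diastolic-function block (common
genetic shares 40/25/9 %, common unique-environment shares 23/49/11 %),
then run the full pipeline — complete-case filter, full independent-pathway
fit, backward elimination, report:

```python
from twinpath import ip_backward_elimination, render_report, simulate_twin_dataset
from twinpath.simulate import diastolic_like_config

config = diastolic_like_config(n_mz=2000, n_dz=2000, seed=7)
dataset = simulate_twin_dataset(config)
trace = ip_backward_elimination(dataset, config.trait_names, alpha=0.05, seed=1)
print(render_report(trace.selected, trace, "Diastolic").to_text())
```

```
Diastolic Model — selected: drop specific C:LSrE
Variable                                            LSrE       EeLat         DCT
Common genetic and environmental factors
Genetic factors (Ac)                                 38%         22%          9%
Shared environmental factors (Cc)                     0%          0%          0%
Environmental factors (Ec)                           24%         51%         11%
Specific genetic and environmental factors
Genetic factors (As)                                  0%         27%         30%
Shared environmental factors (Cs)                     0%          0%          0%
Environmental factors (Es)                           38%          0%         50%
Overall contribution of genetic and environmental factors
Genetic factors (A)                                  38%         49%         38%
Shared environmental factors (C)                      0%          0%          0%
Environmental factors (E)                            62%         51%         62%
```

Each column is one trait; cells are integer-percent variance shares.  The
common rows say how much of the trait's variance is carried by factors
shared with the other traits (here: a common genetic and a common
environmental factor across all three, recovering the generating 40/25/9
and 23/49/11 within sampling error), the specific rows what is private to
the trait, and the overall block their sums — the trait's heritability
(A row) and environmental share (E row).  At the bundled study-scale
default (54 MZ + 38 DZ pairs) the same pipeline runs but the shares carry
wide sampling error; the cohort size is the dominant limit.

The same pipeline is available from the shell:

```
twinpath simulate --preset diastolic-like --seed 7 --out cohort.csv
twinpath correlations --data cohort.csv
twinpath fit --data cohort.csv --preset diastolic --seed 1 --out run/
```

`fit` writes `report.txt`, `decomposition.csv` (full-precision shares),
`fit_table.csv` (−2LL / df / AIC / LRT p per candidate) and
`provenance.json`.  Presets: `systolic` (GLS, GCS, BasalRot, ApicalRot),
`diastolic` (LSrE, EeLat, DCT), `systolo-diastolic` (GLS, LSrE, EeLat, DCT).

## Input format

Wide CSV, one row per twin pair:
`pair_id, zygosity (MZ/DZ), age_1, age_2, sex_1, sex_2` and `T_1, T_2` per
trait T.  Sex is coded 0 = male, 1 = female; missing values are empty
cells; UTF-8 with `.` decimals.

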