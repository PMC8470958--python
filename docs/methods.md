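# Methods

## Model

The sampling unit is the twin pair.  For p traits the stacked pair vector
y = (twin 1 traits, twin 2 traits) is modelled as multivariate normal with
zygosity-specific covariance

    Sigma_z = [[V, W_z], [W_z, V]],   V = Σ_S Sigma_S,
    W_z     = Σ_S κ(S, z) Sigma_S,    Sigma_S = λ_S λ_Sᵀ + diag(s_S²),

where S ranges over the included variance sources and the cross-twin
sharing coefficients κ are: additive genetic A — 1 (MZ) / ½ (DZ); shared
environment C — 1 / 1; dominance D — 1 / ¼; unique environment E — 0 / 0.
λ_S is the loading vector of the single common S factor (the
independent-pathway part; identically zero in univariate models, and a
free common factor requires at least three traits for identification) and
s_S the trait-specific paths.  C and D are never included together: with
twins reared together they are not jointly identifiable.  E is always
included — it also carries measurement error, and without it the pair
covariance is singular.

Assumptions inherited from the classical twin design: equal environments
for MZ and DZ pairs, random mating, negligible gene–environment
interaction and correlation, and multivariate-normal phenotypes after
covariate adjustment.

### Means and covariates

Each individual's mean is `intercept_i + β_age,i · age + β_sex,i · sex`
(sex coded 0 = male / 1 = female).  Adjustment happens inside the means
model rather than by pre-residualizing phenotypes, so the twin covariance
structure is untouched by the adjustment.  The literature this package
serves rarely states which convention was used; the means-model route is
the cleaner default and is what the likelihood below assumes.

## Likelihood and optimization

The fit criterion is the exact −2 log-likelihood
`Σ_pairs [2p·log 2π + log det Sigma_z + rᵀ Sigma_z⁻¹ r]`.  It is evaluated
from per-zygosity sufficient statistics (cross-moment matrices of the pair
vectors and of the covariate patterns), which makes one evaluation O(p³),
independent of the number of pairs, with the quadratic form obtained via a
Cholesky factorization of Sigma_z.  Analytic gradients with respect to all
paths and means parameters are supplied to the optimizer.

Parameterizing variances through unconstrained real paths (variance =
path²) keeps every iterate positive semidefinite without constrained
optimization.  The price is a sign indeterminacy; after fitting, signs are
canonicalized (first entry of each free loading vector ≥ 0, specific paths
≥ 0), so estimates are unique and reproducible across runs.

Optimization is L-BFGS-B from 10 deterministic starting points by default
(relative function tolerance 1e-10, projected-gradient tolerance 1e-5,
memory 25).  Start 0 splits each trait's sample variance equally over that
trait's free paths and sets the means to pooled sample means; later starts
scatter paths multiplicatively and randomize loading signs, all driven by
one seeded generator.  Covariates are centered at their pooled means
inside the optimizer (an exact reparameterization, undone on output),
which decorrelates intercepts from slopes and speeds convergence
substantially.  The best optimum across starts is kept; if no start meets
tolerance the model is returned with `converged = False`, never as an
exception.

Pairs are put into a canonical within-pair order (lexicographic on
phenotypes, age, sex) before the statistics are accumulated.  The model is
twin-exchangeable, so this is mathematically a no-op; it makes the
likelihood — and every downstream fit — bit-for-bit invariant to swapping
twins within a pair.  Double-entry twin correlations are computed from
per-pair symmetric sums for the same reason.

### Saturated reference model

The fit ceiling is an unstructured model: free per-zygosity mean vectors
(2p each) plus shared age/sex slopes, and free per-zygosity 2p×2p
covariances.  It is fitted by alternating exact conditional maximizations
(GLS for the means, residual second-moment matrices for the covariances),
which is coordinate ascent on the exact likelihood; with no covariates it
lands on the closed-form Gaussian MLE in one step.

## Model selection

Submodels are compared by the likelihood-ratio test: Δ(−2LL) (clamped at
zero) against χ² with Δdf equal to the difference in free parameters;
α = 0.05 by default, configurable everywhere.

*Family screen.*  ADE replaces ACE when r_MZ > 2·r_DZ in the double-entry
twin correlations (ties go to ACE), since under ACE r_MZ = a² + c² can be
at most twice r_DZ = ½a² + c².

*Univariate sequence.*  The full three-source model is fitted, then the
submodels AE, CE, E (AE, E under ADE), each LRT-compared with the full
model; the submodel with the fewest free parameters among those with
p ≥ α is selected (ties by lower AIC), defaulting to the full model.  AIC
is reported throughout but selection is by LRT.

*Independent-pathway backward elimination.*  From the full model (common
A, C, E factors plus specific A, C, E paths per trait), every currently
free element — a common factor as a whole, or a single specific path — is
tentatively fixed to zero and LRT-tested against the current model; the
element with the largest p among those with p ≥ α is removed and the
search repeats.  Two refinements:

- **Factors before paths.**  A common factor that loads on a single trait
  is observationally equivalent to that trait's specific path, so a pure
  largest-p-first rule can remove the specific path and strand an empty
  common factor that then carries genuinely trait-specific variance and
  can no longer be dropped.  When both classes contain droppable
  candidates, whole common factors are therefore removed first
  (largest-p-first within the class).  This resolves the equivalence
  toward the more parsimonious structure (a factor removal frees p
  parameters, a path removal one).
- **Variance floor.**  A candidate that would leave some trait with no
  free path (zero total variance, hence a singular likelihood) is skipped
  and logged.

The final model is additionally gated by an LRT against the initial full
model; if that test is significant, the last accepted model that still
passes it is returned.  Candidate fits are warm-started from the current
estimates with the removed element zeroed.

*Boundary caveat.*  Null variance components lie on the boundary of the
parameter space, so the true null distribution of the LRT is a χ̄² mixture
with more mass near zero; the naive χ² p-values used here are conservative
for removal (they under-reject), which is standard practice in twin
modelling.  Tests of interior parameters (covariate slopes) are exactly
calibrated, and the test suite verifies the nominal 5 % rate for dropping
a null sex effect.

### Reported decomposition

Standardized shares come from the selected model: per trait i,
V_i = Σ_S (λ_{S,i}² + s_{S,i}²), common share λ²/V, specific share s²/V;
they sum to one per trait by construction (enforced to 1e-9).  Rendered
tables round half-up to integer percent, so a rendered column may sum to
99–101.  The full-model shares are also available but are noisier where a
true component is zero: the A-vs-C split is identified only through the
DZ group, and at a few thousand pairs a spurious common-C share of up to
~0.1 can appear in the full fit; the elimination step prunes it, which is
why the decomposition of record is the selected model's.

## Synthetic cohorts

The generator draws, per source, one common latent factor and one specific
latent factor per trait, with cross-twin correlation ρ = κ(S, z) realized
as `x_j = √ρ·shared + √(1−ρ)·unique_j`, so twins are exchangeable and the
margins are exactly standard normal; phenotypes are linear in the latents
through the configured paths plus the means model.  Ages (clipped at 18)
and sexes are drawn once per pair — twins share a birth date and the
design is same-sex.  Defaults echo a middle-aged volunteer twin cohort:
54 MZ + 38 DZ pairs, age 56 ± 9 years, 65 % female.  One integer seed
drives a single generator stream; identical seeds give bit-identical
datasets.

Three bundled truths cover the qualitative regimes the selection machinery
must distinguish, on unit trait variance with a mild means model
(β_age = 0.02 per year, β_sex = 0.2):

- *systolic-like* — four deformation traits, no common factors; specific
  genetic shares 76/77/57/64 %, the remainder specific E.  (The natural
  source for the fourth column reported specific shares summing to 110 %;
  the generator keeps its specific-E share of 36 % and assigns the
  complement to specific A, since shares must sum to one.)
- *diastolic-like* — three traits sharing a common genetic factor
  (40/25/9 %) and a common unique-environment factor (23/49/11 %).
- *systolo-diastolic-like* — GLS with purely trait-specific determination
  (74 % genetic) alongside the diastolic block; common loadings on GLS are
  zero, so the block structure tests co-heritability detection.

What the generator does **not** emulate: non-normal or censored
phenotypes, opposite-sex DZ pairs, sex-limitation or gene–environment
interaction, missingness mechanisms beyond missing-completely-at-random,
and measurement error beyond what E absorbs.  Passing tests therefore
certify the estimator and search under the model's own assumptions — not
robustness to their violation in real echocardiographic data.

## Numerical choices and problem sizes

Tolerances: LRT zero-statistic tolerance 1e-6; share normalization check
1e-9; saturated-fit convergence 1e-10 relative.  Degenerate inputs raise
typed errors (singular model covariance, zero-variance traits, too few
pairs per zygosity group) rather than crashing the search; non-converged
candidates are never selected.

Simulation-backed checks use sizes at which sampling error is well inside
the asserted bands while keeping the suite fast: moment checks against
Monte-Carlo covariances at 10⁶ pairs per zygosity; parameter recovery at
2000 + 2000 (multivariate) and 5000 + 5000 (univariate) pairs; selection
consistency over 50 seeded replicates at 2000 + 2000; LRT calibration over
500 replicates at 200 + 200.  Replicate studies use one initial multi-start
fit (4–6 starts) and warm-started single-start candidate fits.

## Known limitations

No confidence intervals for shares (no bootstrap or profile likelihood);
no FIML — missing data are handled by complete-case filtering of pairs;
no Cholesky or common-pathway multivariate models; no sex-limitation
models; the boundary-conservative LRT noted above.  Univariate fits of a
full three-source model near a boundary (e.g. true c² = 0) inherit the
usual slow √n behaviour of boundary MLEs; the submodel sequence is the
remedy, as in standard practice.
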