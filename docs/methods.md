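# Methods

## Model family

All models are multigroup Gaussian moment structures over the 2m observed
variables of a relative pair (member-1 block, then member-2 block), fitted by
full-information maximum likelihood. Three families share one interface:

**Saturated pair models.** Unstructured means/variances plus a within-pair
covariance (or correlation) per group, under nested equality constraints:
none (15 free parameters for one variable over three groups), within-pair
equal (9), additionally across-group equal (5), additionally DZ = sibling
correlation (4). These are the reference models for the homogeneity tests and
the twin correlations. In the constrained levels the within-pair association
is parameterized as a correlation so it can be profiled directly.

**Univariate ACE family.** Per-member variance `a11^2 + c11^2 + e11^2`;
cross-member covariance `kappa * a11^2 + c11^2` with kappa fixed at 1 (MZ) or
0.5 (DZ, siblings) and the shared-environment correlation fixed at 1 in all
groups (equal environments). Siblings are a separate group with DZ-equal
moments; the saturated ladder's last level tests the DZ = sibling constraint
that this equality relies on. Submodels AE/CE/E are structural zeros, not
re-parameterizations, so nesting is exact.

**PRS-augmented model.** Observed triple (phenotype, trait PRS, SUD PRS) per
member. Latent PRS factors have unit variance and correlation `a32`; the
observed scores are scaled by free standard deviations `d11`, `d22` (with
standardized score data these sit near 1, and path coefficients coincide
with correlations). Within-person covariances: `Cov(Y,P1) = d11*(b21 +
b31*a32)`, `Cov(Y,P2) = d22*(b31 + b21*a32)`, `Var(Y) = b21^2 + b31^2 +
2*b21*b31*a32 + a11^2 + c11^2 + e11^2`. Every PRS-involving cross-member
covariance is multiplied by kappa; the phenotype cross-member covariance is
`kappa*(PRS part + a11^2) + c11^2`. Residual A/C/E act on the phenotype only
(the path diagram places no residual structure on the scores).

Path coefficients, not variance components, are the free parameters;
`a11, c11` are bounded at 0 (resolving the sign indeterminacy), `e11 >=
1e-8`, `|a32| <= 0.999`, `d > 1e-6`, and `b21, b31` are sign-free.

**Degenerate MZ covariance.** MZ co-twins have identical genotypes, hence
identical PRSs; the implied 6x6 MZ covariance is exactly singular. The
likelihood is therefore defined on the reduced observed vector: where both
PRS copies are observed the second is dropped, and where only the second is
observed it is moved into the first slot. This loses no information (the
copies are equal whenever both observed) and makes every marginal covariance
nonsingular.

## Likelihood and optimization

Pairs are grouped by missingness pattern and reduced to per-pattern
sufficient statistics (count, mean, maximum-likelihood scatter), so one
likelihood evaluation costs O(#patterns) rather than O(#pairs); the value is
identical to the pairwise sum. Pairs with every cell missing contribute zero
and are counted. Non-positive-definite marginal covariances evaluate to +inf
through the public function; inside the optimizer they are mapped to a large
finite penalty (1e10) because L-BFGS-B's line search cannot interpolate
across infinities but backtracks correctly off a finite plateau.

Optimization is bound-constrained L-BFGS-B with finite-difference gradients,
multi-start (default 5 starts, jitter scale 0.1 on standardized data,
seed-controlled). Each start is polished by restarting L-BFGS-B (which
resets its curvature memory) until the improvement falls below 1e-8
relative; this reliably escapes premature line-search stalls. The
convergence flag requires the best two starts to agree within 1e-4 in −2LL
*or* a small projected gradient; because finite-difference gradient noise
scales with |−2LL|, the gradient tolerance is relative (1e-5 times the −2LL
magnitude) rather than absolute. Saturated models are started at the
per-group sample moments, which are already the MLE on complete data.

AIC is −2LL + 2·(free parameters). Model comparisons use Δ−2LL referred to a
chi-square with df equal to the difference in free parameter counts; no
boundary-mixture correction is applied to variance-component tests (the
convention of the mainstream workflow this mirrors), which is conservative
for parameters on a bound and exact for the sign-free PRS paths.

## Confidence intervals

Profile likelihood at 95%: each bound is where the profile −2LL
(re-optimizing all other free parameters, warm-started along the path)
exceeds the minimum by chi-square(1, 0.95) = 3.841, located by geometric
bracketing plus Brent root refinement. Bounds clipped at structural limits
carry a boundary flag (e.g. `c11 >= 0`); profiles that never reach the
threshold inside the admissible region are flagged one-sided. Standardized
*shares* are profiled through an equality-constrained substitution: fixing
the residual A share at s imposes `a11^2 = s/(1-s) * (c11^2 + e11^2)`, which
eliminates `a11` and leaves an ordinary inner optimization. Wald covariances
(2·H^{-1} from the numeric Hessian of −2LL) are available for quick
standard errors and are used in the recovery tests to express "within 3
Monte-Carlo SE".

Two share conventions are reported, because published twin-model summary
tables are ambiguous on this point: residual-relative shares
(`a11^2/(a11^2+c11^2+e11^2)`, the values such tables print — an AE row reads
0.91/0.09 even with a nonzero PRS path) and total-relative shares, which sum
to one together with the PRS-explained share. Both are exposed on
`StandardizedSummary`.

## Identification

Local identification is the rank of the central-difference Jacobian (step
1e-6, relative) of the stacked unique moments — group means plus
lower-triangular covariances — with respect to the free parameters,
identified iff rank equals the free-parameter count. Rank is computed by SVD
with an absolute floor of 1e-10 on singular values. A second, jittered probe
guards against symmetry-collapsed points (a parameter sitting exactly where
the Jacobian loses rank non-generically); if the two ranks disagree the
report is flagged ambiguous and the larger rank kept. When deficient, the
parameters loading on the null-space singular vectors are named — for an
MZ-only ACE model this flags `a11`/`c11`, whose squares enter the two
distinct moments only as a sum.

## Synthetic generator

The generator is the package's stated world: three relative groups at study
scale (222 MZ, 328 DZ, 387 sibling pairs), phenotype built from the
PRS-augmented model exactly as specified above. Genetic sharing uses a
family-shared + segregation variance split (half/half for DZ and siblings;
full sharing for MZ), which yields cross-member genetic correlations of
exactly 0.5 and 1 rather than approximately. C is fully shared in every
group, including siblings — the base model makes no special-twin-environment
distinction, and a homogeneity-violating preset (member-2 SD inflated by
sqrt(2)) exists precisely to exercise the assumption tests. Covariates: age
mean 10.0 y (SD 0.6) shared exactly by twins, sibling age gaps centred on
1.3 y (SD 0.5, random sign); sex Bernoulli(0.5) per individual (effect 0.1);
standardized intracranial volume per individual (effect 0.3); ten
family-shared genetic PCs with effects 0.02 each, consistent with PCs
explaining well under 1% of phenotype variance. Missingness is MCAR per cell
(default 0). Default truth follows the cortical-surface-like preset
(a11^2=0.55, c11^2=0.26, e11^2=0.18, b21=0.13, b31=0.06, a32=0.04); the
putamen-like preset is the AE-dominant case (0.91/0.09, b21=0.20). Preset
variance components are the published summary-row values taken as raw
components (they sum to ~1 before the small PRS part), so residual-relative
truth shares equal the published numbers exactly.

What the generator does *not* emulate: PRS measurement error (scores are
noiseless genetic values), informative missingness, scanner/site effects,
assortative mating, dominance, gene–environment interaction, or sex-specific
genetic effects. A green recovery test therefore establishes correctness of
the estimation machinery under the model's own assumptions, not robustness
to their violation.

## Design choices on genuinely open points

- **CI method** is profile likelihood (the convention of the SEM software
  the workflow mirrors); the source workflow does not state Wald vs profile.
- **Residualization** of the phenotype on age, sex, intracranial volume, and
  ten PCs is pooled over all individuals ignoring family clustering, as a
  pre-step; the within-family dependence is then carried by the twin model.
  Residualization and PRS standardization statistics come from the analysis
  sample itself. Residuals are not rescaled to unit variance afterwards.
- **Stage-1 structure selection** keeps both PRS paths and `a32` free in all
  ACE/AE/CE/E candidates; a `sequential=False` flag runs the single-shot
  alternative from the full ACE structure.
- **FDR grouping** defaults to independent correction within each drug-PRS
  analysis group across regions.
- **Sex homogeneity** is tested on stacked individuals with a plain
  two-group normal LRT (df 2), ignoring family clustering — a deliberate
  simplification, flagged in its row label.
- **Member-slot assignment** is arbitrary and preserved from input; all
  moment structures are exchangeable in the two slots, and slot-swap
  invariance of the likelihood is tested.
- The Table-1-style mixed-model screen uses family as the clustering unit
  and the variance-partition definitions of marginal/conditional R^2
  (fixed, and fixed + random, over total).

## Numerical tolerances

Likelihood-oracle agreement 1e-8; saturated-MLE moment match 1e-4; nesting
monotonicity tolerance 1e-4 (violations indicate optimizer failure and fail
tests); PSD tolerance −1e-10 on the minimum eigenvalue; profile root
tolerance 1e-5 in parameter units. Recovery tests at 5000 pairs/group use 3
Wald SEs; calibration tests use 500 null replicates at study scale and
require rejection rates in [0.03, 0.07] at alpha = 0.05.

## Known limitations

No ACDE, dominance, sex-limitation, or special-twin-environment (T) models;
no Bayesian estimation or sandwich standard errors; saturated models are
single-phenotype (the multivariate moments are exercised through the
PRS-augmented model); the naive chi-square reference for boundary parameters
is conservative; profile CIs assume a unimodal profile within the bracket.
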