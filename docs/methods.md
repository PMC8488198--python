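# Methods

## Model

For one gene with m cis-SNPs the observed data are the marginal eQTL
z-scores γ̂₁ ∈ ℝᵐ, the marginal GWAS z-scores γ̂₂ ∈ ℝᵐ, and two LD
matrices R̂₁, R̂₂ estimated from reference panels matching the eQTL and
GWAS populations. Under the regression-with-summary-statistics (RSS)
approximation, marginal z-scores computed by simple linear regression
satisfy

    γ̂₁ | γ ~ N(R̂₁ γ, R̂₁),        γ̂₂ | γ ~ N(α′ R̂₂ γ, R̂₂),

where γ is the vector of *joint* standardized cis effects on expression
and α′ couples the two arms: the GWAS joint effects are assumed
proportional to the eQTL joint effects (no horizontal pleiotropy), with
proportionality α′ = α·c on the z-score scale. The constant
c = (σ̂_y/σ̂_z)·√(n₂/n₁) is positive, so testing α′ = 0 is equivalent to
testing the expression-on-trait effect α = 0; c is used only to report
α̂ on the raw scale when the sample SDs and sizes are supplied. A single
Gaussian prior γ ~ N(0, σ²_γ I) closes the model. The free parameters
per gene are θ = (σ²_γ, α′).

The approximation quality of the RSS arms improves with the sample sizes
behind the z-scores and with the polygenicity of the signal; no formal
diagnostic is attached, but the exact marginal likelihood (below) is
exposed for empirical checks.

### Constant-dropping convention

Every working likelihood surface drops the terms free of γ and θ,
namely −½ γ̂ᵀR̂⁻¹γ̂ − ½ log|2πR̂| for each arm. These cancel in the
likelihood-ratio statistic, and avoiding them is what lets the fit run
without inverting LD matrices. `model_core.dropped_constant` recovers
them when a full log-density is needed.

## Fitting: PX-VBEM

The marginal log-likelihood decomposes as ELBO + KL(q‖posterior). With a
fully factorized Gaussian q(γ) = ∏ₖ N(μₖ, s²ₖ), both the variational
factors and the parameters have closed-form coordinate maximizers, so
the fit alternates:

* **E-step** — one ascending Gauss–Seidel sweep; coordinate k gets the
  exact full conditional given the freshest means of the others:
  s²ₖ = 1/(τ²R̂₁,ₖₖ + α′²R̂₂,ₖₖ + 1/σ²_γ),
  μₖ = s²ₖ(τγ̂₁,ₖ + α′γ̂₂,ₖ − τ²Σ_{l≠k}R̂₁,ₖₗμₗ − α′²Σ_{l≠k}R̂₂,ₖₗμₗ).
  The sweep is sequential in ascending SNP order (fixed for
  determinism) and maintains running products R̂μ so each coordinate
  costs O(m); the inner loop is numba-compiled.
* **M-step** — σ²_γ = (Σμ²ₖ + s²ₖ)/m; α′ = γ̂₂ᵀμ/(μᵀR̂₂μ + ΣR̂₂,ₖₖs²ₖ);
  τ = γ̂₁ᵀμ/(μᵀR̂₁μ + ΣR̂₁,ₖₖs²ₖ). Given q the ELBO separates in the
  three parameters, so the simultaneous update is a joint maximizer.

τ is a redundant *parameter-expansion* multiplier on the eQTL-arm mean
(the expansion is applied to that arm only); maximizing over it
accelerates convergence on LD-correlated instances. The expanded fit is
reduced back to τ = 1 via σ²_γ ← τ²σ²_γ, α′ ← α′/τ (and μ ← τμ,
s² ← τ²s² for the posterior), which leaves both the marginal likelihood
and the ELBO unchanged. Expansion is applied under both the null and the
alternative fit so the two surfaces are comparable.

Defaults: initialization σ²_γ = 0.01, α′ = 0, τ = 1, μ = 0, s² = σ²_γ;
convergence when the relative ELBO change per iteration falls below
10⁻⁶, capped at 1000 iterations; σ²_γ floored at 10⁻⁸ so genes with no
eQTL signal yield a well-defined (degenerate) fit rather than an error.
Each half-step is monotone in the ELBO, and the trace is recorded per
half-step so monotonicity is directly testable. The fit is deterministic
given data and initialization.

## The likelihood-ratio test

H₀: α′ = 0 against H₁: α′ ≠ 0. Both fits share initialization and
tolerances; the alternative fit is warm-started from the null fit's
posterior, which suppresses spurious negative statistics. The model is
linear-Gaussian, so its marginal is available in closed form: the
stacked z-scores are zero-mean Gaussian with blocks
Cov(γ̂₁) = R̂₁ + τ²σ²_γR̂₁R̂₁, Cov(γ̂₂) = R̂₂ + α′²σ²_γR̂₂R̂₂, and
cross-covariance τα′σ²_γR̂₁R̂₂. The statistic plugs the two PX-VBEM
estimates into this exact marginal:

    Λ = 2·[log L(θ̂_alt) − log L(θ̂_null)],   p = P(χ²₁ > Λ).

**Why not the raw ELBO difference?** The ELBO is the natural surrogate,
and it is what the optimizer maximizes. But the null and alternative
fits carry *different* KL gaps, and in the weak-eQTL-information regime
(small n₁·h²_C) the gap differential dominates: we measured 28–30%
rejection at nominal 5% with the ELBO statistic, and essentially zero
correlation with the exact-marginal LRT on the same data. Evaluating the
exact marginal at the variational estimates instead tracks the full
numerical-MLE LRT almost perfectly (r ≈ 0.999 in that regime) and
restores calibration (4–5% empirical size). The cost is one 2m × 2m
solve per fit — per gene, not per iteration, so the motivation for the
variational fit (no LD inversions inside the optimization loop) is
preserved. `lrt(..., statistic="elbo")` retains the surrogate for
comparison.

Because the two surfaces are maximized separately, Λ can come out
negative by numerical noise; negative values are clamped to 0 (placing a
point mass at p = 1) and counted. Batch runs report the genomic
inflation factor λ_GC = median(Λ)/0.4549364 (the χ²₁ median); gene lists
use a fixed p < 5×10⁻⁶ cut by convention, with Bonferroni available as
an option. Score tests, fine-mapping, and pleiotropy-robust variants are
out of scope; under horizontal pleiotropy the null being tested is "no
expression-trait effect and no pleiotropy", as for all TWAS of this
type.

## LD estimation and harmonization

Reference panels are small relative to m (defaults assume a few hundred
samples against ~100 SNPs), so the sample Pearson correlation P of the
mean-centered dosage columns is shrunk toward the identity:
R = (1−s)P + sI, guaranteeing eigenvalues ≥ s. Defaults: s = 0.1 for
real panels, s = 0.05 throughout the simulation suite (a sensitivity
check at the concordance settings gave R² between 0.90 and 0.93 for s in
[0.01, 0.1], so conclusions do not hinge on it). Harmonization
intersects SNPs across the four sources, takes the GWAS panel's allele
orientation as the reference frame, flips z-score signs and dosage
orientation for swapped pairs (also after strand complement), and drops
strand-ambiguous (A/T, C/G) variants with logged counts. Cis-window
extraction is upstream: inputs arrive already windowed per gene. PLINK
and VCF parsing are out of scope; users supply delimited dosage matrices
or precomputed correlation matrices.

## Synthetic data

The generator emulates a linked eQTL/GWAS design:

* **Genotypes** — rows of a latent Gaussian with AR(1) covariance
  Σₖₗ = ρ^|k−l| (ρ ∈ {0.2, 0.5, 0.8} in the study grid; AR(1) is the
  standard concrete choice for a banded LD structure and makes the
  adjacent-SNP correlation equal ρ on the latent scale), thresholded at
  the Hardy–Weinberg quantiles of a per-SNP MAF ~ U(0.05, 0.5) to give
  0/1/2 dosages.
* **Expression** — y = W₁γ + e₁, with spike-and-slab γ (each SNP causal
  with probability π, at least one causal enforced) and e₁ scaled so the
  realized cis-heritability h²_C = var(W₁γ)/(var(W₁γ)+σ²_e1) hits its
  target exactly per replicate (empirical, not theoretical, variances —
  exact control at finite n).
* **Trait** — z = αW₂γ + e₂ with unit noise and α scaled the same way to
  the target h²_T; h²_T = 0 gives the null (α = 0).
* **Summary statistics** — per-SNP simple linear regression on the
  centered dosage column, n−2 df standard errors; LD matrices from
  fresh panels (n₃ = n₄ = 400) drawn from the same genotype law.

Scenario variants: `shared` uses one genotype law (one ρ, one MAF
vector) for all four matrices; `distinct_ld` gives the GWAS side an
independent law with a different ρ (default 0.8 against the eQTL side's
0.5; both exposed in config); `distinct_ld_and_architecture`
additionally retains only `overlap_fraction` (default 0.5) of the eQTL
causal set on the GWAS side, replacing the rest with new causal SNPs of
matched effect variance. Defaults elsewhere: m = 100 cis-SNPs; power
study at n₁ = 500, n₂ = 10000; concordance and type-I studies at
n₁ = n₂ = 5000; heritability grids h²_C ∈ {0.01, …, 0.09},
h²_T ∈ {0.001, 0.002, 0.003}; sparsity grid {0.1, …, 0.5, 1}; rejection
level 0.05 (the power study's nominal level is a parameter).

What the generator does *not* emulate: real LD (block structure,
long-range LD, allele-frequency-dependent LD), population stratification
or relatedness, non-Gaussian expression noise, horizontal pleiotropy,
and imperfect SNP overlap between sources. Passing tests therefore
certify internal statistical correctness of the method under its own
assumptions — calibration and power on real cohorts additionally depend
on those unmodeled features.

Every generator is a pure function of (config, seed); experiment
harnesses spawn independent child seeds per cell and replicate, so runs
are bitwise reproducible and cells are independently seeded.

## Comparator methods

* **Individual-level-eQTL LRT** (`comm_s2_lrt`) — the same latent-effect
  model with the eQTL arm replaced by the exact Gaussian likelihood
  y | γ ~ N(W₁S₁γ, σ²_e I), where S₁ = diag(σ̂_y/(√n₁·sd(wₖ))) keeps γ on
  the z-score scale; σ²_e is a free parameter. Fitted by the same
  PX-VBEM machinery on precomputed sufficient statistics (Gram matrix,
  cross-products), tested with the same exact-marginal LRT — the
  (n+m)-dimensional marginal is evaluated with the Woodbury identity and
  the determinant lemma so only m × m algebra is ever done.
* **Two-stage TWAS** (`two_stage_twas`) — stage 1 fits ridge or elastic
  net (mixing 0.5) of expression on standardized genotypes with 5-fold
  cross-validated penalty (deterministic fold assignment); stage 2 forms
  the weighted summary z-score Σₖwₖσₖγ̂₂,ₖ/√(wᵀDR̂₂Dw) with D the
  reference-panel dosage SDs and per-dosage weights w. An empty model
  (elastic net may select nothing) reports p = 1 and is flagged.

## Numerical choices and degenerate inputs

Zero M-step denominators keep the previous parameter value and log a
warning; a fit that collapses to τ = 0 is returned with the variance
floored and flagged degenerate. Zero-variance genotype columns are
errors naming the SNP. A perfectly fitting SNP in the summary-statistic
generator either errors (default) or yields a |z| = 10⁶ sentinel.
Relative ELBO convergence uses max(|previous|, 10⁻³) in the denominator
to behave near zero. LD matrices are validated for symmetry and unit
diagonal on construction; positive definiteness is the shrinkage
estimator's contract.

## Problem sizes in the shipped experiments

The acceptance script runs the power cell at its full 500 replicates.
The concordance experiment uses 300 paired replicates pooled over the
15-cell heritability grid (20 per cell) rather than the 2000 of the
original design; R² and slope are pooled-population quantities, so the
reduction widens their Monte-Carlo error without shifting them. The
type-I experiment in the test suite uses 2000 null replicates pooled
over the h²_C grid. Oracle-equivalence checks run at m ≤ 5 with
uncorrelated LD — there the mean-field family contains the exact
posterior, so the variational optimum must coincide with the exact
marginal MLE and any ascent or reduction bug is visible; under
correlated LD the fit is intentionally only a lower-bound maximizer and
the comparison is kept as a bound (ELBO ≤ exact marginal), not an
equality.

## Known limitations

The χ²₁ reference is asymptotic and assumes the null parameter is
interior; for genes with essentially no eQTL signal σ²_γ sits at its
floor and the test is conservative-to-misbehaved in ways the clamping
and flags surface but do not repair. The RSS arms treat panel-estimated
LD as fixed truth; small panels with large m inflate statistics (the
empirical size at n₁ = 500, h²_C = 0.01 is ~4–5% with the marginal
statistic but was measured up to ~10% for the *numerically exact* LRT in
that regime — the boundary effect, not the variational approximation, is
the binding constraint). Mean-field underestimates posterior variance
under strong LD, which is why the exact marginal, not the ELBO, anchors
the reported statistic.
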