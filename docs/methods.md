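# Methods

## Model and tests

The package works with binary-coded genotypes G ∈ {0,1} and a binary
disease indicator x under the retrospective logistic risk relation
Pr(x = 1 | G) = expit(μ + θG). The per-marker score statistic

    Z = Σᵢ (xᵢ − x̄)(gᵢ − π̂) / √( n x̄(1−x̄) π̂(1−π̂) )

is N(0,1) under the null; for a balanced design it reduces to
½√n (π̂₁ − π̂₀)/√(π̂(1−π̂)). Across a block, cor(Z_j, Z_k) equals the
genotype correlation cor(G_j, G_k) under the null and local alternatives,
so the score vector is treated as N_K(Δ, R) with R estimated from the
pooled genotype columns (`estimate_R`) or supplied analytically. Under a
local alternative with log odds ratio θ at causal marker c, the induced
mean is Δ_j = θ · R_{j,c} · B_j with B_j = √(n x̄(1−x̄) π_j(1−π_j)); an
uncorrelated marker has Δ_j = 0. Where block frequencies differ, an
alternative scaling of the induced mean through the non-causal marker's
own frequency is possible; the column-times-B rule is used throughout
because it is the form the prior-weighted constructions operationalize.

Block-level tests built from (Z, R):

* `pvalue_zmax` — p = 2(1 − Φ_R(Z_max·1_K)) ("printed" mode, the form used
  in the power tables) or the exact rectangle 1 − Pr(−Z_max ≤ Z ≤ Z_max)
  ("rectangle" mode). The printed form double-counts the overlap of the
  two tails and therefore bounds the rectangle form from above; with
  strongly negatively correlated blocks this makes the printed test
  visibly conservative (rejection ≈ 0.036 at α = 0.05 on the 7-marker
  fixture), which is a property of the method, not an error.
* `pvalue_bonferroni` — K times the best two-sided single-marker p.
* `weights_optimal` / `pvalue_linear` — L = R⁻¹Δ/√(Δ′R⁻¹Δ), equivalently
  the leading-eigenvector route through H = R^{−1/2}ΔΔ′R^{−1/2}; both are
  implemented and agree to 1e-8 (H is rank one). L′Z is tested against
  N(0,1) since L′RL = 1.
* `weights_prior` — maximizes the prior-averaged (pre-posterior)
  non-centrality: H = R^{−1/2}[Σ_k w_k Δ^(k)(Δ^(k))′]R^{−1/2} with
  Δ^(k) = (k-th column of R) ∘ B; the weights are R^{−1/2} times the
  leading eigenvector. A uniform prior gives the agnostic combination; a
  two-point prior the paired combination; a point mass reproduces the
  optimal weights.

Numerical choices: R^{−1/2} by symmetric eigendecomposition with
eigenvalues floored at 1e-10; linear systems solved (Cholesky) with a
ridge of 1e-8 on the diagonal, never via an explicit inverse — the
embedded blocks contain near-collinear pairs (r = 0.99). The optimal
weights are renormalized against the unridged R so L′RL = 1 exactly, and
the non-centrality is evaluated as (L′Δ)², keeping the closed-form and
eigen routes consistent to machine precision. Eigenvector sign is fixed by
L′Δ̄ > 0 (Δ̄ the prior-mean Δ); if the leading eigenspace is degenerate
(e.g. independent markers under a symmetric prior) the prior-mean Δ is
projected onto it, which makes the weights deterministic and symmetric.
p-values are clamped to [0,1] (the printed max-Z form can exceed 1 for
small statistics). Monomorphic markers are hard errors: a silent NaN would
corrupt every maximum over |Z|.

The MVN CDF uses scipy's randomized quasi-Monte-Carlo rule with an
explicitly seeded generator, so every p-value is bit-reproducible for a
given call seed. Inside the power engine the max-Z p-value is computed
adaptively: a cheap evaluation (maxpts 4,000) decides most replicates, and
only p-values within 0.01 (then 0.0015) of a significance threshold are
refined at maxpts 60,000 and 500,000 — decision errors near the boundary
are ~1e-4, far below the Monte-Carlo standard error of the rejection
fractions.

## Synthetic data

`BlockSpec` holds marker frequencies plus a target pairwise Pearson
correlation matrix, at either allele (haplotype) or dominant-carrier
resolution. Parametric compound-symmetry and AR(1) builders cover designed
experiments; two embedded fixtures carry the printed MAFs and pairwise
correlations of an 8-marker and a 7-marker chromosome-10 LD block.

Two generators produce correlated binary draws:

* `fit_joint_bernoulli` (default for K ≤ 12) — the maximum-entropy joint
  distribution over the 2^K patterns matching every marginal and pairwise
  product moment, fitted by Newton iteration on the exponential-family
  dual. Published LD tables routinely sit on their pairwise Fréchet
  bounds (real haplotype structure with D′ ≈ 1), where a Gaussian copula
  has no jointly consistent parameterization; the explicit pattern
  distribution does, so the fixtures are reproduced essentially exactly.
  Pairwise targets are pulled a relative 1e-3 toward independence so
  boundary targets keep finite parameters.
* `calibrate_latent` — the dichotomized-Gaussian construction: thresholds
  Φ⁻¹(1 − p_k), each pairwise latent correlation solved by bracketed
  root-finding on the bivariate normal orthant probability (evaluated by
  deterministic quadrature of the correlation-derivative identity), then
  nearest-PD repair by eigenvalue clipping with rescaling to unit
  diagonal. Appropriate for large K and for parametric CS/AR(1) blocks,
  where no repair is needed.

Both report `max_abs_repair`: the largest gap, on the binary correlation
scale, between what the fitted model actually induces and the printed
target. Two sources feed it: (i) printed targets that exceed their
Fréchet bound outright — MAFs and correlations are rounded independently
in publications, so e.g. r = 0.93 at MAFs 0.25/0.22 overshoots the
attainable 0.92 — are clipped to the bound (violations beyond 0.05 on the
correlation scale abort with the bound printed); (ii) any PD repair. For
the embedded fixtures the max-entropy engine's gap is ≈ 0.011 and 0.010,
entirely due to one clipped pair per block; the latent engine's gap on the
8-marker fixture is ≈ 0.25 because its pairwise latent solutions are
jointly far from positive definite — the main reason the joint fit is the
default. Downstream fidelity checks use tolerance 0.003 + `max_abs_repair`.

Disease status follows logit Pr(case | G) = μ + θ·G_causal with μ chosen
so the population prevalence is 10% (the score tests and the retrospective
odds-ratio identity are insensitive to this choice in the rare-to-moderate
range). Case-control samples are drawn prospectively by batch rejection
until both quotas fill, with a guard at 10⁴·(n_case + n_control) draws.

## Study designs

`StudyConfig(design=...)` selects the resolution of a simulation study:

* `"haplotype"` (default) — sampling units are haplotypes, two per
  subject (so 1000 cases contribute 2000 case haplotypes), G is the allele
  indicator, the risk acts on the causal allele, and score statistics and
  R̂ are computed on the haplotype units. The score vector then carries
  the block's allele-level correlation structure. This is the resolution
  at which haplotype-based association analyses of dense blocks operate,
  and the one that reproduces the embedded fixtures' published operating
  characteristics: dominant-coded diploid carriers of common alleles
  mathematically cannot attain strong negative correlations (the carrier
  Fréchet bound at frequency ≈ 0.74 is about −0.35), so the 7-marker
  block's printed structure — and the conservative max-Z null and
  optimal-combination power observed on it — only arise at haplotype
  resolution.
* `"dominant"` — diploid subjects; two independent haplotypes are paired
  and dominant-coded (carrier frequency 1 − (1−p)²), the risk acts on
  carrier status, and the score statistics carry the induced, attenuated
  carrier-level correlation, available in closed form via
  `genotype_level`.

Combination weights in `run_study` are built once from the analytic
unit-level block — they encode each method's assumed prior knowledge, not
the realized data — and rescaled per replicate so L′R̂L = 1 against the
estimated correlation (`correlation_mode="estimated"`, the practical
workflow; `"oracle"` uses the population matrix). Per-replicate RNG
streams derive from (seed, odds-ratio index, replicate index), making
results independent of evaluation order and resumable per odds ratio.

## Importance sampling for far tails

`tail_rejection_is` estimates Pr(p_method < α) under the null for α far
below naive Monte-Carlo resolution (down to 5×10⁻⁸). The rejection regions
reduce to thresholds: {max|Z| > t} for the max-statistic tests (t solved
from the MVN p-value, monotone in the maximum) and {|L′Z| > z_{α/2}} for
linear combinations. For max-statistic regions the proposal is a symmetric
mixture over all 2K mean shifts ±c·R e_j — one per marker tail — under
which the likelihood-ratio weight collapses to K·exp(c²/2)/Σ_j cosh(c z_j),
bounded above so the estimator cannot explode; a single symmetric shift
along R L suffices for linear regions. The scale c is tuned on a pilot so
roughly 30% of proposals land in the region. The estimate carries a
delta-method standard error and an effective-sample-size flag (< 50 marks
the estimate unreliable). The sampler is validated against closed forms
(K = 1; independent-marker Bonferroni) and against naive Monte-Carlo at
α = 10⁻⁴–10⁻².

## Problem sizes and what the tests show

The default study size everywhere is 1000 cases + 1000 controls per
replicate with 10,000 replicates per table cell (Monte-Carlo SE ≤ 0.005),
and 3,000 replicates per grid point for the qualitative-ordering
experiments; unit tests use smaller calibration runs (2,500–3,000
replicates) with 99% binomial confidence bands. Simulator fidelity is
checked at 10⁶ haplotypes and odds-ratio recovery over 200 replicates.

The generator matches marginals and pairwise correlations (exactly, for
small blocks); it does not reproduce higher-order haplotype structure of
any real population, recombination hotspots, genotyping error, population
stratification, or missingness. Passing tests therefore demonstrate the
operating characteristics of the tests under the stated moment structure,
not performance on arbitrary real cohorts. Known limitations: the
max-entropy engine enumerates 2^K patterns and is capped at K = 12; the
printed-form max-Z test is conservative under strong negative correlation
(by construction); covariate adjustment, additive/recessive codings,
imputation dosages and missing-genotype handling are out of scope — inputs
must be complete, binary-coded matrices.
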