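# multimarker

Multi-marker association tests for case-control studies in linkage-
disequilibrium (LD) blocks: per-marker score tests, the correlation-
calibrated maximum-Z test, Bonferroni correction, and optimal /
prior-weighted linear combinations of score statistics — together with a
correlated-binary genotype simulator and a Monte-Carlo power engine.

## The problem

Genome-wide association studies test hundreds of thousands of SNPs one at a
time and correct with Bonferroni, which ignores that neighbouring markers
in an LD block are strongly correlated. Exploiting that correlation buys
power at the same family-wise error rate. This package implements the
closed-form multi-marker tests that make this practical for analysts
working block-by-block, and the simulation machinery needed to study their
operating characteristics.

## The statistics

For binary disease status x ∈ {0,1} and a binary-coded genotype
G ∈ {0,1} (e.g. dominant coding), the per-marker score test of
H₀: no association is

    Z = Σᵢ (xᵢ − x̄)(gᵢ − π̂) / √( n x̄(1−x̄) π̂(1−π̂) )  ~  N(0, 1),

and across the K markers of a block **Z** ~ N_K(0, **R**) where **R** is —
to first order — the Pearson correlation matrix of the genotype columns,
estimable from the data at hand. The block-level tests are:

* **Maximum Z** — Z_max = max_k |Z_k| with p = 2(1 − Φ_R(Z_max·1_K)) from
  the multivariate normal CDF (an exact-rectangle variant
  1 − Pr(−Z_max ≤ **Z** ≤ Z_max) is also provided);
* **Bonferroni** — p = min(1, K · 2(1 − Φ(Z_max)));
* **Optimal linear combination** — with Δ = E(**Z**) under a local
  alternative (Δ_k = θ R_{k,c} B_k, B_k = √(n x̄(1−x̄) π_k(1−π_k)), causal
  marker c), the weights **L** = **R**⁻¹Δ / √(Δ′**R**⁻¹Δ) maximize the
  non-centrality (E L′**Z**)² = Δ′**R**⁻¹Δ subject to L′**R**L = 1;
* **Prior-weighted combinations** — the weights maximizing the
  pre-posterior expected non-centrality under a prior over which marker is
  causal: a uniform prior over all K markers ("agnostic", `comb_eq`) or
  over a candidate subset (`comb_pair`).

The simulator builds correlated binary haplotypes with prescribed
frequencies and pairwise correlations — by an exact maximum-entropy joint
Bernoulli fit over the 2^K patterns for small blocks, or a dichotomized
Gaussian (latent-threshold) model for larger ones — and draws case-control
samples from a logistic risk model by rejection sampling. Two embedded
fixtures reproduce an 8-marker and a 7-marker chromosome-10 LD block
(printed MAFs and pairwise correlations from a smoking-cohort genome scan).

## Worked example

Simulate one case-control data set (1000 cases / 1000 controls, dominant
coding) from the 8-marker block with a causal effect of OR = 1.7 at marker
5, then test the block:

```bash
multimarker simulate --block chr10-8 --odds-ratio 1.7 --causal-marker 5 \
    --n-case 1000 --n-control 1000 --seed 7 --out demo.tsv
multimarker test --genotypes demo.tsv \
    --methods bonferroni,zmax,comb_opt,comb_eq --causal-marker 5 \
    --pair 5,4 --seed 7 --out results
```

`results/scores.tsv` holds the per-marker score statistics; marker 5 (the
causal one) reaches Z = 6.00 and its neighbour in strong LD (marker 6,
r = 0.96) Z = 5.60, while the nearly uncorrelated marker 7 stays at
Z = −1.16. `results/tests.tsv` collects the block-level tests:

```
method          statistic     p_value
bonferroni      6.003992082   1.540192748e-08
zmax            6.003992082   2.722291237e-08
comb_opt        5.985750902   2.15393803e-09
comb_eq         4.023617848   5.731088572e-05
comb_pair(5,4)  5.039159703   4.675802017e-07
```

The optimal combination (which assumes the causal marker is known)
achieves the smallest p-value; the data-driven maximum-Z test is close
behind; the agnostic equal-prior combination pays for spreading its
weights over all eight markers.

Power studies run from a YAML config
(`multimarker power --config study.yaml --out outdir`), and far-tail null
rejection probabilities — e.g. at genome-wide α = 5×10⁻⁸, far beyond naive
simulation — via the importance sampler
(`multimarker tail --block chr10-8 --method zmax --alpha 5e-8`).

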