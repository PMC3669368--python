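# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package. It is written for a reader who wants to know
exactly what is simulated and what a passing test suite does — and does not
— establish.

## Genotype simulation

All simulators work at the haplotype-allele level: a genotype is the sum of
two independent Bernoulli "layers". This has two consequences that hold by
construction rather than approximately: every site is in Hardy-Weinberg
equilibrium regardless of LD structure, and the correlation between two
genotype codes equals the correlation imposed between the corresponding
alleles (correlated layers add; the factor of two cancels in the
correlation). Correlation could equally be imposed on the genotype codes
directly; the allele level was chosen because it preserves HWE exactly.

* **Exchangeable blocks** use the conditional-linear-family construction:
  allele j+1 is Bernoulli with mean `p + r/(1+(j-1)r) · Σ(y_i − p)`. For
  equal marginals this conditional mean always stays in [0, 1], so any
  r ∈ [0, 1) is feasible; the empirical pairwise correlation is verified in
  tests at mean absolute error ≤ 0.03.
* **Causal-anchored blocks** draw each tag allele conditionally on the
  anchor allele with mean `p + r(a − p)`. Tags are conditionally independent
  given the anchor, so tag-tag correlation is exactly r² (0.25 / 0.81 at the
  grid's r = 0.5 / 0.9) — the minimum achievable under a one-factor
  structure.
* **Feasibility.** Unequal Bernoulli marginals bound the achievable
  correlation (Fréchet): r ≤ min(√(p₁q₂/p₂q₁), √(p₂q₁/p₁q₂)). Grid settings
  violating the bound are rejected before simulation, never clipped. This is
  why the causal-anchored grid shares one MAF between causal and tag SNPs:
  a 5%/30% pair caps r at ≈ 0.35, below the grid's 0.9.

### Realistic-LD fixture

`make_realistic_fixture` builds a *synthetic* haplotype pool emulating a
phased ~900 kb region: 80 common SNPs, a central ~400 kb gene containing 33
of them (23 intergenic SNPs on the left flank, 24 on the right), 6 causal
SNPs (4 intragenic, 2 flanking close to the gene), MAFs in [0.06, 0.50], and
a moderate-strong LD block (pairwise r² > 0.5) straddling the gene's upper
boundary. Haplotypes are generated by a first-order Markov chain of
correlated Bernoulli alleles (lag-1 correlation ≈ 0.8–0.98 inside designated
blocks, ≈ 0.05 elsewhere, always clipped to 98% of the Fréchet bound) over
4000 haplotype draws, then collapsed to unique haplotypes with empirical
frequencies. It reproduces the *composition* of the region it emulates
(intragenic/intergenic/causal counts, MAF band, a boundary-crossing block),
not its exact per-window SNP counts or fine LD pattern; window-size results
on the fixture are therefore qualitative, not positionally exact.

## Disease model

Each causal SNP k of a disease architecture with i causal SNPs carries a
unique prevalence P(D_U) = 0.10/i and conditional risks

    P(D|G=0) = P(D_U) / [(1−m)² + 2γm(1−m) + (2γ−1)m²],
    P(D|G=1) = γ·P(D|G=0),    P(D|G=2) = (2γ−1)·P(D|G=0),

whose HWE-weighted mean equals P(D_U) exactly (an algebraic identity
asserted to 1e-12 in tests). Disease status is the OR of one Bernoulli draw
per causal SNP, giving overall prevalence 1 − (1 − 0.10/i)^i ≈ 9.6–10% for
i ∈ {1, 2, 4, 8}. Parameter combinations implying a conditional probability
above 1 raise an error naming the offending combination. γ is applied per
causal SNP; the per-SNP relative risk is exposed as a parameter rather than
derived from any set-level quantity.

### Included vs generating causal SNPs

An important modelling decision: in the factorial grids the generating
disease architecture is **fixed at 8 causal SNPs** (each with
P(D_U) = 0.10/8) and the setting's "number of causal SNPs" controls how many
of them are *included in the analyzed SNP set*. The alternative reading —
each setting's architecture having exactly the analyzed causal count i, with
P(D_U) = 0.10/i — mechanically forces power to *fall* as i grows: with
overall prevalence pinned near 10%, the i causal SNPs compete to explain the
same cases, so each SNP's case-enrichment scales as 1/i and the summed
noncentrality as 1/i. Only the fixed-architecture reading yields the
documented behaviour of gene-based tests (power rising with the number of
causal SNPs included in the set) and a meaningful causal/non-causal
cancellation ratio; it also matches how the realistic-LD analysis treats its
six causal SNPs (always generating disease, variably included by
window/LD rules). `SimulationSetting` exposes both knobs: `n_causal`
(included) and `n_causal_model` (architecture, default equal to
`n_causal`); the grid constructors pin `n_causal_model = 8`.

## SNP-set tests

* **Trend test.** Cochran-Armitage with additive scores in score-test form,
  `T = n · corr(G, D)²`, 1 df, two-sided via the χ² tail. Monomorphic
  columns get T = 0, p = 1.
* **GATES.** `P = min_j Me · p_(j) / Me(j)` over ascending p-values, with
  `Me = M − Σ_{λ>1}(λ−1)` from the eigenvalues of the p-value correlation
  matrix and Me(j) from the leading j×j submatrix. The p-value correlation
  is approximated from genotype correlation r by the sixth-order polynomial
  of the original GATES publication (evaluated at |r|, clipped to [0, 1]);
  the transform is pluggable (ρ = r² available as a simpler fallback).
* **VEGAS.** Observed statistic = Σ (or max) of per-SNP trend χ²; the null
  is simulated by squaring `L·z` with L the Cholesky factor of the sample LD
  matrix and z i.i.d. standard normal. p = (1 + #{null ≥ observed}) /
  (1 + n_sim), so p > 0 always; exceedance is non-strict. If the LD matrix
  is not positive definite, diagonal jitter 1e-8 is added, escalating ×10 to
  at most 1e-4 before raising. Default n_sim = 1000; the sum and max
  statistics share one matrix of null draws within a replicate.
* **LR.** Logistic likelihood-ratio test against the intercept-only model,
  one additive covariate per SNP. Monomorphic and linearly dependent columns
  are dropped (pivoted QR); df = retained columns. The fit is a
  Newton-Raphson iteration with step halving written in-package (a
  statsmodels fit is the independent oracle in tests); quasi-separated or
  non-convergent fits are flagged and excluded from power denominators
  rather than assigned an arbitrary p-value.
* **LR-PC.** Columns standardized (correlation-matrix PCA, matching the
  "80% of genotype correlation" rule), minimal X components with cumulative
  explained variance ≥ 0.80 retained, logistic LRT with df = X.

An empty SNP set (e.g. all columns monomorphic, or a tag-only mask with no
tags) yields p = 1 for every method.

## Power engine

Following the study's procedure, each setting simulates **one large
population** (20 × the case-control sample size, at least enough to expect
1.5 × the required cases; regenerated twice as large on shortfall) with
disease status assigned once; replicated case-control samples (n/2 cases,
n/2 controls, without replacement) are then drawn from that population.
Power is the rejection fraction at α (default 0.05 — the per-gene threshold
is a study choice and is exposed prominently). Because replicates
share a population, power estimates carry a small conditional component
beyond binomial noise; this is the study's own design and is most visible
for large SNP sets (the population's chance genotype-status associations
are shared across replicates).

Seeds: every stream derives from (base seed, setting id, purpose, replicate)
via CRC-hashed `SeedSequence`s, so results are identical across worker
counts and unaffected by enabling/disabling individual methods.

Grids: the no-LD grid is 32 causal-side combinations × 9 non-causal options
= 288 settings; the causal-anchored grid 96 (192 with tag-only duplicates).
For the exchangeable-LD grid this package enumerates 1-block {r=0.5, r=0.9}
layouts for 2/4/8/32 non-causal SNPs and 2-block {low/low, high/high,
high/low} layouts for counts ≥ 4 (blocks need two members), i.e. 34
non-causal configurations × 32 = 1088 settings.

## Summary regression

Per method, OLS of power on numerically coded main effects (γ as 1.25/2.0,
counts as integers, MAFs as 0.05/0.30, n as 2000/4000; in LD grids, LD level
as the fraction of high-LD blocks and block count as 1/2). Settings with no
non-causal SNPs code `maf_noncausal = 0`. Power is modeled untransformed so
that coefficients read directly as absolute power per SNP; a logit-power
option exists for sensitivity checks but changes the coefficient scale and
is off by default. Cancellation
ratios are computed from unrounded coefficients, not from two-decimal
displays. A non-positive loss estimate makes the ratio undefined —
reported as missing, not raised, since small grids can flip the sign by
Monte Carlo noise.

## Problem sizes used in the checked runs

The acceptance script runs the 288-setting no-LD grid at 100 replicates per
setting (the study's full scale is 500), VEGAS at 1000 null draws, and
estimates the disease-model prevalence on a population of 100,000. At 100
replicates the per-setting binomial error (≈ 0.04 at mid power) propagates
into the regression coefficients: the per-non-causal-SNP loss is estimated
with a standard error around 20% of its value, and the cancellation ratios
inherit a coefficient of variation of roughly 20–25%. Qualitative LD
experiments in the test suite use 200–300 replicates on selected settings
and rely on paired case-control draws (same sampling seeds across SNP-set
selections) to sharpen contrasts.

## Limitations

* Synthetic genotypes only: no phasing, imputation, recombination maps, sex
  chromosomes, covariates, or missing data (missingness is rejected, not
  imputed).
* The fixture's LD is a constructed stand-in; conclusions about specific
  window sizes on real genes do not follow from it.
* The full LR test's LRT is asymptotic; with very many covariates relative
  to n (e.g. 80 SNPs at n = 1000) it becomes mildly anti-conservative,
  which is inherent to the method as studied, not corrected here.
* Self-contained tests only; no competitive/enrichment tests, no
  rare-variant burden or variance-component tests, no covariate adjustment.
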