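# Methods

## The modelling problem

A complex disease has population prevalence *K*. Its genetics can be
summarised either by recurrence risk ratios to relatives (λ_MZ, λ_Sib, λ_OP,
λ_OG — the prevalence among relatives of affected probands divided by *K*) or
by locus-level parameters: *n* contributing loci, risk-allele frequency *p*,
and a per-allele effect. Connecting the two requires a rule for how per-locus
effects combine into the penetrance g_x of a multilocus genotype carrying *x*
risk alleles. `polyrisk` implements four such rules and everything needed to
confront them with observed familial risks.

Shared assumptions: loci are biallelic, independent, in Hardy-Weinberg
equilibrium and exchangeable (equal *p* and equal effect), so *x* ~
Binomial(2n, p) and g depends on the genotype only through *x*; mating is
random, there is no inbreeding and no fertility difference by disease status;
relatives resemble each other only through their genes (no shared
environment); disease is a lifetime binary state (no onset-age structure, no
ascertainment correction).

## Risk functions and calibration

Every model must satisfy E(g) = Σ_x q_x g_x = K, with q_x the exact binomial
pmf over the full support 0..2n (no normal approximation, no ±4 SD
truncation). All solvers enforce |E(g) − K| ≤ max(1e−10, 1e−8·K); the
achieved residual is stored on the calibrated model.

**Unconstrained multiplicative (`risch`)** — g_x = f_n·τ^x with the closed
form f_n = K/(1+p(τ−1))^{2n}. Risks above 1 are *retained*: quantifying the
damage they do is the point of keeping this model. Moments involving g are
accumulated in log space (`logsumexp`) because tail risks can overflow while
the pmf underflows.

**Constrained multiplicative (`crisch`)** — g_x = min(f_n·τ^x, 1). Capping
removes probability mass, so f_n is re-solved by bracketed Brent iteration on
log f_n between the closed-form baseline (residual ≤ 0) and log K +
2n·|log τ| (residual ≥ 0). When the cap is inactive on the support the closed
form is returned unchanged, making `crisch` ≡ `risch` exactly.

**Odds (`odds`)** — odds(g_x) = γ^x·C_n, i.e. g_x = expit(x·log γ + log C_n).
C_n is solved the same way on log C_n, bracketed around the null odds
K/(1−K). γ = 1 returns K/(1−K) exactly. (The risk form g = O/(1+O) is the
only one consistent with g ∈ [0,1]; a sign variant g = O/(1−O) sometimes seen
in print cannot be a probability.)

**Liability threshold (`probit`)** — each allele adds *a* on a latent
standard-normal liability; disease occurs when genetic value u_x = (x−2np)·a
plus a residual ~ N(0, 1−h²_l) exceeds a threshold *t*, so
g_x = Φ((u_x − t)/√(1−h²_l)). The per-allele effect a = √(h²_l/(2np(1−p)))
makes the binomial genetic variance on the liability scale equal h²_l with
total phenotypic variance 1. The closed-form threshold t = Φ⁻¹(1−K) treats
the genetic values as exactly normal; for finite *n* the binomial lattice
leaves a small residual (≈1e−2 relative at n=1000, K=0.01), so `calibrate()`
refines *t* by a 1-D solve to restore E(g) = K exactly. `probit_params`
still returns the textbook closed form; the refinement is typically < 0.01
liability SD and is reported via the stored baseline.

Degenerate inputs: τ = 1 (or h²_l = 0) collapses every model to g ≡ K.
Monotonicity (g nondecreasing in *x* for τ > 1, h²_l > 0) holds by
construction and is property-tested.

## Population quantities

Broad-sense heritability on the 0-1 risk scale is
H²₀₁ = Var(g)/(K(1−K)); the denominator is the phenotypic variance of the
binary outcome. For the unconstrained model the impossible risks g_x > 1
enter as-is — that is how a 0.9% sliver of the population can carry half the
apparent heritability (the flagship diagnostic at K=0.1, n=1000, p=0.1,
τ=1.1: risks cross 1 above x = 232, and capping drops H²₀₁ from 0.54 to
0.27). An optional `support_sd` argument recomputes the summation on a
truncated, renormalised support as a diagnostic; published values of this
quantity appear to have used some such truncation or simulation, so only the
full-support value is asserted in tests.

The impossible-risk threshold is reported as the largest integer x with
g_x ≤ 1 (so "risk exceeds 1 when x > threshold"), computed from
−ln f_n/ln τ with integer-boundary guards, and the mass above it from the
exact binomial survival function.

## Recurrence risks to relatives

Three routes, used to check one another:

1. **Analytic λ_MZ** — MZ twins share the genotype, so
   λ_MZ = E(g²)/K² = 1 + Var(g)/K², giving the broad-sense estimator
   H²₀₁ = (λ_MZ−1)·K/(1−K) (the James identity). λ_MZ ≤ 1/K for any model
   with risks in [0,1].
2. **Analytic λ_Sib** — two sibs' counts (X₁, X₂) are a sum over n i.i.d.
   loci of a dependent per-locus genotype pair (shared parents, independent
   transmissions given parents). The exact 3×3 per-locus joint is raised to
   its n-th convolution power by 2-D FFT; λ_Sib = E[g(X₁)g(X₂)]/K². Memory
   is O(n²), so this route is limited to n ≤ 2500.
3. **Gene-dropping simulation** — per-family: four grandparent founders
   (per-locus genotypes Binomial(2, p)), one parent bred from each founder
   couple, two children, and an MZ co-twin sharing child 1's genotype.
   Transmission is exact Mendelian segregation per locus (homozygotes
   transmit deterministically, heterozygotes flip a fair coin), vectorised
   over families in int8 chunks. Disease is Bernoulli(g_x) independently per
   individual given the genotype. One proband→relative pair per family per
   relative type keeps pairs independent across families, so the attached
   standard errors are exact binomials. λ_R divides the conditional
   recurrence by the *realized* prevalence of the relatives' generation,
   cancelling finite-sample drift; the nominal K is also reported.

An earlier design represented individuals by genotype-class counts
(multinomial over mother×father locus classes) to be O(1) in *n*; it was
dropped because non-founder couples then need per-family multivariate
hypergeometric contingency draws that do not vectorise. The per-locus int8
scheme is distributionally identical and fast in practice (~13 s per 10⁵
families at n = 1000 on one CPU).

What a green simulation test establishes: the simulator agrees with the
analytic λ_MZ and λ_Sib and with a brute-force enumeration over all parental
genotypes at n ≤ 3, within quoted Monte-Carlo error. What it does not: any
claim about real pedigrees — the generator emulates the stated model world
(exchangeable loci, no shared environment, random mating), not linkage,
assortative mating, ascertainment or variable family sizes.

Estimators from λ: broad-sense H²₀₁ = (λ_MZ−1)K/(1−K); narrow-sense
h²₀₁ ≈ 4(λ_OG−1)K/(1−K) (grandparent-grandchild pairs share r = 1/4 of
additive variance and essentially no dominance, so this is less contaminated
than the parent-offspring version). Ratio diagnostics: λ_MZ/λ_Sib² (= 1
under the unconstrained multiplicative model), (λ_MZ−1)/(λ_Sib−1) (> 2
signals non-additive risk-scale variance) and (λ_Sib−1)/(λ_OP−1) (> 1
signals dominance).

## Benchmarked comparison

Models are matched on the two observables: K and the per-allele relative risk
at the mean genotype, taken from the probit model as τ = g_{2np+1}/g_{2np}
(2np rounded to the nearest integer when not integral — the benchmark is a
local slope at the mean). That τ (= γ for the odds model) parameterises the
multiplicative and odds models. `solve_effect_for_lambda` inverts the map
effect → analytic λ_MZ by bracketed Brent iteration (λ_MZ is increasing in
the effect); targets ≥ 1/K are rejected for the constrained models.

With (K, h²_l) fixed, H²₀₁ depends only weakly on how the liability variance
is spread over (n, p): with n ≥ 1000 all values on an
n ∈ {1000, 2000, 5000} × p ∈ {0.1, 0.3} grid fit in a band of half-width
0.01 per model. The insensitivity is asymptotic — at n = 100 the per-locus
effects are large and the band widens to ~±0.03 — which is why the grid test
is run in the many-small-effect regime.

## Scale conversions

- Liability quantities: t = Φ⁻¹(1−K), z = φ(t), i = z/K (mean liability of
  the affected group).
- Robertson transform: h²₀₁ = h²_l·z²/(K(1−K)), the liability→risk-scale map
  for *additive* heritability; its ceiling is 2/π ≈ 0.64 at K = 0.5,
  h²_l = 1.
- Single-locus OR algebra: with penetrances (f, τf, τ²f) and the n = 1
  prevalence constraint f = K/(1+p(τ−1))², OR_het = τ(1−f)/(1−τf) and
  OR_hom = τ²(1−f)/(1−τ²f). OR_hom/OR²_het ≥ 1 quantifies the OR/RR gap and
  → 1 as f → 0. (This baseline convention reproduces the standard worked
  ratio checks 1.13 and 1.00003; no convention tried reproduces one
  occasionally-printed OR_het value of 2.49 — the formulas above give 2.20 —
  so only the ratio checks are asserted.)
- Per-allele variance under the unconstrained model:
  v = p(1−p)(τ−1)²/[1+p(τ−1)]², with the small-effect approximation
  nv ≈ np(1−p)(τ−1)².
- Marginal vs conditional τ under the probit model: a locus fitted alone has
  all other loci folded into residual variance, giving the attenuated
  marginal effect Φ(a−t)/Φ(−t), always below the conditional
  g_{2np+1}/g_{2np}.

## The disease table

`table1.tsv` packages published (K, λ_MZ, λ_Sib, λ_OP) estimates for 15
complex diseases together with the published derived summaries kept verbatim
(as strings, preserving their original rounding). `derive_columns` recomputes
every derivable summary from the raw values. One caveat is pinned in tests:
the lowest-prevalence row prints a heritability of 0.24 where exact
recomputation of (λ_MZ−1)K/(1−K) gives 0.232 — consistent with the
prevalence having been rounded for display — so that row is held to ±0.01
while the other 13 printed values are asserted to exact 2-dp rounding.
`liability_h2_from_mz_concordance` (bivariate-normal liability with MZ
correlation = h²_l) is provided as a model-based helper for the table's final
column but is not asserted against it, since that column's provenance is not
recoverable from the raw values.

## Numerical choices

- Bracketed Brent root-finding on log-baselines, xtol 1e−14, ≤ 200
  iterations; calibration residuals checked post-hoc and stored.
- Exact binomial pmfs from `scipy.stats.binom`; log-space accumulation
  wherever unconstrained risks appear.
- Simulation chunk size 10⁴ families (int8 genotype arrays, ~10 MB per
  individual per chunk at n = 1000); a single `numpy` Generator seeded once
  drives the whole sample, and results are bit-reproducible for a fixed
  (seed, chunk size, platform).
- Default simulation size 10⁵ families in tests (standard errors are always
  attached); the acceptance script runs the sib-recurrence simulation at
  10⁶ families.

## Known limitations

- Exchangeable loci only: unequal frequencies or effects are not supported.
- No linkage, inbreeding, assortative mating, shared environment,
  onset-age structure or ascertainment.
- `lambda_sib_exact` is O(n²) in memory (n ≤ 2500); larger models fall back
  to simulation.
- The unconstrained model's heritability and λ_MZ are reported as defined
  (impossible risks included); they are diagnostics of the model's failure,
  not estimates of anything biological.
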