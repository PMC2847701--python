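# polyrisk

Multi-locus models of genetic disease risk: how do per-locus effects measured
in association studies combine into an individual's disease probability, and
what do the candidate combination rules imply for the risks observed in
relatives of affected people?

## Who this is for

Statistical geneticists and genetic epidemiologists reconciling two
descriptions of the same disease: the traditional one (prevalence *K* and
recurrence risk ratios λ_R to relatives of type R — MZ twin, sib,
parent-offspring, grandparent-grandchild) and the locus-level one (number of
risk loci *n*, risk-allele frequency *p*, per-allele relative risk τ or odds
factor γ, liability-scale heritability h²_l).

## The models

An individual carries *x* risk alleles out of 2*n*, with *x* ~ Binomial(2n, p)
under Hardy-Weinberg equilibrium and exchangeable loci.  Four risk functions
g_x (probability of disease given *x*) are implemented, each calibrated so
that the population mean risk Σ_x q_x g_x equals the prevalence *K*:

| model    | scale of additivity | risk function |
|----------|--------------------|---------------|
| `risch`  | log risk           | g_x = f_n τ^x, f_n = K/(1+p(τ−1))^{2n} — risks may exceed 1, deliberately |
| `crisch` | log risk, capped   | g_x = min(f_n τ^x, 1), f_n re-solved numerically |
| `odds`   | log odds           | g_x/(1−g_x) = γ^x C_n, C_n solved numerically |
| `probit` | liability          | g_x = Φ((u_x − t)/√(1−h²_l)), u_x = (x−2np)·a, a = √(h²_l/(2np(1−p))), t ≈ Φ⁻¹(1−K) |

On top of the calibrated models the package computes, exactly over the
binomial support:

- **risk-scale heritability** H²₀₁ = Var(g)/(K(1−K)) and risk-function tables;
- **impossible-risk diagnostics** for the unconstrained multiplicative model
  (where g_x > 1, and how much population mass sits there);
- **recurrence risks**: λ_MZ = E(g²)/K² and λ_Sib = E[g(X₁)g(X₂)]/K² in
  closed/FFT form, plus a vectorised gene-dropping simulator of
  three-generation families for λ_MZ, λ_Sib, λ_OP, λ_OG with Monte-Carlo
  standard errors;
- **scale conversions**: single-locus OR↔RR algebra, liability threshold
  quantities, Robertson's transform h²₀₁ = h²_l·z²/(K(1−K)), per-allele
  variance v = p(1−p)(τ−1)²/[1+p(τ−1)]², marginal vs conditional τ;
- **benchmarked comparisons**: model sets matched on (K, τ) through the
  probit anchor τ = g_{2np+1}/g_{2np}, comparison grids, and inversion from a
  target λ_MZ back to the effect size;
- a packaged table of published (K, λ_R) estimates for 15 complex diseases
  with recomputation of its derived heritability/ratio columns.

## Worked example

Match the four models on prevalence and single-allele effect size, then ask
what each implies for relatives:

```python
import polyrisk as pr

bset = pr.build_benchmark_set(K=0.01, n=1000, p=0.3, h2l=0.5)
for kind in ("crisch", "odds", "probit"):
    m = bset.models[kind]
    print(kind, pr.heritability_risk_scale(m),
          pr.lambda_mz_exact(m), pr.lambda_sib_exact(m))
```

`python examples/03_benchmark_comparison.py` formats this as

```
anchored per-allele relative risk tau = 1.1884

model      H2_01  lambda_MZ  lambda_Sib
crisch     0.519       52.4        10.0
odds       0.347       35.4         8.2
probit     0.124       13.2         4.5
```

All three models share K = 0.01 and a per-allele relative risk of 1.19, yet
an MZ twin of an affected person is 52 times more likely than average to be
affected under the constrained multiplicative model and only 13 times under
the liability-threshold model — the combination rule, not the locus effects,
drives familial risk.  λ_MZ/λ_Sib² equals 1 only for the unconstrained
multiplicative model; the constrained models push it below 1 for rare
diseases, which is what published twin/sib data show.

The other scripts in `examples/` each demonstrate one capability: model
calibration, impossible-risk diagnostics, family simulation, scale
conversions, and the disease table.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch — the single-locus
odds-ratio checks, the impossible-risk threshold of the unconstrained model,
the disease-table heritabilities, and the matched-model recurrence risks
(analytic λ_MZ for the constrained-multiplicative and probit models, and
λ_Sib from a seeded gene-dropping simulation of 10⁶ families) — and writes
them as JSON.  Runs in about two minutes on one CPU.

## Scope and limitations

Loci are independent, biallelic, exchangeable (equal p and τ) and in
Hardy-Weinberg equilibrium; mating is random, fertility unaffected by disease,
and relatives resemble each other only through their genes (no shared
environment).  Disease is a lifetime yes/no state: onset age and
ascertainment are out of scope.  See `docs/methods.md` for the model
derivations, numerical choices and what the simulator does and does not
emulate.
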