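"""Scale conversions: odds ratios, liability thresholds and heritabilities.

Walks through the single-locus algebra linking relative risks to odds ratios,
the liability-threshold quantities for a given prevalence, Robertson's
transform from liability-scale to risk-scale additive heritability, and the
marginal-vs-conditional distinction for a per-allele effect estimated one
locus at a time.
"""

import polyrisk as pr

# odds ratios implied by relative risks tau, tau^2 at a single locus
high = pr.single_locus_or(K=0.1, p=0.1, tau=2.0)
low = pr.single_locus_or(K=0.01, p=0.1, tau=1.05)
print("single-locus OR algebra:")
print(f"  K=0.10, tau=2.00: OR_het={high.or_het:.3f}  OR_hom/OR_het^2={high.hom_over_het_sq:.2f}")
print(f"  K=0.01, tau=1.05: OR_het={low.or_het:.4f}  OR_hom/OR_het^2={low.hom_over_het_sq:.5f}")
print("  (ORs and RRs are interchangeable only when penetrance is low)\n")

# liability threshold quantities
for K in (0.05, 0.01):
    lq = pr.liability_quantities(K)
    print(f"K={K}: threshold t={lq.t:.3f}, density z={lq.z:.4f}, mean affected liability i={lq.i:.3f}")
print()

# Robertson transform and its ceiling
print("risk-scale additive heritability h2_01 = h2_l * z^2 / (K(1-K)):")
for K, h2l in ((0.5, 1.0), (0.1, 0.8), (0.01, 0.8)):
    print(f"  K={K}, h2_l={h2l}: h2_01 = {pr.robertson_h2_01(h2l, K):.3f}")
print("  (even a fully heritable liability caps at 0.64 on the risk scale)\n")

# per-allele variance under the unconstrained multiplicative model
v = pr.per_allele_variance(p=0.3, tau=1.2)
print(f"per-allele risk-scale variance v(p=0.3, tau=1.2) = {v:.6f}")
print(f"small-effect approximation p(1-p)(tau-1)^2       = {pr.per_allele_variance_approx(0.3, 1.2):.6f}\n")

# marginal vs conditional per-allele relative risk under the probit model
probit = pr.calibrate(pr.ModelConfig("probit", 0.01, 1000, 0.3, h2l=0.5))
a, _ = probit.baseline
print(f"conditional tau (at mean genotype)  : {pr.tau_from_probit(probit):.3f}")
print(f"marginal tau (single locus fitted)  : {pr.marginal_tau_probit(a, 0.01):.3f}")
print("A locus fitted alone looks weaker than its effect at the mean")
print("background, because every other locus becomes residual variance.")
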