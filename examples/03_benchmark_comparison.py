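"""Compare models matched on prevalence and per-allele effect size.

The liability-threshold (probit) model at K=0.01, n=1000, p=0.3, h2l=0.5
implies a per-allele relative risk at the mean genotype of about 1.19; feeding
that same effect to the constrained multiplicative and odds models gives three
models that agree on the two observables (K, tau) yet imply very different
recurrence risks to relatives.
"""

import polyrisk as pr

bset = pr.build_benchmark_set(K=0.01, n=1000, p=0.3, h2l=0.5)
print(f"anchored per-allele relative risk tau = {bset.tau_benchmark:.4f}\n")

print(f"{'model':8} {'H2_01':>7} {'lambda_MZ':>10} {'lambda_Sib':>11}")
for kind in ("crisch", "odds", "probit"):
    model = bset.models[kind]
    print(
        f"{kind:8} {pr.heritability_risk_scale(model):7.3f} "
        f"{pr.lambda_mz_exact(model):10.1f} {pr.lambda_sib_exact(model):11.1f}"
    )

print()
print("Identical single-locus effects, wildly different familial risk: the")
print("constrained multiplicative model concentrates risk in the genotype")
print("tail (MZ twin recurrence 52x population prevalence), the liability")
print("threshold model spreads it (13x).  Observed MZ/sib recurrence pairs")
print("for real diseases sit between these extremes.")
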