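"""The unconstrained multiplicative model implies impossible risks.

At K=0.1, n=1000, p=0.1, tau=1.1 the mean person carries 200 risk alleles and
anyone with more than 232 has a nominal disease probability above 1.  Only
0.9% of the population sits there, but those genotypes dominate the genetic
variance: capping risks at 1 (the constrained model) halves the risk-scale
heritability.
"""

import polyrisk as pr

params = dict(K=0.1, n=1000, p=0.1, tau=1.1)

risch = pr.calibrate(pr.ModelConfig("risch", **params))
crisch = pr.calibrate(pr.ModelConfig("crisch", **params))
report = pr.impossible_risk_report(risch)
dist = pr.genotype_pmf(params["n"], params["p"])

print(f"mean risk-allele count        : {dist.mean:.0f}")
print(f"risk exceeds 1 for counts     > {report.threshold_x}")
print(f"population mass above        : {report.mass_above:.4f}")
print(f"H2_01, unconstrained          : {pr.heritability_risk_scale(risch):.3f}")
print(f"H2_01, risks capped at 1      : {pr.heritability_risk_scale(crisch):.3f}")
print()
print("A fraction of a percent of 'impossible' genotypes carries half the")
print("apparent heritability - the unconstrained model is not a realistic")
print("description of disease risk, however convenient its algebra.")
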