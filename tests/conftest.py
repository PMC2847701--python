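"""Shared fixtures: calibrated models and simulation samples reused across tests.

Simulation fixtures are session-scoped because gene-dropping at many loci is
the expensive part of the suite; every stochastic check reuses these samples
and quotes its Monte-Carlo standard error explicitly.
"""

import pytest

import polyrisk as pr


@pytest.fixture(scope="session")
def bench_001():
    """Benchmark set at the flagship parameters K=0.01, n=1000, p=0.3, h2l=0.5."""
    return pr.build_benchmark_set(0.01, 1000, 0.3, 0.5)


@pytest.fixture(scope="session")
def small_crisch():
    """A small, fast constrained-multiplicative model for simulation checks."""
    return pr.calibrate(pr.ModelConfig("crisch", 0.05, 30, 0.2, tau=1.3))


@pytest.fixture(scope="session")
def small_crisch_sample(small_crisch):
    return pr.simulate_families(small_crisch, 50_000, seed=7)


@pytest.fixture(scope="session")
def null_sample():
    """tau = 1: genotype carries no risk information, all lambdas should be 1."""
    model = pr.calibrate(pr.ModelConfig("crisch", 0.1, 20, 0.3, tau=1.0))
    return pr.simulate_families(model, 30_000, seed=13)


def lambda_ratio_se(est: pr.RelativeRiskEstimates) -> tuple[float, float]:
    """(lambda_MZ/lambda_Sib^2, its delta-method SE) from simulation estimates."""
    lm, ls = est.lambdas["MZ"], est.lambdas["Sib"]
    sm, ss = est.standard_errors["MZ"], est.standard_errors["Sib"]
    ratio = lm / ls**2
    se = ratio * ((sm / lm) ** 2 + (2.0 * ss / ls) ** 2) ** 0.5
    return ratio, se
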