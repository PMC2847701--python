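"""Recurrence risks to relatives: analytic lambdas, the gene-dropping
simulator, lambda-based heritability estimators and ratio diagnostics.

The simulator is pinned by two independent oracles: the analytic
lambda_MZ = E(g^2)/K^2, and a brute-force enumeration of all parental
genotype/transmission combinations for n <= 3 loci.
"""

from itertools import product

import numpy as np
import pytest

import polyrisk as pr
from conftest import lambda_ratio_se


def lambda_sib_enumerate(model: pr.CalibratedModel) -> float:
    """Brute-force sib recurrence risk for small n.

    Enumerates every (mother, father) multilocus genotype pair under
    Hardy-Weinberg weights; given the parents, the two sibs' risk-allele
    counts are i.i.d. with a per-locus Mendelian transmission distribution, so
    P(both affected) = E_parents[ P(child affected | parents)^2 ] and
    lambda_Sib = P(both affected) / K^2.
    """
    cfg = model.config
    n, p, K = cfg.n, cfg.p, cfg.K
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    transmit = {0: np.array([1.0, 0.0]), 1: np.array([0.5, 0.5]), 2: np.array([0.0, 1.0])}
    g = np.asarray(model.risk_vector())
    p_both = 0.0
    for mother in product(range(3), repeat=n):
        w_mother = np.prod([hw[c] for c in mother])
        for father in product(range(3), repeat=n):
            w = w_mother * np.prod([hw[c] for c in father])
            child_dist = np.array([1.0])
            for mc, fc in zip(mother, father):
                joint = np.outer(transmit[mc], transmit[fc])
                locus = [joint[0, 0], joint[0, 1] + joint[1, 0], joint[1, 1]]
                child_dist = np.convolve(child_dist, locus)
            p_affected = float(child_dist @ g[: child_dist.size])
            p_both += w * p_affected**2
    return p_both / K**2


class TestAnalyticLambdaMZ:
    def test_constant_risk_gives_one(self):
        m = pr.calibrate(pr.ModelConfig("odds", 0.2, 15, 0.3, tau=1.0))
        assert pr.lambda_mz_exact(m) == pytest.approx(1.0, rel=1e-9)

    def test_probit_flagship(self, bench_001):
        # published matched-model value 13.0 (stochastic, 1e6 families)
        assert pr.lambda_mz_exact(bench_001.models["probit"]) == pytest.approx(13.0, rel=0.02)

    def test_crisch_flagship(self, bench_001):
        assert pr.lambda_mz_exact(bench_001.models["crisch"]) == pytest.approx(52.0, rel=0.02)

    def test_bounded_by_inverse_prevalence(self, bench_001):
        for kind in ("crisch", "odds", "probit"):
            assert pr.lambda_mz_exact(bench_001.models[kind]) <= 1.0 / 0.01 + 1e-9


class TestAnalyticLambdaSib:
    def test_matches_enumeration_oracle_exactly(self):
        """The FFT convolution of the per-locus sib-pair joint agrees with the
        brute-force enumeration over all parental genotypes at small n."""
        for params in (dict(K=0.2, n=2, p=0.3, tau=1.6), dict(K=0.1, n=3, p=0.4, tau=1.8)):
            model = pr.calibrate(pr.ModelConfig("crisch", **params))
            assert pr.lambda_sib_exact(model) == pytest.approx(
                lambda_sib_enumerate(model), rel=1e-10
            )

    def test_constant_risk_gives_one(self):
        m = pr.calibrate(pr.ModelConfig("odds", 0.2, 15, 0.3, tau=1.0))
        assert pr.lambda_sib_exact(m) == pytest.approx(1.0, abs=1e-9)

    def test_matched_model_values(self, bench_001):
        # published matched-model sib risks ~10, ~8 and ~4 (grid: 9.9, 8.1, 4.4)
        sib = {k: pr.lambda_sib_exact(bench_001.models[k]) for k in ("crisch", "odds", "probit")}
        assert sib["crisch"] == pytest.approx(10.0, rel=0.02)
        assert sib["odds"] == pytest.approx(8.1, rel=0.02)
        assert sib["probit"] == pytest.approx(4.4, rel=0.02)
        assert sib["crisch"] > sib["odds"] > sib["probit"]

    def test_bounded_by_mz(self, bench_001):
        for kind in ("crisch", "odds", "probit"):
            model = bench_001.models[kind]
            assert 1.0 <= pr.lambda_sib_exact(model) <= pr.lambda_mz_exact(model)

    def test_large_n_guard(self):
        m = pr.calibrate(pr.ModelConfig("odds", 0.1, 3000, 0.3, tau=1.01))
        with pytest.raises(ValueError, match="simulator"):
            pr.lambda_sib_exact(m)


class TestSimulator:
    def test_mendelian_conservation_of_allele_count(self, small_crisch_sample):
        s = small_crisch_sample
        cfg = s.model.config
        mean = s.genotype_stats["sum_c1"] / s.n_families
        var = s.genotype_stats["sum_c12"] / s.n_families - mean**2
        se = np.sqrt(var / s.n_families)
        assert abs(mean - 2 * cfg.n * cfg.p) <= 3 * se

    def test_mz_twin_counts_identical(self, small_crisch_sample):
        assert small_crisch_sample.mz_count_correlation() == pytest.approx(1.0, abs=1e-12)

    def test_sib_count_correlation_half(self, small_crisch_sample):
        s = small_crisch_sample
        corr = s.sib_count_correlation()
        se = 1.0 / np.sqrt(s.n_families)  # Fisher-style large-sample SE
        assert abs(corr - 0.5) <= 3 * se

    def test_reproducible_under_seed(self, small_crisch):
        a = pr.simulate_families(small_crisch, 5_000, seed=42)
        b = pr.simulate_families(small_crisch, 5_000, seed=42)
        assert a.pair_counts == b.pair_counts
        assert a.generation_counts == b.generation_counts
        assert a.genotype_stats == b.genotype_stats

    def test_realized_prevalence_near_nominal(self, small_crisch_sample):
        s = small_crisch_sample
        K = s.model.config.K
        for generation in ("grandparents", "parents", "children"):
            aff, tot = s.generation_counts[generation]
            se = np.sqrt(K * (1 - K) / tot)
            assert abs(aff / tot - K) <= 5 * se

    def test_rejects_tiny_samples_and_impossible_risks(self, small_crisch):
        with pytest.raises(ValueError):
            pr.simulate_families(small_crisch, 10, seed=1)
        bad = pr.calibrate(pr.ModelConfig("risch", 0.1, 1000, 0.1, tau=1.1))
        with pytest.raises(ValueError):
            pr.simulate_families(bad, 5_000, seed=1)


class TestEstimateLambdas:
    def test_null_model_lambdas_are_one(self, null_sample):
        est = pr.estimate_lambdas(null_sample)
        for kind, lam in est.lambdas.items():
            assert abs(lam - 1.0) <= 3 * est.standard_errors[kind], kind

    def test_simulated_mz_matches_analytic(self, small_crisch_sample):
        est = pr.estimate_lambdas(small_crisch_sample)
        exact = pr.lambda_mz_exact(small_crisch_sample.model)
        assert abs(est.lambdas["MZ"] - exact) <= 3 * est.standard_errors["MZ"]

    def test_lambda_ordering(self, small_crisch_sample):
        est = pr.estimate_lambdas(small_crisch_sample)
        lam, se = est.lambdas, est.standard_errors
        assert lam["MZ"] >= lam["Sib"] - 3 * (se["MZ"] + se["Sib"])
        assert lam["Sib"] >= lam["OP"] - 3 * (se["Sib"] + se["OP"])
        assert lam["MZ"] <= 1.0 / est.realized_prevalence

    @pytest.mark.parametrize(
        "params",
        [dict(K=0.2, n=2, p=0.3, tau=1.6), dict(K=0.1, n=3, p=0.4, tau=1.8)],
    )
    def test_sib_lambda_against_enumeration_oracle(self, params):
        model = pr.calibrate(pr.ModelConfig("crisch", **params))
        expected = lambda_sib_enumerate(model)
        sample = pr.simulate_families(model, 80_000, seed=21)
        est = pr.estimate_lambdas(sample)
        assert abs(est.lambdas["Sib"] - expected) <= 3 * est.standard_errors["Sib"]

    def test_simulated_sib_matches_exact_at_many_loci(self, small_crisch_sample):
        est = pr.estimate_lambdas(small_crisch_sample)
        exact = pr.lambda_sib_exact(small_crisch_sample.model)
        assert abs(est.lambdas["Sib"] - exact) <= 3 * est.standard_errors["Sib"]

    def test_zero_probands_is_informative_error(self):
        # prevalence so low that no proband is affected in a tiny sample
        model = pr.calibrate(pr.ModelConfig("crisch", 1e-6, 5, 0.2, tau=1.1))
        sample = pr.simulate_families(model, 1_000, seed=3)
        with pytest.raises(ValueError, match="n_families"):
            pr.estimate_lambdas(sample)


class TestHeritabilityEstimators:
    def test_eq1_worked_values(self):
        # Crohn's disease and ankylosing spondylitis rows of the disease table
        assert round(pr.h2_01_from_lambda_mz(600, 0.001), 2) == 0.60
        assert round(pr.h2_01_from_lambda_mz(630, 0.001), 2) == 0.63

    def test_eq1_null_and_bound(self):
        assert pr.h2_01_from_lambda_mz(1.0, 0.05) == 0.0
        with pytest.raises(ValueError):
            pr.h2_01_from_lambda_mz(25.0, 0.05)  # exceeds 1/K = 20

    def test_narrow_sense_estimator(self):
        assert pr.narrow_h2_from_lambda_og(1.0, 0.1) == 0.0
        assert pr.narrow_h2_from_lambda_og(1.15, 0.5) == pytest.approx(0.60, abs=1e-9)

    def test_narrow_sense_matches_robertson_transform(self):
        """Simulated grandparent-grandchild recurrence recovers the Robertson
        liability->risk transform of the additive heritability."""
        model = pr.calibrate(pr.ModelConfig("probit", 0.5, 200, 0.5, h2l=0.95))
        est = pr.estimate_lambdas(pr.simulate_families(model, 60_000, seed=3))
        expected = pr.robertson_h2_01(0.95, 0.5)  # 0.6366 * 0.95 = 0.605
        se_h2 = 4 * est.standard_errors["OG"] * 0.5 / 0.5
        assert abs(est.h2_01_narrow - expected) <= 3 * se_h2

    def test_effect_recovery_from_simulated_lambda(self):
        """Inverting the analytic lambda_MZ at a simulated estimate recovers the
        generating effect size within its propagated uncertainty."""
        true_tau = 1.3
        model = pr.calibrate(pr.ModelConfig("crisch", 0.1, 50, 0.2, tau=true_tau))
        est = pr.estimate_lambdas(pr.simulate_families(model, 60_000, seed=17))
        tau_hat = pr.solve_effect_for_lambda("crisch", 0.1, 50, 0.2, est.lambdas["MZ"])
        # propagate the lambda SE through the inverse map numerically
        d_lam = 0.05
        tau_hi = pr.solve_effect_for_lambda("crisch", 0.1, 50, 0.2, est.lambdas["MZ"] + d_lam)
        slope = (tau_hi - tau_hat) / d_lam
        se_tau = abs(slope) * est.standard_errors["MZ"]
        assert abs(tau_hat - true_tau) <= 2 * se_tau


class TestRatioDiagnostics:
    def test_schizophrenia_excess_ratio(self):
        diag = pr.ratio_diagnostics(52.1, 8.6, 10.0)
        assert round(diag.excess_ratio, 1) == 6.7

    def test_bipolar_mz_over_sib_sq(self):
        diag = pr.ratio_diagnostics(60.0, 7.0, 7.0)
        assert round(diag.mz_over_sib_sq, 1) == 1.2
        assert diag.dominance_ratio == pytest.approx(1.0)

    def test_multiplicative_identity(self):
        diag = pr.ratio_diagnostics(49.0, 7.0)
        assert diag.mz_over_sib_sq == pytest.approx(1.0)
        assert diag.dominance_ratio is None

    def test_degenerate_sib_lambda(self):
        diag = pr.ratio_diagnostics(2.0, 1.0)
        assert diag.excess_ratio is None

    def test_pair_kind_coefficients(self):
        assert pr.PAIR_KINDS["MZ"].r == 1.0 and pr.PAIR_KINDS["MZ"].u == 1.0
        assert pr.PAIR_KINDS["Sib"].r == 0.5 and pr.PAIR_KINDS["Sib"].u == 0.25
        assert pr.PAIR_KINDS["OP"].r == 0.5 and pr.PAIR_KINDS["OP"].u == 0.0
        assert pr.PAIR_KINDS["OG"].r == 0.25 and pr.PAIR_KINDS["OG"].u == 0.0


def test_table2_ratio_pattern_small_heritability():
    """lambda_MZ/lambda_Sib^2 stays near 1 for weak liability heritability."""
    model = pr.calibrate(pr.ModelConfig("probit", 0.1, 200, 0.3, h2l=0.1))
    est = pr.estimate_lambdas(pr.simulate_families(model, 60_000, seed=29))
    ratio, se = lambda_ratio_se(est)
    # the published grid shows 0.96-1.00 at h2l = 0.1
    assert abs(ratio - 1.0) <= 0.05 + 3 * se


def test_ratio_approaches_one_at_half_prevalence():
    """At K = 0.5 the multiplicative identity lambda_MZ = lambda_Sib^2 holds."""
    bset = pr.build_benchmark_set(0.5, 200, 0.3, 0.5)
    est = pr.estimate_lambdas(pr.simulate_families(bset.models["crisch"], 50_000, seed=9))
    ratio, se = lambda_ratio_se(est)
    assert abs(ratio - 1.0) <= 0.03 + 3 * se
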