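"""Recurrence risks to relatives: analytic results and gene-dropping simulation.

The recurrence risk ratio λ_R = K_R / K compares the disease risk of relatives
of type R of affected probands with the population prevalence.  For MZ twins
(who share the whole genotype) the ratio has the exact form

    λ_MZ = E(g²) / K²  =  1 + Var(g)/K²

over the binomial genotype distribution, which also yields the broad-sense
risk-scale heritability estimator H²₀₁ = (λ_MZ - 1) K/(1-K).  For other
relative types (sibs, parent-offspring, grandparent-grandchild) the risks are
estimated by Monte-Carlo simulation of three-generation families with exact
Mendelian transmission at n independent exchangeable loci.

Family structure per simulated family: two founder couples (four
grandparents), one parent bred from each couple, two children of the parent
couple, plus an MZ co-twin sharing the first child's genotype.  Disease status
is drawn independently per individual as Bernoulli(g_x) given the risk-allele
count x — relatives are correlated only through their genes (no shared
environment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import CalibratedModel
from .population import _risk_moments

__all__ = [
    "PAIR_KINDS",
    "RelativePairKind",
    "FamilySample",
    "RelativeRiskEstimates",
    "RatioDiagnostics",
    "lambda_mz_exact",
    "lambda_sib_exact",
    "simulate_families",
    "estimate_lambdas",
    "h2_01_from_lambda_mz",
    "narrow_h2_from_lambda_og",
    "ratio_diagnostics",
]


@dataclass(frozen=True)
class RelativePairKind:
    """Relationship coefficients: r = 2x kinship, u = P(both alleles IBD)."""

    label: str
    r: float
    u: float


PAIR_KINDS = {
    "MZ": RelativePairKind("MZ", r=1.0, u=1.0),
    "Sib": RelativePairKind("Sib", r=0.5, u=0.25),
    "OP": RelativePairKind("OP", r=0.5, u=0.0),
    "OG": RelativePairKind("OG", r=0.25, u=0.0),
}


@dataclass
class FamilySample:
    """Tallies from a simulated set of three-generation families.

    ``pair_counts`` maps each relative type to (affected probands, pairs with
    both proband and relative affected).  One proband -> relative pair is
    scored per family per type (MZ: first child -> co-twin; Sib: first ->
    second child; OP: mother -> first child; OG: first grandparent -> first
    child), so pairs are independent across families and the binomial
    standard errors attached by :func:`estimate_lambdas` are exact.
    ``generation_counts`` maps generation label ('grandparents', 'parents',
    'children') to (affected individuals, individuals).  ``genotype_stats``
    carries sufficient statistics of child risk-allele counts for checks of
    Mendelian conservation and sib/twin genotype correlations.
    """

    model: CalibratedModel
    n_families: int
    seed: int
    pair_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    generation_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    genotype_stats: dict[str, float] = field(default_factory=dict)

    def realized_prevalence(self, generation: str = "children") -> float:
        aff, tot = self.generation_counts[generation]
        return aff / tot

    def sib_count_correlation(self) -> float:
        """Pearson correlation of sib risk-allele counts."""
        return self._count_correlation("c1", "c2", "c1c2")

    def mz_count_correlation(self) -> float:
        """Pearson correlation of MZ co-twin risk-allele counts (1 by sharing)."""
        return self._count_correlation("c1", "twin", "c1twin")

    def _count_correlation(self, a: str, b: str, ab: str) -> float:
        s = self.genotype_stats
        f = self.n_families
        cov = s[f"sum_{ab}"] / f - (s[f"sum_{a}"] / f) * (s[f"sum_{b}"] / f)
        va = s[f"sum_{a}2"] / f - (s[f"sum_{a}"] / f) ** 2
        vb = s[f"sum_{b}2"] / f - (s[f"sum_{b}"] / f) ** 2
        return cov / math.sqrt(va * vb)


@dataclass(frozen=True)
class RelativeRiskEstimates:
    """λ estimates with Monte-Carlo standard errors and derived heritabilities."""

    lambdas: dict[str, float]
    standard_errors: dict[str, float]
    realized_prevalence: float
    h2_01_broad: float
    h2_01_narrow: float


@dataclass(frozen=True)
class RatioDiagnostics:
    """Ratios of λ values that discriminate between genetic architectures.

    ``mz_over_sib_sq`` = λ_MZ/λ_Sib² equals 1 under the unconstrained
    multiplicative model; ``excess_ratio`` = (λ_MZ-1)/(λ_Sib-1) exceeds 2 when
    non-additive (risk-scale) variance matters; ``dominance_ratio`` =
    (λ_Sib-1)/(λ_OP-1) exceeds 1 in the presence of dominance variance.
    """

    mz_over_sib_sq: float
    excess_ratio: float | None
    dominance_ratio: float | None = None


def lambda_mz_exact(model: CalibratedModel) -> float:
    """Analytic MZ recurrence risk ratio E(g²)/K² over the exact support."""
    m1, m2 = _risk_moments(model)
    return m2 / model.config.K**2


def lambda_sib_exact(model: CalibratedModel) -> float:
    """Exact sibling recurrence risk ratio E[g(X₁)g(X₂)] / K².

    Two sibs' risk-allele counts (X₁, X₂) are the sum over n i.i.d. loci of a
    dependent per-locus genotype pair (shared parents, independent Mendelian
    transmissions given the parents).  The per-locus 3x3 joint distribution is
    raised to the n-th convolution power with a 2-D FFT, giving the exact
    sib-pair count distribution, against which the risk function is averaged.

    Memory scales as the squared support, so this is limited to n <= 2500
    (the simulator covers larger models).
    """
    cfg = model.config
    n, p, K = cfg.n, cfg.p, cfg.K
    if n > 2500:
        raise ValueError("exact sib-pair distribution needs n <= 2500; use the simulator")
    hw = np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])
    transmit = (np.array([1.0, 0.0]), np.array([0.5, 0.5]), np.array([0.0, 1.0]))
    joint = np.zeros((3, 3))
    for gm in range(3):
        for gf in range(3):
            child = np.convolve(transmit[gm], transmit[gf])  # genotype pmf given parents
            joint += hw[gm] * hw[gf] * np.outer(child, child)
    size = 1
    while size < 2 * (2 * n + 1):
        size *= 2
    padded = np.zeros((size, size))
    padded[:3, :3] = joint
    pair_pmf = np.fft.ifft2(np.fft.fft2(padded) ** n).real[: 2 * n + 1, : 2 * n + 1]
    g = np.asarray(model.risk_vector(), dtype=float)
    if cfg.kind == "risch" and float(np.max(g)) > 1.0:
        raise ValueError(
            "unconstrained risch model has g_x > 1 on the support; "
            "sib recurrence is only meaningful for risks in [0, 1]"
        )
    return float(g @ pair_pmf @ g) / K**2


def _transmit(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per locus: homozygotes transmit deterministically, hets flip a coin."""
    coin = rng.integers(0, 2, size=genotype.shape, dtype=np.int8)
    return (genotype >> 1) + ((genotype & 1) & coin)


def simulate_families(
    model: CalibratedModel,
    n_families: int,
    seed: int,
    chunk_size: int = 10_000,
) -> FamilySample:
    """Gene-dropping simulation of three-generation families.

    Genotypes are per-locus int8 arrays; founders draw Binomial(2, p) per
    locus, children receive one exact Mendelian gamete from each parent, and
    the MZ co-twin copies the first child's genotype.  Disease status is
    Bernoulli(g_x) independently per individual.  Vectorised over families in
    chunks; bit-reproducible for a fixed seed and chunk size.
    """
    if n_families < 1_000:
        raise ValueError(f"n_families must be >= 1000 for usable tallies, got {n_families}")
    n_families = int(n_families)
    rng = np.random.default_rng(seed)
    cfg = model.config
    n, p = cfg.n, cfg.p
    g = np.asarray(model.risk_vector(), dtype=float)
    if cfg.kind == "risch" and np.any(g > 1.0):
        raise ValueError(
            "unconstrained risch model has g_x > 1 on the support; "
            "simulate the crisch model instead"
        )

    pair_defs = {"MZ": 0, "Sib": 0, "OP": 0, "OG": 0}
    probands = dict.fromkeys(pair_defs, 0)
    both = dict.fromkeys(pair_defs, 0)
    gen_aff = {"grandparents": 0, "parents": 0, "children": 0}
    gen_tot = {"grandparents": 0, "parents": 0, "children": 0}
    stats = {
        "sum_c1": 0.0, "sum_c12": 0.0, "sum_c2": 0.0, "sum_c22": 0.0,
        "sum_c1c2": 0.0, "sum_twin": 0.0, "sum_twin2": 0.0, "sum_c1twin": 0.0,
    }

    done = 0
    while done < n_families:
        F = min(chunk_size, n_families - done)
        done += F

        gp = [rng.binomial(2, p, size=(F, n)).astype(np.int8) for _ in range(4)]
        mother = _transmit(gp[0], rng) + _transmit(gp[1], rng)
        father = _transmit(gp[2], rng) + _transmit(gp[3], rng)
        child1 = _transmit(mother, rng) + _transmit(father, rng)
        child2 = _transmit(mother, rng) + _transmit(father, rng)

        x_gp = [a.sum(axis=1, dtype=np.int64) for a in gp]
        x_mother = mother.sum(axis=1, dtype=np.int64)
        x_father = father.sum(axis=1, dtype=np.int64)
        x_c1 = child1.sum(axis=1, dtype=np.int64)
        x_c2 = child2.sum(axis=1, dtype=np.int64)
        x_twin = x_c1  # MZ co-twin shares the genotype
        del gp, mother, father, child1, child2

        def affected(x: np.ndarray) -> np.ndarray:
            return rng.random(x.shape[0]) < g[x]

        a_gp = [affected(x) for x in x_gp]
        a_mother, a_father = affected(x_mother), affected(x_father)
        a_c1, a_c2, a_twin = affected(x_c1), affected(x_c2), affected(x_twin)

        gen_aff["grandparents"] += int(sum(a.sum() for a in a_gp))
        gen_tot["grandparents"] += 4 * F
        gen_aff["parents"] += int(a_mother.sum() + a_father.sum())
        gen_tot["parents"] += 2 * F
        gen_aff["children"] += int(a_c1.sum() + a_c2.sum())
        gen_tot["children"] += 2 * F

        # one proband -> relative pair per family per type (independent across families)
        pairs = {
            "MZ": (a_c1, a_twin),
            "Sib": (a_c1, a_c2),
            "OP": (a_mother, a_c1),
            "OG": (a_gp[0], a_c1),
        }
        for label, (a_pro, a_rel) in pairs.items():
            probands[label] += int(a_pro.sum())
            both[label] += int((a_pro & a_rel).sum())

        stats["sum_c1"] += float(x_c1.sum())
        stats["sum_c12"] += float((x_c1.astype(float) ** 2).sum())
        stats["sum_c2"] += float(x_c2.sum())
        stats["sum_c22"] += float((x_c2.astype(float) ** 2).sum())
        stats["sum_c1c2"] += float((x_c1 * x_c2).sum())
        stats["sum_twin"] += float(x_twin.sum())
        stats["sum_twin2"] += float((x_twin.astype(float) ** 2).sum())
        stats["sum_c1twin"] += float((x_c1 * x_twin).sum())

    return FamilySample(
        model=model,
        n_families=n_families,
        seed=int(seed),
        pair_counts={k: (probands[k], both[k]) for k in pair_defs},
        generation_counts={k: (gen_aff[k], gen_tot[k]) for k in gen_aff},
        genotype_stats=stats,
    )


def estimate_lambdas(sample: FamilySample) -> RelativeRiskEstimates:
    """λ_R per relative type, with binomial Monte-Carlo standard errors.

    λ_R = P(relative affected | proband affected) / K̂ where K̂ is the realized
    prevalence of the relatives' generation (children for all four relative
    types), which cancels finite-sample drift of the denominator.
    """
    K_hat = sample.realized_prevalence("children")
    lambdas: dict[str, float] = {}
    ses: dict[str, float] = {}
    for label, (n_pro, n_both) in sample.pair_counts.items():
        if n_pro == 0:
            raise ValueError(
                f"no affected probands for pair kind {label}; "
                "increase n_families (rare disease, small sample)"
            )
        cond = n_both / n_pro
        lambdas[label] = cond / K_hat
        ses[label] = math.sqrt(max(cond * (1.0 - cond), 0.0) / n_pro) / K_hat
    K = sample.model.config.K
    return RelativeRiskEstimates(
        lambdas=lambdas,
        standard_errors=ses,
        realized_prevalence=K_hat,
        h2_01_broad=h2_01_from_lambda_mz(min(lambdas["MZ"], 1.0 / K), K),
        h2_01_narrow=narrow_h2_from_lambda_og(max(lambdas["OG"], 1.0), K),
    )


def h2_01_from_lambda_mz(lambda_mz: float, K: float) -> float:
    """Broad-sense risk-scale heritability H²₀₁ = (λ_MZ - 1) K/(1-K).

    Follows from the James identity K_MZ = K + Var_G/K, so that
    Var_G = (λ_MZ - 1) K² and H²₀₁ = Var_G / (K(1-K)).
    """
    if lambda_mz < 1.0:
        raise ValueError(f"lambda_MZ must be >= 1, got {lambda_mz}")
    if lambda_mz > 1.0 / K * (1.0 + 1e-12):
        raise ValueError(f"lambda_MZ = {lambda_mz} exceeds the bound 1/K = {1.0 / K:.4g}")
    return (lambda_mz - 1.0) * K / (1.0 - K)


def narrow_h2_from_lambda_og(lambda_og: float, K: float) -> float:
    """Narrow-sense risk-scale heritability h²₀₁ ≈ 4 (λ_OG - 1) K/(1-K).

    Grandparent-grandchild pairs share only r = 1/4 of additive variance and
    essentially no dominance, so this estimator is less contaminated by
    non-additive variance than 2(λ_OP - 1)K/(1-K).
    """
    if lambda_og < 1.0:
        raise ValueError(f"lambda_OG must be >= 1, got {lambda_og}")
    return 4.0 * (lambda_og - 1.0) * K / (1.0 - K)


def ratio_diagnostics(
    lambda_mz: float, lambda_sib: float, lambda_op: float | None = None
) -> RatioDiagnostics:
    """λ-ratio diagnostics of genetic architecture (see class docstring)."""
    if lambda_mz < 1.0 or lambda_sib < 1.0 or (lambda_op is not None and lambda_op < 1.0):
        raise ValueError("lambda values must be >= 1")
    excess = None if lambda_sib == 1.0 else (lambda_mz - 1.0) / (lambda_sib - 1.0)
    dominance = None
    if lambda_op is not None and lambda_op > 1.0:
        dominance = (lambda_sib - 1.0) / (lambda_op - 1.0)
    return RatioDiagnostics(
        mz_over_sib_sq=lambda_mz / lambda_sib**2,
        excess_ratio=excess,
        dominance_ratio=dominance,
    )
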