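"""Scale conversions linking per-locus effects, odds ratios and heritabilities.

Single-locus odds-ratio/relative-risk algebra, liability-threshold quantities,
Robertson's transformation between liability-scale and risk-scale (additive)
heritability, the per-allele variance contribution under the unconstrained
multiplicative model, and the marginal vs conditional per-allele relative risk
under the liability-threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "LiabilityQuantities",
    "SingleLocusOR",
    "liability_quantities",
    "robertson_h2_01",
    "single_locus_or",
    "per_allele_variance",
    "per_allele_variance_approx",
    "marginal_tau_probit",
]


@dataclass(frozen=True)
class LiabilityQuantities:
    """Standard liability-threshold quantities for prevalence K.

    t = Φ⁻¹(1-K) is the threshold in liability SD units, z the standard
    normal density at t, and i = z/K the mean liability of the affected group
    (the selection intensity of truncation selection).
    """

    K: float
    t: float
    z: float
    i: float


@dataclass(frozen=True)
class SingleLocusOR:
    """Odds ratios implied by single-locus relative risks tau, tau^2.

    ``f`` is the wild-type homozygote penetrance; ``hom_over_het_sq`` is
    OR_hom / OR_het², the classic check of whether relative risks and odds
    ratios are interchangeable (it tends to 1 as f -> 0).
    """

    f: float
    or_het: float
    or_hom: float
    hom_over_het_sq: float


def liability_quantities(K: float) -> LiabilityQuantities:
    """Threshold, density and affected-group mean liability for prevalence K."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must be in (0, 1), got {K}")
    t = float(ndtri(1.0 - K))
    z = float(norm.pdf(t))
    return LiabilityQuantities(K=K, t=t, z=z, i=z / K)


def robertson_h2_01(h2l: float, K: float) -> float:
    """Narrow-sense risk-scale heritability under the liability model.

    h²₀₁ = h²_l · z² / (K(1-K)), where z is the normal density at the
    liability threshold.  Maximised at K = 0.5, where z²/(K(1-K)) =
    (2/π)/0.25... i.e. the ceiling is ≈ 0.6366 even when h²_l = 1.
    """
    if not 0.0 <= h2l <= 1.0:
        raise ValueError(f"h2l must be in [0, 1], got {h2l}")
    lq = liability_quantities(K)
    return h2l * lq.z**2 / (K * (1.0 - K))


def single_locus_or(K: float, p: float, tau: float) -> SingleLocusOR:
    """Odds ratios for a single biallelic locus with relative risks tau, tau².

    The baseline penetrance is solved from the n = 1 prevalence constraint,
    f = K / (1 + p(tau-1))², so genotype penetrances are (f, tau f, tau² f)
    under Hardy-Weinberg frequencies.  Then

        OR_het = tau (1 - f) / (1 - tau f)
        OR_hom = tau² (1 - f) / (1 - tau² f)

    and OR_hom / OR_het² >= 1 for tau > 1, approaching 1 as f -> 0 (where odds
    ratios and relative risks become equivalent for practical purposes).
    """
    if tau <= 0.0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not 0.0 < K < 1.0 or not 0.0 < p < 1.0:
        raise ValueError("K and p must be in (0, 1)")
    f = K / (1.0 + p * (tau - 1.0)) ** 2
    if tau * tau * f >= 1.0:
        raise ValueError(
            f"homozygote penetrance tau^2 f = {tau * tau * f:.4g} >= 1; "
            "odds ratios undefined for these parameters"
        )
    or_het = tau * (1.0 - f) / (1.0 - tau * f)
    or_hom = tau * tau * (1.0 - f) / (1.0 - tau * tau * f)
    return SingleLocusOR(
        f=f, or_het=or_het, or_hom=or_hom, hom_over_het_sq=or_hom / or_het**2
    )


def per_allele_variance(p: float, tau: float) -> float:
    """Scaled per-allele genetic variance on the risk scale (unconstrained model).

    v = p(1-p)(tau-1)² / [1 + p(tau-1)]²; the total genetic variance on the
    risk scale is proportional to n·v.
    """
    if tau <= 0.0:
        raise ValueError(f"tau must be positive, got {tau}")
    return p * (1.0 - p) * (tau - 1.0) ** 2 / (1.0 + p * (tau - 1.0)) ** 2


def per_allele_variance_approx(p: float, tau: float) -> float:
    """Small-tau approximation v ≈ p(1-p)(tau-1)² (so n·v ≈ np(1-p)(tau-1)²)."""
    return p * (1.0 - p) * (tau - 1.0) ** 2


def marginal_tau_probit(a: float, K: float) -> float:
    """Marginal per-allele relative risk of one locus under the liability model.

    When a single risk locus is fitted alone, all other loci fold into the
    residual liability (variance -> 1), and the estimated per-allele relative
    risk is Φ(a - t)/Φ(-t).  This is smaller than the conditional effect
    g_{2np+1}/g_{2np} evaluated at the mean multilocus background.
    """
    t = liability_quantities(K).t
    return float(ndtr(a - t) / ndtr(-t))
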