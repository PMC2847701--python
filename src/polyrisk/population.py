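"""Exact population-level quantities over the binomial genotype distribution.

Everything here is computed by direct summation over the full support
x = 0..2n of the risk-allele count (no normal approximation, no support
truncation unless explicitly requested), so results are deterministic and
exact to floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .models import CalibratedModel

__all__ = [
    "GenotypeDistribution",
    "ImpossibleRiskReport",
    "genotype_pmf",
    "heritability_risk_scale",
    "impossible_risk_report",
    "risk_function_table",
]


@dataclass(frozen=True)
class GenotypeDistribution:
    """Binomial(2n, p) distribution of risk-allele counts."""

    n: int
    p: float
    x: np.ndarray
    pmf: np.ndarray
    logpmf: np.ndarray

    @property
    def mean(self) -> float:
        return 2.0 * self.n * self.p

    @property
    def sd(self) -> float:
        return math.sqrt(2.0 * self.n * self.p * (1.0 - self.p))

    def tail_mass_above(self, x0: int) -> float:
        """P(X > x0), exact binomial survival function."""
        return float(binom.sf(x0, 2 * self.n, self.p))


@dataclass(frozen=True)
class ImpossibleRiskReport:
    """Where and how often the unconstrained multiplicative model exceeds g=1.

    ``threshold_x`` is the largest count x with g_x <= 1 (so risks are
    impossible for x > threshold_x); ``mass_above`` is the exact binomial
    probability of such genotypes; ``constraint_active`` says whether any
    genotype on the support has g_x > 1.
    """

    threshold_x: int
    mass_above: float
    constraint_active: bool


def genotype_pmf(n: int, p: float) -> GenotypeDistribution:
    """Exact Binomial(2n, p) pmf over 0..2n (log-space stable for large n)."""
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    n = int(n)
    x = np.arange(2 * n + 1)
    logpmf = binom.logpmf(x, 2 * n, p)
    return GenotypeDistribution(n=n, p=p, x=x, pmf=np.exp(logpmf), logpmf=logpmf)


def _risk_moments(model: CalibratedModel) -> tuple[float, float]:
    """(E g, E g^2) over the exact support; log-space for the unconstrained model.

    Unconstrained risks can be astronomically large in the far tail while the
    pmf underflows, so the risch moments are accumulated as log-sums.
    """
    cfg = model.config
    dist = genotype_pmf(cfg.n, cfg.p)
    if cfg.kind == "risch":
        logg = model.log_risk(dist.x)
        m1 = float(np.exp(logsumexp(dist.logpmf + logg)))
        m2 = float(np.exp(logsumexp(dist.logpmf + 2.0 * logg)))
        return m1, m2
    g = model.risk_vector()
    return float(dist.pmf @ g), float(dist.pmf @ g**2)


def heritability_risk_scale(model: CalibratedModel, support_sd: float | None = None) -> float:
    """Broad-sense heritability on the 0-1 risk scale.

    H²₀₁ = Var(g) / (K(1-K)) with Var(g) = Σ_x q_x (g_x - E g)² over the
    binomial genotype distribution; K(1-K) is the phenotypic variance of the
    0-1 disease outcome.  For the unconstrained ``risch`` model, risks g_x > 1
    enter as-is, which is exactly how the model's impossible-risk artefact
    inflates the heritability.

    Parameters
    ----------
    support_sd : float, optional
        If given, restrict the summation to 2np ± support_sd standard
        deviations of the allele count (weights renormalised).  Exposed as a
        diagnostic; the default (None) uses the full exact support.
    """
    cfg = model.config
    if support_sd is None:
        m1, m2 = _risk_moments(model)
        var_g = m2 - m1 * m1
    else:
        dist = genotype_pmf(cfg.n, cfg.p)
        lo = dist.mean - support_sd * dist.sd
        hi = dist.mean + support_sd * dist.sd
        keep = (dist.x >= lo) & (dist.x <= hi)
        q = dist.pmf[keep] / dist.pmf[keep].sum()
        g = np.atleast_1d(model.risk(dist.x[keep]))
        m1 = float(q @ g)
        var_g = float(q @ (g - m1) ** 2)
    return var_g / (cfg.K * (1.0 - cfg.K))


def impossible_risk_report(model: CalibratedModel) -> ImpossibleRiskReport:
    """Diagnose g_x > 1 under the unconstrained multiplicative model.

    The risk f_n τ^x crosses 1 at x = -ln(f_n)/ln(τ); we report the largest
    integer count that still satisfies g_x <= 1 (so the printed convention is
    "risk exceeds 1 when x > threshold_x"), and the exact binomial mass above
    it.
    """
    cfg = model.config
    if cfg.kind != "risch":
        raise ValueError("impossible-risk diagnostics apply to the unconstrained (risch) model")
    two_n = 2 * cfg.n
    dist = genotype_pmf(cfg.n, cfg.p)
    log_f = math.log(model.baseline)
    if cfg.tau <= 1.0 or log_f + two_n * math.log(cfg.tau) <= 0.0:
        return ImpossibleRiskReport(threshold_x=two_n, mass_above=0.0, constraint_active=False)
    threshold = int(math.floor(-log_f / math.log(cfg.tau)))
    # guard the floor against exact-boundary rounding
    while threshold + 1 <= two_n and log_f + (threshold + 1) * math.log(cfg.tau) <= 0.0:
        threshold += 1
    while threshold > 0 and log_f + threshold * math.log(cfg.tau) > 0.0:
        threshold -= 1
    threshold = min(threshold, two_n)
    return ImpossibleRiskReport(
        threshold_x=threshold,
        mass_above=dist.tail_mass_above(threshold),
        constraint_active=threshold < two_n,
    )


def risk_function_table(
    models: list[CalibratedModel],
    x_range: tuple[int, int] | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate risk functions g_x side by side for models sharing (n, p).

    Columns: ``x``, ``q_x`` (genotype probability), ``frac_ge_x`` (proportion
    of the population carrying x or more risk alleles), then one g_x column
    per model.  The default x range is the mean ± 4 SD of the allele count,
    clipped to the support.
    """
    if not models:
        raise ValueError("need at least one model")
    n, p = models[0].config.n, models[0].config.p
    for m in models[1:]:
        if (m.config.n, m.config.p) != (n, p):
            raise ValueError("all models must share (n, p)")
    if labels is None:
        labels = []
        for m in models:
            label = m.config.kind
            while label in labels:
                label += "'"
            labels.append(label)
    elif len(labels) != len(models):
        raise ValueError("labels must match models")
    dist = genotype_pmf(n, p)
    if x_range is None:
        lo = max(0, int(math.floor(dist.mean - 4.0 * dist.sd)))
        hi = min(2 * n, int(math.ceil(dist.mean + 4.0 * dist.sd)))
    else:
        lo, hi = int(x_range[0]), int(x_range[1])
        if lo < 0 or hi > 2 * n or lo > hi:
            raise ValueError(f"x_range must lie within 0..{2 * n}")
    xs = np.arange(lo, hi + 1)
    out = pd.DataFrame(
        {
            "x": xs,
            "q_x": dist.pmf[xs],
            "frac_ge_x": binom.sf(xs - 1, 2 * n, p),
        }
    )
    for label, m in zip(labels, models):
        out[label] = np.atleast_1d(m.risk(xs))
    return out
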