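"""Multi-locus models of genetic disease risk.

A complex disease with population prevalence ``K`` is assumed to be influenced
by ``n`` independent biallelic loci in Hardy-Weinberg equilibrium, each with
risk-allele frequency ``p``, so that an individual's risk-allele count ``x`` is
Binomial(2n, p).  Four models map the count ``x`` to a probability of disease
``g_x`` (the penetrance of the multilocus genotype):

``risch``
    Multiplicative on the risk scale, ``g_x = f_n * tau**x`` with per-allele
    relative risk ``tau``.  The baseline ``f_n`` (risk of the all-wild-type
    genotype) has the closed form ``K / (1 + p(tau-1))**(2n)``.  Risks are NOT
    constrained to [0, 1]; ``g_x > 1`` is possible and deliberately retained so
    the artefacts of the unconstrained model can be quantified.

``crisch``
    The constrained variant: ``g_x = min(f_n * tau**x, 1)``.  Because capping
    removes probability mass, ``f_n`` must be re-solved numerically from
    ``E(g) = K``.

``odds``
    Multiplicative on the odds scale: ``g_x / (1 - g_x) = gamma**x * C_n``,
    with per-allele odds factor ``gamma`` and baseline odds ``C_n`` solved
    numerically from ``E(g) = K``.

``probit``
    The liability-threshold model.  Each risk allele adds ``a`` on a latent
    standard-normal liability scale; disease occurs when genetic value plus a
    residual ~ N(0, 1 - h2l) exceeds a threshold ``t``.  Parameterised by the
    liability-scale heritability ``h2l``, with ``a = sqrt(h2l / (2np(1-p)))``
    so the binomial genetic variance on the liability scale equals ``h2l``.

Every calibrated model satisfies the identity ``E(g) = sum_x q_x g_x = K``
over the exact binomial support (``q_x`` the binomial pmf), which all solvers
enforce to |E(g) - K| <= max(1e-10, 1e-8 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp, ndtr, ndtri
from scipy.stats import binom

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "CalibratedModel",
    "CalibrationError",
    "risch_baseline",
    "crisch_calibrate",
    "odds_calibrate",
    "probit_params",
    "calibrate",
    "risk",
]

MODEL_KINDS = ("risch", "crisch", "odds", "probit")

#: |E(g) - K| must not exceed max(_ABS_TOL, _REL_TOL * K) after calibration.
_ABS_TOL = 1e-10
_REL_TOL = 1e-8
_MAX_ITER = 200


class CalibrationError(RuntimeError):
    """Raised when a baseline solver fails to bracket or converge."""


@dataclass(frozen=True)
class ModelConfig:
    """Parameter bundle defining one risk model.

    Parameters
    ----------
    kind : {"risch", "crisch", "odds", "probit"}
    K : float
        Disease prevalence, 0 < K < 1.
    n : int
        Number of risk loci, n >= 1.
    p : float
        Risk-allele frequency, 0 < p < 1.
    tau : float, optional
        Per-allele relative risk (per-allele odds factor gamma for the odds
        model).  Required for risch/crisch/odds; tau = 1 is the null model.
    h2l : float, optional
        Heritability on the liability scale, 0 <= h2l < 1.  Required for
        probit.
    """

    kind: str
    K: float
    n: int
    p: float
    tau: float | None = None
    h2l: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency p must be in (0, 1), got {self.p}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"number of loci n must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if self.kind == "probit":
            if self.tau is not None:
                raise ValueError("probit model takes h2l, not tau")
            if self.h2l is None or not 0.0 <= self.h2l < 1.0:
                raise ValueError(f"probit model requires h2l in [0, 1), got {self.h2l}")
        else:
            if self.h2l is not None:
                raise ValueError(f"{self.kind} model takes tau, not h2l")
            if self.tau is None or self.tau <= 0.0:
                raise ValueError(f"{self.kind} model requires tau > 0, got {self.tau}")

    @property
    def support(self) -> np.ndarray:
        """Risk-allele counts 0..2n."""
        return np.arange(2 * self.n + 1)


@dataclass(frozen=True)
class CalibratedModel:
    """A :class:`ModelConfig` plus its solved baseline constant.

    ``baseline`` is ``f_n`` for risch/crisch, ``C_n`` for odds, and the pair
    ``(a, t)`` for probit (per-allele liability effect and threshold; ``t`` is
    refined numerically from the closed-form Φ⁻¹(1-K) so that E(g) = K holds
    exactly over the binomial support).  ``calibration_residual`` is the
    measured |E(g) - K|.
    """

    config: ModelConfig
    baseline: float | tuple[float, float]
    calibration_residual: float

    def log_risk(self, x) -> np.ndarray:
        """log g_x; only defined for the multiplicative kinds."""
        cfg = self.config
        if cfg.kind not in ("risch", "crisch"):
            raise ValueError("log_risk is only defined for risch/crisch models")
        x = np.asarray(x)
        logg = math.log(self.baseline) + x * math.log(cfg.tau)
        if cfg.kind == "crisch":
            logg = np.minimum(logg, 0.0)
        return logg

    def risk(self, x):
        """Penetrance g_x for risk-allele count(s) x in 0..2n."""
        cfg = self.config
        x = np.asarray(x)
        if np.any(x < 0) or np.any(x > 2 * cfg.n):
            raise ValueError(f"x must lie in 0..{2 * cfg.n}")
        if cfg.kind in ("risch", "crisch"):
            g = np.exp(self.log_risk(x))
        elif cfg.kind == "odds":
            g = expit(x * math.log(cfg.tau) + math.log(self.baseline))
        else:  # probit
            a, t = self.baseline
            s = math.sqrt(1.0 - cfg.h2l)
            u = (x - 2.0 * cfg.n * cfg.p) * a
            g = ndtr((u - t) / s)
        return g if g.ndim else float(g)

    def risk_vector(self) -> np.ndarray:
        """g_x over the full support 0..2n."""
        return np.atleast_1d(self.risk(self.config.support))


def _binom_pmf(n: int, p: float) -> np.ndarray:
    return binom.pmf(np.arange(2 * n + 1), 2 * n, p)


def risch_baseline(K: float, n: int, p: float, tau: float) -> float:
    """Closed-form baseline risk f_n = K / (1 + p(tau-1))**(2n).

    f_n is the probability of disease for an individual carrying only
    wild-type alleles; with this constant the binomial expectation of
    ``f_n tau**x`` equals K exactly.  Evaluated on the log scale to survive
    large n.
    """
    ModelConfig("risch", K, n, p, tau)
    return math.exp(math.log(K) - 2 * n * math.log1p(p * (tau - 1.0)))


def _solve_log_baseline(func, lo: float, hi: float, K: float, what: str) -> float:
    """Bracketed root solve of func (monotone increasing) on a log baseline."""
    flo, fhi = func(lo), func(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"{what}: root not bracketed on [{lo:.6g}, {hi:.6g}] "
            f"(f(lo)={flo:.3e}, f(hi)={fhi:.3e}, K={K})"
        )
    return brentq(func, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=_MAX_ITER)


def crisch_calibrate(K: float, n: int, p: float, tau: float) -> float:
    """Solve f_n so that E(min(f_n tau**x, 1)) = K over Binomial(2n, p).

    Equals :func:`risch_baseline` exactly whenever the cap is inactive
    (max_x f_n tau**x <= 1); otherwise strictly larger, since truncation
    removes probability mass that the baseline must compensate.
    """
    cfg = ModelConfig("crisch", K, n, p, tau)
    log_f0 = math.log(risch_baseline(K, n, p, tau))
    log_tau = math.log(tau)
    x = cfg.support.astype(float)
    q = _binom_pmf(n, p)
    # cap inactive at the closed-form baseline -> already calibrated
    if log_f0 + float(np.max(x)) * max(log_tau, 0.0) <= 0.0 and log_f0 <= 0.0:
        return math.exp(log_f0)

    def resid(log_f: float) -> float:
        return float(q @ np.exp(np.minimum(log_f + x * log_tau, 0.0))) - K

    hi = math.log(K) + 2 * n * abs(log_tau) + 1.0
    log_f = _solve_log_baseline(resid, log_f0, hi, K, "crisch calibration")
    if abs(resid(log_f)) > max(_ABS_TOL, _REL_TOL * K):
        raise CalibrationError(f"crisch calibration residual {resid(log_f):.3e} too large")
    return math.exp(log_f)


def odds_calibrate(K: float, n: int, p: float, tau: float) -> float:
    """Solve the baseline odds C_n so that E(g) = K, g = O/(1+O), O = gamma**x C_n.

    ``tau`` plays the role of the per-allele odds factor gamma.  For gamma = 1
    the solution is the null odds K/(1-K).
    """
    cfg = ModelConfig("odds", K, n, p, tau)
    logit_K = math.log(K) - math.log1p(-K)
    if tau == 1.0:
        return math.exp(logit_K)
    log_g = math.log(tau)
    x = cfg.support.astype(float)
    q = _binom_pmf(n, p)

    def resid(log_C: float) -> float:
        return float(q @ expit(x * log_g + log_C)) - K

    half_width = 2 * n * abs(log_g) + 1.0
    log_C = _solve_log_baseline(
        resid, logit_K - half_width, logit_K + half_width, K, "odds calibration"
    )
    if abs(resid(log_C)) > max(_ABS_TOL, _REL_TOL * K):
        raise CalibrationError(f"odds calibration residual {resid(log_C):.3e} too large")
    return math.exp(log_C)


def probit_params(K: float, n: int, p: float, h2l: float) -> tuple[float, float]:
    """Closed-form liability-threshold parameters (a, t).

    t = Φ⁻¹(1-K) positions the threshold so that a unit-variance normal
    liability exceeds it with probability K; a = sqrt(h2l / (2np(1-p)))
    scales the per-allele effect so the binomial genetic variance on the
    liability scale equals h2l.
    """
    ModelConfig("probit", K, n, p, h2l=h2l)
    t = float(ndtri(1.0 - K))
    a = math.sqrt(h2l / (2.0 * n * p * (1.0 - p)))
    return a, t


def _probit_refine_t(K: float, n: int, p: float, h2l: float) -> tuple[float, float]:
    """Refine t so that the *binomial* expectation of g equals K exactly.

    The closed-form t assumes the genetic values are exactly normal; for
    finite n the binomial lattice leaves a small residual, removed here by a
    1-D solve around the nominal threshold.
    """
    a, t0 = probit_params(K, n, p, h2l)
    if h2l == 0.0:
        return a, t0
    s = math.sqrt(1.0 - h2l)
    x = np.arange(2 * n + 1, dtype=float)
    q = _binom_pmf(n, p)
    u = (x - 2.0 * n * p) * a

    def resid(t: float) -> float:
        return float(q @ ndtr((u - t) / s)) - K

    if abs(resid(t0)) <= max(_ABS_TOL, _REL_TOL * K):
        return a, t0
    lo, hi = t0 - 1.0, t0 + 1.0
    # resid is decreasing in t
    while resid(lo) < 0.0:
        lo -= 1.0
    while resid(hi) > 0.0:
        hi += 1.0
    t = brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=_MAX_ITER)
    return a, float(t)


def calibrate(config: ModelConfig) -> CalibratedModel:
    """Solve the model's baseline constant so that population mean risk is K."""
    cfg = config
    if cfg.kind == "risch":
        baseline: float | tuple[float, float] = risch_baseline(cfg.K, cfg.n, cfg.p, cfg.tau)
    elif cfg.kind == "crisch":
        baseline = crisch_calibrate(cfg.K, cfg.n, cfg.p, cfg.tau)
    elif cfg.kind == "odds":
        baseline = odds_calibrate(cfg.K, cfg.n, cfg.p, cfg.tau)
    else:
        baseline = _probit_refine_t(cfg.K, cfg.n, cfg.p, cfg.h2l)
    model = CalibratedModel(cfg, baseline, calibration_residual=math.nan)
    residual = abs(_mean_risk(model) - cfg.K)
    object.__setattr__(model, "calibration_residual", residual)
    return model


def _mean_risk(model: CalibratedModel) -> float:
    """E(g) over the exact binomial support (log-space for risch)."""
    cfg = model.config
    if cfg.kind == "risch":
        x = cfg.support
        logq = binom.logpmf(x, 2 * cfg.n, cfg.p)
        return float(np.exp(logsumexp(logq + model.log_risk(x))))
    q = _binom_pmf(cfg.n, cfg.p)
    return float(q @ model.risk_vector())


def risk(model: CalibratedModel, x):
    """Penetrance g_x; functional alias for :meth:`CalibratedModel.risk`."""
    return model.risk(x)
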