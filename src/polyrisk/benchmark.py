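"""Benchmarked model comparison anchored on the liability-threshold model.

To compare the multiplicative, odds and liability-threshold models fairly,
all are matched on two observable quantities: the prevalence K and the effect
size of one risk allele at the mean multilocus background.  The
liability-threshold (probit) model is parameterised by (K, n, p, h2l); its
implied per-allele relative risk at the mean genotype,

    tau = g_{2np+1} / g_{2np},

is then fed to the multiplicative (risch/crisch) and odds models (with the
odds factor gamma set equal to tau), so that all four models share (K, n, p)
and the benchmark effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .models import CalibratedModel, ModelConfig, calibrate
from .population import heritability_risk_scale
from .relatives import lambda_mz_exact

__all__ = [
    "BenchmarkSet",
    "tau_from_probit",
    "build_benchmark_set",
    "comparison_grid",
    "solve_effect_for_lambda",
]


@dataclass(frozen=True)
class BenchmarkSet:
    """Four calibrated models sharing (K, n, p) and the probit-anchored tau."""

    K: float
    n: int
    p: float
    h2l_anchor: float
    tau_benchmark: float
    models: dict[str, CalibratedModel]


def tau_from_probit(model: CalibratedModel) -> float:
    """Per-allele relative risk at the mean genotype, g_{2np+1}/g_{2np}.

    2np is rounded to the nearest integer when not integral (the benchmark is
    a local slope at the mean count).  h2l = 0 gives the null value 1.
    """
    cfg = model.config
    if cfg.kind != "probit":
        raise ValueError("tau benchmark is defined from the probit model")
    if cfg.h2l == 0.0:
        return 1.0
    x0 = int(round(2 * cfg.n * cfg.p))
    x0 = min(max(x0, 0), 2 * cfg.n - 1)
    return float(model.risk(x0 + 1) / model.risk(x0))


def build_benchmark_set(K: float, n: int, p: float, h2l: float) -> BenchmarkSet:
    """Calibrate all four models matched on (K, n, p) and the probit tau."""
    probit = calibrate(ModelConfig("probit", K, n, p, h2l=h2l))
    tau = tau_from_probit(probit)
    models = {"probit": probit}
    for kind in ("risch", "crisch", "odds"):
        models[kind] = calibrate(ModelConfig(kind, K, n, p, tau=tau))
    return BenchmarkSet(K=K, n=int(n), p=p, h2l_anchor=h2l, tau_benchmark=tau, models=models)


def comparison_grid(
    K_list, n_list, p_list, h2l_list, include_lambda_mz: bool = True
) -> pd.DataFrame:
    """Long-format comparison over a (K, n, p, h2l) grid.

    One row per parameter combination per model, with the benchmark tau, the
    risk-scale broad-sense heritability, and (optionally) the analytic MZ
    recurrence risk ratio.  Deterministic — no simulation involved.
    """
    rows = []
    for K, n, p, h2l in product(K_list, n_list, p_list, h2l_list):
        bset = build_benchmark_set(K, n, p, h2l)
        for kind, model in bset.models.items():
            row = {
                "K": K, "n": int(n), "p": p, "h2l": h2l,
                "tau": bset.tau_benchmark, "model": kind,
                "h2_01_broad": heritability_risk_scale(model),
            }
            if include_lambda_mz:
                row["lambda_mz"] = lambda_mz_exact(model)
            rows.append(row)
    return pd.DataFrame(rows)


def solve_effect_for_lambda(
    kind: str,
    K: float,
    n: int,
    p: float,
    target_lambda_mz: float,
    rtol: float = 1e-6,
) -> float:
    """Invert a model: the effect size whose analytic λ_MZ matches a target.

    Returns tau (risch/crisch/odds) or h2l (probit).  λ_MZ is bounded above by
    1/K for any model with risks in [0, 1]; targets at or beyond the bound are
    rejected.  Bisection on the effect parameter, which λ_MZ increases with.
    """
    from scipy.optimize import brentq

    if target_lambda_mz < 1.0:
        raise ValueError(f"target lambda_MZ must be >= 1, got {target_lambda_mz}")
    if target_lambda_mz == 1.0:
        return 0.0 if kind == "probit" else 1.0
    if kind != "risch" and target_lambda_mz >= 1.0 / K:
        raise ValueError(
            f"target lambda_MZ = {target_lambda_mz} is unattainable: "
            f"lambda_MZ < 1/K = {1.0 / K:.6g} for models with risks in [0, 1]"
        )

    def lam(effect: float) -> float:
        cfg = (
            ModelConfig("probit", K, n, p, h2l=effect)
            if kind == "probit"
            else ModelConfig(kind, K, n, p, tau=effect)
        )
        return lambda_mz_exact(calibrate(cfg))

    if kind == "probit":
        lo, hi = 1e-12, 1.0 - 1e-9
    else:
        lo, hi = 1.0 + 1e-12, 2.0
        while lam(hi) < target_lambda_mz:
            hi = 1.0 + 2.0 * (hi - 1.0)
            if hi > 1e6:
                raise ValueError(
                    f"could not bracket target lambda_MZ = {target_lambda_mz} "
                    f"for the {kind} model"
                )
    effect = brentq(
        lambda e: lam(e) - target_lambda_mz, lo, hi,
        xtol=1e-12, rtol=min(rtol, 1e-8), maxiter=200,
    )
    achieved = lam(effect)
    if abs(achieved - target_lambda_mz) > rtol * target_lambda_mz:
        raise RuntimeError(
            f"effect solve did not converge: lambda_MZ = {achieved:.6g} "
            f"vs target {target_lambda_mz:.6g}"
        )
    return float(effect)
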