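"""Published epidemiological recurrence-risk estimates and derived columns.

Ships a compilation of prevalence and recurrence-risk-ratio estimates for 15
common complex diseases (``table1.tsv``) and recomputes the derived summary
columns — the Eq-1 broad-sense risk-scale heritability and the λ-ratio
diagnostics — from the raw (K, λ_R) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .relatives import h2_01_from_lambda_mz, ratio_diagnostics

__all__ = [
    "EpiRecord",
    "load_table1",
    "table1_frame",
    "derive_columns",
    "table1_with_derived",
    "liability_h2_from_mz_concordance",
]


@dataclass(frozen=True)
class EpiRecord:
    """One disease's observed (K, λ_R) values plus derived summaries."""

    disease: str
    K: float
    lambda_mz: float | None
    lambda_sib: float | None
    lambda_op: float | None = None
    h2_01: float | None = None
    dominance_ratio: float | None = None
    excess_ratio: float | None = None
    mz_over_sib_sq: float | None = None


def table1_frame() -> pd.DataFrame:
    """The packaged disease table as a DataFrame.

    Raw λ columns are numeric (NaN where no estimate is published); the
    ``*_printed`` columns keep the published derived values verbatim as
    strings, preserving their original rounding precision.
    """
    path = resources.files("polyrisk.data").joinpath("table1.tsv")
    with path.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("K", "lambda_mz", "lambda_sib", "lambda_op"):
        frame[col] = pd.to_numeric(frame[col])
    return frame


def load_table1() -> list[EpiRecord]:
    """The 15 disease records (raw columns only)."""
    frame = table1_frame()
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            EpiRecord(
                disease=row.disease,
                K=float(row.K),
                lambda_mz=None if pd.isna(row.lambda_mz) else float(row.lambda_mz),
                lambda_sib=None if pd.isna(row.lambda_sib) else float(row.lambda_sib),
                lambda_op=None if pd.isna(row.lambda_op) else float(row.lambda_op),
            )
        )
    return records


def derive_columns(record: EpiRecord) -> EpiRecord:
    """Fill the derived summaries computable from the raw (K, λ) values.

    h2_01 needs λ_MZ; the ratio diagnostics need λ_MZ and λ_Sib; the
    dominance ratio additionally needs λ_OP.  Missing inputs leave the
    corresponding derived field as None.
    """
    h2 = None
    if record.lambda_mz is not None:
        h2 = h2_01_from_lambda_mz(record.lambda_mz, record.K)
    mz_sq = excess = dominance = None
    if record.lambda_mz is not None and record.lambda_sib is not None:
        diag = ratio_diagnostics(record.lambda_mz, record.lambda_sib, record.lambda_op)
        mz_sq, excess, dominance = diag.mz_over_sib_sq, diag.excess_ratio, diag.dominance_ratio
    return replace(
        record,
        h2_01=h2,
        dominance_ratio=dominance,
        excess_ratio=excess,
        mz_over_sib_sq=mz_sq,
    )


def table1_with_derived() -> list[EpiRecord]:
    """All records with derived columns filled where computable."""
    return [derive_columns(rec) for rec in load_table1()]


def liability_h2_from_mz_concordance(K: float, lambda_mz: float) -> float:
    """Liability-scale heritability implied by MZ concordance (bivariate normal).

    Assumes MZ co-twins' liabilities are bivariate standard normal with
    correlation rho = h2l (all twin resemblance genetic).  Solves rho so that
    P(both liabilities exceed the threshold) equals K_MZ * K = lambda_mz * K².
    This is a model-based helper, not a value asserted against any published
    column.
    """
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal

    from .scales import liability_quantities

    if lambda_mz < 1.0 or lambda_mz * K > 1.0:
        raise ValueError("need 1 <= lambda_mz <= 1/K")
    t = liability_quantities(K).t
    target = lambda_mz * K * K  # P(both twins affected)

    def p_both(rho: float) -> float:
        cdf = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
        return float(cdf) - (1.0 - 2.0 * K)  # P(both > t)

    if p_both(0.0) >= target:
        return 0.0
    hi = 1.0 - 1e-9
    if p_both(hi) <= target:
        return 1.0
    return float(brentq(lambda r: p_both(r) - target, 0.0, hi, xtol=1e-10))
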