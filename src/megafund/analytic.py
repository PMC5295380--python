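"""Closed-form tranche calculus for ideal, reliable and unfair megafunds.

All quantities follow from two binomial tail sums.  A senior tranche of an
SPV holding NL non-lemons defaults when fewer than

    K = ceil( (D*I*s / B) * (1+r)^T )

programs succeed, because K is the smallest success count whose payouts
``k * B*N/(M*D)`` cover the promised amount ``I_senior * (1+r)^T``.  The
pooled equity tranche defaults when fewer than

    K' = ceil( (N*I*s*(1+r)^T + N*I*(1-s)) / B )

programs succeed fund-wide; for a single SPV this is exact, for several
SPVs it is the standard estimate obtained by treating the total senior
take as fixed at its promised level.  Default probabilities are binomial
lower tails at these thresholds; expected values and annual yields follow
by direct averaging.

An *ideal* fund is the special case n = 0; an *unfair* fund is handled as
two reliable sub-funds (clean and toxic SPVs) whose defaults and values
are averaged with weights M1, M2.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

from .params import AnalyticParams, ParameterError, TrancheResult, UnfairParams

__all__ = [
    "senior_threshold",
    "senior_default_prob",
    "senior_value_and_yield",
    "equity_threshold",
    "equity_default_prob",
    "equity_value_and_yield",
    "unfair_senior",
    "unfair_equity",
    "fund_summary",
    "table_report",
]


def _ceil(x: float) -> int:
    """Standard ceiling; exact integers map to themselves."""
    return int(math.ceil(x - 1e-12)) if abs(x - round(x)) < 1e-12 else int(math.ceil(x))


def _binom_lower_tail(threshold: int, n: int, p: float) -> float:
    """P(X < threshold) for X ~ Binomial(n, p), computed stably."""
    if threshold <= 0:
        return 0.0
    if n == 0:
        return 1.0
    return float(binom.cdf(threshold - 1, n, p))


# ----------------------------------------------------------------------
# Senior tranche
# ----------------------------------------------------------------------
def senior_threshold(params: AnalyticParams) -> int:
    """Minimum success count K at which an SPV's senior tranche is whole.

    K = ceil( (D*I*s/B) * (1+r)^T ).  Independent of M: the per-SPV
    promise and the per-success payment both scale as 1/M.
    """
    pre = (
        params.spv_size
        * params.investment_per_program
        * params.senior_share
        / params.success_value
    ) * params.growth_factor
    return max(_ceil(pre), 0)


def senior_preceiling(params: AnalyticParams) -> float:
    """The real-valued success count before the ceiling (Table display)."""
    return (
        params.spv_size
        * params.investment_per_program
        * params.senior_share
        / params.success_value
    ) * params.growth_factor


def senior_default_prob(params: AnalyticParams) -> float:
    """P(senior default) = binomial lower tail below K over the SPV's NL non-lemons."""
    K = senior_threshold(params)
    return _binom_lower_tail(K, params.n_nonlemons_per_spv, params.success_prob)


def senior_value_and_yield(params: AnalyticParams) -> TrancheResult:
    """Expected value and annual yield of one SPV's senior tranche.

    The tranche pays the promised ``I_senior*(1+r)^T`` with probability
    1-d; on default each of the k < K successes still pays the tranche
    its ``B*N/(M*D)`` recovery.
    """
    K = senior_threshold(params)
    NL = params.n_nonlemons_per_spv
    p = params.success_prob
    d = _binom_lower_tail(K, NL, p)
    i_senior = params.senior_investment_per_spv
    promised = i_senior * params.growth_factor
    ks = np.arange(K)
    recovery = float(
        np.sum(binom.pmf(ks, NL, p) * ks) * params.payment_per_success
    )
    value = (1.0 - d) * promised + recovery
    annual_yield = (value / i_senior) ** (1.0 / params.horizon_years) - 1.0
    return TrancheResult(
        threshold=K,
        default_prob=d,
        expected_value=value,
        annual_yield=annual_yield,
        investment=i_senior,
    )


# ----------------------------------------------------------------------
# Equity tranche (pooled across SPVs)
# ----------------------------------------------------------------------
def equity_threshold(params: AnalyticParams) -> int:
    """Minimum fund-wide success count K' at which equity is made whole.

    K' = ceil( (N*I*s*(1+r)^T + N*I*(1-s)) / B ): the successes must
    cover the aggregate senior promise plus the equity principal.  Exact
    for M = 1; the estimate used for several SPVs.
    """
    return max(_ceil(equity_preceiling(params)), 0)


def equity_preceiling(params: AnalyticParams) -> float:
    NI = params.total_investment
    s = params.senior_share
    return (NI * s * params.growth_factor + NI * (1.0 - s)) / params.success_value


def equity_default_prob(params: AnalyticParams) -> float:
    """P(equity default): binomial lower tail below K' over all N-n non-lemons."""
    Kp = equity_threshold(params)
    return _binom_lower_tail(
        Kp, params.n_assets - params.n_lemons, params.success_prob
    )


def equity_value_and_yield(
    params: AnalyticParams, senior: TrancheResult | None = None
) -> TrancheResult:
    """Expected value and annual yield of the pooled equity tranche.

    V_equities = (N-n)*p*B - M*V_senior: the fund's average gross value
    minus the average total senior take.  A non-positive residual marks
    the tranche as wiped out (value 0, yield -100 %/yr).
    """
    if senior is None:
        senior = senior_value_and_yield(params)
    gross = (
        (params.n_assets - params.n_lemons)
        * params.success_prob
        * params.success_value
    )
    value = gross - params.n_spvs * senior.expected_value
    i_eq = params.equity_investment
    wiped = value <= 0.0
    if wiped:
        return TrancheResult(
            threshold=equity_threshold(params),
            default_prob=equity_default_prob(params),
            expected_value=0.0,
            annual_yield=-1.0,
            investment=i_eq,
            wiped_out=True,
        )
    annual_yield = (value / i_eq) ** (1.0 / params.horizon_years) - 1.0
    return TrancheResult(
        threshold=equity_threshold(params),
        default_prob=equity_default_prob(params),
        expected_value=value,
        annual_yield=annual_yield,
        investment=i_eq,
    )


# ----------------------------------------------------------------------
# Unfair megafund
# ----------------------------------------------------------------------
def _subfund_senior(params: UnfairParams, lemons_per_spv: int) -> tuple[float, float]:
    """(default prob, expected value) of a senior tranche whose SPV holds
    ``lemons_per_spv`` lemons, i.e. NL = D - lemons_per_spv non-lemons."""
    b = params.base
    K = senior_threshold(b)
    NL = b.spv_size - lemons_per_spv
    p = b.success_prob
    d = _binom_lower_tail(K, NL, p)
    promised = b.senior_investment_per_spv * b.growth_factor
    ks = np.arange(K)
    recovery = float(np.sum(binom.pmf(ks, NL, p) * ks) * b.payment_per_success)
    return d, (1.0 - d) * promised + recovery


def unfair_senior(params: UnfairParams) -> TrancheResult:
    """Overall senior tranche of an unfair fund: M-weighted average of the
    clean (d1 lemons per SPV) and toxic (d2 lemons per SPV) sub-funds."""
    b = params.base
    M1, M2 = params.n_clean_spvs, params.n_toxic_spvs
    d1, v1 = _subfund_senior(params, params.lemons_per_clean_spv)
    d2, v2 = _subfund_senior(params, params.lemons_per_toxic_spv)
    M = b.n_spvs
    d = (M1 * d1 + M2 * d2) / M
    value = (M1 * v1 + M2 * v2) / M
    i_senior = b.senior_investment_per_spv
    annual_yield = (value / i_senior) ** (1.0 / b.horizon_years) - 1.0
    return TrancheResult(
        threshold=senior_threshold(b),
        default_prob=d,
        expected_value=value,
        annual_yield=annual_yield,
        investment=i_senior,
    )


def unfair_equity(params: UnfairParams) -> TrancheResult:
    """Equity tranche of an unfair fund.

    Pooling makes every equity tranche share the same fund-wide residual,
    so the reliable-fund equity formulas apply unchanged and the result
    delegates to :func:`equity_value_and_yield` /
    :func:`equity_default_prob` on the base parameters.
    """
    return equity_value_and_yield(params.base)


# ----------------------------------------------------------------------
# Reporting
# ----------------------------------------------------------------------
def fund_summary(params: AnalyticParams | UnfairParams) -> dict[str, float]:
    """All headline numbers for one parameter set, as a flat dict."""
    if isinstance(params, UnfairParams):
        senior = unfair_senior(params)
        equity = unfair_equity(params)
        base = params.base
    else:
        senior = senior_value_and_yield(params)
        equity = equity_value_and_yield(params, senior)
        base = params
    return {
        "senior_preceiling_K": senior_preceiling(base),
        "senior_K": senior.threshold,
        "senior_default": senior.default_prob,
        "senior_yield": senior.annual_yield,
        "equity_yield": equity.annual_yield,
        "equity_Kprime": equity.threshold,
        "equity_preceiling_Kprime": equity_preceiling(base),
        "equity_default": equity.default_prob,
        "equity_wiped_out": float(equity.wiped_out),
    }


def table_report(
    cases: Mapping[str, AnalyticParams | UnfairParams] | Iterable[tuple[str, AnalyticParams | UnfairParams]],
) -> pd.DataFrame:
    """One row per named parameter set with senior K/d/y and equity y/K'/d.

    Percentages are rounded to one decimal for display (``*_pct``
    columns); thresholds show both the pre-ceiling value and the integer.
    Full-precision values are available from :func:`fund_summary`.
    """
    items = cases.items() if isinstance(cases, Mapping) else cases
    rows = []
    for name, params in items:
        s = fund_summary(params)
        rows.append(
            {
                "case": name,
                "senior_K_pre": round(s["senior_preceiling_K"], 1),
                "senior_K": int(s["senior_K"]),
                "senior_d_pct": round(100 * s["senior_default"], 1),
                "senior_y_pct": round(100 * s["senior_yield"], 1),
                "equity_y_pct": round(100 * s["equity_yield"], 1),
                "equity_Kp_pre": round(s["equity_preceiling_Kprime"], 1),
                "equity_Kp": int(s["equity_Kprime"]),
                "equity_d_pct": round(100 * s["equity_default"], 1),
            }
        )
    columns = [
        "case",
        "senior_K_pre",
        "senior_K",
        "senior_d_pct",
        "senior_y_pct",
        "equity_y_pct",
        "equity_Kp_pre",
        "equity_Kp",
        "equity_d_pct",
    ]
    return pd.DataFrame(rows, columns=columns)
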