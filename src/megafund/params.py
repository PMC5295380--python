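"""Parameter containers for the closed-form tranche calculus.

A megafund pools ``N`` drug-development programs, of which ``n`` are
"lemons" — programs with hidden flaws whose success probability is taken
to be zero.  The remaining ``N - n`` non-lemons each succeed independently
with probability ``p``, and a success is worth ``B`` (millions, present
value at the horizon ``T`` years).  The fund places the programs into
``M`` special purpose vehicles (SPVs) of ``D`` programs each, every
program being shared across the same number ``M*D/N`` of SPVs.  A
fraction ``s`` of the invested capital ``N*I`` funds senior tranches
(one per SPV, promised an annual coupon ``r``); the rest funds a single
pooled equity tranche.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class AnalyticParams:
    """Parameter vector of the closed-form megafund model.

    Parameters
    ----------
    n_assets : int
        N, total number of drug-development programs in the fund.
    n_lemons : int
        n, number of lemons (success probability zero).
    n_spvs : int
        M, number of special purpose vehicles.
    spv_size : int
        D, programs per SPV.
    success_prob : float
        p, per-program success probability of a non-lemon.
    success_value : float
        B, value of one success (millions, present value at horizon).
    investment_per_program : float
        I, upfront investment per program (millions).
    senior_share : float
        s, fraction of capital allocated to senior tranches.
    senior_rate : float
        r, annual coupon promised to senior tranches.
    horizon_years : float
        T, investment horizon in years.
    strict : bool
        If True (default), a non-integral per-SPV non-lemon count is an
        error; if False it is rounded to the nearest integer.
    """

    n_assets: int
    n_lemons: int
    n_spvs: int
    spv_size: int
    success_prob: float
    success_value: float = 12.3
    investment_per_program: float = 0.2
    senior_share: float = 0.5
    senior_rate: float = 0.05
    horizon_years: float = 10.0
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        N, n, M, D = self.n_assets, self.n_lemons, self.n_spvs, self.spv_size
        if not (0 <= n <= N):
            raise ParameterError(f"need 0 <= n_lemons <= n_assets, got n={n}, N={N}")
        if M < 1:
            raise ParameterError(f"need at least one SPV, got M={M}")
        if not (1 <= D <= N):
            raise ParameterError(f"need 1 <= spv_size <= n_assets, got D={D}, N={N}")
        if M * D < N:
            raise ParameterError(
                f"M*D = {M * D} < N = {N}: cannot place every program in an SPV"
            )
        if not (0.0 <= self.success_prob <= 1.0):
            raise ParameterError(f"success_prob must be in [0, 1], got {self.success_prob}")
        if not (0.0 < self.senior_share < 1.0):
            raise ParameterError(f"senior_share must be in (0, 1), got {self.senior_share}")
        if self.success_value <= 0 or self.investment_per_program <= 0:
            raise ParameterError("success_value and investment_per_program must be > 0")
        if self.horizon_years < 1:
            raise ParameterError(f"horizon_years must be >= 1, got {self.horizon_years}")
        nl = D * (N - n) / N
        if self.strict and abs(nl - round(nl)) > 1e-9:
            raise ParameterError(
                f"per-SPV non-lemon count D*(N-n)/N = {nl:.4f} is not an integer; "
                "use strict=False to round"
            )

    # ------------------------------------------------------------------
    # Derived quantities
    # ------------------------------------------------------------------
    @property
    def n_nonlemons_per_spv(self) -> int:
        """NL = D*(N-n)/N, non-lemons held by each SPV."""
        nl = self.spv_size * (self.n_assets - self.n_lemons) / self.n_assets
        return int(round(nl))

    @property
    def total_investment(self) -> float:
        """N*I, total capital invested in the fund."""
        return self.n_assets * self.investment_per_program

    @property
    def senior_investment_per_spv(self) -> float:
        """I_senior = N*I*s/M, capital behind each SPV's senior tranche."""
        return self.total_investment * self.senior_share / self.n_spvs

    @property
    def equity_investment(self) -> float:
        """I_equities = N*I*(1-s), capital behind the pooled equity tranche."""
        return self.total_investment * (1.0 - self.senior_share)

    @property
    def growth_factor(self) -> float:
        """(1+r)^T, the senior compounding factor over the horizon."""
        return (1.0 + self.senior_rate) ** self.horizon_years

    @property
    def payment_per_success(self) -> float:
        """B*N/(M*D), what one success pays each SPV that holds it."""
        return (
            self.success_value
            * self.n_assets
            / (self.n_spvs * self.spv_size)
        )


@dataclass(frozen=True)
class UnfairParams:
    """An unfair megafund: detected lemons concentrated in toxic SPVs.

    The M SPVs split into ``n_clean_spvs`` (M1) holding ``lemons_per_clean_spv``
    (d1) lemons each and ``n_toxic_spvs`` (M2) holding ``lemons_per_toxic_spv``
    (d2 > d1) each.  Lemon slots must be conserved:
    ``M1*d1 + M2*d2 = n*(M*D/N)``.
    """

    base: AnalyticParams
    n_clean_spvs: int
    n_toxic_spvs: int
    lemons_per_clean_spv: int
    lemons_per_toxic_spv: int

    def __post_init__(self) -> None:
        b = self.base
        M1, M2 = self.n_clean_spvs, self.n_toxic_spvs
        d1, d2 = self.lemons_per_clean_spv, self.lemons_per_toxic_spv
        if M1 + M2 != b.n_spvs:
            raise ParameterError(f"M1 + M2 = {M1 + M2} must equal M = {b.n_spvs}")
        if not (0 <= d1 <= d2 <= b.spv_size):
            raise ParameterError(
                f"need 0 <= d1 <= d2 <= D, got d1={d1}, d2={d2}, D={b.spv_size}"
            )
        if M2 > 0 and d2 <= d1 and d1 != d2:
            raise ParameterError("toxic SPVs must hold strictly more lemons")
        slots = b.n_lemons * b.n_spvs * b.spv_size / b.n_assets
        if b.strict and abs(M1 * d1 + M2 * d2 - slots) > 1e-6:
            raise ParameterError(
                f"lemon slots not conserved: M1*d1 + M2*d2 = {M1 * d1 + M2 * d2} "
                f"but n*M*D/N = {slots:.4f}"
            )


@dataclass(frozen=True)
class TrancheResult:
    """Closed-form characteristics of one tranche.

    Attributes
    ----------
    threshold : int
        Minimum number of successes avoiding default (K for senior
        tranches, K' for equity).
    default_prob : float
        Probability the tranche cannot pay its promised amount.
    expected_value : float
        Average value the tranche pays (millions).
    annual_yield : float
        (expected_value / investment)^(1/T) - 1.
    investment : float
        Capital behind the tranche (per SPV for senior, aggregate for
        equity).
    wiped_out : bool
        True when the expected residual value is non-positive (equity
        only); yield is then reported as -1.0 (i.e. -100 % per year).
    """

    threshold: int
    default_prob: float
    expected_value: float
    annual_yield: float
    investment: float
    wiped_out: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.default_prob <= 1.0):
            raise ParameterError(f"default_prob out of [0,1]: {self.default_prob}")
        if self.expected_value < 0:
            raise ParameterError(f"expected_value must be >= 0: {self.expected_value}")
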