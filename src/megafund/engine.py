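"""Semester-stepped Monte Carlo engine for the megafund.

Each simulated path builds a fund from a fresh asset pool: lemons are
(possibly) detected, the behavior decides what gets funded, SPVs are
structured, and every asset is stepped semester by semester under its
transition matrix while SPV cash reserves accrue interest, pay periodic
and milestone costs, and collect sale proceeds.  At the horizon a
two-tranche waterfall settles each SPV: the senior tranche is paid first
up to its promised amount, and the residuals of all SPVs are pooled into
a single fund-wide equity tranche.

Capital accounting: investors commit ``C = N_funded * I / (1 - v)``; the
fraction ``v`` is spent on validation and the remaining ``N_funded * I``
funds the programs.  Tranche principals (the yield denominators and the
senior promise basis) are shares of the full committed ``C``, so
validation is a real drag that must pay for itself through lemon removal
and improved non-lemon odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_COSTS,
    DEFAULT_LEMON_SEVERITY,
    DEFAULT_NONLEMON_MATRIX,
    CostSchedule,
    Phase,
    TransitionMatrix,
    build_lemon_matrix,
)
from .structuring import (
    FundBehavior,
    SPVStructure,
    ValidationPolicy,
    apply_behavior,
    build_spvs,
    detect_lemons,
)

__all__ = ["SimConfig", "SimResult", "run_path", "run_paths", "validation_sweep"]

_TRANCHES = ("senior", "senior_clean", "senior_toxic", "equity")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one Monte Carlo run."""

    n_assets: int = 200
    lemon_fraction: float = 0.5
    behavior: FundBehavior = FundBehavior.RELIABLE
    validation_fraction: float = 0.0
    n_paths: int = 20_000
    seed: int = 0
    horizon_semesters: int = 12
    investment_per_program: float = 0.2
    senior_share: float = 0.5
    senior_rate: float = 0.085
    cash_rate_semester: float = 0.01
    waterfall_mode: str = "recovery"
    uplift_slope: float = 1.0
    toxic_fraction: float = 0.25
    detection_scale: float = 10.0
    false_positive_rate: float = 0.0
    lemon_severity: float = DEFAULT_LEMON_SEVERITY
    nonlemon_matrix: TransitionMatrix = DEFAULT_NONLEMON_MATRIX
    lemon_matrix: TransitionMatrix | None = None
    costs: CostSchedule = DEFAULT_COSTS
    # Optional overrides of the M = N/4, D = N/2 structuring rule and of
    # the number of years over which the senior promise compounds
    # (default: the simulated horizon in years).
    n_spvs: int | None = None
    spv_size: int | None = None
    promise_years: float | None = None

    def __post_init__(self) -> None:
        if self.n_paths < 1 or self.horizon_semesters < 1:
            raise ValueError("n_paths and horizon_semesters must be >= 1")
        if not (0.0 <= self.lemon_fraction <= 1.0):
            raise ValueError("lemon_fraction must be in [0, 1]")
        if self.waterfall_mode not in ("recovery", "minimal"):
            raise ValueError("waterfall_mode must be 'recovery' or 'minimal'")
        if not (0.0 < self.senior_share < 1.0):
            raise ValueError("senior_share must be in (0, 1)")
        if self.uplift_slope < 0:
            raise ValueError("uplift_slope must be >= 0")
        self.policy  # validates validation_fraction

    @property
    def policy(self) -> ValidationPolicy:
        return ValidationPolicy(
            validation_fraction=self.validation_fraction,
            detection_scale=self.detection_scale,
            false_positive_rate=self.false_positive_rate,
        )

    @property
    def horizon_years(self) -> float:
        return self.horizon_semesters / 2.0

    def matrices(self) -> tuple[TransitionMatrix, TransitionMatrix]:
        """(non-lemon, lemon) matrices with the validation uplift applied.

        Validation improves the characterization of non-lemons: their
        advance probabilities scale by ``1 + uplift_slope * v``.
        """
        uplift = 1.0 + self.uplift_slope * self.validation_fraction
        nonlemon = self.nonlemon_matrix.with_advance_uplift(uplift)
        lemon = self.lemon_matrix
        if lemon is None:
            lemon = build_lemon_matrix(self.nonlemon_matrix, self.lemon_severity)
        return nonlemon, lemon


def _settle_waterfall(
    values: np.ndarray,
    senior_promise: float,
    mode: str,
) -> tuple[np.ndarray, float]:
    """Per-SPV senior payments and the pooled equity residual.

    ``recovery`` mode pays a defaulted senior whatever value its SPV has;
    ``minimal`` mode pays a defaulted senior nothing.  Either way the
    fund-wide residual (including anything a defaulted senior did not
    take) flows to the single pooled equity tranche.
    """
    recoverable = np.maximum(values, 0.0)
    if mode == "recovery":
        senior_paid = np.minimum(recoverable, senior_promise)
    else:
        senior_paid = np.where(recoverable >= senior_promise, senior_promise, 0.0)
    residual = float(values.sum() - senior_paid.sum())
    return senior_paid, max(residual, 0.0)


def run_path(config: SimConfig, rng: np.random.Generator) -> dict[str, Any]:
    """Simulate one fund path; returns the raw settlement record.

    The record carries per-SPV senior payments, default flags and toxic
    designation, the pooled equity payment, both tranches' principals,
    and totals for money-conservation checks.
    """
    n_pool = config.n_assets
    n_lemons = int(round(n_pool * config.lemon_fraction))
    is_lemon = np.zeros(n_pool, dtype=bool)
    is_lemon[rng.choice(n_pool, size=n_lemons, replace=False)] = True

    flags = detect_lemons(is_lemon, config.policy, rng)
    funded = apply_behavior(is_lemon, flags, config.behavior)
    lemon_f = is_lemon[funded]
    flags_f = flags[funded]
    n_f = int(funded.sum())

    structure = build_spvs(
        n_f,
        flags_f,
        config.behavior,
        rng,
        toxic_fraction=config.toxic_fraction,
        n_spvs=config.n_spvs,
        spv_size=config.spv_size,
    )
    M = structure.n_spvs
    shares = structure.membership / structure.membership_counts  # (M, n_f)

    v = config.validation_fraction
    investable = n_f * config.investment_per_program
    committed = investable / (1.0 - v)
    senior_principal = config.senior_share * committed / M
    equity_principal = (1.0 - config.senior_share) * committed
    years = config.promise_years if config.promise_years is not None else config.horizon_years
    senior_promise = senior_principal * (1.0 + config.senior_rate) ** years

    nonlemon, lemon = config.matrices()
    cum = np.stack([np.cumsum(nonlemon.probs, axis=1), np.cumsum(lemon.probs, axis=1)])
    type_idx = lemon_f.astype(int)
    costs = config.costs
    periodic = np.zeros(4)
    milestone = np.zeros(4)
    for ph in Phase:
        periodic[ph] = costs.periodic_cost(ph)
        milestone[ph] = costs.milestone_payment(ph)

    cash_per_asset = config.investment_per_program - costs.upfront
    spv_cash = shares @ np.full(n_f, cash_per_asset)

    phases = np.zeros(n_f, dtype=int)
    total_sales = 0.0
    for _ in range(config.horizon_semesters):
        spv_cash *= 1.0 + config.cash_rate_semester
        transient = phases < int(Phase.SOLD)
        if not transient.any():
            continue
        flow = np.zeros(n_f)
        flow[transient] -= periodic[phases[transient]]
        u = rng.random(n_f)
        rows = cum[type_idx[transient], phases[transient]]
        new = (u[transient, None] > rows[:, :3]).sum(axis=1)
        advanced = (new != phases[transient]) & (new != int(Phase.FAILED))
        idx = np.flatnonzero(transient)
        adv_idx = idx[advanced]
        flow[adv_idx] -= milestone[new[advanced]]
        sold = adv_idx[new[advanced] == int(Phase.SOLD)]
        flow[sold] += costs.sale_value
        total_sales += costs.sale_value * len(sold)
        phases[idx] = new
        spv_cash += shares @ flow

    senior_paid, equity_paid = _settle_waterfall(
        spv_cash, senior_promise, config.waterfall_mode
    )
    return {
        "senior_paid": senior_paid,
        "senior_default": spv_cash < senior_promise - 1e-12,
        "toxic": structure.toxic,
        "equity_paid": equity_paid,
        "senior_principal": senior_principal,
        "equity_principal": equity_principal,
        "total_value": float(spv_cash.sum()),
        "total_sales": total_sales,
        "n_funded": n_f,
        "years": years,
    }


@dataclass(frozen=True)
class SimResult:
    """Aggregated Monte Carlo summaries for each tranche.

    ``stats`` maps each tranche ('senior', 'senior_clean', 'senior_toxic',
    'equity') to mean annual yield, default frequency and their Monte
    Carlo standard errors.  Yields are annualized over the simulated
    horizon; a tranche paid nothing yields -100 % per year.
    """

    behavior: FundBehavior
    validation_fraction: float
    n_paths: int
    seed: int
    stats: dict[str, dict[str, float]]
    config: SimConfig = field(repr=False, compare=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tranche in _TRANCHES:
            if tranche not in self.stats:
                continue
            rows.append(
                {
                    "behavior": FundBehavior(self.behavior).value,
                    "validation_fraction": self.validation_fraction,
                    "tranche": tranche,
                    **self.stats[tranche],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, Any]:
        return {
            "behavior": FundBehavior(self.behavior).value,
            "validation_fraction": self.validation_fraction,
            "n_paths": self.n_paths,
            "seed": self.seed,
            "stats": self.stats,
        }


def _yield_from_payment(paid: np.ndarray, principal: float, years: float) -> np.ndarray:
    ratio = np.asarray(paid, dtype=float) / principal
    return np.where(ratio > 0, ratio ** (1.0 / years) - 1.0, -1.0)


def run_paths(config: SimConfig) -> SimResult:
    """Run ``config.n_paths`` independent paths under a seeded RNG tree.

    Each path draws from its own child stream of the master seed, so
    results are reproducible and unchanged by execution order, and
    extending ``n_paths`` leaves earlier paths untouched.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_paths)
    groups: dict[str, list[np.ndarray]] = {t: [] for t in _TRANCHES}
    group_defaults: dict[str, list[float]] = {t: [] for t in _TRANCHES}
    for child in seeds:
        rec = run_path(config, np.random.default_rng(child))
        years = rec["years"]
        sy = _yield_from_payment(rec["senior_paid"], rec["senior_principal"], years)
        sd = rec["senior_default"]
        toxic = rec["toxic"]
        groups["senior"].append(sy.mean())
        group_defaults["senior"].append(sd.mean())
        if toxic.any():
            groups["senior_toxic"].append(sy[toxic].mean())
            group_defaults["senior_toxic"].append(sd[toxic].mean())
            groups["senior_clean"].append(sy[~toxic].mean())
            group_defaults["senior_clean"].append(sd[~toxic].mean())
        ey = float(
            _yield_from_payment(
                np.array([rec["equity_paid"]]), rec["equity_principal"], years
            )[0]
        )
        groups["equity"].append(np.array(ey))
        group_defaults["equity"].append(
            float(rec["equity_paid"] < rec["equity_principal"] - 1e-12)
        )

    stats: dict[str, dict[str, float]] = {}
    n = config.n_paths
    for tranche in _TRANCHES:
        ys = np.asarray(groups[tranche], dtype=float)
        ds = np.asarray(group_defaults[tranche], dtype=float)
        if ys.size == 0:
            continue
        f = float(ds.mean())
        stats[tranche] = {
            "mean_yield": float(ys.mean()),
            "yield_se": float(ys.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "default_freq": f,
            "default_se": float(np.sqrt(max(f * (1.0 - f), 0.0) / n)),
            "n_paths": float(n),
        }
    return SimResult(
        behavior=config.behavior,
        validation_fraction=config.validation_fraction,
        n_paths=config.n_paths,
        seed=config.seed,
        stats=stats,
        config=config,
    )


def validation_sweep(
    config: SimConfig,
    v_grid: list[float],
    behaviors: list[FundBehavior] | None = None,
) -> pd.DataFrame:
    """One SimResult row-set per (behavior, validation fraction).

    Returns a tidy frame: behavior x v x tranche with yields, default
    frequencies and standard errors.  Every cell reuses the same master
    seed, so the sweep is a pure function of (config, grid).
    """
    if behaviors is None:
        behaviors = [config.behavior]
    frames = []
    for behavior in behaviors:
        for v in v_grid:
            cfg = replace(config, behavior=FundBehavior(behavior), validation_fraction=v)
            frames.append(run_paths(cfg).to_frame())
    return pd.concat(frames, ignore_index=True)
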