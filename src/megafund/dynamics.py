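"""Per-asset drug-development dynamics for the Monte Carlo engine.

Each program is a four-state Markov chain stepped once per semester:

    Preclinical -> PhaseI -> Sold   (reached Phase II; monetized at once)
                 \\-------> Failed  (withdrawn)

``Sold`` and ``Failed`` are absorbing.  Lemons — programs with hidden
flaws — move under a strictly worse matrix: their advance probabilities
are deflated and their failure probabilities inflated, the inflation
growing with the phase already reached (flawed programs that survive
early screens fail harder and later).

The numeric matrices are calibration inputs, shipped as editable
defaults: the default non-lemon chain reaches ``Sold`` within the
12-semester horizon with probability close to 10 %, so a pool that is
half lemons (whose success probability is driven near zero) has the
~5 % blended success rate typical of early-stage portfolios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Phase",
    "TransitionMatrix",
    "Asset",
    "CostSchedule",
    "build_lemon_matrix",
    "step_asset",
    "absorption_probabilities",
    "DEFAULT_NONLEMON_MATRIX",
    "DEFAULT_LEMON_SEVERITY",
    "DEFAULT_COSTS",
]


class Phase(IntEnum):
    """Development phases; SOLD and FAILED are absorbing."""

    PRECLINICAL = 0
    PHASE1 = 1
    SOLD = 2
    FAILED = 3


N_PHASES = 4
TRANSIENT = (Phase.PRECLINICAL, Phase.PHASE1)
_ADVANCE_OF = {Phase.PRECLINICAL: Phase.PHASE1, Phase.PHASE1: Phase.SOLD}


@dataclass(frozen=True)
class TransitionMatrix:
    """A per-semester row-stochastic matrix over the four phases."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_PHASES, N_PHASES):
            raise ValueError(f"transition matrix must be {N_PHASES}x{N_PHASES}, got {p.shape}")
        if np.any(p < -1e-12):
            raise ValueError("transition probabilities must be non-negative")
        rowsums = p.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValueError(f"rows must sum to 1, got sums {rowsums}")
        for absorbing in (Phase.SOLD, Phase.FAILED):
            expected = np.zeros(N_PHASES)
            expected[absorbing] = 1.0
            if not np.allclose(p[absorbing], expected, atol=1e-12):
                raise ValueError(f"row {absorbing.name} must be absorbing")

    @classmethod
    def from_rates(
        cls,
        preclinical_advance: float,
        preclinical_fail: float,
        phase1_advance: float,
        phase1_fail: float,
    ) -> "TransitionMatrix":
        """Build from per-semester advance/failure rates; the remainder stays put."""
        m = np.zeros((N_PHASES, N_PHASES))
        for phase, adv, fail in (
            (Phase.PRECLINICAL, preclinical_advance, preclinical_fail),
            (Phase.PHASE1, phase1_advance, phase1_fail),
        ):
            stay = 1.0 - adv - fail
            if stay < -1e-12:
                raise ValueError(f"advance + fail > 1 in phase {phase.name}")
            m[phase, _ADVANCE_OF[phase]] = adv
            m[phase, Phase.FAILED] = fail
            m[phase, phase] = max(stay, 0.0)
        m[Phase.SOLD, Phase.SOLD] = 1.0
        m[Phase.FAILED, Phase.FAILED] = 1.0
        return cls(m)

    def advance_prob(self, phase: Phase) -> float:
        return float(self.probs[phase, _ADVANCE_OF[phase]])

    def fail_prob(self, phase: Phase) -> float:
        return float(self.probs[phase, Phase.FAILED])

    def with_advance_uplift(self, factor: float) -> "TransitionMatrix":
        """Multiply advance probabilities by ``factor``, reducing the stay
        probability to keep rows stochastic (validation improves the odds
        of well-characterized programs)."""
        if factor < 0:
            raise ValueError("uplift factor must be non-negative")
        m = self.probs.copy()
        for phase in TRANSIENT:
            adv_old = m[phase, _ADVANCE_OF[phase]]
            delta = adv_old * (factor - 1.0)
            stay = m[phase, phase] - delta
            if stay < -1e-12:
                raise ValueError(f"uplift factor {factor} overflows row {phase.name}")
            m[phase, _ADVANCE_OF[phase]] = adv_old * factor
            m[phase, phase] = max(stay, 0.0)
        return TransitionMatrix(m)


# Default non-lemon chain: P(Sold within 12 semesters) ~ 0.10.
DEFAULT_NONLEMON_MATRIX = TransitionMatrix.from_rates(
    preclinical_advance=0.12,
    preclinical_fail=0.22,
    phase1_advance=0.10,
    phase1_fail=0.22,
)

DEFAULT_LEMON_SEVERITY = 2.0


def build_lemon_matrix(
    base: TransitionMatrix, severity: float = DEFAULT_LEMON_SEVERITY
) -> TransitionMatrix:
    """Derive the lemon chain from the non-lemon chain.

    For transient phase index ``i`` (0 = Preclinical, 1 = PhaseI):

        advance' = advance / severity
        fail'    = fail * (1 + (severity - 1) * (1 + i))

    so the failure inflation grows strictly with the phase reached, and
    ``severity = 1`` returns the base matrix unchanged.  Rows are kept
    stochastic by adjusting the stay probability; a severity pushing any
    row past probability 1 is an error.
    """
    if severity < 1.0:
        raise ValueError(f"severity must be >= 1, got {severity}")
    m = base.probs.copy()
    for i, phase in enumerate(TRANSIENT):
        adv_old = m[phase, _ADVANCE_OF[phase]]
        fail_old = m[phase, Phase.FAILED]
        adv = adv_old / severity
        fail = fail_old * (1.0 + (severity - 1.0) * (1.0 + i))
        stay = m[phase, phase] + (adv_old - adv) - (fail - fail_old)
        if stay < -1e-12:
            raise ValueError(
                f"severity {severity} makes phase {phase.name} probabilities exceed 1"
            )
        m[phase, _ADVANCE_OF[phase]] = adv
        m[phase, Phase.FAILED] = fail
        m[phase, phase] = max(stay, 0.0)
    return TransitionMatrix(m)


@dataclass(frozen=True)
class CostSchedule:
    """Cash flows attached to one program (millions).

    ``upfront`` is paid at funding; ``periodic`` accrues each semester a
    program spends in a transient phase; ``milestone`` is paid to the
    developers on each phase advance; ``sale_value`` is realized the
    moment the program reaches ``Sold``.  The numeric defaults are
    calibration placeholders sized so a 0.2-per-program capital base
    covers screening, upfronts and running costs over the horizon.
    """

    upfront: float = 0.1
    periodic: dict[Phase, float] = field(
        default_factory=lambda: {Phase.PRECLINICAL: 0.005, Phase.PHASE1: 0.01}
    )
    milestone: dict[Phase, float] = field(
        default_factory=lambda: {Phase.PHASE1: 0.02, Phase.SOLD: 0.05}
    )
    sale_value: float = 12.3

    def __post_init__(self) -> None:
        values = [self.upfront, self.sale_value, *self.periodic.values(), *self.milestone.values()]
        if any(v < 0 for v in values):
            raise ValueError("all cost-schedule amounts must be non-negative")

    def periodic_cost(self, phase: Phase) -> float:
        return self.periodic.get(phase, 0.0)

    def milestone_payment(self, phase: Phase) -> float:
        return self.milestone.get(phase, 0.0)


DEFAULT_COSTS = CostSchedule()


@dataclass(frozen=True)
class Asset:
    """One drug-development program and its running account."""

    id: int
    is_lemon: bool
    detected_as_lemon: bool = False
    phase: Phase = Phase.PRECLINICAL
    cumulative_cost: float = 0.0
    realized_value: float = 0.0

    def __post_init__(self) -> None:
        if self.realized_value > 0 and self.phase is not Phase.SOLD:
            raise ValueError("realized_value requires phase SOLD")


def step_asset(
    asset: Asset,
    lemon_matrix: TransitionMatrix,
    nonlemon_matrix: TransitionMatrix,
    costs: CostSchedule,
    rng: np.random.Generator,
) -> Asset:
    """Advance one asset by one semester.

    Accrues the periodic cost of the phase the asset occupies, samples the
    next phase from its type's matrix, adds the milestone payment on an
    advance, and books the sale value on reaching ``Sold``.  Absorbing
    assets are returned unchanged.
    """
    if asset.phase in (Phase.SOLD, Phase.FAILED):
        return asset
    matrix = lemon_matrix if asset.is_lemon else nonlemon_matrix
    cost = costs.periodic_cost(asset.phase)
    new_phase = Phase(rng.choice(N_PHASES, p=matrix.probs[asset.phase]))
    realized = asset.realized_value
    if new_phase != asset.phase and new_phase is not Phase.FAILED:
        cost += costs.milestone_payment(new_phase)
        if new_phase is Phase.SOLD:
            realized = costs.sale_value
    return replace(
        asset,
        phase=new_phase,
        cumulative_cost=asset.cumulative_cost + cost,
        realized_value=realized,
    )


def absorption_probabilities(
    matrix: TransitionMatrix, horizon: int, start: Phase = Phase.PRECLINICAL
) -> np.ndarray:
    """Exact phase distribution after ``horizon`` semesters from ``start``.

    Serves as the closed-form oracle for the sampled dynamics: repeated
    application of the transition matrix to a point mass.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    dist = np.zeros(N_PHASES)
    dist[start] = 1.0
    return dist @ np.linalg.matrix_power(matrix.probs, horizon)
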