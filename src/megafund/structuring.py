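"""SPV construction, fund behavior and validation-driven lemon detection.

A fund starts from a pool of assets (by default 200, half of them
lemons).  Spending a fraction ``v`` of total investment on in silico /
in vitro validation detects each lemon independently with probability

    p_detection(v) = 1 - exp(-10 v)

(zero without validation, ~95 % at v = 0.30).  The three fund behaviors
then differ in what they do with the flags:

* **ideal** — every lemon is removed before funding, whatever ``v``;
* **reliable** — detected lemons are removed, the rest of the pool is
  spread randomly across SPVs;
* **unfair** — nothing is removed; detected lemons are deliberately
  concentrated into a quarter of the SPVs (the *toxic* SPVs), whose
  senior tranches are then sold to uninformed investors.

``M = N/4`` SPVs of ``D = N/2`` assets each are built from the ``N``
funded assets, under the single hard constraint that every asset belongs
to at least one SPV.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FundBehavior",
    "ValidationPolicy",
    "SPVStructure",
    "detect_lemons",
    "apply_behavior",
    "build_spvs",
]


class FundBehavior(str, Enum):
    IDEAL = "ideal"
    RELIABLE = "reliable"
    UNFAIR = "unfair"


@dataclass(frozen=True)
class ValidationPolicy:
    """Validation spending and the detection model it buys.

    ``detection_scale`` is the exponential rate of the detection curve
    (10 by default, so that 30 % validation detects ~95 % of lemons).
    ``false_positive_rate`` is the per-non-lemon probability of a
    spurious flag; the default is 0 (validation errs only by omission).
    """

    validation_fraction: float = 0.0
    detection_scale: float = 10.0
    false_positive_rate: float = 0.0

    def __post_init__(self) -> None:
        v = self.validation_fraction
        if not (0.0 <= v < 1.0):
            raise ValueError(f"validation_fraction must be in [0, 1), got {v}")
        if not (0.0 <= self.false_positive_rate <= 1.0):
            raise ValueError("false_positive_rate must be in [0, 1]")
        if self.detection_scale <= 0:
            raise ValueError("detection_scale must be > 0")

    @property
    def detection_probability(self) -> float:
        """p_detection = 1 - exp(-scale * v)."""
        return 1.0 - math.exp(-self.detection_scale * self.validation_fraction)


def detect_lemons(
    is_lemon: np.ndarray, policy: ValidationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Flag each true lemon independently with probability p_detection(v).

    Non-lemons are flagged only at the configured false-positive rate
    (0 by default).  Returns a boolean array aligned with ``is_lemon``.
    """
    is_lemon = np.asarray(is_lemon, dtype=bool)
    u = rng.random(is_lemon.shape)
    q = policy.detection_probability
    flags = np.where(is_lemon, u < q, u < policy.false_positive_rate)
    return flags


def apply_behavior(
    is_lemon: np.ndarray,
    flags: np.ndarray,
    behavior: FundBehavior,
) -> np.ndarray:
    """Decide which assets the fund actually funds.

    Returns a boolean *funded* mask over the pool: the ideal fund drops
    every lemon (flagged or not), the reliable fund drops flagged assets,
    the unfair fund funds everything and keeps the flags for structuring.
    """
    is_lemon = np.asarray(is_lemon, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    behavior = FundBehavior(behavior)
    if behavior is FundBehavior.IDEAL:
        return ~is_lemon
    if behavior is FundBehavior.RELIABLE:
        return ~flags
    return np.ones_like(is_lemon)


@dataclass(frozen=True)
class SPVStructure:
    """Asset-to-SPV membership with toxic designation.

    ``membership`` is an (M, N) boolean matrix over the *funded* assets;
    ``toxic`` marks the SPVs an unfair manager packs with detected
    lemons.
    """

    membership: np.ndarray
    toxic: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        t = np.asarray(self.toxic, dtype=bool)
        object.__setattr__(self, "membership", m)
        object.__setattr__(self, "toxic", t)
        if m.ndim != 2 or t.shape != (m.shape[0],):
            raise ValueError("membership must be (M, N) with one toxic flag per SPV")
        sizes = m.sum(axis=1)
        if len(set(sizes.tolist())) > 1:
            raise ValueError(f"all SPVs must have equal size, got {sorted(set(sizes))}")
        if m.shape[0] and np.any(m.sum(axis=0) == 0):
            raise ValueError("every asset must belong to at least one SPV")

    @property
    def n_spvs(self) -> int:
        return self.membership.shape[0]

    @property
    def spv_size(self) -> int:
        return int(self.membership[0].sum()) if self.n_spvs else 0

    @property
    def membership_counts(self) -> np.ndarray:
        """How many SPVs hold each asset (>= 1 by construction)."""
        return self.membership.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Audit dump: one row per asset with its SPV ids."""
        rows = []
        for asset in range(self.membership.shape[1]):
            spvs = np.flatnonzero(self.membership[:, asset])
            rows.append(
                {
                    "asset_id": asset,
                    "spv_ids": ";".join(map(str, spvs)),
                    "n_spvs": len(spvs),
                    "in_toxic_spv": bool(self.toxic[spvs].any()),
                }
            )
        return pd.DataFrame(rows)


def _sample_members(
    n_assets: int, size: int, preferred: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Choose ``size`` distinct assets, exhausting ``preferred`` ids first."""
    if preferred is None or len(preferred) == 0:
        return rng.choice(n_assets, size=size, replace=False)
    preferred = np.asarray(preferred)
    if len(preferred) >= size:
        return rng.choice(preferred, size=size, replace=False)
    others = np.setdiff1d(np.arange(n_assets), preferred, assume_unique=False)
    fill = rng.choice(others, size=size - len(preferred), replace=False)
    return np.concatenate([preferred, fill])


def build_spvs(
    n_assets: int,
    flags: np.ndarray,
    behavior: FundBehavior,
    rng: np.random.Generator,
    toxic_fraction: float = 0.25,
    n_spvs: int | None = None,
    spv_size: int | None = None,
) -> SPVStructure:
    """Build M = N/4 SPVs of D = N/2 assets each from the funded pool.

    Every SPV samples its members uniformly without replacement; an
    asset left out of all SPVs is repaired into a random SPV by swapping
    out a multiply-held member, so coverage is guaranteed.  Under unfair
    behavior, floor(toxic_fraction * M) SPVs are toxic: they are filled
    with flagged lemons first, while the remaining SPVs draw from the
    unflagged assets when enough exist.

    ``flags`` is the detection mask over the funded assets (all False
    for ideal/reliable funds, whose flagged assets were already removed).
    ``n_spvs`` / ``spv_size`` override the N/4 and N/2 rules, e.g. to
    reproduce a single-SPV fund holding every asset.
    """
    flags = np.asarray(flags, dtype=bool)
    behavior = FundBehavior(behavior)
    if flags.shape != (n_assets,):
        raise ValueError("flags must have one entry per funded asset")
    if n_spvs is None and n_assets % 4:
        # routine for reliable funds with partial detection; warn once
        warnings.warn(
            "funded asset count not divisible by 4; flooring M = N // 4",
            RuntimeWarning,
            stacklevel=2,
        )
    M = n_spvs if n_spvs is not None else n_assets // 4
    D = spv_size if spv_size is not None else n_assets // 2
    if M < 1 or D < 1:
        raise ValueError(f"pool of {n_assets} assets is too small to structure")
    if D > n_assets:
        raise ValueError("SPV size exceeds asset count")

    toxic = np.zeros(M, dtype=bool)
    if behavior is FundBehavior.UNFAIR:
        toxic[: int(toxic_fraction * M)] = True

    flagged_ids = np.flatnonzero(flags)
    unflagged_ids = np.flatnonzero(~flags)
    membership = np.zeros((M, n_assets), dtype=bool)
    for j in range(M):
        if toxic[j]:
            members = _sample_members(n_assets, D, flagged_ids, rng)
        elif behavior is FundBehavior.UNFAIR and len(unflagged_ids) >= D:
            members = rng.choice(unflagged_ids, size=D, replace=False)
        else:
            members = rng.choice(n_assets, size=D, replace=False)
        membership[j, members] = True

    # Coverage repair: swap uncovered assets over multiply-held ones.
    counts = membership.sum(axis=0)
    for asset in np.flatnonzero(counts == 0):
        j = rng.integers(M)
        held = np.flatnonzero(membership[j] & (membership.sum(axis=0) > 1))
        if len(held) == 0:  # pragma: no cover - needs every member singly held
            j = int(np.argmax((membership & (membership.sum(axis=0) > 1)).sum(axis=1)))
            held = np.flatnonzero(membership[j] & (membership.sum(axis=0) > 1))
        out = rng.choice(held)
        membership[j, out] = False
        membership[j, asset] = True

    return SPVStructure(membership=membership, toxic=toxic)
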