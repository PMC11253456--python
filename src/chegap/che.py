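"""Catastrophic health expenditure (CHE) measurement.

A household's annual health expenditure is the sum of direct medical costs,
direct non-medical costs (transport, cafeteria, lodging) and indirect costs
valued by the human-capital approach (lost days x daily valuation).  The
household is flagged catastrophic when the health share of its budget
strictly exceeds a threshold; the budget denominator is, by default, total
household expenditure with health spending included (budget-share
convention), with non-food and health-exclusive variants available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .survey import ExpenditureProfile, HouseholdRecord

__all__ = [
    "CheResult",
    "HeadcountResult",
    "UndefinedShareError",
    "annual_health_expenditure",
    "che_flag",
    "che_headcount",
]

THRESHOLD_RANGE = (0.10, 0.40)


class UndefinedShareError(ValueError):
    """The budget denominator is zero; the expenditure share is undefined."""


def annual_health_expenditure(profile: ExpenditureProfile) -> float:
    """Direct medical + direct non-medical + lost_days x daily_valuation."""
    return (
        profile.direct_medical
        + profile.direct_nonmedical
        + profile.lost_days * profile.daily_valuation
    )


def _denominator(
    profile: ExpenditureProfile, kind: str, include_health: bool
) -> float:
    health = annual_health_expenditure(profile)
    total = profile.food + profile.nonfood_nonhealth + (health if include_health else 0.0)
    if kind == "total":
        return total
    if kind == "nonfood":
        return total - profile.food
    raise ValueError(f"denominator_kind must be 'total' or 'nonfood', got {kind!r}")


@dataclass(frozen=True)
class CheResult:
    """Health-expenditure share and catastrophic flag for one household."""

    health_expenditure: float
    denominator_expenditure: float
    share: float
    threshold: float
    denominator_kind: str
    catastrophic: bool


def che_flag(
    profile: ExpenditureProfile,
    threshold: float = 0.10,
    denominator_kind: str = "total",
    include_health: bool = True,
) -> CheResult:
    """Flag one household's expenditure profile at a given threshold.

    The catastrophic flag uses strict inequality (share > threshold): a
    share exactly at the threshold does not count.  Thresholds outside the
    conventional 10-40% band are refused.
    """
    lo, hi = THRESHOLD_RANGE
    if not lo <= threshold <= hi:
        raise ValueError(f"threshold must lie in [{lo}, {hi}], got {threshold}")
    health = annual_health_expenditure(profile)
    denom = _denominator(profile, denominator_kind, include_health)
    if denom <= 0.0:
        raise UndefinedShareError(
            f"denominator ({denominator_kind}) is {denom}; share undefined"
        )
    share = health / denom
    return CheResult(
        health_expenditure=health,
        denominator_expenditure=denom,
        share=share,
        threshold=threshold,
        denominator_kind=denominator_kind,
        catastrophic=share > threshold,
    )


@dataclass(frozen=True)
class HeadcountResult:
    """CHE headcount for a collection, optionally within one insurance stratum.

    ``proportion`` is flagged/denominator for the counted population.  When a
    stratum is requested both conventions are reported: the within-stratum
    incidence (flagged / stratum size) and the share-of-total incidence
    (flagged / full analytic sample) — published tables frequently print the
    latter.
    """

    count: int
    n: int
    proportion: float
    stratum: str | None = None
    n_stratum: int | None = None
    within_stratum_proportion: float | None = None
    share_of_total_proportion: float | None = None
    n_excluded: int = 0


def che_headcount(
    records: Sequence[HouseholdRecord],
    threshold: float = 0.10,
    denominator_kind: str = "total",
    include_health: bool = True,
    stratum: str | None = None,
) -> HeadcountResult:
    """Count catastrophic households at a threshold, optionally by stratum.

    Households with a zero budget denominator are excluded and counted in
    ``n_excluded``.  Raises on an empty collection (after exclusions).
    """
    flags: list[tuple[str, bool]] = []
    n_excluded = 0
    for rec in records:
        try:
            res = che_flag(rec.expenditure, threshold, denominator_kind, include_health)
        except UndefinedShareError:
            n_excluded += 1
            continue
        flags.append((rec.insurance, res.catastrophic))
    if not flags:
        raise ValueError("no households with a defined expenditure share")
    n_total = len(flags)
    if stratum is None:
        count = sum(f for _, f in flags)
        return HeadcountResult(
            count=count, n=n_total, proportion=count / n_total, n_excluded=n_excluded
        )
    in_stratum = [f for s, f in flags if s == stratum]
    if not in_stratum:
        raise ValueError(f"no households in stratum {stratum!r}")
    count = sum(in_stratum)
    return HeadcountResult(
        count=count,
        n=n_total,
        proportion=count / n_total,
        stratum=stratum,
        n_stratum=len(in_stratum),
        within_stratum_proportion=count / len(in_stratum),
        share_of_total_proportion=count / n_total,
        n_excluded=n_excluded,
    )


def che_flags(
    records: Iterable[HouseholdRecord],
    threshold: float = 0.10,
    denominator_kind: str = "total",
    include_health: bool = True,
) -> list[CheResult]:
    """Per-household CHE results in record order (zero denominators raise)."""
    return [
        che_flag(r.expenditure, threshold, denominator_kind, include_health)
        for r in records
    ]
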