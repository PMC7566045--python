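"""Age-specific fertility: TFR, terminal-age extension, births, NRR, CCF50.

ASFR is stored per 5-year maternal age group from 10-14 through 50-54
(nine groups), in births per woman-year.  TFR = 5 * sum(ASFR).  The sex
ratio at birth (SRB) is male births per female birth; the female share of
births is 1/(1+SRB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .lifetable import LifeTable

__all__ = [
    "MATERNAL_AGE_STARTS",
    "FertilitySchedule",
    "CohortFertility",
    "tfr_from_asfr",
    "extend_terminal_asfr",
    "births_from_schedule",
    "nrr_and_replacement",
    "ccf50",
    "second_round_fertility",
]

MATERNAL_AGE_STARTS = (10, 15, 20, 25, 30, 35, 40, 45, 50)
INTERIOR_AGE_STARTS = MATERNAL_AGE_STARTS[1:-1]  # 15 .. 45


@dataclass
class FertilitySchedule:
    """ASFR by 5-year maternal age group plus sex ratio at birth."""

    asfr: dict[int, float]
    srb: float = 1.05

    def __post_init__(self) -> None:
        if self.srb <= 0:
            raise ValueError("srb must be positive")
        for a, v in self.asfr.items():
            if v < 0:
                raise ValueError(f"negative asfr at age group {a}")
            if a not in MATERNAL_AGE_STARTS:
                raise ValueError(f"unexpected maternal age group start {a}")

    @property
    def complete(self) -> bool:
        return all(a in self.asfr for a in MATERNAL_AGE_STARTS)

    def as_array(self) -> np.ndarray:
        return np.array([self.asfr[a] for a in MATERNAL_AGE_STARTS])


def tfr_from_asfr(sched: FertilitySchedule) -> float:
    """Total fertility rate: 5 x sum of the nine 5-year-group ASFRs."""
    if not sched.complete:
        missing = [a for a in MATERNAL_AGE_STARTS if a not in sched.asfr]
        raise ValueError(f"schedule missing maternal age groups {missing}")
    return 5.0 * float(sum(sched.asfr[a] for a in MATERNAL_AGE_STARTS))


def extend_terminal_asfr(
    asfr_interior: dict[int, float], r10: float = 0.03, r50: float = 0.02, srb: float = 1.05
) -> FertilitySchedule:
    """Extend an interior (15-49) schedule to the 10-14 and 50-54 groups.

    The terminal groups are fixed ratios of the adjacent interior groups:
    asfr(10-14) = r10 * asfr(15-19) and asfr(50-54) = r50 * asfr(45-49).
    """
    if r10 < 0 or r50 < 0:
        raise ValueError("extension ratios must be non-negative")
    missing = [a for a in INTERIOR_AGE_STARTS if a not in asfr_interior]
    if missing:
        raise ValueError(f"interior schedule missing age groups {missing}")
    full = {a: float(asfr_interior[a]) for a in INTERIOR_AGE_STARTS}
    full[10] = r10 * full[15]
    full[50] = r50 * full[45]
    return FertilitySchedule(asfr=full, srb=srb)


def births_from_schedule(
    sched: FertilitySchedule, female_pop: dict[int, float]
) -> dict[str, float]:
    """Births implied by a schedule applied to female person-years by age group."""
    if any(v < 0 for v in female_pop.values()):
        raise ValueError("female populations must be non-negative")
    total = float(sum(sched.asfr.get(a, 0.0) * female_pop.get(a, 0.0) for a in MATERNAL_AGE_STARTS))
    female_share = 1.0 / (1.0 + sched.srb)
    return {
        "total": total,
        "female": total * female_share,
        "male": total * (1.0 - female_share),
    }


def _nrr(sched: FertilitySchedule, female_lt: LifeTable) -> float:
    """NRR = (1/(1+srb)) * sum_a asfr_a * (nLa / l0) over maternal groups."""
    l0 = female_lt.lx[0]
    total = 0.0
    for a in MATERNAL_AGE_STARTS:
        asfr = sched.asfr.get(a, 0.0)
        if asfr == 0.0:
            continue
        i = female_lt.grid.index_of(float(a))
        total += asfr * female_lt.Lx[i] / l0
    return total / (1.0 + sched.srb)


def nrr_and_replacement(sched: FertilitySchedule, female_lt: LifeTable) -> dict[str, float]:
    """Net reproduction rate and the replacement-level TFR at fixed shape.

    Replacement TFR is the TFR at which a uniformly rescaled schedule gives
    NRR = 1; because NRR is linear in the scale it equals TFR/NRR.
    """
    for a in (10.0, 50.0):
        if not female_lt.grid.contains_boundary(a):
            raise ValueError("female life table must cover maternal ages 10-54")
    nrr = _nrr(sched, female_lt)
    if nrr <= 0:
        raise ValueError("NRR is zero; replacement TFR undefined")
    tfr = tfr_from_asfr(sched) if sched.complete else 5.0 * float(sum(sched.asfr.values()))
    return {"NRR": nrr, "replacement_TFR": tfr / nrr}


def replacement_tfr_by_root(sched: FertilitySchedule, female_lt: LifeTable) -> float:
    """Replacement TFR found by root-finding on a scaled schedule (oracle path)."""
    tfr = tfr_from_asfr(sched)

    def g(scale: float) -> float:
        scaled = FertilitySchedule(
            asfr={a: v * scale for a, v in sched.asfr.items()}, srb=sched.srb
        )
        return _nrr(scaled, female_lt) - 1.0

    scale = brentq(g, 1e-9, 1e6, xtol=1e-14, rtol=1e-14)
    return tfr * scale


@dataclass
class CohortFertility:
    """Cumulative fertility of one female birth cohort by exact age."""

    birth_cohort: int
    cumulative_asfr: dict[float, float] = field(default_factory=dict)
    ccf50: float = float("nan")


def ccf50(cohort_asfr: dict[float, float], widths: dict[float, float] | None = None) -> float:
    """Completed cohort fertility by age 50: sum of width x asfr over 15-49.

    ``cohort_asfr`` maps age (single-year starts, or 5-year group starts
    when ``widths`` gives 5) to the cohort's ASFR at that age.  Coverage of
    ages 15-49 must be complete; extra 10-14 / 50-54 entries are included.
    """
    if widths is None:
        widths = {a: 1.0 for a in cohort_asfr}
    covered = np.zeros(60 - 10)
    total = 0.0
    for a, rate in cohort_asfr.items():
        w = widths[a]
        if rate < 0:
            raise ValueError("cohort asfr must be non-negative")
        total += w * rate
        lo, hi = int(round(a)) - 10, int(round(a + w)) - 10
        covered[max(lo, 0) : min(hi, len(covered))] += 1
    required = covered[15 - 10 : 50 - 10]
    if np.any(required < 1):
        missing = [i + 15 for i, c in enumerate(required) if c < 1]
        raise ValueError(f"incomplete cohort coverage at ages {missing}")
    return total


def second_round_fertility(
    pattern: FertilitySchedule,
    observed_total_births: float,
    female_pop: dict[int, float],
    variance_multiplier: float = 4.0,
    reference_variance: float = 1e-4,
) -> dict[int, tuple[float, float]]:
    """Split an observed total-births count into pseudo-ASFR observations.

    The total is allocated proportionally to the first-round age pattern of
    expected births; each pseudo-observation carries an inflated variance
    (``variance_multiplier`` x the reference-source variance) reflecting
    the indirect nature of total-birth sources.  Returns
    {age_group: (pseudo_asfr, variance)}.
    """
    expected = {
        a: pattern.asfr.get(a, 0.0) * female_pop.get(a, 0.0) for a in MATERNAL_AGE_STARTS
    }
    tot_expected = sum(expected.values())
    if tot_expected <= 0:
        if observed_total_births > 0:
            raise ValueError("first-round pattern implies zero births but total observed > 0")
        return {a: (0.0, variance_multiplier * reference_variance) for a in MATERNAL_AGE_STARTS}
    scale = observed_total_births / tot_expected
    out = {}
    for a in MATERNAL_AGE_STARTS:
        if female_pop.get(a, 0.0) > 0:
            out[a] = (
                pattern.asfr.get(a, 0.0) * scale,
                variance_multiplier * reference_variance,
            )
    return out
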