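"""Relational model life tables, old-age extension, shocks and HIV assembly.

The relational system maps a standard survival schedule into a full life
table matching target child (5q0) and adult (45q15) mortality through the
Brass-type logit transform Y(x) = logit(1 - lx/l0) with
Y = alpha + beta * Y_standard.  Standards come from a compact synthetic
library of parametric (Heligman-Pollard-style) schedules spanning the
observed range of child and adult mortality; nearest standards in
(logit 5q0, logit 45q15) space are pooled by inverse-distance weighting.

Old-age rates above 90 are extended with a logistic (Kannisto) hazard fit
on ages 60-89: logit(mx) is linear in age, so the fit is a weighted linear
regression and the extension is bounded above by 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .ages import AgeGrid, build_age_grid, GBD23
from .lifetable import LifeTable, lifetable_from_qx

__all__ = [
    "Standard",
    "StandardLibrary",
    "RelationalCoefficients",
    "ShockEvent",
    "make_standard_library",
    "select_standard",
    "fit_relational",
    "extend_old_age",
    "disaggregate_shock",
    "assemble_all_cause",
]


@dataclass
class Standard:
    """One standard life table: an lx schedule on the gbd23 grid."""

    id: str
    sex: str
    lx: np.ndarray  # radix 1.0
    grid: AgeGrid
    q5: float = field(init=False)
    q45_15: float = field(init=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError(f"standard {self.id}: lx not monotone")
        i5 = self.grid.index_of(5.0)
        i15 = self.grid.index_of(15.0)
        i60 = self.grid.index_of(60.0)
        self.q5 = 1.0 - self.lx[i5] / self.lx[0]
        self.q45_15 = 1.0 - self.lx[i60] / self.lx[i15]

    def logit_survival(self) -> np.ndarray:
        """Y(x) = logit(1 - lx/l0) for interior boundaries (x > 0)."""
        s = np.clip(self.lx[1:] / self.lx[0], 1e-12, 1 - 1e-12)
        return logit(1.0 - s)


@dataclass
class StandardLibrary:
    standards: list[Standard]

    def __post_init__(self) -> None:
        if not self.standards:
            raise ValueError("empty standard library")

    def __len__(self) -> int:
        return len(self.standards)


def _hp_hazard(x: np.ndarray, a: float, b: float, c: float, d: float, g: float, h: float) -> np.ndarray:
    """Heligman-Pollard-style hazard: child + background + senescent terms.

    The child term decays steeply with age so that the infant share of
    under-5 deaths matches observed patterns (hazard at age 2 is roughly a
    tenth of the infant hazard).
    """
    child = a * np.exp(-b * (x + 0.02) ** c)
    background = d
    senescent = g * np.exp(h * x)
    mu = child + background + senescent / (1.0 + senescent)
    return mu


def make_standard_library(
    n: int = 25, grid: AgeGrid | None = None, sexes: Sequence[str] = ("female", "male")
) -> StandardLibrary:
    """Synthetic standard library spanning 5q0 in [0.003, 0.25], 45q15 in [0.05, 0.6].

    Parameter paths are deterministic: child-mortality levels on a log grid
    with adult levels varied against them, so that the (5q0, 45q15) cloud
    covers the plausible plane rather than a single curve.  Shapes pass the
    vetting checks: hazards monotone above age 30, bounded infant/adult
    ratio.
    """
    if grid is None:
        grid = build_age_grid(GBD23)
    bounds = grid.boundaries
    mids = np.array(
        [s + (w if not np.isnan(w) else 10.0) / 2 for s, w in zip(grid.starts, grid.widths)]
    )
    standards = []
    levels = np.linspace(0.0, 1.0, n)
    for i, u in enumerate(levels):
        # child level: log-spaced from very low to very high mortality
        a = np.exp(np.log(0.009) + u * (np.log(1.5) - np.log(0.009)))
        # adult senescent level: anti-correlated wobble to decouple 45q15 from 5q0
        wob = 0.5 + 0.9 * ((i * 7) % n) / max(n - 1, 1)
        g = 2.2e-5 * np.exp(2.2 * u) * wob
        d = 0.0004 + 0.004 * u * wob
        for sex in sexes:
            mult = 1.0 if sex == "male" else 0.82
            mu = _hp_hazard(mids, a, 2.6, 0.5, d * mult, g * mult, 0.105)
            # integrate piecewise-constant hazard over intervals to get lx
            widths = grid.closed_widths
            H = np.concatenate([[0.0], np.cumsum(mu[:-1] * widths[:-1])])
            lx = np.exp(-H)
            standards.append(Standard(id=f"std_{i:02d}_{sex}", sex=sex, lx=lx, grid=grid))
    return StandardLibrary(standards=standards)


def vet_standard(std: Standard) -> bool:
    """Deterministic shape checks replacing manual vetting of standards."""
    lx = std.lx
    widths = std.grid.closed_widths
    with np.errstate(divide="ignore", invalid="ignore"):
        haz = -np.diff(np.log(np.maximum(lx, 1e-300))) / widths[:-1]
    i30 = std.grid.index_of(30.0)
    monotone_old = bool(np.all(np.diff(haz[i30:]) > -1e-9))
    infant = haz[0]
    adult = haz[std.grid.index_of(40.0)]
    ratio_ok = bool(infant / max(adult, 1e-12) < 2000)
    return monotone_old and ratio_ok


def select_standard(
    lib: StandardLibrary,
    target: dict[str, float],
    k: int = 3,
    sex: str | None = None,
) -> np.ndarray:
    """Pool the k nearest standards in (logit 5q0, logit 45q15) space.

    Returns a pooled lx schedule (radix 1) as the inverse-distance-weighted
    average of logit-survival.  An exact summary match returns that
    standard unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cands = [s for s in lib.standards if sex is None or s.sex == sex]
    if not cands:
        raise ValueError("no standards for requested sex")
    t = np.array([logit(target["5q0"]), logit(target["45q15"])])
    pts = np.array([[logit(s.q5), logit(s.q45_15)] for s in cands])
    dist = np.linalg.norm(pts - t, axis=1)
    order = np.argsort(dist)
    if dist[order[0]] < 1e-12:
        return cands[order[0]].lx.copy()
    chosen = order[: min(k, len(cands))]
    w = 1.0 / dist[chosen]
    w = w / w.sum()
    Y = np.array([cands[i].logit_survival() for i in chosen])
    pooled_Y = (w[:, None] * Y).sum(axis=0)
    lx = np.concatenate([[1.0], 1.0 - expit(pooled_Y)])
    return np.minimum.accumulate(lx)


@dataclass
class RelationalCoefficients:
    alpha: float
    beta: float
    standard_id: str = "pooled"

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive")


ALPHA_BOX = (-2.0, 2.0)
BETA_BOX = (0.3, 3.0)


def _relational_lx(standard_lx: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    Y = logit(np.clip(1.0 - standard_lx[1:] / standard_lx[0], 1e-12, 1 - 1e-12))
    lx = np.concatenate([[1.0], 1.0 - expit(alpha + beta * Y)])
    return np.minimum.accumulate(lx)


def _summaries_from_lx(lx: np.ndarray, grid: AgeGrid) -> tuple[float, float]:
    i5, i15, i60 = grid.index_of(5.0), grid.index_of(15.0), grid.index_of(60.0)
    return 1.0 - lx[i5] / lx[0], 1.0 - lx[i60] / lx[i15]


def fit_relational(
    standard_lx: np.ndarray,
    targets: dict[str, float],
    grid: AgeGrid | None = None,
    tol: float = 1e-10,
) -> tuple[RelationalCoefficients, LifeTable]:
    """Solve for (alpha, beta) matching target 5q0 and 45q15, build the table.

    Two-dimensional root finding (Levenberg-Marquardt-safeguarded least
    squares within the alpha/beta box); the returned life table reproduces
    both targets to 1e-8.
    """
    if grid is None:
        grid = build_age_grid(GBD23)
    t5, t45 = targets["5q0"], targets["45q15"]
    if not (0 < t5 < 1 and 0 < t45 < 1):
        raise ValueError("targets must lie in (0,1)")

    from scipy.optimize import brentq

    i5 = grid.index_of(5.0)
    Y = logit(np.clip(1.0 - standard_lx[1:] / standard_lx[0], 1e-12, 1 - 1e-12))
    Y5 = Y[i5 - 1]

    def alpha_for(beta: float) -> float:
        # 5q0 = expit(alpha + beta*Y5)  =>  alpha solved in closed form
        return float(logit(t5) - beta * Y5)

    def f(beta: float) -> float:
        a = alpha_for(beta)
        _, q45 = _summaries_from_lx(_relational_lx(standard_lx, a, beta), grid)
        return logit(np.clip(q45, 1e-12, 1 - 1e-12)) - logit(t45)

    lo, hi = BETA_BOX
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no (alpha, beta) in the search box reproduces the targets "
            f"(f({lo})={flo:.3g}, f({hi})={fhi:.3g})"
        )
    beta = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    alpha = alpha_for(beta)
    if not (ALPHA_BOX[0] - 1e-9 <= alpha <= ALPHA_BOX[1] + 1e-9):
        raise ValueError(f"alpha {alpha:.4g} outside the search box")
    q5, q45 = _summaries_from_lx(_relational_lx(standard_lx, alpha, beta), grid)
    if abs(q5 - t5) > 1e-8 or abs(q45 - t45) > 1e-8:
        raise ValueError(
            f"relational fit failed to reproduce targets "
            f"(achieved 5q0={q5:.6g}, 45q15={q45:.6g})"
        )
    coef = RelationalCoefficients(alpha=float(alpha), beta=float(beta))
    lx = _relational_lx(standard_lx, coef.alpha, coef.beta)
    qx = np.empty(grid.n)
    qx[:-1] = 1.0 - lx[1:] / np.maximum(lx[:-1], 1e-300)
    qx[-1] = 1.0
    lt = lifetable_from_qx(np.clip(qx, 0.0, 1 - 1e-12), grid)
    return coef, lt


def extend_old_age(
    mx_60_89: np.ndarray | dict[float, float],
) -> dict[str, float]:
    """Extend old-age mortality to 90-94 and 95+ with a Kannisto hazard.

    Fits logit(mx) = log(A) + B*x on the 5-year groups 60-64 ... 85-89
    (interval midpoints), then evaluates the logistic hazard at 92.5 for
    90-94 and at 100 for the open 95+ group (the approximate mean age at
    death there).  The extension is non-decreasing and bounded by 1.
    """
    if isinstance(mx_60_89, dict):
        ages = np.array(sorted(mx_60_89), dtype=float)
        mx = np.array([mx_60_89[a] for a in ages])
    else:
        mx = np.asarray(mx_60_89, dtype=float)
        ages = 60.0 + 5.0 * np.arange(len(mx))
    if len(mx) < 4:
        raise ValueError("need at least 4 age groups of input")
    if np.any(mx <= 0):
        raise ValueError("input rates must be positive")
    mids = ages + 2.5
    y = logit(np.clip(mx, 1e-12, 1 - 1e-12))
    X = np.column_stack([np.ones_like(mids), mids])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    logA, B = float(coef[0]), float(coef[1])

    def kannisto(x: float) -> float:
        return float(expit(logA + B * x))

    m90 = max(kannisto(92.5), mx[-1])
    m95 = max(kannisto(100.0), m90)
    return {"mx_90_94": m90, "mx_95_plus": m95, "logA": logA, "B": B}


@dataclass
class ShockEvent:
    """A fatal discontinuity: conflict or disaster deaths for one location-year."""

    location: str
    year: int
    cause: str
    total_deaths: float

    def __post_init__(self) -> None:
        if self.total_deaths < 0:
            raise ValueError("shock deaths must be non-negative")


def disaggregate_shock(
    event: ShockEvent,
    population: dict[tuple[str, float], float],
    pattern: dict[tuple[str, float], float],
) -> dict[tuple[str, float], float]:
    """Split an all-age both-sex shock total by a global cause age-sex pattern.

    Allocation is proportional to pattern_rate x population per (sex, age)
    cell and rescaled so the cells sum to the event total exactly.
    """
    keys = sorted(population)
    weights = np.array([pattern.get(kk, 0.0) * population[kk] for kk in keys])
    if np.any(weights < 0):
        raise ValueError("pattern rates and populations must be non-negative")
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("all-zero pattern x population; cannot allocate")
    alloc = weights / total_w * event.total_deaths
    return {kk: float(v) for kk, v in zip(keys, alloc)}


def assemble_all_cause(
    hiv_free_mx: np.ndarray,
    grid: AgeGrid,
    person_years: np.ndarray,
    hiv_mx: np.ndarray | None = None,
    shock_deaths: np.ndarray | None = None,
) -> tuple[np.ndarray, LifeTable]:
    """All-cause death envelope and recomputed life table.

    deaths = hiv_free_mx * PY + hiv_mx * PY + shock deaths per age group;
    the with-HIV with-shock life table is rebuilt from the implied mx
    (HIV enters by simple rate addition, with no competing-risk
    correction).
    """
    hiv_free_mx = np.asarray(hiv_free_mx, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    hiv = np.zeros_like(hiv_free_mx) if hiv_mx is None else np.asarray(hiv_mx, dtype=float)
    shocks = np.zeros_like(hiv_free_mx) if shock_deaths is None else np.asarray(shock_deaths, dtype=float)
    if np.any(hiv < 0) or np.any(shocks < 0) or np.any(hiv_free_mx < 0):
        raise ValueError("negative mortality components")
    deaths = hiv_free_mx * person_years + hiv * person_years + shocks
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(person_years > 0, deaths / person_years, hiv_free_mx + hiv)
    from .lifetable import lifetable_from_mx

    lt = lifetable_from_mx(mx, grid)
    return deaths, lt
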