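"""Abridged and single-year life tables, summary probabilities and crude rates.

Life tables are built from age-specific death rates ``mx`` under either the
standard Greville-type conversion ``qx = n*mx / (1 + (n - ax)*mx)`` with
mid-interval ``ax`` (Coale-Demeny-style linear functions of 1m0 below age 5),
or a piecewise-constant-hazard rule ``qx = 1 - exp(-n*mx)``.  Under the
constant-hazard rule a flat hazard mu yields e0 = 1/mu exactly, which the
test suite uses as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .ages import AgeGrid, build_age_grid, SINGLE_YEAR_0_110

__all__ = [
    "LifeTable",
    "VitalSeries",
    "lifetable_from_mx",
    "summary_probabilities",
    "abridged_to_single_year",
    "constrain_under5_detail",
    "crude_rates",
    "annualized_rate_of_change",
    "lifetable_from_qx",
]

RADIX = 100_000.0

#: Coale-Demeny-style coefficients for mean age at death in the infant (1a0)
#: and child (4a1) intervals as linear functions of 1m0 (both sexes pooled;
#: the exact convention is configurable).  Form: a + b * 1m0, capped.
DEFAULT_AX_COEFFS = {
    "1a0": {"a": 0.0467, "b": 2.875, "cutoff_m": 0.107, "high": 0.330},
    "4a1": {"a": 1.653, "b": -3.013, "cutoff_m": 0.107, "high": 1.352},
}

AxRule = Literal["midpoint+infant", "constant_hazard"]


@dataclass
class LifeTable:
    """Full life-table columns on an :class:`AgeGrid` (radix 100 000)."""

    grid: AgeGrid
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    def validate(self) -> None:
        if np.any(np.diff(self.lx) > 1e-9):
            raise ValueError("lx must be non-increasing")
        if abs(self.lx[0] - RADIX) > 1e-6:
            raise ValueError("l0 must equal the radix")
        if abs(self.qx[-1] - 1.0) > 1e-12:
            raise ValueError("terminal qx must be 1")

    def lx_at(self, age: float) -> float:
        """Survivors at an exact-age boundary of the grid."""
        return float(self.lx[self.grid.index_of(age)])

    @property
    def e0(self) -> float:
        return float(self.ex[0])

    def to_frame(self, **keys) -> pd.DataFrame:
        """Serialize to the CSV column layout (open-interval width empty)."""
        widths = ["" if np.isnan(w) else w for w in self.grid.widths]
        df = pd.DataFrame(
            {
                "age_start": self.grid.starts,
                "age_width": widths,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )
        for k, v in reversed(list(keys.items())):
            df.insert(0, k, v)
        return df


def _infant_child_ax(grid: AgeGrid, mx: np.ndarray, coeffs: Mapping | None) -> np.ndarray:
    """ax per interval: CD-style under-5 values, mid-interval elsewhere.

    The under-1 interval (or its neonatal subdivisions) uses 1a0(1m0); the
    1-4 interval uses 4a1(1m0).  Sub-year intervals (ENN/LNN/PNN) keep
    half-width ax: at day scale the decedent timing correction is
    negligible relative to the interval width.
    """
    coeffs = dict(DEFAULT_AX_COEFFS if coeffs is None else coeffs)
    widths = grid.closed_widths
    ax = widths / 2.0
    # effective 1m0: person-year-weighted mx below age 1
    sub1 = [i for i, s in enumerate(grid.starts) if s < 1.0 - 1e-9]
    m0 = float(np.average(mx[sub1], weights=widths[sub1])) if sub1 else 0.0
    for i, s in enumerate(grid.starts[:-1]):
        w = widths[i]
        if abs(s) < 1e-12 and abs(w - 1.0) < 1e-9:
            c = coeffs["1a0"]
            ax[i] = c["a"] + c["b"] * m0 if m0 < c["cutoff_m"] else c["high"]
        elif abs(s - 1.0) < 1e-9 and abs(w - 4.0) < 1e-9:
            c = coeffs["4a1"]
            ax[i] = c["a"] + c["b"] * m0 if m0 < c["cutoff_m"] else c["high"]
    return ax


def lifetable_from_mx(
    mx: np.ndarray | list,
    grid: AgeGrid | str,
    ax_rule: AxRule = "midpoint+infant",
    ax_coeffs: Mapping | None = None,
) -> LifeTable:
    """Build a life table from age-specific death rates.

    Under ``"midpoint+infant"``: ``qx = n*mx/(1 + (n-ax)*mx)`` with
    mid-interval ax above age 5 and Coale-Demeny-style infant/child ax;
    ``Lx = n*l(x+n) + ax*dx``.  Under ``"constant_hazard"``:
    ``qx = 1 - exp(-n*mx)`` and ``Lx = dx/mx`` (exact for a piecewise-flat
    hazard).  The open interval always has qx = 1 and ``Lx = lx/mx``.
    """
    if isinstance(grid, str):
        grid = build_age_grid(grid)
    mx = np.asarray(mx, dtype=float)
    if mx.shape != (grid.n,):
        raise ValueError(f"mx must have {grid.n} entries, got {mx.shape}")
    if np.any(mx < 0):
        raise ValueError("mx must be non-negative")
    if not mx[-1] > 0:
        raise ValueError("terminal mx must be positive")

    n = grid.closed_widths
    qx = np.empty(grid.n)
    if ax_rule == "constant_hazard":
        ax = np.empty(grid.n)
        qx[:-1] = 1.0 - np.exp(-n[:-1] * mx[:-1])
    elif ax_rule == "midpoint+infant":
        ax = _infant_child_ax(grid, mx, ax_coeffs)
        qx[:-1] = n[:-1] * mx[:-1] / (1.0 + (n[:-1] - ax[:-1]) * mx[:-1])
    else:
        raise ValueError(f"unknown ax rule {ax_rule!r}")
    qx[:-1] = np.clip(qx[:-1], 0.0, 1.0)
    qx[-1] = 1.0

    lx = np.empty(grid.n)
    lx[0] = RADIX
    for i in range(grid.n - 1):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = np.empty(grid.n)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]

    Lx = np.empty(grid.n)
    if ax_rule == "constant_hazard":
        with np.errstate(divide="ignore", invalid="ignore"):
            Lx[:-1] = np.where(mx[:-1] > 0, dx[:-1] / mx[:-1], n[:-1] * lx[:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            ax[:-1] = np.where(
                dx[:-1] > 0, (Lx[:-1] - n[:-1] * lx[1:]) / np.maximum(dx[:-1], 1e-300), n[:-1] / 2
            )
    else:
        Lx[:-1] = n[:-1] * lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1] if lx[-1] > 0 else 0.0
    ax[-1] = Lx[-1] / dx[-1] if dx[-1] > 0 else 0.0

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    lt = LifeTable(grid=grid, mx=mx, ax=ax, qx=qx, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex)
    lt.validate()
    return lt


def lifetable_from_qx(
    qx: np.ndarray | list,
    grid: AgeGrid,
    ax_rule: AxRule = "midpoint+infant",
    ax_coeffs: Mapping | None = None,
) -> LifeTable:
    """Build a life table from probabilities by inverting the qx formula to mx."""
    qx = np.asarray(qx, dtype=float)
    if np.any((qx[:-1] < 0) | (qx[:-1] >= 1)):
        raise ValueError("closed-interval qx must lie in [0, 1)")
    n = grid.closed_widths
    mx = np.empty(grid.n)
    if ax_rule == "constant_hazard":
        mx[:-1] = -np.log1p(-qx[:-1]) / n[:-1]
        mx[-1] = max(mx[-2], 1e-8) if grid.n > 1 else 1.0
        return lifetable_from_mx(mx, grid, ax_rule)
    # invert Greville with provisional half-width ax, then refine infant ax
    ax = n / 2.0
    for _ in range(4):
        mx[:-1] = qx[:-1] / (n[:-1] - (n[:-1] - ax[:-1]) * qx[:-1])
        mx[-1] = max(mx[-2] * 1.5, 1e-8)
        ax = _infant_child_ax(grid, mx, ax_coeffs)
        ax[-1] = 0.0
    return lifetable_from_mx(mx, grid, ax_rule, ax_coeffs)


def summary_probabilities(
    lt: LifeTable, ex_ages: tuple[float, ...] = (0.0,)
) -> dict[str, float]:
    """5q0, 45q15 and life expectancy at requested exact ages.

    Requires the grid to contain the boundaries 5, 15 and 60.
    """
    for b in (5.0, 15.0, 60.0):
        if not lt.grid.contains_boundary(b):
            raise ValueError(f"grid lacks required boundary at age {b}")
    l0, l5 = lt.lx[0], lt.lx_at(5.0)
    l15, l60 = lt.lx_at(15.0), lt.lx_at(60.0)
    out = {
        "5q0": 1.0 - l5 / l0,
        "45q15": 1.0 - l60 / l15 if l15 > 0 else 1.0,
    }
    for a in ex_ages:
        out[f"ex_{a:g}"] = float(lt.ex[lt.grid.index_of(a)])
    return out


def abridged_to_single_year(lt: LifeTable, max_age: int = 110) -> LifeTable:
    """Expand an abridged table to single years of age.

    Interior lx values are filled by monotone piecewise-cubic (PCHIP)
    interpolation of log-survival, which reproduces group-boundary lx
    exactly and preserves monotonicity; ages beyond the last closed
    boundary are extended at the open-interval hazard.
    """
    if np.any(np.diff(lt.lx) > 1e-9):
        raise ValueError("input lx must be non-increasing")
    bounds = lt.grid.boundaries
    log_l = np.log(np.maximum(lt.lx, 1e-300))
    interp = PchipInterpolator(bounds, log_l)
    last = bounds[-1]
    ages = np.arange(0, max_age + 1, dtype=float)
    log_single = np.empty(ages.shape)
    inside = ages <= last + 1e-9
    log_single[inside] = interp(ages[inside])
    m_open = lt.mx[-1]
    log_single[~inside] = interp(last) - m_open * (ages[~inside] - last)
    lx1 = np.exp(log_single)
    # per-year hazards, then rebuild under the constant-hazard rule
    haz = -(np.diff(log_single))
    haz = np.maximum(haz, 1e-12)
    mx1 = np.append(haz, max(m_open, haz[-1]))
    grid1 = build_age_grid(SINGLE_YEAR_0_110) if max_age == 110 else None
    if grid1 is None:
        starts = [(float(a), 1.0) for a in range(max_age)] + [(float(max_age), None)]
        grid1 = build_age_grid(starts)
    out = lifetable_from_mx(mx1, grid1, ax_rule="constant_hazard")
    # boundary lx are preserved by construction of the hazards
    return out


def constrain_under5_detail(
    provisional_q: np.ndarray | list, target_5q0: float
) -> np.ndarray:
    """Scale detailed under-5 probabilities to match a target 5q0.

    A single scalar k multiplies all component hazards -log(1-q_i) so that
    1 - prod(1 - q_i') equals the target.  Because the hazards share one
    scalar, k = log(1-target) / log(prod(1-q_i)) solves the root problem
    exactly; q_i' = 1 - (1-q_i)^k.
    """
    q = np.asarray(provisional_q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("provisional q must lie in [0, 1)")
    if not 0.0 <= target_5q0 < 1.0:
        raise ValueError("target 5q0 must lie in [0, 1)")
    if target_5q0 == 0.0:
        return np.zeros_like(q)
    log_surv = np.log1p(-q).sum()
    if log_surv == 0.0:
        raise ValueError("all provisional q are zero but target is positive")
    k = np.log1p(-target_5q0) / log_surv
    return 1.0 - (1.0 - q) ** k


@dataclass
class VitalSeries:
    """Tallies of person-years, deaths and births by (location, year, sex, age).

    Backed by a DataFrame with columns location, year, sex, age_start,
    person_years, deaths, births.
    """

    table: pd.DataFrame

    REQUIRED = ("location", "year", "sex", "age_start", "person_years", "deaths", "births")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"VitalSeries table missing columns {missing}")
        for c in ("person_years", "deaths", "births"):
            if (self.table[c] < 0).any():
                raise ValueError(f"negative values in {c}")


def crude_rates(vs: VitalSeries, location, year) -> dict[str, float]:
    """Crude birth/death rates and natural rate of increase, per 1000 PY."""
    sub = vs.table[(vs.table["location"] == location) & (vs.table["year"] == year)]
    py = float(sub["person_years"].sum())
    if py <= 0:
        raise ValueError(f"zero person-years for {location}, {year}")
    cbr = float(sub["births"].sum()) / py * 1000.0
    cdr = float(sub["deaths"].sum()) / py * 1000.0
    return {"CBR": cbr, "CDR": cdr, "NRI": cbr - cdr}


def annualized_rate_of_change(v_start: float, v_end: float, n_years: float) -> float:
    """Continuous (log) annualised rate of change: ln(v_end/v_start)/n."""
    if v_start <= 0 or v_end <= 0:
        raise ValueError("values must be positive")
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    return float(np.log(v_end / v_start) / n_years)
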