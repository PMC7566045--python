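"""Sullivan healthy life expectancy, SDI and expected-by-SDI outcomes.

HALE at age x is the Sullivan expectation sum_{a>=x} La*(1 - yld_a) / lx:
life-table person-years discounted by the fraction of each year lived with
disability.  SDI is the geometric mean of three min-max-scaled components
(lag-distributed income, schooling, and total fertility under age 25 —
inverted, so lower young-age fertility raises the index).

Expected outcomes given SDI use an ensemble of 50 cubic-spline
meta-regression members.  Each member has five knots on [0,1]: the two
boundaries plus three interior knots drawn in [0.1, 0.8] with pairwise
gaps of at least 0.1; the outermost segments are linear with slopes
matching the adjacent cubic pieces (a natural-spline construction on the
interior knots), so extrapolation beyond the data is linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .ages import AgeGrid
from .lifetable import LifeTable, lifetable_from_mx

__all__ = [
    "HealthStateRates",
    "SDITriple",
    "SDIBounds",
    "SplineEnsemble",
    "sullivan_hale",
    "compute_sdi",
    "fit_spline_ensemble",
    "expected_mortality_le",
    "rake_expected_fertility",
    "pearson_correlation",
]


@dataclass
class HealthStateRates:
    """YLD per capita by age group: fraction of each year lived with disability."""

    yld: np.ndarray

    def __post_init__(self) -> None:
        self.yld = np.asarray(self.yld, dtype=float)
        if np.any((self.yld < 0) | (self.yld >= 1)):
            raise ValueError("yld per capita must lie in [0, 1)")


def sullivan_hale(lt: LifeTable, yld: HealthStateRates) -> np.ndarray:
    """HALE by age: HALE(x) = sum_{a>=x} La*(1-yld_a) / lx (abridged form)."""
    if len(yld.yld) != lt.grid.n:
        raise ValueError("yld and life table grids misaligned")
    healthy_Lx = lt.Lx * (1.0 - yld.yld)
    healthy_Tx = np.cumsum(healthy_Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(lt.lx > 0, healthy_Tx / lt.lx, 0.0)


@dataclass
class SDIBounds:
    """Min-max scaling bounds for the three SDI components."""

    income: tuple[float, float] = (250.0, 60_000.0)  # worst, best (LDI per capita)
    schooling: tuple[float, float] = (0.0, 17.0)  # worst, best (years)
    tfu25: tuple[float, float] = (3.0, 0.0)  # worst, best (births per woman under 25)


@dataclass
class SDITriple:
    """Lag-distributed income per capita, mean schooling years, TFU25."""

    income: float
    schooling: float
    tfu25: float


def _scale(value: float, worst: float, best: float) -> float:
    if worst == best:
        raise ValueError("degenerate SDI component bounds")
    x = (value - worst) / (best - worst)
    return float(np.clip(x, 0.0, 1.0))


def compute_sdi(t: SDITriple, bounds: SDIBounds | None = None) -> float:
    """SDI: geometric mean of the scaled components (TFU25 inverted), in [0,1].

    Income is scaled on the log so proportional income gains count equally
    across the range.
    """
    b = bounds or SDIBounds()
    inc = _scale(np.log(max(t.income, 1e-9)), np.log(b.income[0]), np.log(b.income[1]))
    sch = _scale(t.schooling, *b.schooling)
    fer = _scale(t.tfu25, *b.tfu25)
    return float((inc * sch * fer) ** (1.0 / 3.0))


@dataclass
class SplineMember:
    knots: tuple[float, float, float]  # interior knots
    coef: np.ndarray  # [intercept, slope, gamma_1, ..., gamma_{K-2}]

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Natural (restricted) cubic spline basis: linear outside the knots."""
        x = np.asarray(x, dtype=float)
        k = np.asarray(self.knots)
        K = len(k)
        kmax = k[-1]
        kprev = k[-2]

        def d(j):
            # Harrell's restricted construction: cubic and quadratic terms
            # cancel beyond the last knot, leaving a linear tail
            return (
                np.maximum(x - k[j], 0.0) ** 3
                - np.maximum(x - kprev, 0.0) ** 3 * ((kmax - k[j]) / (kmax - kprev))
                + np.maximum(x - kmax, 0.0) ** 3 * ((kprev - k[j]) / (kmax - kprev))
            )

        cols = [np.ones_like(x), x]
        for j in range(K - 2):
            cols.append(d(j))
        return np.column_stack(cols)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.basis(x) @ self.coef


@dataclass
class SplineEnsemble:
    members: list[SplineMember]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("member weights must sum to 1")
        for m in self.members:
            k = m.knots
            if not (0.1 - 1e-12 <= k[0] and k[-1] <= 0.8 + 1e-12):
                raise ValueError("interior knots must lie in [0.1, 0.8]")
            if np.any(np.diff(k) < 0.1 - 1e-12):
                raise ValueError("interknot distance must be >= 0.1")

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        preds = np.stack([m.predict(x) for m in self.members])
        return (self.weights[:, None] * preds).sum(axis=0)


def _draw_knots(rng: np.random.Generator, n_interior: int = 3,
                lo: float = 0.1, hi: float = 0.8, min_gap: float = 0.1) -> tuple[float, ...]:
    # rejection sampling; the feasible region is ample for 3 knots on [0.1,0.8]
    while True:
        k = np.sort(rng.uniform(lo, hi, size=n_interior))
        if np.all(np.diff(k) >= min_gap):
            return tuple(float(v) for v in k)


def fit_spline_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    n_models: int = 50,
    seed: int = 0,
    ridge: float = 1e-8,
    trim: float = 0.0,
) -> SplineEnsemble:
    """Fit the 50-member cubic-spline ensemble of y on x (x in [0,1]-ish).

    Each member is a penalised least-squares natural cubic spline on three
    random interior knots (linear tails).  ``trim`` optionally drops the
    given symmetric fraction of largest absolute residuals after an
    initial fit and refits (0 by default for determinism).  Member weights
    are uniform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 data points")
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_models):
        knots = _draw_knots(rng)
        m = SplineMember(knots=knots, coef=np.zeros(2 + 1))
        B = m.basis(x)
        keep = np.ones(len(x), dtype=bool)
        for _pass in range(2 if trim > 0 else 1):
            Bk, yk = B[keep], y[keep]
            if Bk.shape[0] < Bk.shape[1]:
                raise ValueError("fewer points than spline coefficients")
            P = ridge * np.eye(B.shape[1])
            P[0, 0] = P[1, 1] = 0.0  # never penalise the linear part
            coef = np.linalg.solve(Bk.T @ Bk + P, Bk.T @ yk)
            if trim > 0:
                resid = np.abs(y - B @ coef)
                cut = np.quantile(resid, 1.0 - trim)
                keep = resid <= cut
        m.coef = coef
        members.append(m)
    weights = np.full(n_models, 1.0 / n_models)
    return SplineEnsemble(members=members, weights=weights)


def expected_mortality_le(
    ensembles: dict[tuple[float, str], SplineEnsemble],
    sdi: float,
    grid: AgeGrid,
    sex: str = "female",
    observed_mx: np.ndarray | None = None,
) -> dict:
    """Expected log-mortality at a given SDI, life table and e0.

    ``ensembles`` maps (age_start, sex) to a fitted ensemble of log(mx) on
    SDI, one per age-sex group.  SDI outside [0,1] extrapolates along the
    linear tails (flagged in the output).  When ``observed_mx`` is given
    the observed-minus-expected e0 difference is included.
    """
    missing = [a for a in grid.starts if (a, sex) not in ensembles]
    if missing:
        raise ValueError(f"no ensemble for age groups {missing} ({sex})")
    warn = not (0.0 <= sdi <= 1.0)
    log_mx = np.array([float(ensembles[(a, sex)].predict(sdi)[0]) for a in grid.starts])
    mx = np.exp(log_mx)
    lt = lifetable_from_mx(mx, grid)
    out = {
        "expected_mx": mx,
        "expected_e0": lt.e0,
        "lifetable": lt,
        "extrapolated": warn,
    }
    if observed_mx is not None:
        lt_obs = lifetable_from_mx(np.asarray(observed_mx, dtype=float), grid)
        out["observed_e0"] = lt_obs.e0
        out["observed_minus_expected"] = lt_obs.e0 - lt.e0
    return out


def rake_expected_fertility(asfr: dict[int, float], target_tfr: float) -> dict[int, float]:
    """Uniform multiplicative raking of an ASFR schedule to a target TFR."""
    current = 5.0 * sum(asfr.values())
    if current <= 0:
        if target_tfr > 0:
            raise ValueError("cannot rake an all-zero schedule to a positive TFR")
        return dict(asfr)
    factor = target_tfr / current
    return {a: v * factor for a, v in asfr.items()}


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance")
    return float(pearsonr(a, b).statistic)
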