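"""Death distribution methods for vital-registration completeness.

Two censuses bracketing a period of registered deaths allow completeness
``c`` (the fraction of deaths captured by the registry, relative to census
coverage) to be inferred from the age distribution of the population and
the deaths:

* GGB (generalised growth balance): the entry rate into ages x+ minus the
  growth rate of ages x+ should equal the death rate of ages x+ in a
  closed population; orthogonal regression of the balance residual on the
  observed death rate gives 1/c as the slope and the relative census
  coverage k as the intercept.
* SEG (synthetic extinct generations): the population at age x is
  reconstructed from deaths above x grown forward at age-specific growth
  rates; c is the median ratio of reconstructed to observed population.
* GGB-SEG: k from GGB is applied to align the censuses, then SEG.

Inference is restricted to an age trim; the optimum trim minimises the
diagnostic residual RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stgpr import (
    ObservationPoint,
    STGPRConfig,
    LocationHierarchy,
    run_stgpr,
)

__all__ = [
    "RegistrationDataset",
    "CompletenessEstimate",
    "ggb",
    "seg",
    "ggb_seg",
    "select_age_trim",
    "synthesize_completeness",
]


@dataclass
class RegistrationDataset:
    """Two census age distributions and intercensal registered deaths.

    ``census1``/``census2`` map 5-year age-group starts to counts (the last
    listed group is treated as open); ``deaths`` are registered deaths by
    the same age groups over the whole intercensal period; ``date1`` and
    ``date2`` are decimal-year census reference dates.
    """

    census1: dict[float, float]
    census2: dict[float, float]
    deaths: dict[float, float]
    date1: float
    date2: float
    location: str = ""
    sex: str = "both"

    def __post_init__(self) -> None:
        if not self.date2 > self.date1:
            raise ValueError("census dates must be ordered")
        a1, a2, ad = (tuple(sorted(d)) for d in (self.census1, self.census2, self.deaths))
        if not (a1 == a2 == ad):
            raise ValueError("censuses and deaths must share one age grid")
        for d in (self.census1, self.census2, self.deaths):
            if any(v < 0 for v in d.values()):
                raise ValueError("counts must be non-negative")

    @property
    def ages(self) -> np.ndarray:
        return np.array(sorted(self.census1), dtype=float)

    @property
    def dt(self) -> float:
        return self.date2 - self.date1

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = self.ages
        n1 = np.array([self.census1[x] for x in a])
        n2 = np.array([self.census2[x] for x in a])
        d = np.array([self.deaths[x] for x in a])
        return n1, n2, d


@dataclass
class CompletenessEstimate:
    c: float
    method: str
    age_trim: tuple[float, float]
    k: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("completeness must be positive")
        if not self.age_trim[0] < self.age_trim[1]:
            raise ValueError("trim low must be < high")

    @property
    def capped(self) -> float:
        """Completeness capped at 1 for use when adjusting registered deaths."""
        return min(self.c, 1.0)


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Total-least-squares line y = a + b x; returns (a, b, residual rms)."""
    mx, my = x.mean(), y.mean()
    X = np.column_stack([x - mx, y - my])
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 0 or abs(vt[0, 0]) < 1e-12:
        raise ValueError("singular orthogonal regression")
    b = vt[0, 1] / vt[0, 0]
    a = my - b * mx
    resid = (y - a - b * x) / np.sqrt(1 + b**2)
    return float(a), float(b), float(np.sqrt(np.mean(resid**2)))


def _ggb_points(ds: RegistrationDataset, trim: tuple[float, float]):
    """Balance-equation points b(x+)-r(x+) vs d(x+) for trim ages."""
    a = ds.ages
    n1, n2, d = ds.arrays()
    dt = ds.dt
    widths = np.diff(a)  # widths of closed groups
    geo = np.sqrt(np.maximum(n1 * n2, 1e-300))
    xs, bx, rx, dxr = [], [], [], []
    for i in range(1, len(a)):
        x = a[i]
        if not (trim[0] <= x <= trim[1]):
            continue
        N1p, N2p = n1[i:].sum(), n2[i:].sum()
        if N1p <= 0 or N2p <= 0:
            continue
        Dp = d[i:].sum()
        PY = dt * np.sqrt(N1p * N2p)
        # density at exact age x from the two adjacent groups (geometric means)
        dens = (geo[i - 1] / widths[i - 1] + (geo[i] / widths[i] if i < len(a) - 1 else geo[i - 1] / widths[i - 1])) / 2.0
        Nx_entries = dens * dt  # person-entries into x+ over the period, per year handled below
        b = dens / np.sqrt(N1p * N2p)
        r = np.log(N2p / N1p) / dt
        dd = Dp / PY
        xs.append(x)
        bx.append(b)
        rx.append(r)
        dxr.append(dd)
    return np.array(xs), np.array(bx), np.array(rx), np.array(dxr)


def ggb(ds: RegistrationDataset, trim: tuple[float, float] = (15.0, 75.0)) -> CompletenessEstimate:
    """Generalised growth balance completeness estimate over an age trim.

    First pass estimates the census-2:census-1 relative coverage
    ``k = exp(-intercept * dt)`` from the balance regression; the second
    census is then aligned by k and the regression re-run so the slope is
    1/c with c relative to common census coverage.
    """
    xs, bx, rx, dxr = _ggb_points(ds, trim)
    if len(xs) < 4:
        raise ValueError("need at least 4 age points inside the trim")
    a, b, _ = _orthogonal_fit(dxr, bx - rx)
    k = float(np.exp(-a * ds.dt))
    # align census 2 to census 1 coverage and refit
    ds_adj = RegistrationDataset(
        census1=ds.census1,
        census2={x: v / k for x, v in ds.census2.items()},
        deaths=ds.deaths,
        date1=ds.date1,
        date2=ds.date2,
        location=ds.location,
        sex=ds.sex,
    )
    xs2, bx2, rx2, dxr2 = _ggb_points(ds_adj, trim)
    a2, b2, rms2 = _orthogonal_fit(dxr2, bx2 - rx2)
    if b2 <= 0:
        raise ValueError("non-positive GGB slope; data inconsistent with method")
    return CompletenessEstimate(
        c=1.0 / b2,
        method="GGB",
        age_trim=trim,
        k=k,
        diagnostics={"intercept": a2, "slope": b2, "residual_rms": rms2, "n_points": len(xs2)},
    )


def seg(
    ds: RegistrationDataset,
    trim: tuple[float, float] = (15.0, 75.0),
    k: float = 1.0,
    e_open: float = 5.0,
) -> CompletenessEstimate:
    """Synthetic extinct generations completeness estimate.

    ``k`` is the census-2:census-1 relative coverage correction applied to
    the second census before computing growth rates; ``e_open`` is the
    remaining life expectancy assumed at the open age group (from a
    reference life table) used to seed the reconstruction.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    a = ds.ages
    n1, n2, d = ds.arrays()
    n2 = n2 / k
    dt = ds.dt
    geo = np.sqrt(np.maximum(n1 * n2, 1e-300))
    widths = np.append(np.diff(a), np.nan)
    with np.errstate(divide="ignore"):
        r = np.where((n1 > 0) & (n2 > 0), np.log(np.maximum(n2, 1e-300) / np.maximum(n1, 1e-300)) / dt, 0.0)
    d_yr = d / dt  # deaths per year by age group
    nA = len(a)
    # reconstruct person-years-density at each exact age x (Bennett-Horiuchi)
    Nhat_exact = np.zeros(nA)  # N(x) at exact age a[i]
    rA = r[-1]
    z = rA * e_open
    Nhat_exact[nA - 1] = d_yr[-1] * np.exp(z) * (1.0 - z**2 / 6.0)
    for i in range(nA - 2, 0, -1):
        w = widths[i]
        Nhat_exact[i] = Nhat_exact[i + 1] * np.exp(w * r[i]) + d_yr[i] * np.exp(w * r[i] / 2.0)
    ratios = []
    xs = []
    for i in range(1, nA - 1):
        x = a[i]
        if not (trim[0] <= x <= trim[1]):
            continue
        # observed and reconstructed counts in group [x, x+w)
        w = widths[i]
        Nhat_group = w * (Nhat_exact[i] + Nhat_exact[i + 1]) / 2.0 if i + 1 < nA else w * Nhat_exact[i]
        N_obs = geo[i]
        if N_obs > 0 and Nhat_group > 0:
            ratios.append(Nhat_group / N_obs)
            xs.append(x)
    if not ratios:
        raise ValueError("empty trim for SEG")
    ratios = np.array(ratios)
    c = float(np.median(ratios))
    rms = float(np.sqrt(np.mean((ratios - c) ** 2)))
    return CompletenessEstimate(
        c=c,
        method="SEG",
        age_trim=trim,
        k=k,
        diagnostics={"ratios": ratios.tolist(), "ages": xs, "residual_rms": rms},
    )


def ggb_seg(
    ds: RegistrationDataset,
    trim: tuple[float, float] = (15.0, 75.0),
    e_open: float = 5.0,
) -> CompletenessEstimate:
    """Combined method: relative census coverage k from GGB, then SEG."""
    g = ggb(ds, trim)
    s = seg(ds, trim, k=g.k, e_open=e_open)
    return CompletenessEstimate(
        c=s.c,
        method="GGB-SEG",
        age_trim=trim,
        k=g.k,
        diagnostics={**s.diagnostics, "ggb_slope": g.diagnostics["slope"]},
    )


def select_age_trim(
    ds: RegistrationDataset,
    method: str,
    candidate_trims: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Choose the trim minimising the method's diagnostic residual RMSE.

    Ties (within 1e-12) go to the widest trim.  Deterministic.
    """
    if not candidate_trims:
        raise ValueError("no candidate trims")
    fn = {"GGB": ggb, "SEG": seg, "GGB-SEG": ggb_seg}[method]
    results = []
    for trim in candidate_trims:
        try:
            est = fn(ds, trim)
        except (ValueError, KeyError):
            continue
        rms = est.diagnostics["residual_rms"]
        width = trim[1] - trim[0]
        results.append((rms, -width, trim))
    if not results:
        raise ValueError("all candidate trims infeasible")
    best_rms = min(r for r, _, _ in results)
    # tie-break: widest among those within tolerance of the best
    contenders = [(w, t) for r, w, t in results if r <= best_rms + 1e-12]
    contenders.sort()
    return contenders[0][1]


def synthesize_completeness(
    ddm_points: Sequence[tuple[float, float]],
    years: Sequence[float],
    child_completeness: dict[float, float] | None = None,
    point_variance: float = 0.05,
    config: STGPRConfig | None = None,
    location: str = "loc",
) -> pd.DataFrame:
    """Smooth DDM point estimates into a completeness time series with UI.

    ``ddm_points`` are (year, c-hat) pairs.  Smoothing runs in logit space
    through the ST-GPR engine, optionally with a child-registration
    completeness series as a covariate.  Returns a frame with year, mean,
    lower, upper, and mean_capped (truncated to at most 1 for use when
    adjusting registered deaths).
    """
    if not ddm_points and not child_completeness:
        raise ValueError("need DDM points or a child completeness series")
    if config is None:
        config = STGPRConfig(transform="logit", amplitude=0.5, length_scale=15.0, n_draws=200)
    hierarchy = LocationHierarchy.flat([location])
    obs = [
        ObservationPoint(
            location=location,
            year=float(y),
            value=float(np.clip(c, 1e-6, 1.499)) / 1.5,  # map (0,1.5] into (0,1) for logit
            variance=point_variance,
            source_id="ddm",
        )
        for y, c in ddm_points
    ]
    covariates = None
    standard = None
    if child_completeness:
        covariates = pd.DataFrame(
            {
                "child_completeness": [
                    child_completeness.get(float(y), np.interp(y, sorted(child_completeness), [child_completeness[k] for k in sorted(child_completeness)]))
                    for y in years
                ]
            },
            index=pd.MultiIndex.from_product([[location], [float(y) for y in years]]),
        )
    cells = pd.DataFrame({"location": location, "year": [float(y) for y in years]})
    ds = run_stgpr(obs, config, hierarchy, cells, covariates, standard)
    out = ds.summary()
    for col in ("mean", "lower", "upper"):
        out[col] = out[col] * 1.5  # undo the (0,1.5] mapping
    out["mean_capped"] = np.minimum(out["mean"], 1.0)
    return out[["year", "mean", "lower", "upper", "mean_capped"]]
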