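"""Spatiotemporal Gaussian process regression for demographic data synthesis.

Three stages: (1) a linear prior in transform space with covariate fixed
effects fit on "standard" locations only and nested location random
intercepts; (2) locally weighted residual smoothing across time, age and
the location hierarchy; (3) a Gaussian-process posterior over time per
series with heteroskedastic observation noise, sampled to a fixed number
of draws (1000 in production).  The 95% uncertainty interval of a 1000-draw
cell is the 25th and 975th order statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

__all__ = [
    "ObservationPoint",
    "STGPRConfig",
    "DrawSet",
    "LocationHierarchy",
    "fit_stage1",
    "adjust_source_bias",
    "spacetime_smooth",
    "gp_posterior",
    "summarize_draws",
    "run_stgpr",
    "TRANSFORMS",
]

TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "logit": (lambda p: logit(np.clip(p, 1e-12, 1 - 1e-12)), expit),
    "log": (lambda r: np.log(np.maximum(r, 1e-300)), np.exp),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda x: x),
}


@dataclass
class ObservationPoint:
    """One data point in transform space with its sampling variance."""

    location: str
    year: float
    value: float
    variance: float
    source_id: str = "vr"
    source_type: str = "vr"
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("observation variance must be positive")


@dataclass
class STGPRConfig:
    transform: Literal["logit", "log", "identity"] = "logit"
    covariates: tuple[str, ...] = ()
    lam: float = 0.7  # time-weight decay
    zeta: float = 0.9  # spatial borrowing (weight multiplier per hierarchy step)
    omega: float = 1.0  # age-weight decay
    amplitude: float = 0.3  # GP kernel standard deviation in transform space
    length_scale: float = 10.0  # GP time length-scale, years
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lam, self.zeta, self.omega) < 0:
            raise ValueError("lambda, zeta, omega must be non-negative")
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")


class LocationHierarchy:
    """A small rooted location tree with named levels."""

    def __init__(self, parents: dict[str, str | None]):
        self.parents = dict(parents)
        roots = [k for k, v in self.parents.items() if v is None]
        if len(roots) != 1:
            raise ValueError("hierarchy must have exactly one root")
        self.root = roots[0]

    def ancestors(self, loc: str) -> list[str]:
        out, cur = [], self.parents.get(loc)
        while cur is not None:
            out.append(cur)
            cur = self.parents.get(cur)
        return out

    def distance(self, a: str, b: str) -> int:
        """Steps to the lowest common ancestor (0 for identical locations)."""
        if a == b:
            return 0
        pa = [a] + self.ancestors(a)
        pb = [b] + self.ancestors(b)
        sb = set(pb)
        for d, anc in enumerate(pa):
            if anc in sb:
                return max(d, pb.index(anc))
        return max(len(pa), len(pb))

    @classmethod
    def flat(cls, locations: Sequence[str], root: str = "global") -> "LocationHierarchy":
        return cls({root: None, **{l: root for l in locations if l != root}})


@dataclass
class Stage1Fit:
    coefficients: dict[str, float]
    random_effects: dict[str, float]
    residual_sd: float
    transform: str

    def predict(self, covariate_row: dict[str, float], location: str,
                hierarchy: LocationHierarchy | None = None) -> float:
        eta = self.coefficients.get("const", 0.0)
        for c, b in self.coefficients.items():
            if c != "const":
                eta += b * covariate_row.get(c, 0.0)
        if location in self.random_effects:
            eta += self.random_effects[location]
        elif hierarchy is not None:
            for anc in hierarchy.ancestors(location):
                if anc in self.random_effects:
                    eta += self.random_effects[anc]
                    break
        return eta


def fit_stage1(
    obs: Sequence[ObservationPoint],
    covariates: pd.DataFrame | None,
    hierarchy: LocationHierarchy,
    standard_locations: Sequence[str] | None = None,
) -> Stage1Fit:
    """Stage-1 prior: WLS fixed effects on standard locations + shrunk intercepts.

    Fixed covariate effects are estimated only from observations in
    ``standard_locations`` (all locations if None), by weighted least
    squares with weights 1/variance.  Location random intercepts are
    empirical-Bayes shrunk mean residuals, nested: a location's intercept
    shrinks toward its parent's.

    ``covariates`` is indexed by (location, year) with one column per
    covariate name; values must exist for every observation.
    """
    obs = list(obs)
    if not obs:
        raise ValueError("no observations")
    standard = set(standard_locations) if standard_locations is not None else {
        o.location for o in obs
    }
    cov_names = list(covariates.columns) if covariates is not None else []

    def xrow(o: ObservationPoint) -> list[float]:
        if not cov_names:
            return [1.0]
        r = covariates.loc[(o.location, o.year)]
        return [1.0] + [float(r[c]) for c in cov_names]

    std_obs = [o for o in obs if o.location in standard]
    if len(std_obs) < 1 + len(cov_names):
        raise ValueError("not enough standard-location observations for the design")
    X = np.array([xrow(o) for o in std_obs])
    y = np.array([o.value for o in std_obs])
    w = np.array([1.0 / o.variance for o in std_obs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient stage-1 design")
    res = sm.WLS(y, X, weights=w).fit()
    beta = {"const": float(res.params[0])}
    beta.update({c: float(b) for c, b in zip(cov_names, res.params[1:])})

    # residuals for every observation (all locations)
    resid = {}
    for o in obs:
        eta = float(np.dot(xrow(o), [beta["const"]] + [beta[c] for c in cov_names]))
        resid.setdefault(o.location, []).append((o.value - eta, 1.0 / o.variance))
    resid_all = np.concatenate([[r for r, _ in v] for v in resid.values()])
    sigma2 = float(np.var(resid_all)) if len(resid_all) > 1 else 1.0
    tau2 = max(sigma2 / 2.0, 1e-8)  # between-location variance, simple default

    # parent-level intercepts first, then children shrink toward them
    random_effects: dict[str, float] = {hierarchy.root: 0.0}
    # accumulate precision-weighted residual means by node, pushing up the tree
    node_data: dict[str, list[tuple[float, float]]] = {}
    for loc, pairs in resid.items():
        node_data.setdefault(loc, []).extend(pairs)
        for anc in hierarchy.ancestors(loc):
            node_data.setdefault(anc, []).extend(pairs)
    for node in sorted(node_data, key=lambda n: len(hierarchy.ancestors(n))):
        pairs = node_data[node]
        wsum = sum(p for _, p in pairs)
        mean = sum(r * p for r, p in pairs) / wsum
        parent = hierarchy.parents.get(node)
        parent_re = random_effects.get(parent, 0.0) if parent else 0.0
        shrink = tau2 / (tau2 + sigma2 / max(len(pairs), 1))
        random_effects[node] = parent_re + shrink * (mean - parent_re)
    random_effects[hierarchy.root] = 0.0

    return Stage1Fit(
        coefficients=beta,
        random_effects=random_effects,
        residual_sd=float(np.sqrt(sigma2)),
        transform="",
    )


def adjust_source_bias(
    obs: Sequence[ObservationPoint],
    source_effects: dict[str, float],
    reference_source: dict[str, str],
) -> list[ObservationPoint]:
    """Shift non-reference sources by (RE_ref - RE_source) in transform space.

    ``source_effects`` maps source_id to its random effect;
    ``reference_source`` maps location to the designated reference
    source_id there.  Variances are unchanged.
    """
    out = []
    for o in obs:
        if o.location not in reference_source:
            raise ValueError(f"no reference source designated for {o.location}")
        ref = reference_source[o.location]
        shift = 0.0
        if o.source_id != ref:
            shift = source_effects.get(ref, 0.0) - source_effects.get(o.source_id, 0.0)
        out.append(
            ObservationPoint(
                location=o.location,
                year=o.year,
                value=o.value + shift,
                variance=o.variance,
                source_id=o.source_id,
                source_type=o.source_type,
                age=o.age,
                sex=o.sex,
            )
        )
    return out


def estimate_source_effects(
    obs: Sequence[ObservationPoint], prior: Stage1Fit | None = None
) -> dict[str, float]:
    """Source random effects: mean residual (or mean value) by source_id."""
    by_src: dict[str, list[float]] = {}
    for o in obs:
        by_src.setdefault(o.source_id, []).append(o.value)
    grand = np.mean([v for vs in by_src.values() for v in vs])
    return {s: float(np.mean(vs) - grand) for s, vs in by_src.items()}


def spacetime_smooth(
    residuals: pd.DataFrame,
    config: STGPRConfig,
    hierarchy: LocationHierarchy | None = None,
    prediction_cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stage-2 locally weighted residual smoothing.

    ``residuals`` has columns location, year, resid and optionally age.
    For each prediction cell the smoothed residual is a weighted average of
    observed residuals with time weight ``1 - (|dt|/(1 + max|dt|))**lam``,
    age weight ``1/(1+omega)**|da|`` and spatial weight ``zeta**d`` for a
    hierarchy distance d; weights normalise to 1.  Cells with no data get
    residual 0.
    """
    if prediction_cells is None:
        prediction_cells = residuals[
            [c for c in ("location", "year", "age") if c in residuals.columns]
        ].drop_duplicates()
    has_age = "age" in residuals.columns and "age" in prediction_cells.columns
    r_loc = residuals["location"].to_numpy()
    r_year = residuals["year"].to_numpy(dtype=float)
    r_val = residuals["resid"].to_numpy(dtype=float)
    r_age = residuals["age"].to_numpy(dtype=float) if has_age else None

    out_rows = []
    for row in prediction_cells.itertuples(index=False):
        cell = row._asdict() if hasattr(row, "_asdict") else dict(row)
        dt = np.abs(r_year - cell["year"])
        dmax = dt.max() if len(dt) else 0.0
        w = 1.0 - (dt / (1.0 + dmax)) ** config.lam
        if has_age:
            da = np.abs(r_age - cell["age"])
            w = w / (1.0 + config.omega) ** da
        if hierarchy is not None:
            dist = np.array([hierarchy.distance(cell["location"], l) for l in r_loc])
            w = w * config.zeta ** dist
        else:
            w = w * (r_loc == cell["location"])
        wsum = w.sum()
        smoothed = float((w * r_val).sum() / wsum) if wsum > 0 else 0.0
        cell["smoothed_resid"] = smoothed
        out_rows.append(cell)
    return pd.DataFrame(out_rows)


@dataclass
class DrawSet:
    """Draw-level estimates per cell plus mean/lower/upper summaries.

    ``draws`` is indexed by cell key tuples with shape (n_cells, n_draws).
    """

    cells: pd.DataFrame  # key columns, one row per cell
    draws: np.ndarray  # (n_cells, n_draws)

    def __post_init__(self) -> None:
        if self.draws.shape[0] != len(self.cells):
            raise ValueError("draws and cells misaligned")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def summary(self) -> pd.DataFrame:
        s = summarize_draws(self.draws)
        out = self.cells.copy()
        out["mean"] = s["mean"]
        out["lower"] = s["lower"]
        out["upper"] = s["upper"]
        return out


def summarize_draws(draws: np.ndarray) -> dict[str, np.ndarray]:
    """Mean and 95% UI of draw-level estimates.

    For 1000 draws the UI bounds are the 25th and 975th order statistics;
    otherwise nearest-rank quantiles at 2.5% / 97.5%.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    n = draws.shape[1]
    if n == 0:
        raise ValueError("empty draw set")
    srt = np.sort(draws, axis=1)
    if n == 1000:
        lo_i, hi_i = 24, 974  # 25th and 975th order statistics
    else:
        lo_i = max(int(np.ceil(0.025 * n)) - 1, 0)
        hi_i = min(int(np.ceil(0.975 * n)) - 1, n - 1)
    return {
        "mean": draws.mean(axis=1),
        "lower": srt[:, lo_i],
        "upper": srt[:, hi_i],
    }


def _sqexp(t1: np.ndarray, t2: np.ndarray, amplitude: float, ls: float) -> np.ndarray:
    d = t1[:, None] - t2[None, :]
    return amplitude**2 * np.exp(-0.5 * (d / ls) ** 2)


def gp_posterior(
    stage2_mean: pd.DataFrame,
    obs: Sequence[ObservationPoint],
    config: STGPRConfig,
    rng: np.random.Generator | None = None,
) -> DrawSet:
    """Stage-3 GP posterior over time, sampled to draws, one series at a time.

    ``stage2_mean`` has columns location, year, mean (and optionally age,
    sex, carried through).  The GP has the stage-2 surface as its mean
    function, a squared-exponential kernel in time, and heteroskedastic
    noise equal to each observation's data variance.  With no data the
    posterior reverts to the stage-2 mean with the prior kernel variance.
    """
    if config.amplitude <= 0 or config.length_scale <= 0:
        raise ValueError("kernel parameters must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    group_keys = [c for c in ("location", "age", "sex") if c in stage2_mean.columns]
    all_cells = []
    all_draws = []
    for key, g in stage2_mean.groupby(group_keys, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sel = dict(zip(group_keys, key))
        g = g.sort_values("year")
        t_pred = g["year"].to_numpy(dtype=float)
        mu_pred = g["mean"].to_numpy(dtype=float)
        series_obs = [
            o
            for o in obs
            if o.location == sel.get("location", o.location)
            and (sel.get("age") is None or o.age == sel.get("age") or pd.isna(sel.get("age")))
            and (sel.get("sex") is None or o.sex == sel.get("sex") or pd.isna(sel.get("sex")))
        ]
        if series_obs:
            t_obs = np.array([o.year for o in series_obs], dtype=float)
            y_obs = np.array([o.value for o in series_obs], dtype=float)
            v_obs = np.array([o.variance for o in series_obs], dtype=float)
            # stage-2 mean at observation times (nearest grid year)
            mu_obs = np.interp(t_obs, t_pred, mu_pred)
            K_oo = _sqexp(t_obs, t_obs, config.amplitude, config.length_scale)
            K_po = _sqexp(t_pred, t_obs, config.amplitude, config.length_scale)
            K_pp = _sqexp(t_pred, t_pred, config.amplitude, config.length_scale)
            A = K_oo + np.diag(v_obs) + 1e-10 * np.eye(len(t_obs))
            L = np.linalg.cholesky(A)
            alpha = np.linalg.solve(L.T, np.linalg.solve(L, y_obs - mu_obs))
            post_mean = mu_pred + K_po @ alpha
            V = np.linalg.solve(L, K_po.T)
            post_cov = K_pp - V.T @ V
        else:
            post_mean = mu_pred
            post_cov = _sqexp(t_pred, t_pred, config.amplitude, config.length_scale)
        post_cov = post_cov + 1e-10 * np.eye(len(t_pred))
        try:
            Lp = np.linalg.cholesky(post_cov)
        except np.linalg.LinAlgError:
            w, U = np.linalg.eigh(post_cov)
            Lp = U @ np.diag(np.sqrt(np.maximum(w, 0.0)))
        z = rng.standard_normal((len(t_pred), config.n_draws))
        draws = post_mean[:, None] + Lp @ z
        cells = g[group_keys + ["year"]].reset_index(drop=True)
        all_cells.append(cells)
        all_draws.append(draws)
    cells = pd.concat(all_cells, ignore_index=True)
    draws = np.vstack(all_draws)
    return DrawSet(cells=cells, draws=draws)


def run_stgpr(
    obs: Sequence[ObservationPoint],
    config: STGPRConfig,
    hierarchy: LocationHierarchy,
    prediction_cells: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    standard_locations: Sequence[str] | None = None,
) -> DrawSet:
    """Full three-stage pipeline in transform space; draws are back-transformed."""
    fwd, inv = TRANSFORMS[config.transform]
    tobs = [
        ObservationPoint(
            location=o.location,
            year=o.year,
            value=float(fwd(o.value)),
            variance=o.variance,
            source_id=o.source_id,
            source_type=o.source_type,
            age=o.age,
            sex=o.sex,
        )
        for o in obs
    ]
    stage1 = fit_stage1(tobs, covariates, hierarchy, standard_locations)

    def prior_at(loc: str, year: float) -> float:
        row = {}
        if covariates is not None and (loc, year) in covariates.index:
            row = covariates.loc[(loc, year)].to_dict()
        return stage1.predict(row, loc, hierarchy)

    resid = pd.DataFrame(
        {
            "location": [o.location for o in tobs],
            "year": [o.year for o in tobs],
            "resid": [o.value - prior_at(o.location, o.year) for o in tobs],
        }
    )
    stage2 = spacetime_smooth(resid, config, hierarchy, prediction_cells)
    stage2["mean"] = [
        prior_at(r.location, r.year) + r.smoothed_resid for r in stage2.itertuples()
    ]
    ds = gp_posterior(stage2[["location", "year", "mean"]], tobs, config)
    ds.draws = inv(ds.draws)
    return ds
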