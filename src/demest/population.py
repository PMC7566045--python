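"""Cohort-component population projection and Bayesian reconstruction.

The deterministic engine projects sex- and age-structured populations on
5-year age groups with annual steps: each year a fifth of every group
advances to the next, survival follows the year's life-table rates,
births come from age-specific fertility applied to female exposure and
split by the sex ratio at birth, and net migrants move half before and
half after survival.  An event ledger records births and deaths so the
demographic balancing identity dP = B - D + M holds exactly.

The Bayesian layer (BCCMP) treats the baseline population, a
low-dimensional net-migration schedule (a Rogers-Castro-like fixed age
shape times a yearly level path) and optionally the completeness of death
registration as unknowns, scores projections against censuses (lognormal
coverage error) and registered deaths, and draws from the posterior either
by adaptive random-walk Metropolis or a Laplace approximation at the MAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "PopulationState",
    "MigrationSchedule",
    "BCCMPPrior",
    "ProjectionRates",
    "project_ccmpp",
    "census_loglik",
    "estimate_baseline_migration",
    "bccmp_completeness",
    "rogers_castro_shape",
]

SEXES = ("female", "male")


@dataclass
class PopulationState:
    """Counts by sex x 5-year age group at one instant."""

    counts: dict[str, np.ndarray]  # sex -> counts per age group
    age_starts: np.ndarray
    date: float

    def __post_init__(self) -> None:
        for s, v in self.counts.items():
            v = np.asarray(v, dtype=float)
            if np.any(v < 0):
                raise ValueError(f"negative counts for {s}")
            self.counts[s] = v

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def copy(self) -> "PopulationState":
        return PopulationState(
            {s: v.copy() for s, v in self.counts.items()}, self.age_starts.copy(), self.date
        )


@dataclass
class MigrationSchedule:
    """Net migrants per sex x age group x year (negative = emigration)."""

    by_year: dict[int, dict[str, np.ndarray]]

    def get(self, year: int, sex: str, n_age: int) -> np.ndarray:
        if year in self.by_year and sex in self.by_year[year]:
            return np.asarray(self.by_year[year][sex], dtype=float)
        return np.zeros(n_age)

    @classmethod
    def zero(cls) -> "MigrationSchedule":
        return cls(by_year={})


@dataclass
class ProjectionRates:
    """Per-year demographic rates driving the projection.

    ``survival(year, sex)`` returns per-age annual survival probabilities
    (exp(-mx) on each 5-year group); ``asfr(year)`` maps maternal age-group
    starts to rates; ``srb(year)`` is male births per female birth.
    """

    survival: Callable[[int, str], np.ndarray]
    asfr: Callable[[int], dict[int, float]]
    srb: Callable[[int], float] = lambda y: 1.05


def project_ccmpp(
    baseline: PopulationState,
    rates: ProjectionRates,
    migration: MigrationSchedule,
    horizon: int,
    clip_negative: bool = True,
) -> tuple[list[PopulationState], dict]:
    """Annual cohort-component projection on 5-year age groups.

    Returns the state at each year end (year 0 = baseline) plus an event
    ledger with per-year births, deaths by sex/age, and net migration, and
    a flag for any clipped negative counts.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ages = baseline.age_starts
    n_age = len(ages)
    states = [baseline.copy()]
    ledger = {"births": [], "deaths": [], "migration": [], "clipped": False}
    cur = baseline.copy()
    for step in range(horizon):
        year = int(round(cur.date)) + 0
        nxt = {s: np.zeros(n_age) for s in SEXES}
        deaths_rec = {s: np.zeros(n_age) for s in SEXES}
        mig_rec = {s: np.zeros(n_age) for s in SEXES}
        half_m = {s: 0.5 * migration.get(year, s, n_age) for s in SEXES}

        exposures = {}
        for s in SEXES:
            p = cur.counts[s] + half_m[s]
            if clip_negative and np.any(p < 0):
                ledger["clipped"] = True
                p = np.maximum(p, 0.0)
            surv = rates.survival(year, s)
            dead = p * (1.0 - surv)
            alive = p - dead
            deaths_rec[s] += dead
            # cohort-fraction advancement: 1/5 of each group moves up annually
            stay = alive * 0.8
            move = alive * 0.2
            adv = stay.copy()
            adv[1:] += move[:-1]
            adv[-1] += move[-1]  # open terminal group retains its movers
            exposures[s] = p  # start-of-step exposure (post half-migration)
            nxt[s] = adv

        # births from female mid-step exposure, split by SRB, infant survival
        asfr = rates.asfr(year)
        srb = rates.srb(year)
        fexp = exposures["female"]
        births = 0.0
        for a, rate in asfr.items():
            idx = np.searchsorted(ages, a, side="right") - 1
            if 0 <= idx < n_age:
                births += rate * fexp[idx]
        fem_share = 1.0 / (1.0 + srb)
        for s, share in (("female", fem_share), ("male", 1.0 - fem_share)):
            b = births * share
            s0 = rates.survival(year, s)[0]
            infant_dead = b * (1.0 - s0)
            deaths_rec[s][0] += infant_dead
            nxt[s][0] += b - infant_dead
        for s in SEXES:
            nxt[s] = nxt[s] + half_m[s]
            mig_rec[s] = 2.0 * half_m[s]
            if clip_negative and np.any(nxt[s] < 0):
                ledger["clipped"] = True
                nxt[s] = np.maximum(nxt[s], 0.0)
        cur = PopulationState({s: nxt[s] for s in SEXES}, ages, cur.date + 1.0)
        states.append(cur.copy())
        ledger["births"].append(births)
        ledger["deaths"].append(deaths_rec)
        ledger["migration"].append(mig_rec)
    return states, ledger


def census_loglik(
    projected: Sequence[PopulationState],
    censuses: Sequence[PopulationState],
    coverage_sd: float = 0.03,
) -> float:
    """Independent normal log density on log counts, sd = coverage sd.

    Each census is matched to the projected state at its date (nearest
    year).  Zero projected count against a positive census count is an
    error (the model cannot explain the observation).
    """
    if coverage_sd <= 0:
        raise ValueError("coverage sd must be positive")
    dates = np.array([p.date for p in projected])
    total = 0.0
    for cen in censuses:
        i = int(np.argmin(np.abs(dates - cen.date)))
        proj = projected[i]
        for s in cen.counts:
            obs = cen.counts[s]
            pred = proj.counts[s]
            pos = obs > 0
            if np.any(pos & (pred <= 0)):
                raise ValueError("zero projected count with positive census count")
            o, p = obs[pos], pred[pos]
            z = (np.log(o) - np.log(p)) / coverage_sd
            total += float(np.sum(-0.5 * z**2 - np.log(coverage_sd) - 0.5 * np.log(2 * np.pi)))
    return total


def rogers_castro_shape(age_starts: np.ndarray) -> np.ndarray:
    """A fixed migration age profile: childhood tail, labour peak near 25.

    Normalised to sum to 1 so a yearly level parameter carries the scale.
    """
    mids = age_starts + 2.5
    child = 0.35 * np.exp(-0.08 * mids)
    labour = np.exp(-0.5 * ((mids - 25.0) / 8.0) ** 2)
    shape = child + labour
    return shape / shape.sum()


@dataclass
class BCCMPPrior:
    baseline_log_sd: float = 0.10
    migration_level_sd: float = 0.02  # as a fraction of total population per year
    migration_smooth_sd: float = 0.01  # random-walk increment sd on the level path
    completeness_logit_mean: float = 2.0
    completeness_logit_sd: float = 1.5
    census_coverage_sd: float = 0.03
    death_log_sd: float = 0.05

    def __post_init__(self) -> None:
        for f in ("baseline_log_sd", "migration_level_sd", "census_coverage_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class BCCMPResult:
    draws: np.ndarray  # (n_draws, n_params)
    param_names: list[str]
    map_estimate: np.ndarray
    baseline_draws: dict[str, np.ndarray]  # sex -> (n_draws, n_age)
    migration_level_draws: np.ndarray  # (n_draws, n_knots)
    completeness_draws: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)


def _unpack(theta, n_age, n_knots, with_c, shared_sex):
    if shared_sex:
        eps_f = eps_m = theta[:n_age]
        k = n_age
    else:
        eps_f = theta[:n_age]
        eps_m = theta[n_age : 2 * n_age]
        k = 2 * n_age
    mlev = theta[k : k + n_knots]
    c_logit = theta[-1] if with_c else None
    return eps_f, eps_m, mlev, c_logit


def _build_problem(
    baseline_prior: PopulationState,
    rates: ProjectionRates,
    censuses: Sequence[PopulationState],
    prior: BCCMPPrior,
    horizon: int,
    n_knots: int,
    registered_deaths: np.ndarray | None,
    shared_sex: bool = False,
):
    ages = baseline_prior.age_starts
    n_age = len(ages)
    shape = rogers_castro_shape(ages)
    years0 = int(round(baseline_prior.date))
    knot_years = np.linspace(0, horizon, n_knots)
    with_c = registered_deaths is not None
    ref_total = baseline_prior.total()

    def migration_from_levels(mlev: np.ndarray) -> MigrationSchedule:
        yearly = np.interp(np.arange(horizon), knot_years, mlev)
        by_year = {}
        for t, lev in enumerate(yearly):
            m = lev * ref_total * shape
            by_year[years0 + t] = {"female": 0.5 * m, "male": 0.5 * m}
        return MigrationSchedule(by_year=by_year)

    def project(theta):
        eps_f, eps_m, mlev, c_logit = _unpack(theta, n_age, n_knots, with_c, shared_sex)
        base = PopulationState(
            {
                "female": baseline_prior.counts["female"] * np.exp(eps_f),
                "male": baseline_prior.counts["male"] * np.exp(eps_m),
            },
            ages,
            baseline_prior.date,
        )
        mig = migration_from_levels(mlev)
        states, ledger = project_ccmpp(base, rates, mig, horizon)
        return states, ledger, c_logit

    def neg_log_post(theta):
        try:
            states, ledger, c_logit = project(theta)
            ll = census_loglik(states, censuses, prior.census_coverage_sd)
        except (ValueError, FloatingPointError):
            return 1e12
        eps_f, eps_m, mlev, _ = _unpack(theta, n_age, n_knots, with_c, shared_sex)
        lp = -0.5 * np.sum((eps_f / prior.baseline_log_sd) ** 2)
        if not shared_sex:
            lp += -0.5 * np.sum((eps_m / prior.baseline_log_sd) ** 2)
        lp += -0.5 * np.sum((mlev / prior.migration_level_sd) ** 2)
        if n_knots > 1:
            lp += -0.5 * np.sum((np.diff(mlev) / prior.migration_smooth_sd) ** 2)
        if with_c:
            c = 1.0 / (1.0 + np.exp(-c_logit))
            lp += -0.5 * ((c_logit - prior.completeness_logit_mean) / prior.completeness_logit_sd) ** 2
            if len(registered_deaths) > 0:
                tot_deaths = np.array(
                    [sum(d[s].sum() for s in SEXES) for d in ledger["deaths"]]
                )[: len(registered_deaths)]
                pred = np.maximum(c * tot_deaths, 1e-12)
                obs = np.maximum(registered_deaths, 1e-12)
                z = (np.log(obs) - np.log(pred)) / prior.death_log_sd
                ll += float(np.sum(-0.5 * z**2))
        return -(ll + lp)

    n_eps = n_age if shared_sex else 2 * n_age
    n_params = n_eps + n_knots + (1 if with_c else 0)
    eps_names = (
        [f"eps_{int(a)}" for a in ages]
        if shared_sex
        else [f"eps_f_{int(a)}" for a in ages] + [f"eps_m_{int(a)}" for a in ages]
    )
    names = (
        eps_names
        + [f"mig_level_{i}" for i in range(n_knots)]
        + (["c_logit"] if with_c else [])
    )
    return neg_log_post, project, n_params, names, with_c, n_age, n_knots


def _laplace_draws(neg_log_post, theta0, n_params, n_draws, rng, maxfun=600):
    res = minimize(neg_log_post, theta0, method="L-BFGS-B",
                   options={"maxfun": maxfun, "ftol": 1e-10})
    theta_map = res.x
    # numerical Hessian by central differences
    h = 1e-4
    H = np.zeros((n_params, n_params))
    f0 = neg_log_post(theta_map)
    for i in range(n_params):
        for j in range(i, n_params):
            ei = np.zeros(n_params); ei[i] = h
            ej = np.zeros(n_params); ej[j] = h
            fpp = neg_log_post(theta_map + ei + ej)
            fpm = neg_log_post(theta_map + ei - ej)
            fmp = neg_log_post(theta_map - ei + ej)
            fmm = neg_log_post(theta_map - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    w, U = np.linalg.eigh(H)
    w = np.maximum(w, 1e-6)
    cov = (U / w) @ U.T
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_params))
    z = rng.standard_normal((n_draws, n_params))
    return theta_map, theta_map + z @ L.T, {"converged": bool(res.success), "neg_log_post": float(f0)}


def _metropolis_draws(neg_log_post, theta0, n_params, n_draws, rng, n_chains=4):
    """Adaptive random-walk Metropolis; burn-in 50%, split-Rhat reported."""
    per_chain = max(n_draws // n_chains, 50)
    total = per_chain * 2  # burn-in half
    chains = []
    for ch in range(n_chains):
        theta = theta0 + 0.01 * rng.standard_normal(n_params)
        step = 0.02 * np.ones(n_params)
        cur_nlp = neg_log_post(theta)
        kept = []
        accept = 0
        for it in range(total):
            prop = theta + step * rng.standard_normal(n_params)
            nlp = neg_log_post(prop)
            if np.log(rng.uniform()) < cur_nlp - nlp:
                theta, cur_nlp = prop, nlp
                accept += 1
            if it < total // 2 and (it + 1) % 50 == 0:
                rate = accept / (it + 1)
                step *= 1.3 if rate > 0.3 else 0.7
            if it >= total // 2:
                kept.append(theta.copy())
        chains.append(np.array(kept))
    draws = np.vstack(chains)
    # split-Rhat on each parameter
    rhat = []
    for p in range(n_params):
        halves = [c[: len(c) // 2, p] for c in chains] + [c[len(c) // 2 :, p] for c in chains]
        means = np.array([h.mean() for h in halves])
        vars_ = np.array([h.var(ddof=1) if len(h) > 1 else 0.0 for h in halves])
        W = vars_.mean()
        B = means.var(ddof=1) * len(halves[0])
        var_post = (len(halves[0]) - 1) / len(halves[0]) * W + B / len(halves[0])
        rhat.append(float(np.sqrt(var_post / W)) if W > 0 else 1.0)
    return draws, {"split_rhat": rhat, "max_rhat": float(np.max(rhat))}


def estimate_baseline_migration(
    baseline_prior: PopulationState,
    rates: ProjectionRates,
    censuses: Sequence[PopulationState],
    prior: BCCMPPrior | None = None,
    horizon: int | None = None,
    n_knots: int = 4,
    n_draws: int = 500,
    method: str = "laplace",
    seed: int = 0,
    registered_deaths: np.ndarray | None = None,
    rhat_threshold: float = 1.1,
    shared_sex: bool = False,
) -> BCCMPResult:
    """Posterior draws of the baseline population and net-migration schedule.

    Requires at least two censuses.  ``method="laplace"`` (fast mode)
    samples from a Gaussian approximation at the MAP; ``method="rwm"``
    runs 4-chain adaptive random-walk Metropolis with 50% burn-in and
    reports split-Rhat (non-convergence is flagged in diagnostics, never
    silent).  Seeded and reproducible.
    """
    if len(censuses) < 2:
        raise ValueError("need at least 2 censuses")
    prior = prior or BCCMPPrior()
    if horizon is None:
        horizon = int(round(max(c.date for c in censuses) - baseline_prior.date)) + 1
    rng = np.random.default_rng(seed)
    neg_log_post, project, n_params, names, with_c, n_age, n_knots = _build_problem(
        baseline_prior, rates, censuses, prior, horizon, n_knots, registered_deaths,
        shared_sex=shared_sex,
    )
    theta0 = np.zeros(n_params)
    if with_c:
        theta0[-1] = prior.completeness_logit_mean
    if method == "laplace":
        theta_map, draws, diag = _laplace_draws(
            neg_log_post, theta0, n_params, n_draws, rng,
            maxfun=1500 if with_c else 600,
        )
    elif method == "rwm":
        res = minimize(neg_log_post, theta0, method="L-BFGS-B")
        draws, diag = _metropolis_draws(neg_log_post, res.x, n_params, n_draws, rng)
        theta_map = res.x
        diag["converged"] = diag["max_rhat"] <= rhat_threshold
    else:
        raise ValueError(f"unknown sampler {method!r}")

    eps_f = draws[:, :n_age]
    k = n_age if shared_sex else 2 * n_age
    eps_m = eps_f if shared_sex else draws[:, n_age : 2 * n_age]
    baseline_draws = {
        "female": baseline_prior.counts["female"][None, :] * np.exp(eps_f),
        "male": baseline_prior.counts["male"][None, :] * np.exp(eps_m),
    }
    mig_draws = draws[:, k : k + n_knots]
    c_draws = 1.0 / (1.0 + np.exp(-draws[:, -1])) if with_c else None
    return BCCMPResult(
        draws=draws,
        param_names=names,
        map_estimate=theta_map,
        baseline_draws=baseline_draws,
        migration_level_draws=mig_draws,
        completeness_draws=c_draws,
        diagnostics=diag,
    )


def bccmp_completeness(
    baseline_prior: PopulationState,
    rates: ProjectionRates,
    censuses: Sequence[PopulationState],
    registered_deaths: np.ndarray,
    prior: BCCMPPrior | None = None,
    **kwargs,
) -> BCCMPResult:
    """Registration completeness as a likelihood parameter of the BCCMP.

    Registered deaths (total per projection year) are modelled as
    c x projected deaths with lognormal noise; the posterior for c carries
    the method tag "BCCMP" on the completeness interface.
    """
    return estimate_baseline_migration(
        baseline_prior,
        rates,
        censuses,
        prior=prior,
        registered_deaths=np.asarray(registered_deaths, dtype=float),
        **kwargs,
    )
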