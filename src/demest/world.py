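"""Synthetic demographic worlds: ground truth plus noisy multi-source data.

The generator scripts smooth fertility and mortality transitions for a
small set of locations, builds internally consistent population series
through the cohort-component engine, and then derives the observation
types real demographic estimation consumes: vital-registration births and
deaths with incomplete registration, censuses with coverage error,
complete and summary birth histories, and sibling survival histories.

Scenario presets: ``classical_transition`` (smooth fall of death then
birth rates), ``hiv_epidemic`` (an adult mortality bump), ``conflict_shock``
(a one-year fatal discontinuity), ``incomplete_vr`` (death registration
ramping from 60%), ``emigration_wave`` (sustained negative net migration).

Admin data are simulated at the cell level; individuals appear only inside
the survey modules.  All randomness flows from one master seed via
per-operation streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .ages import build_age_grid, five_year_grid, GBD23
from .fertility import FertilitySchedule, extend_terminal_asfr, tfr_from_asfr
from .mlt import StandardLibrary, make_standard_library, select_standard, fit_relational
from .population import (
    PopulationState,
    MigrationSchedule,
    ProjectionRates,
    project_ccmpp,
    rogers_castro_shape,
    SEXES,
)
from .taxonomy import RatesTrajectory, classify_trajectory

__all__ = ["WorldConfig", "TruthBundle", "ObservationBundle", "build_world",
           "observe_admin", "observe_surveys", "SCENARIOS"]

SCENARIOS = (
    "classical_transition",
    "hiv_epidemic",
    "conflict_shock",
    "incomplete_vr",
    "emigration_wave",
)

#: Interior ASFR shape (proportions of TFR/5 per 5-year group, ages 15-49).
ASFR_SHAPE = {15: 0.10, 20: 0.24, 25: 0.25, 30: 0.20, 35: 0.13, 40: 0.06, 45: 0.02}


@dataclass
class WorldConfig:
    locations: tuple[str, ...] = ("loc_a",)
    year_start: int = 1950
    year_end: int = 2019
    scenario: str = "classical_transition"
    # fertility transition: TFR falls from tfr0 to tfr1, midpoint/speed in years
    tfr0: float = 6.5
    tfr1: float = 2.0
    tfr_mid: float = 1995.0
    tfr_speed: float = 4.0
    srb: float = 1.05
    # mortality transition: 5q0 and 45q15 fall log-linearly
    q5_0: float = 0.25
    q5_1: float = 0.03
    q45_0: float = 0.40
    q45_1: float = 0.12
    # HIV bump (adult mortality), used when scenario == "hiv_epidemic"
    hiv_peak_year: int = 1998
    hiv_amplitude: float = 0.010  # added mx at the bump peak, ages 25-45
    hiv_width: float = 7.0
    # shock event, used when scenario == "conflict_shock"
    shock_year: int = 1994
    shock_deaths_per_1000: float = 20.0
    # observation model
    vr_completeness0: float = 0.6
    vr_completeness1: float = 0.95
    census_coverage_sd: float = 0.02
    census_years: tuple[int, ...] | None = None  # default: 4 evenly spaced
    survey_n_mothers: int = 2000
    survey_n_respondents: int = 1500
    recall_years: int = 15
    sibship_frailty_sd: float = 0.5  # lognormal sd of shared sibship mortality multiplier
    # migration level (fraction of population per year) for emigration_wave
    emigration_level: float = -0.005
    baseline_pop: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (self.year_start < self.year_end):
            raise ValueError("year range empty")
        if self.scenario == "hiv_epidemic" and not (
            self.year_start <= self.hiv_peak_year <= self.year_end
        ):
            raise ValueError("HIV bump outside the simulated years")
        if self.scenario == "conflict_shock" and not (
            self.year_start <= self.shock_year <= self.year_end
        ):
            raise ValueError("shock year outside the simulated years")
        if self.census_years is None:
            self.census_years = tuple(
                int(round(y))
                for y in np.linspace(self.year_start + 5, self.year_end - 4, 4)
            )
        for y in self.census_years:
            if not (self.year_start <= y <= self.year_end):
                raise ValueError("census dates must fall within the simulated years")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class TruthBundle:
    config: WorldConfig
    grid5: object
    asfr: dict[tuple[str, int], FertilitySchedule]
    mx: dict[tuple[str, int, str], np.ndarray]  # on the 5-year grid
    hiv_mx: dict[tuple[str, int, str], np.ndarray]
    population: dict[str, list[PopulationState]]
    births: dict[tuple[str, int], float]
    deaths: dict[tuple[str, int, str], np.ndarray]
    person_years: dict[tuple[str, int, str], np.ndarray]
    migration: dict[str, MigrationSchedule]
    stage_labels: dict[str, pd.DataFrame]
    summaries: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    #: detailed under-5 survival: (loc, year) -> lx at exact ages [0, 7/365, 28/365, 1, 5]
    under5_lx: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def crude_rates(self, location: str, year: int) -> dict[str, float]:
        py = sum(self.person_years[(location, year, s)].sum() for s in SEXES)
        b = self.births[(location, year)]
        d = sum(self.deaths[(location, year, s)].sum() for s in SEXES)
        return {"CBR": b / py * 1000, "CDR": d / py * 1000, "NRI": (b - d) / py * 1000}


@dataclass
class ObservationBundle:
    vr_deaths: pd.DataFrame  # location, year, sex, age_start, deaths
    vr_births: pd.DataFrame  # location, year, births
    censuses: pd.DataFrame  # location, date, sex, age_start, count
    cbh: pd.DataFrame  # per-child records from complete birth histories
    sbh: pd.DataFrame  # aggregated CEB/CED by maternal age group
    siblings: pd.DataFrame  # per-sibling records
    manifest: dict = field(default_factory=dict)


def _logistic_path(years: np.ndarray, v0: float, v1: float, mid: float, speed: float) -> np.ndarray:
    return v1 + (v0 - v1) * expit(-(years - mid) / speed)


def _true_asfr(cfg: WorldConfig, year: int, scale: float = 1.0) -> FertilitySchedule:
    tfr = scale * float(
        _logistic_path(np.array([year]), cfg.tfr0, cfg.tfr1, cfg.tfr_mid, cfg.tfr_speed)[0]
    )
    interior = {a: s * tfr / 5.0 for a, s in ASFR_SHAPE.items()}
    interior = {a: v / sum(ASFR_SHAPE.values()) for a, v in interior.items()}
    return extend_terminal_asfr(interior, r10=0.03, r50=0.02, srb=cfg.srb)


def _location_tfr_scale(i: int, n: int) -> float:
    """Deterministic mild between-location fertility variation (within ~8%)."""
    if n <= 1:
        return 1.0
    return 1.0 + 0.08 * (i - (n - 1) / 2.0) / max(n - 1, 1) * 2.0


_STD_CACHE: dict[int, StandardLibrary] = {}


def _collapse_to_5yr(lx23: np.ndarray, grid23, grid5) -> np.ndarray:
    """mx on the 5-year grid implied by an lx schedule on the gbd23 grid."""
    lt = None
    # implied mx per gbd23 interval under constant hazard, then person-year
    # weighted collapse of the under-5 intervals
    widths = grid23.closed_widths
    with np.errstate(divide="ignore"):
        haz = -np.diff(np.log(np.maximum(lx23, 1e-300))) / widths[:-1]
    # person-years per interval (piecewise-constant hazard)
    Lx = np.empty(grid23.n)
    dx = -np.diff(np.append(lx23, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        Lx[:-1] = np.where(haz > 0, (lx23[:-1] - lx23[1:]) / haz, widths[:-1] * lx23[:-1])
    term_m = max(haz[-1], 1e-6)
    Lx[-1] = lx23[-1] / term_m
    mx5 = np.empty(grid5.n)
    # under-5: intervals 0..3 of gbd23
    D = lx23[0] - lx23[4]
    mx5[0] = D / max(Lx[:4].sum(), 1e-12)
    for j, s in enumerate(grid5.starts[1:-1], start=1):
        i = grid23.index_of(float(s))
        D = lx23[i] - lx23[i + 1]
        mx5[j] = D / max(Lx[i], 1e-12)
    mx5[-1] = term_m
    return np.maximum(mx5, 1e-8)


def _true_mortality(cfg: WorldConfig, lib: StandardLibrary, year: int, sex: str,
                    grid23, grid5) -> tuple[np.ndarray, np.ndarray]:
    years = cfg.years
    f = (year - years[0]) / (years[-1] - years[0])
    q5 = float(np.exp(np.log(cfg.q5_0) + f * (np.log(cfg.q5_1) - np.log(cfg.q5_0))))
    q45 = float(np.exp(np.log(cfg.q45_0) + f * (np.log(cfg.q45_1) - np.log(cfg.q45_0))))
    if sex == "male":
        q5 *= 1.08
        q45 *= 1.25
    # the relational family cannot reach arbitrarily extreme child levels;
    # fit at a clamped level and rescale the under-5 hazards exactly after
    q5_fit = float(np.clip(q5, 2e-3, 0.4))
    q45_fit = float(np.clip(q45, 5e-3, 0.85))
    std = select_standard(lib, {"5q0": q5_fit, "45q15": q45_fit}, k=3, sex=sex)
    _, lt = fit_relational(std, {"5q0": q5_fit, "45q15": q45_fit}, grid23)
    lx = lt.lx / lt.lx[0]
    if abs(q5_fit - q5) > 1e-12:
        from .lifetable import constrain_under5_detail

        q_sub = 1.0 - lx[1:5] / lx[:4]
        q_new = constrain_under5_detail(np.clip(q_sub, 1e-15, 1 - 1e-12), q5)
        lx_new = lx.copy()
        for i, qn in enumerate(q_new):
            lx_new[i + 1] = lx_new[i] * (1.0 - qn)
        # survival conditional on reaching age 5 is unchanged
        lx_new[5:] = lx[5:] * (lx_new[4] / lx[4])
        lx = lx_new
    under5 = lx[:5].copy()  # lx at exact ages 0, 7/365, 28/365, 1, 5
    return _collapse_to_5yr(lx, grid23, grid5), under5


def _hiv_bump(cfg: WorldConfig, year: int, grid5) -> np.ndarray:
    bump = np.zeros(grid5.n)
    if cfg.scenario != "hiv_epidemic":
        return bump
    amp = cfg.hiv_amplitude * np.exp(-0.5 * ((year - cfg.hiv_peak_year) / cfg.hiv_width) ** 2)
    for i, s in enumerate(grid5.starts):
        if 25.0 <= s <= 45.0:
            bump[i] = amp
    return bump


def build_world(cfg: WorldConfig) -> TruthBundle:
    """Construct the ground-truth bundle; deterministic given the config seed."""
    grid23 = build_age_grid(GBD23)
    grid5 = five_year_grid(95.0)
    key = id(cfg) * 0 + 1  # single shared library; deterministic
    if key not in _STD_CACHE:
        _STD_CACHE[key] = make_standard_library()
    lib = _STD_CACHE[key]
    years = cfg.years

    asfr: dict = {}
    mx: dict = {}
    hiv: dict = {}
    under5: dict = {}
    # mortality paths are shared across locations: compute once per (year, sex)
    mort_cache = {
        (int(y), s): _true_mortality(cfg, lib, int(y), s, grid23, grid5)
        for y in years
        for s in SEXES
    }
    for i, loc in enumerate(cfg.locations):
        scale = _location_tfr_scale(i, len(cfg.locations))
        for y in years:
            asfr[(loc, int(y))] = _true_asfr(cfg, int(y), scale)
            bump = _hiv_bump(cfg, int(y), grid5)
            for s in SEXES:
                base, u5 = mort_cache[(int(y), s)]
                mx[(loc, int(y), s)] = base + bump
                hiv[(loc, int(y), s)] = bump
                if s == "female":
                    under5[(loc, int(y))] = u5

    population: dict = {}
    births: dict = {}
    deaths: dict = {}
    pys: dict = {}
    migration: dict = {}
    stage_labels: dict = {}

    for loc in cfg.locations:
        def survival(year: int, sex: str, _loc=loc) -> np.ndarray:
            m = mx[(_loc, int(np.clip(year, years[0], years[-1])), sex)]
            return np.exp(-m)

        def asfr_fn(year: int, _loc=loc) -> dict[int, float]:
            return dict(asfr[(_loc, int(np.clip(year, years[0], years[-1])))].asfr)

        rates = ProjectionRates(survival=survival, asfr=asfr_fn, srb=lambda y: cfg.srb)

        # quasi-stable baseline: run in from a flat age pyramid for 40 years
        flat = np.full(grid5.n, cfg.baseline_pop / (2 * grid5.n))
        warm = PopulationState({s: flat.copy() for s in SEXES}, grid5.boundaries, years[0] - 40)
        warm_rates = ProjectionRates(
            survival=lambda y, s: survival(years[0], s),
            asfr=lambda y: asfr_fn(years[0]),
            srb=lambda y: cfg.srb,
        )
        warm_states, _ = project_ccmpp(warm, warm_rates, MigrationSchedule.zero(), 40)
        base = warm_states[-1]
        base = PopulationState(
            {s: base.counts[s] * (cfg.baseline_pop / base.total()) for s in SEXES},
            grid5.boundaries,
            float(years[0]),
        )

        if cfg.scenario == "emigration_wave":
            shape = rogers_castro_shape(grid5.boundaries)
            by_year = {}
            for y in years[:-1]:
                lvl = cfg.emigration_level if 1970 <= y <= 1995 else 0.0
                m = lvl * cfg.baseline_pop * shape
                by_year[int(y)] = {"female": 0.5 * m, "male": 0.5 * m}
            mig = MigrationSchedule(by_year=by_year)
        else:
            mig = MigrationSchedule.zero()
        migration[loc] = mig

        horizon = len(years) - 1
        states, ledger = project_ccmpp(base, rates, mig, horizon)
        population[loc] = states
        for t, y in enumerate(years[:-1]):
            births[(loc, int(y))] = ledger["births"][t]
            for s in SEXES:
                d = ledger["deaths"][t][s].copy()
                m = mx[(loc, int(y), s)]
                if cfg.scenario == "conflict_shock" and int(y) == cfg.shock_year:
                    # young-adult-male-weighted conflict deaths on top of the envelope
                    pop = states[t].counts[s]
                    w = np.zeros(grid5.n)
                    for i, a in enumerate(grid5.starts):
                        if 15 <= a <= 45:
                            w[i] = pop[i] * (3.0 if s == "male" else 1.0)
                    if w.sum() > 0:
                        total = cfg.shock_deaths_per_1000 / 1000.0 * states[t].total() / 2
                        d = d + total * w / w.sum()
                deaths[(loc, int(y), s)] = d
                # person-years defined so deaths = mx * PY holds exactly
                with np.errstate(divide="ignore", invalid="ignore"):
                    pys[(loc, int(y), s)] = np.where(m > 0, ledger["deaths"][t][s] / m, 0.0)
        # final year: carry rates forward for rate-based summaries
        y_last = int(years[-1])
        births[(loc, y_last)] = births[(loc, int(years[-2]))]
        for s in SEXES:
            deaths[(loc, y_last, s)] = deaths[(loc, int(years[-2]), s)]
            pys[(loc, y_last, s)] = pys[(loc, int(years[-2]), s)]

    truth = TruthBundle(
        config=cfg,
        grid5=grid5,
        asfr=asfr,
        mx=mx,
        hiv_mx=hiv,
        population=population,
        births=births,
        deaths=deaths,
        person_years=pys,
        migration=migration,
        stage_labels={},
        under5_lx=under5,
    )
    for loc in cfg.locations:
        cr = [truth.crude_rates(loc, int(y)) for y in years]
        traj = RatesTrajectory(
            years=years,
            cbr=np.array([c["CBR"] for c in cr]),
            cdr=np.array([c["CDR"] for c in cr]),
            net_migration_rate=np.array(
                [
                    sum(migration[loc].get(int(y), s, grid5.n).sum() for s in SEXES)
                    / max(truth.population[loc][t].total(), 1.0)
                    * 1000.0
                    for t, y in enumerate(years)
                ]
            ),
        )
        truth.stage_labels[loc] = classify_trajectory(traj)
    for (loc, y), _ in list(births.items()):
        sched = asfr[(loc, y)]
        truth.summaries[(loc, y)] = {"TFR": tfr_from_asfr(sched)}
    return truth


def _completeness_path(cfg: WorldConfig, year: int) -> float:
    if cfg.scenario != "incomplete_vr":
        c0, c1 = 0.95, 1.0
    else:
        c0, c1 = cfg.vr_completeness0, cfg.vr_completeness1
    years = cfg.years
    f = (year - years[0]) / (years[-1] - years[0])
    return float(c0 + f * (c1 - c0))


def observe_admin(truth: TruthBundle, seed: int | None = None,
                  zero_noise: bool = False) -> ObservationBundle:
    """Vital registration and census observations from the truth bundle.

    VR deaths are binomial thinnings of true deaths at the year's
    completeness; censuses apply multiplicative lognormal coverage error.
    ``zero_noise`` switches sampling off (expected values, completeness
    and coverage held at their paths) for end-to-end identity checks.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    vr_rows, birth_rows, census_rows = [], [], []
    for loc in cfg.locations:
        for y in cfg.years:
            c = _completeness_path(cfg, int(y)) if not zero_noise else 1.0
            for s in SEXES:
                d = truth.deaths[(loc, int(y), s)]
                for i, a in enumerate(truth.grid5.starts):
                    mean = c * d[i]
                    if zero_noise:
                        obs = mean
                    else:
                        obs = float(rng.binomial(int(round(d[i])), c)) if d[i] > 0 else 0.0
                    vr_rows.append(
                        {"location": loc, "year": int(y), "sex": s,
                         "age_start": float(a), "deaths": obs,
                         "source_id": "vr", "source_type": "vr"}
                    )
            b = truth.births[(loc, int(y))]
            vr_b = b if zero_noise else float(rng.binomial(int(round(b)), min(c * 1.0, 1.0)))
            birth_rows.append({"location": loc, "year": int(y), "births": vr_b,
                               "source_id": "vr", "source_type": "vr"})
        for cy in cfg.census_years:
            t = int(cy - cfg.year_start)
            state = truth.population[loc][t]
            for s in SEXES:
                for i, a in enumerate(truth.grid5.starts):
                    err = 1.0 if zero_noise else float(
                        np.exp(rng.normal(0.0, cfg.census_coverage_sd))
                    )
                    census_rows.append(
                        {"location": loc, "date": float(cy), "sex": s,
                         "age_start": float(a), "count": state.counts[s][i] * err,
                         "source_id": f"census_{cy}", "source_type": "census"}
                    )
    manifest = {"seed": cfg.seed if seed is None else seed, "scenario": cfg.scenario}
    return ObservationBundle(
        vr_deaths=pd.DataFrame(vr_rows),
        vr_births=pd.DataFrame(birth_rows),
        censuses=pd.DataFrame(census_rows),
        cbh=pd.DataFrame(),
        sbh=pd.DataFrame(),
        siblings=pd.DataFrame(),
        manifest=manifest,
    )


UNDER5_AGES = np.array([0.0, 7.0 / 365.0, 28.0 / 365.0, 1.0, 5.0])


def _child_death_age(rng: np.random.Generator, under5_lx: np.ndarray) -> float | None:
    """Death age under 5 for one child, or None if it survives to 5.

    Sampled from the world's own detailed under-5 survival schedule
    (lx at the exact ages 0, 7d, 28d, 1y, 5y; uniform within intervals).
    """
    q5 = 1.0 - under5_lx[-1] / under5_lx[0]
    if rng.uniform() >= q5:
        return None
    dx = -np.diff(under5_lx / under5_lx[0])
    p = dx / dx.sum()
    j = rng.choice(len(p), p=p)
    return float(rng.uniform(UNDER5_AGES[j], UNDER5_AGES[j + 1]))


def observe_surveys(truth: TruthBundle, survey_year: int | None = None,
                    seed: int | None = None) -> ObservationBundle:
    """Complete/summary birth histories and sibling histories.

    Mothers are sampled with maternal-age weights from the current female
    population; children arrive by the true ASFR history over the mother's
    reproductive years within the recall window and survive under-5 by the
    birth-year 5q0.  Siblings expose ages 15-59 under the true adult rates;
    only sibships with a surviving potential respondent report, which
    reproduces the survivor-selection bias the weighted estimator corrects.
    """
    cfg = truth.config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 7919)
    survey_year = int(survey_year or cfg.year_end)
    grid5 = truth.grid5
    cbh_rows, sbh_rows, sib_rows = [], [], []
    for loc in cfg.locations:
        t = survey_year - cfg.year_start
        state = truth.population[loc][min(t, len(truth.population[loc]) - 1)]
        fem = state.counts["female"]
        m_ages = [15, 20, 25, 30, 35, 40, 45]
        w = np.array([fem[grid5.index_of(float(a))] for a in m_ages], dtype=float)
        w = w / w.sum()
        n_by_group = rng.multinomial(cfg.survey_n_mothers, w)
        for a, n_m in zip(m_ages, n_by_group):
            ceb_g = 0.0
            ced_g = 0.0
            for _ in range(n_m):
                age_now = a + rng.uniform(0, 5)
                # walk the mother's fertile years (mid-year convention: the
                # survey sits at mid-year, a year-b birth is aged s-b-0.5);
                # each year she bears with probability ASFR(her age group)
                for back in range(-1, int(age_now - 10)):
                    yr = survey_year - 1 - back
                    if yr < cfg.year_start:
                        break
                    age_then = age_now - 1 - back
                    grp = int(age_then // 5 * 5)
                    sched = truth.asfr.get((loc, yr))
                    if sched is None or grp not in sched.asfr:
                        continue
                    p_birth = min(sched.asfr[grp], 0.95)
                    if back == -1:
                        p_birth *= 0.5  # half the survey year has elapsed
                    if rng.uniform() < p_birth:
                        ceb_g += 1
                        byear = yr
                        u5lx = truth.under5_lx[
                            (loc, int(np.clip(byear, cfg.year_start, cfg.year_end)))
                        ]
                        dage = _child_death_age(rng, u5lx)
                        child_age = max(survey_year - byear - 0.5, 0.25)
                        died = dage is not None and dage < min(child_age, 5.0)
                        if died:
                            ced_g += 1
                        cbh_rows.append(
                            {"location": loc, "survey_year": survey_year,
                             "mother_age_group": a, "birth_year": byear,
                             "died_under5": bool(died),
                             "death_age": dage if died else np.nan}
                        )
            sbh_rows.append(
                {"location": loc, "survey_year": survey_year, "age_group": a,
                 "n_mothers": int(n_m), "children_ever_born": ceb_g,
                 "children_surviving": ceb_g - ced_g}
            )
        # sibling histories
        for rid in range(cfg.survey_n_respondents):
            size = int(rng.integers(2, 6))
            # siblings span a wide age range; only respondent eligibility
            # (15-49, alive) is restricted below
            byears = survey_year - rng.integers(5, 70, size=size)
            sexes = np.where(rng.uniform(size=size) < 0.5, "female", "male")
            # shared sibship frailty: mortality clusters within families,
            # which is what the survivor-bias weights are built to counter
            frailty = float(rng.lognormal(-0.5 * cfg.sibship_frailty_sd**2,
                                          cfg.sibship_frailty_sd))
            alive = np.ones(size, dtype=bool)
            dyears = np.full(size, np.nan)
            for j in range(size):
                for yr in range(int(byears[j]) + 15, survey_year):
                    age = yr - byears[j]
                    if age >= 60:
                        break
                    grp = int(age // 5 * 5)
                    yr_c = int(np.clip(yr, cfg.year_start, cfg.year_end))
                    m = truth.mx[(loc, yr_c, str(sexes[j]))]
                    idx = grid5.index_of(float(grp))
                    if rng.uniform() < 1.0 - np.exp(-frailty * m[idx]):
                        alive[j] = False
                        dyears[j] = yr
                        break
            # a potential respondent: sibling aged 15-49 at survey and alive
            ages_now = survey_year - byears
            potential = alive & (ages_now >= 15) & (ages_now < 50)
            n_surv = int(potential.sum())
            if n_surv == 0:
                continue  # unreported sibship: the selection the weights fix
            # respondents are sampled from individuals, so a sibship's chance
            # of reporting scales with its surviving potential respondents
            if rng.uniform() >= n_surv / size:
                continue
            for j in range(size):
                sib_rows.append(
                    {"location": loc, "respondent_id": rid,
                     "sex": str(sexes[j]),
                     "birth_year": float(byears[j]),
                     "death_year": float(dyears[j]) if not alive[j] else np.nan,
                     "sibship_size": size, "surviving_respondents": n_surv}
                )
    return ObservationBundle(
        vr_deaths=pd.DataFrame(),
        vr_births=pd.DataFrame(),
        censuses=pd.DataFrame(),
        cbh=pd.DataFrame(cbh_rows),
        sbh=pd.DataFrame(sbh_rows),
        siblings=pd.DataFrame(sib_rows),
        manifest={"survey_year": survey_year},
    )


def _true_q5(truth: TruthBundle, loc: str, year: int) -> float:
    """True 5q0 from the detailed under-5 survival schedule (female)."""
    lx = truth.under5_lx[
        (loc, int(np.clip(year, truth.config.year_start, truth.config.year_end)))
    ]
    return float(1.0 - lx[-1] / lx[0])
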