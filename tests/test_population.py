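"""Cohort-component projection and Bayesian reconstruction."""

import numpy as np
import pytest

from demest.ages import five_year_grid
from demest.population import (
    BCCMPPrior,
    MigrationSchedule,
    PopulationState,
    ProjectionRates,
    bccmp_completeness,
    census_loglik,
    estimate_baseline_migration,
    project_ccmpp,
    rogers_castro_shape,
)


@pytest.fixture(scope="module")
def setup():
    grid = five_year_grid(45.0)
    ages = grid.boundaries
    mx = 0.004 * np.exp(0.05 * (ages + 2.5))
    mx[-1] = 0.12
    surv = np.exp(-mx)
    asfr = {15: 0.06, 20: 0.11, 25: 0.1, 30: 0.06, 35: 0.02}
    rates = ProjectionRates(survival=lambda y, s: surv, asfr=lambda y: asfr,
                            srb=lambda y: 1.05)
    tb = 1000.0 * np.exp(-0.03 * ages)
    base = PopulationState({"female": tb.copy(), "male": tb.copy()}, ages, 1960.0)
    return grid, rates, base, tb, surv, asfr


class TestProjectCCMPP:
    def test_pure_aging_shifts_cohorts(self):
        """No fertility, no mortality, no migration: counts advance along
        cohort diagonals (1/5 per year) with the total conserved."""
        grid = five_year_grid(20.0)
        ages = grid.boundaries
        rates = ProjectionRates(survival=lambda y, s: np.ones(len(ages)),
                                asfr=lambda y: {}, srb=lambda y: 1.05)
        base = PopulationState({"female": np.array([100.0, 0, 0, 0, 0]),
                                "male": np.zeros(5)}, ages, 2000.0)
        states, ledger = project_ccmpp(base, rates, MigrationSchedule.zero(), 1)
        f = states[1].counts["female"]
        assert f[0] == pytest.approx(80.0)
        assert f[1] == pytest.approx(20.0)
        assert states[1].total() == pytest.approx(100.0)

    def test_closed_population_conservation(self, setup):
        """P(t+1) - P(t) = births - deaths exactly in a closed population."""
        _, rates, base, *_ = setup
        states, ledger = project_ccmpp(base, rates, MigrationSchedule.zero(), 15)
        for t in range(15):
            dP = states[t + 1].total() - states[t].total()
            B = ledger["births"][t]
            D = sum(ledger["deaths"][t][s].sum() for s in ("female", "male"))
            assert dP == pytest.approx(B - D, abs=1e-8)

    def test_balancing_identity_with_migration(self, setup):
        grid, rates, base, *_ = setup
        n = grid.n
        mig = MigrationSchedule(by_year={y: {"female": np.full(n, 3.0),
                                             "male": np.full(n, -2.0)}
                                         for y in range(1960, 1975)})
        states, ledger = project_ccmpp(base, rates, mig, 10)
        for t in range(10):
            dP = states[t + 1].total() - states[t].total()
            B = ledger["births"][t]
            D = sum(ledger["deaths"][t][s].sum() for s in ("female", "male"))
            M = sum(ledger["migration"][t][s].sum() for s in ("female", "male"))
            assert dP == pytest.approx(B - D + M, abs=1e-8)

    def test_linearity_in_baseline_without_fertility(self, setup):
        grid, _, base, _, surv, _ = setup
        rates0 = ProjectionRates(survival=lambda y, s: surv, asfr=lambda y: {},
                                 srb=lambda y: 1.05)
        s1, _ = project_ccmpp(base, rates0, MigrationSchedule.zero(), 8)
        double = PopulationState({s: 2 * v for s, v in base.counts.items()},
                                 base.age_starts, base.date)
        s2, _ = project_ccmpp(double, rates0, MigrationSchedule.zero(), 8)
        np.testing.assert_allclose(s2[8].counts["female"],
                                   2 * s1[8].counts["female"], rtol=1e-12)

    def test_agreement_with_microsimulation(self, setup):
        """Expected totals match an individual-based oracle with the same
        discrete transitions, within 3 Monte-Carlo SE (1e5 agents)."""
        grid, rates, base, _, surv, asfr = setup
        ages = grid.boundaries
        n_age = grid.n
        T = 10
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), T)
        rng = np.random.default_rng(0)
        N = 100_000
        scale = N / base.total()
        counts0 = base.counts["female"]
        cells = rng.choice(2 * n_age, size=N,
                           p=np.repeat(counts0, 2) / counts0.sum() / 2)
        agrp, sex = cells // 2, cells % 2
        for t in range(T):
            # births from start-of-step female exposure (engine convention)
            fexp = np.bincount(agrp[sex == 0], minlength=n_age)
            lam = sum(asfr.get(int(ages[i]), 0.0) * fexp[i] for i in range(n_age))
            nb = rng.poisson(lam)
            bsex = (rng.uniform(size=nb) > 1 / 2.05).astype(int)
            keep = rng.uniform(size=nb) < surv[0]
            die = rng.uniform(size=len(agrp)) > surv[agrp]
            agrp, sex = agrp[~die], sex[~die]
            mv = rng.uniform(size=len(agrp)) < 0.2
            agrp = np.where(mv & (agrp < n_age - 1), agrp + 1, agrp)
            agrp = np.concatenate([agrp, np.zeros(keep.sum(), dtype=int)])
            sex = np.concatenate([sex, bsex[keep]])
        micro = len(agrp) / scale
        det = states[T].total()
        se = np.sqrt(len(agrp)) / scale
        assert abs(micro - det) < 3 * se

    def test_bad_horizon_rejected(self, setup):
        _, rates, base, *_ = setup
        with pytest.raises(ValueError):
            project_ccmpp(base, rates, MigrationSchedule.zero(), 0)


class TestCensusLoglik:
    def test_exact_census_maximises_density(self, setup):
        _, rates, base, *_ = setup
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 10)
        census = states[5].copy()
        best = census_loglik(states, [census], 0.03)
        for factor in (0.97, 1.03):
            worse = PopulationState({s: v * factor for s, v in census.counts.items()},
                                    census.age_starts, census.date)
            assert census_loglik(states, [worse], 0.03) < best

    def test_wider_sd_tolerates_discrepancy(self, setup):
        _, rates, base, *_ = setup
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 10)
        off = PopulationState({s: v * 1.1 for s, v in states[5].counts.items()},
                              states[5].age_starts, states[5].date)
        assert census_loglik(states, [off], 0.06) > census_loglik(states, [off], 0.03)

    def test_matches_closed_form_oracle(self, setup):
        _, rates, base, *_ = setup
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 6)
        rng = np.random.default_rng(1)
        census = PopulationState(
            {s: v * np.exp(rng.normal(0, 0.05, len(v)))
             for s, v in states[3].counts.items()},
            states[3].age_starts, states[3].date)
        sd = 0.04
        got = census_loglik(states, [census], sd)
        oracle = 0.0
        for s in ("female", "male"):
            z = (np.log(census.counts[s]) - np.log(states[3].counts[s])) / sd
            oracle += np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2 * np.pi))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_zero_projection_positive_census_rejected(self, setup):
        grid, rates, base, *_ = setup
        dead = PopulationState({"female": np.zeros(grid.n), "male": np.zeros(grid.n)},
                               grid.boundaries, 1960.0)
        census = base.copy()
        with pytest.raises(ValueError):
            census_loglik([dead], [census], 0.03)


def _noisy_censuses(states, years, ages, n_age, rng, sd=0.03):
    out = []
    for cy in years:
        st = states[cy - 1960]
        out.append(PopulationState(
            {s: st.counts[s] * np.exp(rng.normal(0, sd, n_age))
             for s in ("female", "male")}, ages, float(cy)))
    return out


class TestBCCMP:
    def test_baseline_recovery_and_seeded_determinism(self, setup):
        grid, rates, base, tb, *_ = setup
        ages = grid.boundaries
        rng = np.random.default_rng(42)
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 26)
        censuses = _noisy_censuses(states, (1965, 1975, 1985), ages, grid.n, rng)
        pb = PopulationState({s: tb * 1.08 for s in ("female", "male")}, ages, 1960.0)
        kw = dict(prior=BCCMPPrior(), horizon=26, n_knots=2, n_draws=200,
                  method="laplace", seed=5, shared_sex=True)
        res = estimate_baseline_migration(pb, rates, censuses, **kw)
        est = res.baseline_draws["female"].mean(axis=0)
        assert np.all(np.abs(est / tb - 1) < 0.08)
        res2 = estimate_baseline_migration(pb, rates, censuses, **kw)
        np.testing.assert_array_equal(res.draws, res2.draws)

    def test_zero_migration_world_concentrates_near_zero(self, setup):
        grid, rates, base, tb, *_ = setup
        ages = grid.boundaries
        rng = np.random.default_rng(7)
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 26)
        censuses = _noisy_censuses(states, (1965, 1975, 1985), ages, grid.n, rng)
        pb = PopulationState({s: tb * 1.05 for s in ("female", "male")}, ages, 1960.0)
        prior = BCCMPPrior()
        res = estimate_baseline_migration(pb, rates, censuses, prior=prior,
                                          horizon=26, n_knots=2, n_draws=200,
                                          method="laplace", seed=2, shared_sex=True)
        assert np.all(np.abs(res.migration_level_draws.mean(axis=0))
                      < prior.migration_level_sd / 2)

    def test_too_few_censuses_rejected(self, setup):
        _, rates, base, *_ = setup
        with pytest.raises(ValueError):
            estimate_baseline_migration(base, rates, [base.copy()])

    def test_rwm_reports_rhat(self, setup):
        grid, rates, base, tb, *_ = setup
        ages = grid.boundaries
        rng = np.random.default_rng(3)
        states, _ = project_ccmpp(base, rates, MigrationSchedule.zero(), 16)
        censuses = _noisy_censuses(states, (1965, 1975), ages, grid.n, rng)
        pb = PopulationState({s: tb * 1.03 for s in ("female", "male")}, ages, 1960.0)
        res = estimate_baseline_migration(pb, rates, censuses, prior=BCCMPPrior(),
                                          horizon=16, n_knots=2, n_draws=120,
                                          method="rwm", seed=4, shared_sex=True)
        assert "split_rhat" in res.diagnostics
        assert "converged" in res.diagnostics


@pytest.fixture(scope="module")
def world(setup):
    grid, rates, base, tb, *_ = setup
    rng = np.random.default_rng(7)
    states, ledger = project_ccmpp(base, rates, MigrationSchedule.zero(), 26)
    deaths = np.array([sum(d[s].sum() for s in ("female", "male"))
                       for d in ledger["deaths"]])
    censuses = _noisy_censuses(states, (1965, 1975, 1985), grid.boundaries,
                               grid.n, rng)
    pb = PopulationState({s: tb * 1.08 for s in ("female", "male")},
                         grid.boundaries, 1960.0)
    return rates, censuses, pb, deaths, rng


class TestBCCMPCompleteness:
    @pytest.mark.parametrize("c_true", [1.0, 0.7])
    def test_completeness_recovery(self, world, c_true):
        rates, censuses, pb, deaths, rng = world
        reg = c_true * deaths * np.exp(np.random.default_rng(int(10 * c_true)).normal(0, 0.05, len(deaths)))
        res = bccmp_completeness(pb, rates, censuses, reg, prior=BCCMPPrior(),
                                 horizon=26, n_knots=2, n_draws=200,
                                 method="laplace", seed=3, shared_sex=True)
        assert res.completeness_draws.mean() == pytest.approx(c_true, abs=0.05)

    def test_no_death_data_reverts_to_prior(self, world):
        """An empty registered-death series leaves the completeness posterior
        at its prior (mean within a small KL-style tolerance)."""
        rates, censuses, pb, _, _ = world
        prior = BCCMPPrior()
        res = bccmp_completeness(pb, rates, censuses, np.array([]), prior=prior,
                                 horizon=26, n_knots=2, n_draws=300,
                                 method="laplace", seed=3, shared_sex=True)
        from scipy.special import expit

        prior_mean_c = expit(prior.completeness_logit_mean)
        assert res.completeness_draws.mean() == pytest.approx(prior_mean_c, abs=0.15)


def test_rogers_castro_shape_normalised():
    ages = np.arange(0.0, 50.0, 5.0)
    s = rogers_castro_shape(ages)
    assert s.sum() == pytest.approx(1.0)
    assert 20.0 <= ages[np.argmax(s)] <= 30.0  # labour-force migration peak
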