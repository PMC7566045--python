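"""Sullivan HALE, SDI, spline ensembles and expected-by-SDI outcomes."""

import numpy as np
import pytest

from demest.ages import build_age_grid
from demest.hale import (
    HealthStateRates,
    SDIBounds,
    SDITriple,
    compute_sdi,
    expected_mortality_le,
    fit_spline_ensemble,
    pearson_correlation,
    rake_expected_fertility,
    sullivan_hale,
)
from demest.lifetable import lifetable_from_mx


class TestSullivan:
    def test_zero_yld_equals_ex(self, gompertz_lt):
        h = sullivan_hale(gompertz_lt, HealthStateRates(np.zeros(gompertz_lt.grid.n)))
        np.testing.assert_allclose(h, gompertz_lt.ex)

    def test_constant_yld_scales_ex(self, gompertz_lt):
        y = 0.12
        h = sullivan_hale(gompertz_lt, HealthStateRates(np.full(gompertz_lt.grid.n, y)))
        np.testing.assert_allclose(h, (1 - y) * gompertz_lt.ex, rtol=1e-12)

    def test_matches_weighted_sum_oracle(self, gompertz_lt):
        rng = np.random.default_rng(0)
        yld = rng.uniform(0, 0.3, gompertz_lt.grid.n)
        h = sullivan_hale(gompertz_lt, HealthStateRates(yld))
        lt = gompertz_lt
        for i in (0, 5, 12):
            oracle = np.sum(lt.Lx[i:] * (1 - yld[i:])) / lt.lx[i]
            assert h[i] == pytest.approx(oracle, rel=1e-12)

    def test_hale_never_exceeds_ex(self, gompertz_lt):
        rng = np.random.default_rng(1)
        yld = rng.uniform(0.0, 0.4, gompertz_lt.grid.n)
        h = sullivan_hale(gompertz_lt, HealthStateRates(yld))
        assert np.all(h <= gompertz_lt.ex + 1e-12)

    def test_poor_health_gap_increasing_in_yld(self, gompertz_lt):
        n = gompertz_lt.grid.n
        gaps = []
        for y in (0.05, 0.10, 0.15):
            h = sullivan_hale(gompertz_lt, HealthStateRates(np.full(n, y)))
            gaps.append(gompertz_lt.e0 - h[0])
        assert gaps[0] < gaps[1] < gaps[2]
        assert all(g >= 0 for g in gaps)

    def test_bad_yld_rejected(self):
        with pytest.raises(ValueError):
            HealthStateRates(np.array([0.1, 1.2]))


class TestSDI:
    B = SDIBounds(income=(250.0, 60000.0), schooling=(0.0, 17.0), tfu25=(3.0, 0.0))

    def test_best_bounds_give_one(self):
        assert compute_sdi(SDITriple(60000.0, 17.0, 0.0), self.B) == pytest.approx(1.0)

    def test_worst_component_annihilates(self):
        assert compute_sdi(SDITriple(250.0, 12.0, 1.0), self.B) == 0.0
        assert compute_sdi(SDITriple(30000.0, 0.0, 1.0), self.B) == 0.0
        assert compute_sdi(SDITriple(30000.0, 12.0, 3.0), self.B) == 0.0

    def test_monotone_in_each_component(self):
        base = compute_sdi(SDITriple(5000.0, 8.0, 2.0), self.B)
        assert compute_sdi(SDITriple(10000.0, 8.0, 2.0), self.B) > base
        assert compute_sdi(SDITriple(5000.0, 10.0, 2.0), self.B) > base
        assert compute_sdi(SDITriple(5000.0, 8.0, 1.5), self.B) > base  # lower fertility

    def test_income_rescale_oracle(self):
        """Doubling income moves the log-scaled index by a constant step."""
        s1 = compute_sdi(SDITriple(2000.0, 17.0, 0.0), self.B)
        s2 = compute_sdi(SDITriple(4000.0, 17.0, 0.0), self.B)
        step = np.log(2) / (np.log(60000.0) - np.log(250.0))
        assert s2**3 - s1**3 == pytest.approx(step, rel=1e-9)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            compute_sdi(SDITriple(1000.0, 8.0, 2.0),
                        SDIBounds(schooling=(5.0, 5.0)))


class TestSplineEnsemble:
    def test_knot_constraints_hold_for_every_member(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 100)
        y = np.sin(2 * x)
        ens = fit_spline_ensemble(x, y, n_models=50, seed=1)
        assert len(ens.members) == 50
        for m in ens.members:
            k = np.asarray(m.knots)
            assert k.min() >= 0.1 - 1e-12
            assert k.max() <= 0.8 + 1e-12
            assert np.all(np.diff(k) >= 0.1 - 1e-12)

    def test_linear_data_fits_exactly_linear(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 60)
        y = 2.0 + 3.0 * x
        ens = fit_spline_ensemble(x, y, seed=3)
        xt = np.array([-0.5, 0.25, 0.9, 1.7])  # includes extrapolation
        np.testing.assert_allclose(ens.predict(xt), 2.0 + 3.0 * xt, atol=1e-6)

    def test_convex_signal_beats_global_line(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 200)
        truth = np.sin(3 * x) + 0.3 * x**2
        y = truth + rng.normal(0, 0.05, len(x))
        ens = fit_spline_ensemble(x, y, seed=5)
        line = np.polyfit(x, y, 1)
        rmse_ens = np.sqrt(np.mean((ens.predict(x) - truth) ** 2))
        rmse_line = np.sqrt(np.mean((np.polyval(line, x) - truth) ** 2))
        assert rmse_ens < rmse_line

    def test_prediction_permutation_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 80)
        y = x**2
        ens = fit_spline_ensemble(x, y, seed=7)
        xt = np.linspace(0, 1, 11)
        p1 = ens.predict(xt)
        order = rng.permutation(len(ens.members))
        ens.members = [ens.members[i] for i in order]
        ens.weights = ens.weights[order]
        np.testing.assert_allclose(ens.predict(xt), p1, rtol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spline_ensemble(np.linspace(0, 1, 10), np.zeros(10))

    def test_trimming_downweights_outliers(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 150)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.02, len(x))
        y[:10] += 5.0  # gross outliers
        plain = fit_spline_ensemble(x, y, seed=9, trim=0.0)
        trimmed = fit_spline_ensemble(x, y, seed=9, trim=0.1)
        truth = 1.0 + 2.0 * x
        err_plain = np.mean((plain.predict(x) - truth) ** 2)
        err_trim = np.mean((trimmed.predict(x) - truth) ** 2)
        assert err_trim < err_plain


@pytest.fixture(scope="module")
def trained():
    """Ensembles trained on a known monotone SDI -> mortality map."""
    grid = build_age_grid("gbd23")
    mids = np.array([s + (w if not np.isnan(w) else 10) / 2
                     for s, w in zip(grid.starts, grid.widths)])
    rng = np.random.default_rng(10)
    sdis = rng.uniform(0.05, 0.95, 80)

    def true_log_mx(sdi):
        # mortality falls log-linearly in SDI, more steeply at young ages
        base = np.log(3e-4 * np.exp(0.09 * mids))
        child = np.exp(-0.15 * mids)
        return base - (1.5 * child + 0.8) * sdi

    ensembles = {}
    for i, a in enumerate(grid.starts):
        y = np.array([true_log_mx(s)[i] for s in sdis])
        y = y + rng.normal(0, 0.05, len(y))
        for sex in ("female", "male"):
            ensembles[(a, sex)] = fit_spline_ensemble(sdis, y, n_models=10,
                                                      seed=100 + i)
    return grid, ensembles, true_log_mx


class TestExpectedMortality:
    def test_expected_e0_recovery(self, trained):
        """Expected e0 within 0.5 years of the truth across test SDIs."""
        grid, ensembles, true_log_mx = trained
        for sdi in (0.2, 0.5, 0.8):
            out = expected_mortality_le(ensembles, sdi, grid)
            lt_true = lifetable_from_mx(np.exp(true_log_mx(sdi)), grid)
            assert abs(out["expected_e0"] - lt_true.e0) < 0.5

    def test_difference_zero_when_observed_equals_expected(self, trained):
        grid, ensembles, _ = trained
        out = expected_mortality_le(ensembles, 0.5, grid)
        again = expected_mortality_le(ensembles, 0.5, grid,
                                      observed_mx=out["expected_mx"])
        assert again["observed_minus_expected"] == pytest.approx(0.0, abs=1e-9)

    def test_extrapolation_flagged(self, trained):
        grid, ensembles, _ = trained
        out = expected_mortality_le(ensembles, 1.2, grid)
        assert out["extrapolated"]

    def test_interior_predictions_within_training_range(self, trained):
        grid, ensembles, true_log_mx = trained
        lo = true_log_mx(0.95) - 0.3
        hi = true_log_mx(0.05) + 0.3
        out = expected_mortality_le(ensembles, 0.5, grid)
        log_pred = np.log(out["expected_mx"])
        assert np.all(log_pred >= lo) and np.all(log_pred <= hi)

    def test_missing_age_group_rejected(self, trained):
        grid, ensembles, _ = trained
        partial = {k: v for k, v in ensembles.items() if k[0] != 15.0}
        with pytest.raises(ValueError):
            expected_mortality_le(partial, 0.5, grid)


class TestRaking:
    def test_consistent_schedule_unchanged(self):
        asfr = {a: 0.1 for a in range(15, 50, 5)}
        out = rake_expected_fertility(asfr, 5.0 * sum(asfr.values()))
        for a in asfr:
            assert out[a] == pytest.approx(asfr[a], rel=1e-12)

    def test_uniform_factor(self):
        asfr = {20: 0.3, 25: 0.2}
        out = rake_expected_fertility(asfr, 2.0)
        assert out[20] / asfr[20] == pytest.approx(0.8)
        assert out[25] / asfr[25] == pytest.approx(0.8)

    def test_round_trip_exact(self):
        rng = np.random.default_rng(11)
        asfr = {a: float(v) for a, v in zip(range(10, 55, 5), rng.uniform(0, 0.3, 9))}
        out = rake_expected_fertility(asfr, 2.34)
        assert 5.0 * sum(out.values()) == pytest.approx(2.34, abs=1e-12)

    def test_zero_schedule_rejected(self):
        with pytest.raises(ValueError):
            rake_expected_fertility({20: 0.0}, 2.0)


class TestPearson:
    def test_affine_relation(self):
        a = np.arange(10.0)
        assert pearson_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=50), rng.normal(size=50)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        oracle = np.mean(za * zb)
        assert pearson_correlation(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
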