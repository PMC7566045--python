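"""Relational model life tables, old-age extension, shocks and assembly."""

import numpy as np
import pytest
from scipy.special import expit

from demest.lifetable import summary_probabilities
from demest.mlt import (
    ShockEvent,
    assemble_all_cause,
    disaggregate_shock,
    extend_old_age,
    fit_relational,
    make_standard_library,
    select_standard,
    vet_standard,
)
from demest.mlt import _relational_lx, _summaries_from_lx


class TestStandardLibrary:
    def test_spans_target_ranges(self, std_library):
        q5s = [s.q5 for s in std_library.standards]
        q45s = [s.q45_15 for s in std_library.standards]
        assert min(q5s) <= 0.003 + 0.001 and max(q5s) >= 0.25
        assert min(q45s) <= 0.06 and max(q45s) >= 0.6

    def test_all_standards_vetted(self, std_library):
        assert all(vet_standard(s) for s in std_library.standards)

    def test_monotone_lx(self, std_library):
        for s in std_library.standards:
            assert np.all(np.diff(s.lx) <= 1e-12)


class TestSelectStandard:
    def test_exact_match_returns_member(self, std_library):
        s0 = std_library.standards[10]
        got = select_standard(std_library, {"5q0": s0.q5, "45q15": s0.q45_15},
                              k=3, sex=s0.sex)
        np.testing.assert_allclose(got, s0.lx)

    def test_k1_nearest_neighbour(self, std_library):
        s0 = std_library.standards[6]
        got = select_standard(
            std_library,
            {"5q0": s0.q5 * 1.001, "45q15": s0.q45_15 * 1.001},
            k=1,
            sex=s0.sex,
        )
        np.testing.assert_allclose(got, s0.lx)

    def test_pooled_lx_monotone(self, std_library):
        got = select_standard(std_library, {"5q0": 0.05, "45q15": 0.25}, k=5)
        assert np.all(np.diff(got) <= 1e-12)

    def test_k_zero_rejected(self, std_library):
        with pytest.raises(ValueError):
            select_standard(std_library, {"5q0": 0.05, "45q15": 0.25}, k=0)


class TestFitRelational:
    def test_identity_when_targets_match_standard(self, std_library, gbd23):
        s0 = std_library.standards[12]
        coef, _ = fit_relational(s0.lx, {"5q0": s0.q5, "45q15": s0.q45_15}, gbd23)
        assert coef.alpha == pytest.approx(0.0, abs=1e-6)
        assert coef.beta == pytest.approx(1.0, abs=1e-6)

    def test_forward_generated_coefficients_recovered(self, std_library, gbd23):
        s0 = std_library.standards[12]
        lx_t = _relational_lx(s0.lx, 0.3, 1.15)
        t5, t45 = _summaries_from_lx(lx_t, gbd23)
        coef, _ = fit_relational(s0.lx, {"5q0": t5, "45q15": t45}, gbd23)
        assert coef.alpha == pytest.approx(0.3, abs=1e-6)
        assert coef.beta == pytest.approx(1.15, abs=1e-6)

    def test_targets_reproduced_to_1e8(self, std_library, gbd23):
        s0 = std_library.standards[20]
        targets = {"5q0": 0.07, "45q15": 0.3}
        _, lt = fit_relational(s0.lx, targets, gbd23)
        s = summary_probabilities(lt)
        assert s["5q0"] == pytest.approx(targets["5q0"], abs=1e-8)
        assert s["45q15"] == pytest.approx(targets["45q15"], abs=1e-8)

    def test_output_lx_strictly_decreasing(self, std_library, gbd23):
        s0 = std_library.standards[8]
        _, lt = fit_relational(s0.lx, {"5q0": 0.05, "45q15": 0.2}, gbd23)
        assert np.all(np.diff(lt.lx[:-1]) < 0)

    def test_45q15_monotone_in_target(self, std_library, gbd23):
        """Raising the adult target never increases survivorship l60/l15."""
        s0 = std_library.standards[12]
        prev = None
        for t45 in (0.15, 0.25, 0.35, 0.45):
            _, lt = fit_relational(s0.lx, {"5q0": 0.05, "45q15": t45}, gbd23)
            ratio = lt.lx_at(60.0) / lt.lx_at(15.0)
            if prev is not None:
                assert ratio <= prev + 1e-12
            prev = ratio

    def test_bad_targets_rejected(self, std_library, gbd23):
        with pytest.raises(ValueError):
            fit_relational(std_library.standards[0].lx, {"5q0": 0.0, "45q15": 0.2}, gbd23)


class TestExtendOldAge:
    @staticmethod
    def kannisto(x, A, B):
        return expit(np.log(A) + B * x)

    def test_kannisto_parameters_recovered(self):
        x = np.arange(60, 90, 5) + 2.5
        mx = self.kannisto(x, 2e-5, 0.11)
        ext = extend_old_age(mx)
        assert ext["B"] == pytest.approx(0.11, rel=0.02)
        assert ext["mx_90_94"] == pytest.approx(self.kannisto(92.5, 2e-5, 0.11), rel=0.03)
        assert ext["mx_95_plus"] == pytest.approx(self.kannisto(100.0, 2e-5, 0.11), rel=0.03)

    def test_extension_non_decreasing(self):
        rng = np.random.default_rng(0)
        mx = np.sort(np.exp(rng.normal(-3, 0.5, 6)))
        ext = extend_old_age(mx)
        assert ext["mx_95_plus"] >= ext["mx_90_94"] >= mx[-1] - 1e-12

    def test_logistic_below_gompertz_for_gompertz_input(self):
        """For Gompertz-generated input the bounded logistic extension sits at
        or below the pure exponential extrapolation at 95+."""
        x = np.arange(60, 90, 5) + 2.5
        A, B = 2e-5, 0.11
        mx = A * np.exp(B * x)
        ext = extend_old_age(mx)
        gompertz_95 = A * np.exp(B * 100.0)
        assert ext["mx_95_plus"] <= gompertz_95 * 1.0001

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            extend_old_age(np.array([0.01, 0.02, 0.03]))

    def test_non_positive_rates_rejected(self):
        with pytest.raises(ValueError):
            extend_old_age(np.array([0.01, 0.0, 0.03, 0.05]))

    def test_monotone_hazard_above_60_for_all_standards(self, std_library, gbd23):
        """Relational table + extension yields a monotone old-age hazard for
        every library standard."""
        i60 = gbd23.index_of(60.0)
        i90 = gbd23.index_of(90.0)
        for s in std_library.standards[::5]:
            _, lt = fit_relational(s.lx, {"5q0": s.q5, "45q15": s.q45_15}, gbd23)
            mx_in = lt.mx[i60:i90]
            ext = extend_old_age(mx_in)
            seq = np.concatenate([mx_in, [ext["mx_90_94"], ext["mx_95_plus"]]])
            assert np.all(np.diff(seq) > -1e-9)


class TestShocks:
    @pytest.fixture()
    def pop_pattern(self):
        population = {("male", a): 1000.0 for a in (15.0, 25.0, 35.0)}
        population.update({("female", a): 1000.0 for a in (15.0, 25.0, 35.0)})
        pattern = {("male", a): 3.0 for a in (15.0, 25.0, 35.0)}
        pattern.update({("female", a): 1.0 for a in (15.0, 25.0, 35.0)})
        return population, pattern

    def test_total_conserved(self, pop_pattern):
        population, pattern = pop_pattern
        ev = ShockEvent("x", 1994, "conflict", 5000.0)
        out = disaggregate_shock(ev, population, pattern)
        assert sum(out.values()) == pytest.approx(5000.0, rel=1e-12)

    def test_uniform_pattern_proportional_to_population(self):
        population = {("male", 10.0): 100.0, ("male", 20.0): 300.0}
        pattern = {("male", 10.0): 1.0, ("male", 20.0): 1.0}
        out = disaggregate_shock(ShockEvent("x", 1990, "quake", 40.0), population, pattern)
        assert out[("male", 10.0)] == pytest.approx(10.0)
        assert out[("male", 20.0)] == pytest.approx(30.0)

    def test_conflict_pattern_matches_direct_oracle(self, pop_pattern):
        population, pattern = pop_pattern
        ev = ShockEvent("x", 1994, "conflict", 1000.0)
        out = disaggregate_shock(ev, population, pattern)
        w = {k: pattern[k] * population[k] for k in population}
        tot = sum(w.values())
        for k in population:
            assert out[k] == pytest.approx(1000.0 * w[k] / tot, rel=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            disaggregate_shock(ShockEvent("x", 1990, "quake", 10.0),
                               {("male", 10.0): 100.0}, {("male", 10.0): 0.0})


class TestAssembleAllCause:
    def test_no_hiv_no_shock_is_identity(self, gompertz_lt, gbd23):
        py = np.full(gbd23.n, 1e4)
        deaths, lt = assemble_all_cause(gompertz_lt.mx, gbd23, py)
        np.testing.assert_allclose(lt.mx, gompertz_lt.mx)
        np.testing.assert_allclose(deaths, gompertz_lt.mx * py)

    def test_death_counts_additive(self, gompertz_lt, gbd23):
        py = np.full(gbd23.n, 1e4)
        hiv = np.full(gbd23.n, 0.001)
        shock = np.full(gbd23.n, 5.0)
        deaths, _ = assemble_all_cause(gompertz_lt.mx, gbd23, py, hiv, shock)
        np.testing.assert_allclose(deaths, gompertz_lt.mx * py + hiv * py + shock, rtol=1e-12)

    def test_positive_shock_reduces_e0(self, gompertz_lt, gbd23):
        py = np.full(gbd23.n, 1e4)
        base = assemble_all_cause(gompertz_lt.mx, gbd23, py)[1].e0
        shocked = assemble_all_cause(
            gompertz_lt.mx, gbd23, py, shock_deaths=np.full(gbd23.n, 20.0)
        )[1].e0
        assert shocked < base

    def test_negative_components_rejected(self, gompertz_lt, gbd23):
        py = np.full(gbd23.n, 1e4)
        with pytest.raises(ValueError):
            assemble_all_cause(gompertz_lt.mx, gbd23, py, hiv_mx=np.full(gbd23.n, -0.01))
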