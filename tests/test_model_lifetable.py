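"""Model life table system tests: standards, relational fits, HIV, shocks."""

import numpy as np
import pandas as pd
import pytest

from mortality_engine.demographic_core import AgeGrid, AgeSchedule, Sex
from mortality_engine.model_lifetable import (
    EXTENDED_AGES,
    EmpiricalLifeTableLibrary,
    HIVInputs,
    ShockEvent,
    apply_shocks,
    fit_relational,
    fit_relational_many,
    hiv_overlay,
    lifetable_from_lx,
    reconcile_hiv,
    select_standard,
    summary_from_lx,
)
from mortality_engine.synthetic import baseline_standard

GRID = AgeGrid.gbd()


def _brass(std, alpha, beta):
    l = np.clip(std[1:], 1e-12, 1 - 1e-12)
    y = 0.5 * np.log((1 - l) / l)
    out = np.empty_like(std)
    out[0] = 1.0
    out[1:] = 1.0 / (1.0 + np.exp(2.0 * (alpha + beta * y)))
    return np.minimum.accumulate(out)


def _library(n=30, seed=0):
    rng = np.random.default_rng(seed)
    std = {s: baseline_standard(Sex(s)) for s in ("male", "female")}
    rows = []
    for i in range(n):
        sex = "male" if i % 2 else "female"
        lx = _brass(std[sex], rng.uniform(-0.5, 0.5), rng.uniform(0.85, 1.15))
        row = {
            "location": f"L{i % 5:02d}",
            "region": f"R{i % 2}",
            "year": 1970 + (i * 3) % 47,
            "sex": sex,
            "quality": "vr",
        }
        row.update({f"lx_{j}": lx[j] for j in range(len(EXTENDED_AGES))})
        rows.append(row)
    return EmpiricalLifeTableLibrary(pd.DataFrame(rows))


class TestSelectStandard:
    def test_exact_same_location_year_entry_gets_weight_one(self):
        lib = _library()
        sub, lx = lib.lx_matrix(Sex.FEMALE)
        target = summary_from_lx(EXTENDED_AGES, lx[0])
        std, table = select_standard(
            target, sub["location"].iloc[0], float(sub["year"].iloc[0]),
            lib, Sex.FEMALE,
        )
        assert table["weight"].iloc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(std, lx[0], atol=1e-9)

    def test_weights_nonnegative_and_sum_to_one(self):
        lib = _library()
        rng = np.random.default_rng(1)
        for _ in range(5):
            target = (rng.uniform(0.02, 0.2), rng.uniform(0.08, 0.4))
            _, table = select_standard(target, "LXX", 1995.0, lib, Sex.MALE)
            assert (table["weight"] >= 0).all()
            assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_distance_ranking_matches_brute_force(self):
        """With uniform proximity (same location and year for everyone),
        the k nearest entries by logit-space distance are selected."""
        lib = _library()
        sub, lx = lib.lx_matrix(Sex.FEMALE)
        # neutralise space-time preference by pointing at a foreign location
        target = (0.07, 0.2)
        _, table = select_standard(
            target, "NOWHERE", 3000.0, lib, Sex.FEMALE, k=3, time_scale=1e9,
            space_discount=1.0,
        )
        def lg(p):
            return np.log(p / (1 - p))
        qs = np.array([summary_from_lx(EXTENDED_AGES, row) for row in lx])
        d = np.hypot(lg(qs[:, 0]) - lg(target[0]), lg(qs[:, 1]) - lg(target[1]))
        expected = set(np.argsort(d)[:3])
        got = set(
            sub.reset_index(drop=True).index[
                sub.reset_index(drop=True)
                .merge(table, on=["location", "year"], how="inner")
                .index
            ]
        )
        # compare via distances instead of indices (ties in merge):
        got_d = sorted(table["distance"].to_numpy())
        exp_d = sorted(d[list(expected)])
        np.testing.assert_allclose(got_d, exp_d, atol=1e-12)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalLifeTableLibrary(pd.DataFrame())


class TestFitRelational:
    def test_identity_when_targets_equal_standard(self):
        std = baseline_standard(Sex.FEMALE)
        q5, q45 = summary_from_lx(EXTENDED_AGES, std)
        fit = fit_relational(std, q5, q45)
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)
        assert fit.beta == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.fitted_lx, std, atol=1e-9)

    def test_closure_for_random_feasible_targets(self):
        """100 random feasible targets reproduced to 1e-6 in probability
        space (targets drawn from the relational family itself)."""
        std = baseline_standard(Sex.MALE)
        rng = np.random.default_rng(2)
        for _ in range(100):
            lx = _brass(std, rng.uniform(-0.6, 0.6), rng.uniform(0.7, 1.4))
            t5, t45 = summary_from_lx(EXTENDED_AGES, lx)
            fit = fit_relational(std, t5, t45)
            assert abs(fit.achieved_5q0 - t5) < 1e-6
            assert abs(fit.achieved_45q15 - t45) < 1e-6

    def test_out_of_range_target_rejected(self):
        std = baseline_standard(Sex.MALE)
        with pytest.raises(ValueError):
            fit_relational(std, 0.05, 1.2)

    def test_vectorised_fit_agrees_with_scalar(self):
        std = baseline_standard(Sex.FEMALE)
        fit = fit_relational(std, 0.08, 0.3)
        many = fit_relational_many(std, np.array([0.08]), np.array([0.3]))
        np.testing.assert_allclose(many[0], fit.fitted_lx, atol=1e-8)

    def test_lifetable_from_lx_consistent_with_summaries(self):
        std = baseline_standard(Sex.FEMALE)
        lt = lifetable_from_lx(std, GRID)
        q5, q45 = summary_from_lx(EXTENDED_AGES, std)
        assert 1 - lt.lx[GRID.index_of_age(5.0)] == pytest.approx(q5, abs=1e-12)
        assert lt.Tx[0] == pytest.approx(lt.Lx.sum(), abs=1e-9)


class TestHIV:
    def _inputs(self, cdr, rr=None, pop=None):
        rr_vals = rr if rr is not None else np.ones(23)
        pop_vals = pop if pop is not None else np.full(23, 1000.0)
        return HIVInputs(
            cdr=cdr,
            relative_risk=AgeSchedule(GRID, Sex.BOTH, rr_vals),
            population=AgeSchedule(GRID, Sex.BOTH, pop_vals),
        )

    def test_zero_cdr_is_identity(self):
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        out = hiv_overlay(mx, self._inputs(0.0))
        np.testing.assert_array_equal(out.values, mx.values)

    def test_added_deaths_equal_cdr_times_population(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(0, 1, 23)
        pop = rng.uniform(100, 5000, 23)
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        cdr = 0.004
        out = hiv_overlay(mx, self._inputs(cdr, rr, pop))
        added_deaths = ((out.values - mx.values) * pop).sum()
        assert added_deaths == pytest.approx(cdr * pop.sum(), abs=1e-10)
        assert np.all(out.values >= mx.values)

    def test_uniform_pattern_adds_cdr_everywhere(self):
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        out = hiv_overlay(mx, self._inputs(0.002))
        np.testing.assert_allclose(out.values - mx.values, 0.002, atol=1e-15)

    def test_cdr_without_risk_pattern_rejected(self):
        with pytest.raises(ValueError):
            self._inputs(0.01, rr=np.zeros(23))

    def test_reconcile_is_elementwise_mean(self):
        a = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.002))
        b = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.004))
        out = reconcile_hiv(a, b)
        np.testing.assert_allclose(out.values, 0.003)
        same = reconcile_hiv(a, a)
        np.testing.assert_array_equal(same.values, a.values)

    def test_e0_monotone_nonincreasing_in_cdr(self):
        from mortality_engine.demographic_core import build_abridged_lifetable
        from mortality_engine.synthetic import hiv_relative_risk_pattern

        base = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.008))
        rr = hiv_relative_risk_pattern()
        pop = np.full(23, 1000.0)
        e0s = []
        for cdr in [0.0, 0.001, 0.003, 0.006, 0.01]:
            out = hiv_overlay(
                base,
                HIVInputs(cdr, AgeSchedule(GRID, Sex.BOTH, rr),
                          AgeSchedule(GRID, Sex.BOTH, pop)),
            )
            e0s.append(build_abridged_lifetable(out).e0)
        assert all(a >= b for a, b in zip(e0s, e0s[1:]))


class TestShocks:
    POP = AgeSchedule(GRID, Sex.BOTH, np.full(23, 10_000_000 / 23))

    def test_rate_clause_includes_moderate_event(self):
        """50 deaths in 10 million: 5 per million exceeds 1 per million."""
        ev = ShockEvent("X", 2000, "disaster", 50.0)
        _, report = apply_shocks(
            AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01)), [ev], self.POP
        )
        assert report["included"].iloc[0]

    def test_count_clause_includes_large_event_in_huge_population(self):
        pop = AgeSchedule(GRID, Sex.BOTH, np.full(23, 1_000_000_000 / 23))
        ev = ShockEvent("X", 2000, "conflict", 120.0)
        _, report = apply_shocks(
            AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01)), [ev], pop
        )
        assert report["included"].iloc[0]

    def test_event_below_both_thresholds_excluded(self):
        pop = AgeSchedule(GRID, Sex.BOTH, np.full(23, 1_000_000_000 / 23))
        ev = ShockEvent("X", 2000, "transport", 80.0)
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        out, report = apply_shocks(mx, [ev], pop)
        assert not report["included"].iloc[0]
        assert report["reason"].iloc[0] == "below both thresholds"
        np.testing.assert_array_equal(out.values, mx.values)

    def test_added_deaths_conserved(self):
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        events = [
            ShockEvent("X", 2000, "conflict", 500.0),
            ShockEvent("X", 2000, "epidemic", 3000.0),
        ]
        out, report = apply_shocks(mx, events, self.POP)
        added = ((out.values - mx.values) * self.POP.values).sum()
        assert added == pytest.approx(3500.0, abs=1e-8)

    def test_empty_event_list_is_identity(self):
        mx = AgeSchedule(GRID, Sex.BOTH, np.full(23, 0.01))
        out, report = apply_shocks(mx, [], self.POP)
        np.testing.assert_array_equal(out.values, mx.values)
        assert len(report) == 0

    def test_nonpositive_deaths_rejected(self):
        with pytest.raises(ValueError):
            ShockEvent("X", 2000, "conflict", 0.0)


class TestEndToEndClosure:
    def test_fit_then_remeasure_returns_targets(self):
        """Building the life table from the relational fit and re-measuring
        5q0 and 45q15 returns the requested targets to 1e-6."""
        std = baseline_standard(Sex.MALE)
        rng = np.random.default_rng(9)
        for _ in range(20):
            lx_t = _brass(std, rng.uniform(-0.5, 0.5), rng.uniform(0.8, 1.25))
            t5, t45 = summary_from_lx(EXTENDED_AGES, lx_t)
            fit = fit_relational(std, t5, t45)
            lt = lifetable_from_lx(fit.fitted_lx, GRID)
            q5 = 1 - lt.lx[GRID.index_of_age(5.0)]
            q45 = 1 - lt.lx[GRID.index_of_age(60.0)] / lt.lx[GRID.index_of_age(15.0)]
            assert abs(q5 - t5) < 1e-6
            assert abs(q45 - t45) < 1e-6
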