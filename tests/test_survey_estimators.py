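"""Survey estimator tests: birth histories, sibling histories, bias
adjustment."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from mortality_engine.survey_estimators import (
    CBH_AGE_SEGMENTS_MONTHS,
    SiblingCorrections,
    cbh_direct_5q0,
    sbh_indirect_5q0,
    sibling_45q15,
    sibling_death_rate,
    source_bias_adjust,
)


def _births_frame(birth_dates, death_dates, survey=2010.5, mothers=None):
    n = len(birth_dates)
    return pd.DataFrame(
        {
            "mother_id": mothers if mothers is not None else np.arange(n),
            "birth_date": birth_dates,
            "death_date": death_dates,
            "survey_date": survey,
            "weight": 1.0,
        }
    )


class TestCBH:
    def test_all_children_survive(self):
        df = _births_frame([2000.1, 2001.2, 2002.3], [np.nan] * 3)
        q5, var = cbh_direct_5q0(df, (2000.0, 2008.0))
        assert q5 == 0.0
        assert var >= 0

    def test_all_children_die_before_five(self):
        births = [2000.1, 2000.5, 2001.0]
        deaths = [b + 0.3 for b in births]
        q5, _ = cbh_direct_5q0(_births_frame(births, deaths), (2000.0, 2002.0))
        assert q5 == 1.0

    def test_empty_exposure_raises(self):
        df = _births_frame([2000.0], [np.nan])
        with pytest.raises(ValueError):
            cbh_direct_5q0(df, (1980.0, 1985.0))

    def test_equals_kaplan_meier_product_without_censoring(self):
        """On censoring-free data the synthetic-cohort estimate equals the
        Kaplan-Meier product over age segments."""
        rng = np.random.default_rng(5)
        n = 3000
        births = rng.uniform(2000, 2004, n)
        u = rng.random(n)
        death_age = np.where(u < 0.08, rng.uniform(0, 5, n) ** 2 / 5.0, np.nan)
        deaths = births + death_age
        df = _births_frame(births, deaths, survey=2015.5)
        # the window covers every segment entry, so no child is excluded
        q5, _ = cbh_direct_5q0(df, (2000.0, 2010.0))

        bounds = np.array(CBH_AGE_SEGMENTS_MONTHS) / 12.0
        surv = 1.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            at_risk = np.isnan(death_age) | (death_age >= lo)
            died = (death_age >= lo) & (death_age < hi)
            surv *= 1.0 - died.sum() / at_risk.sum()
        assert q5 == pytest.approx(1.0 - surv, abs=1e-10)

    def test_recovers_known_5q0_at_large_sample(self):
        """50 000 simulated births at true 5q0 = 0.080 recover within
        +/- 0.005."""
        rng = np.random.default_rng(12)
        n = 50_000
        births = rng.uniform(1995, 2005, n)
        # deaths concentrated in infancy, total probability 0.080
        u = rng.random(n)
        death_age = np.where(u < 0.080, 5.0 * rng.random(n) ** 3, np.nan)
        df = _births_frame(births, births + death_age, survey=2012.5,
                           mothers=np.arange(n) // 4)
        q5, var = cbh_direct_5q0(df, (1995.0, 2006.0))
        assert 0.075 <= q5 <= 0.085
        assert var > 0

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)

        def run(n):
            births = rng.uniform(2000, 2005, n)
            u = rng.random(n)
            deaths = births + np.where(u < 0.1, rng.uniform(0, 5, n), np.nan)
            df = _births_frame(births, deaths, survey=2012.5,
                               mothers=np.arange(n) // 3)
            return cbh_direct_5q0(df, (2000.0, 2006.0))[1]

        assert run(8000) < run(500)


class TestSBH:
    def test_no_deaths_gives_zero_everywhere(self):
        df = pd.DataFrame(
            {
                "mother_age_group": ["20-24", "25-29"],
                "ceb": [100, 150],
                "cs": [100, 150],
                "survey_date": 2010.5,
            }
        )
        out = sbh_indirect_5q0(df)
        assert np.allclose(out["q5"], 0.0)

    def test_identity_coefficients_return_raw_proportions(self):
        df = pd.DataFrame(
            {
                "mother_age_group": ["20-24"],
                "ceb": [200],
                "cs": [180],
                "survey_date": 2010.5,
            }
        )
        coef = pd.DataFrame(
            {"age_group": ["20-24"], "multiplier": [1.0], "time_shift": [0.0]}
        )
        out = sbh_indirect_5q0(df, coef)
        assert out["q5"].iloc[0] == pytest.approx(0.1)
        assert out["reference_year"].iloc[0] == pytest.approx(2010.5)

    def test_younger_mothers_map_to_more_recent_dates(self):
        df = pd.DataFrame(
            {
                "mother_age_group": ["20-24", "40-44"],
                "ceb": [100, 300],
                "cs": [95, 270],
                "survey_date": 2010.5,
            }
        )
        out = sbh_indirect_5q0(df).set_index("mother_age_group")
        assert (
            out.loc["20-24", "reference_year"] > out.loc["40-44", "reference_year"]
        )

    def test_missing_age_group_in_table_raises(self):
        df = pd.DataFrame(
            {
                "mother_age_group": ["17-19"],
                "ceb": [10],
                "cs": [9],
                "survey_date": 2010.5,
            }
        )
        with pytest.raises(KeyError):
            sbh_indirect_5q0(df)

    def test_recovers_constant_mortality_world(self, small_world):
        """Dated SBH estimates sit within +/-0.015 of the truth at their
        reference dates in the synthetic world."""
        errs = []
        for (loc, sy), sub in small_world.sbh.groupby(["location", "survey_year"]):
            est = sbh_indirect_5q0(sub)
            for _, r in est.iterrows():
                t = int(
                    np.clip(
                        round(r["reference_year"] - small_world.years[0]),
                        0,
                        len(small_world.years) - 1,
                    )
                )
                truth = small_world.truth_q5_both(loc)[t]
                errs.append(r["q5"] - truth)
        assert abs(float(np.median(errs))) < 0.015


def _toy_sibling_world():
    """Six fully tabulated sibships; deaths and exposure known exactly."""
    sibships = [
        # (sibship, [(birth, death_or_None), ...])
        (0, [(1970, None), (1972, 1999.5), (1975, None)]),
        (1, [(1968, None)]),
        (2, [(1973, None), (1974, 1996.2)]),
        (3, [(1971, 1997.8), (1976, None), (1978, None), (1980, None)]),
        (4, [(1969, None), (1970, None)]),
        (5, [(1977, None), (1979, 1995.1), (1981, None)]),
    ]
    return sibships


def _census_death_rate(sibships, period):
    t0, t1 = period
    D = E = 0.0
    for _, members in sibships:
        for birth, death in members:
            end = death if death is not None else np.inf
            for a in range(15, 60, 5):
                s = max(birth + a, t0)
                e = min(birth + a + 5, t1, end)
                E += max(e - s, 0.0)
                if death is not None and birth + a <= death < birth + a + 5:
                    if t0 <= death < t1:
                        D += 1.0
    return D / E


def _reports_from_interviewing_every_survivor(sibships, survey_year=2005):
    rows = []
    resp_id = 0
    for sid, members in sibships:
        survivors = [
            i
            for i, (b, d) in enumerate(members)
            if d is None and 15 <= survey_year - b < 50
        ]
        S = len(survivors)
        for _ in survivors:
            for b, d in members:
                rows.append(
                    {
                        "respondent_id": resp_id,
                        "sibship_size": len(members),
                        "n_surviving": S,
                        "birth_year": float(b),
                        "death_year": float(d) if d is not None else np.nan,
                        "weight": 1.0,
                    }
                )
            resp_id += 1
    return pd.DataFrame(rows)


class TestSibling:
    def test_gk_weighting_exactly_unbiased_on_enumerated_world(self):
        """Interviewing every surviving eligible sibling, the 1/S-weighted
        death rate equals the brute-force census death rate to 1e-12."""
        sibships = _toy_sibling_world()
        period = (1995.0, 2000.0)
        reports = _reports_from_interviewing_every_survivor(sibships)
        est = sibling_death_rate(reports, period)
        truth = _census_death_rate(sibships, period)
        assert est == pytest.approx(truth, abs=1e-12)

    def test_singleton_sibships_equal_naive_rate(self):
        """All sibships of size one: weights are all 1 and the corrected
        estimator equals the uncorrected one."""
        sibships = [(i, [(1965 + i, 1998.0 if i % 3 == 0 else None)]) for i in range(9)]
        reports = _reports_from_interviewing_every_survivor(sibships)
        period = (1995.0, 2000.0)
        corrected = sibling_death_rate(reports, period)
        naive = sibling_death_rate(
            reports, period, SiblingCorrections(selection=False, zero_reporter=False)
        )
        assert corrected == pytest.approx(naive, abs=1e-14)

    def test_zero_surviving_report_rejected(self):
        df = pd.DataFrame(
            {
                "respondent_id": [0],
                "sibship_size": [2],
                "n_surviving": [0],
                "birth_year": [1970.0],
                "death_year": [np.nan],
            }
        )
        with pytest.raises(ValueError, match="impossible"):
            sibling_45q15(df, (1990.0, 2000.0))

    def test_no_exposure_raises(self):
        df = pd.DataFrame(
            {
                "respondent_id": [0],
                "sibship_size": [1],
                "n_surviving": [1],
                "birth_year": [2004.0],
                "death_year": [np.nan],
            }
        )
        with pytest.raises(ValueError, match="exposure"):
            sibling_45q15(df, (1990.0, 2000.0))

    def test_recovers_known_q45_with_large_sample(self):
        """20 000 respondents from a world with true 45q15 = 0.25 recover
        an estimate in [0.22, 0.28], despite survivor-only reporting."""
        rng = np.random.default_rng(77)
        survey_year = 2005
        n_sibships = 40_000
        sizes = 1 + rng.poisson(3.0, n_sibships)
        total = sizes.sum()
        sid = np.repeat(np.arange(n_sibships), sizes)
        anchor = rng.integers(survey_year - 49, survey_year - 15, n_sibships)
        birth = np.repeat(anchor, sizes) + rng.integers(-6, 7, total)
        # constant adult hazard calibrated to 45q15 = 0.25 over ages 15-60
        q45_true = 0.25
        mu = -np.log(1 - q45_true) / 45.0
        age_at_survey = survey_year - birth
        # death age sampled from the exponential beyond 15; before 15 immortal
        u = rng.random(total)
        death_age = 15.0 - np.log(u) / mu
        died = death_age < age_at_survey
        death_year = np.where(died, birth + death_age, np.nan)
        alive = ~died
        eligible = alive & (age_at_survey >= 15) & (age_at_survey < 50)
        S = np.bincount(sid[eligible], minlength=n_sibships)
        pool = np.nonzero(eligible)[0]
        respondents = rng.choice(pool, 20_000, replace=False)
        rows = []
        order = np.argsort(sid, kind="stable")
        starts = np.searchsorted(sid[order], np.arange(n_sibships))
        ends = np.searchsorted(sid[order], np.arange(n_sibships), side="right")
        frames = []
        for r_i, person in enumerate(respondents):
            j = sid[person]
            mem = order[starts[j]:ends[j]]
            frames.append(
                pd.DataFrame(
                    {
                        "respondent_id": r_i,
                        "sibship_size": sizes[j],
                        "n_surviving": S[j],
                        "birth_year": birth[mem].astype(float),
                        "death_year": death_year[mem],
                        "weight": 1.0,
                    }
                )
            )
        reports = pd.concat(frames, ignore_index=True)
        q45, var = sibling_45q15(reports, (2000.0, 2005.0))
        assert 0.22 <= q45 <= 0.28
        assert var > 0

    def test_gk_correction_removes_most_selection_bias(self, default_world):
        """Survivor-only reporting biases the naive estimator down; the
        GK-weighted estimator removes at least 80% of that bias."""
        sib = default_world.siblings
        naive_err, gk_err = [], []
        for (loc, sy), sub in itertools.islice(
            sib.groupby(["location", "survey_year"]), 20
        ):
            for sex in ("male", "female"):
                ss = sub[sub["sex"] == sex]
                for a, b in ((sy - 10, sy - 5),):
                    t = int(np.clip((a + b) / 2 - 1970, 0, 46))
                    truth = default_world.truth_q45[(loc, sex)][t]
                    try:
                        q_n, _ = sibling_45q15(
                            ss, (float(a), float(b)),
                            SiblingCorrections(False, False), age_smooth="none",
                        )
                        q_g, _ = sibling_45q15(
                            ss, (float(a), float(b)),
                            SiblingCorrections(True, True), age_smooth="none",
                        )
                    except ValueError:
                        continue
                    naive_err.append(q_n - truth)
                    gk_err.append(q_g - truth)
        naive_bias = float(np.mean(naive_err))
        gk_bias = float(np.mean(gk_err))
        assert naive_bias < 0  # survivor selection biases mortality down
        assert abs(gk_bias) <= 0.2 * abs(naive_bias) + 0.005


class TestSourceBiasAdjust:
    def _obs(self):
        years = np.arange(1990.0, 2006.0)
        truth = 0.1 * 0.98 ** (years - 1990)
        ref = pd.DataFrame(
            {
                "location": "A",
                "year": years,
                "value": truth,
                "variance": 1e-6,
                "source_type": "cbh",
            }
        )
        biased = ref.copy()
        biased["source_type"] = "sbh"
        biased["value"] = 1 / (1 + (1 - truth) / truth / np.exp(0.2))  # +0.2 logit
        return pd.concat([ref, biased], ignore_index=True)

    def test_single_source_returned_unchanged(self):
        obs = self._obs()
        only = obs[obs["source_type"] == "cbh"]
        out, offsets = source_bias_adjust(only, "cbh")
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), only.reset_index(drop=True)
        )
        assert offsets == {"cbh": 0.0}

    def test_constant_log_offset_removed(self):
        """A source with a +0.2 logit offset is brought back onto the
        reference within 0.02."""
        out, offsets = source_bias_adjust(self._obs(), "cbh")
        assert offsets["sbh"] == pytest.approx(0.2, abs=0.02)
        adj = out[out["source_type"] == "sbh"]["value"].to_numpy()
        ref = out[out["source_type"] == "cbh"]["value"].to_numpy()
        assert np.max(np.abs(adj - ref)) < 0.02 * ref.mean() + 0.002

    def test_reference_rows_unchanged(self):
        obs = self._obs()
        out, _ = source_bias_adjust(obs, "cbh")
        np.testing.assert_allclose(
            out[out["source_type"] == "cbh"]["value"],
            obs[obs["source_type"] == "cbh"]["value"],
            atol=1e-12,
        )

    def test_disjoint_years_without_pooling_warn_and_pass_through(self):
        obs = self._obs()
        obs.loc[obs["source_type"] == "sbh", "year"] += 50  # no overlap
        obs.loc[obs["source_type"] == "sbh", "location"] = "B"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out, offsets = source_bias_adjust(obs, "cbh", allow_pooling=False)
        assert any("overlap" in str(w.message) for w in caught)
        assert offsets["sbh"] == 0.0

    def test_missing_reference_raises(self):
        obs = self._obs()
        with pytest.raises(ValueError):
            source_bias_adjust(obs, "vr")
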