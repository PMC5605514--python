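"""ST-GPR engine tests: prior, smoothing, GP conditioning, composition."""

import numpy as np
import pandas as pd
import pytest

from mortality_engine.stgpr import (
    STGPRConfig,
    back_transform,
    estimate_nonsampling_variance,
    fit_prior,
    gpr_posterior,
    spacetime_smooth,
    stgpr_estimate,
)
from mortality_engine.stgpr import _kernel_matrix, _tricube

HIER = pd.DataFrame(
    {"location": ["A", "B", "C"], "region": ["R1", "R1", "R2"]}
)


def _covs(years=range(1990, 2011)):
    rows = []
    for loc in ["A", "B", "C"]:
        for y in years:
            rows.append({"location": loc, "year": y, "x": 0.1 * (y - 2000)})
    return pd.DataFrame(rows)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            STGPRConfig(lambda_t=0.0)
        with pytest.raises(ValueError):
            STGPRConfig(zeta=1.5)
        with pytest.raises(ValueError):
            STGPRConfig(n_draws=1)


class TestPrior:
    def test_intercept_only_constant_observations(self):
        obs = pd.DataFrame(
            {
                "location": ["A"] * 5 + ["B"] * 5,
                "year": list(range(1995, 2000)) * 2,
                "value": -2.0,
                "variance": 0.01,
            }
        )
        cfg = STGPRConfig(covariates=())
        prior = fit_prior(obs, _covs(), HIER, cfg)
        np.testing.assert_allclose(prior["prior"], -2.0, atol=1e-8)

    def test_exact_linear_function_recovered(self):
        covs = _covs()
        obs = covs.rename(columns={"x": "value"}).copy()
        obs["value"] = 1.5 + 2.0 * covs["x"]
        obs["variance"] = 1.0
        cfg = STGPRConfig(covariates=("x",))
        prior = fit_prior(obs, covs, HIER, cfg)
        merged = prior.merge(covs, on=["location", "year"])
        np.testing.assert_allclose(
            merged["prior"], 1.5 + 2.0 * merged["x"], atol=1e-8
        )

    def test_data_free_location_inherits_parent_fit(self):
        covs = _covs()
        obs = pd.DataFrame(
            {
                "location": ["A"] * 6,
                "year": range(1995, 2001),
                "value": -1.0,
                "variance": 0.01,
            }
        )
        cfg = STGPRConfig(covariates=())
        prior = fit_prior(obs, covs, HIER, cfg)
        # B shares A's region and pools toward it; C (other region) gets the
        # global level
        b = prior[prior["location"] == "B"]["prior"].iloc[0]
        c = prior[prior["location"] == "C"]["prior"].iloc[0]
        assert b == pytest.approx(-1.0, abs=0.2)
        assert np.isfinite(c)


class TestSpacetimeSmooth:
    def test_zero_residuals_give_zeros(self):
        res = pd.DataFrame(
            {"location": ["A", "B"], "year": [2000, 2001], "resid": [0.0, 0.0]}
        )
        out = spacetime_smooth(res, HIER, 10.0, 0.7)
        assert np.allclose(out["smoothed"], 0.0)

    def test_hand_computed_tricube_weights(self):
        """Single residual r at year t: the tricube weight at t+-1 matches
        (1-(1/lambda)^3)^3 computed by hand, and the own-location component
        carries at least the zeta share."""
        lam = 5.0
        w1 = (1 - (1 / lam) ** 3) ** 3
        np.testing.assert_allclose(_tricube(np.array([1.0]), lam), [w1], atol=1e-12)
        res = pd.DataFrame({"location": ["A"], "year": [2000], "resid": [1.0]})
        out = spacetime_smooth(
            res, HIER, lam, 0.7,
            targets=pd.DataFrame({"location": ["A"] * 3, "year": [1999, 2000, 2001]}),
            density_scale=0.0,
        )
        # only one residual exists: the smoothed value equals it wherever
        # the kernel reaches
        np.testing.assert_allclose(out["smoothed"], 1.0, atol=1e-12)

    def test_small_bandwidth_approaches_interpolation(self):
        res = pd.DataFrame(
            {"location": ["A", "A"], "year": [2000, 2005], "resid": [1.0, -1.0]}
        )
        out = spacetime_smooth(
            res, HIER, 0.6, 1.0,
            targets=pd.DataFrame(
                {"location": ["A"] * 3, "year": [2000, 2002, 2005]}
            ),
            density_scale=0.0,
        )
        vals = dict(zip(out["year"], out["smoothed"]))
        assert vals[2000] == pytest.approx(1.0, abs=1e-9)
        assert vals[2005] == pytest.approx(-1.0, abs=1e-9)
        assert vals[2002] == 0.0  # nothing within bandwidth

    def test_smoothed_value_is_convex_combination(self):
        rng = np.random.default_rng(0)
        res = pd.DataFrame(
            {
                "location": rng.choice(["A", "B", "C"], 30),
                "year": rng.integers(1990, 2010, 30),
                "resid": rng.normal(0, 1, 30),
            }
        )
        out = spacetime_smooth(res, HIER, 8.0, 0.7)
        assert out["smoothed"].max() <= res["resid"].max() + 1e-12
        assert out["smoothed"].min() >= res["resid"].min() - 1e-12


class TestGPRPosterior:
    YEARS = np.arange(1990.0, 2011.0)

    def test_no_observations_returns_prior_exactly(self):
        prior = np.sin(self.YEARS / 3.0)
        es = gpr_posterior(self.YEARS, prior, [], [], [], 0.3, 10.0, 50, seed=0)
        np.testing.assert_array_equal(es.mean, prior)

    def test_single_point_closed_form(self):
        """Posterior at the observed point: prior + k0/(k0+s2) * innovation."""
        k0, s2 = 0.3**2, 0.05
        es = gpr_posterior(
            np.array([2000.0]), np.array([1.0]),
            np.array([2000.0]), np.array([2.0]), np.array([s2]),
            eta=0.3, rho=10.0, n_draws=50, seed=0,
        )
        assert es.mean[0] == pytest.approx(1.0 + k0 / (k0 + s2), abs=1e-10)

    def test_vanishing_noise_interpolates_data(self):
        rng = np.random.default_rng(1)
        oy = self.YEARS[::4]
        ov = rng.normal(0, 0.3, len(oy))
        es = gpr_posterior(
            self.YEARS, np.zeros_like(self.YEARS), oy, ov,
            np.full(len(oy), 1e-10), 0.3, 10.0, 50, seed=0,
        )
        at = np.searchsorted(self.YEARS, oy)
        np.testing.assert_allclose(es.mean[at], ov, atol=1e-4)

    def test_posterior_variance_never_exceeds_prior_variance(self):
        rng = np.random.default_rng(2)
        oy = self.YEARS[::3]
        es = gpr_posterior(
            self.YEARS, np.zeros_like(self.YEARS), oy,
            rng.normal(0, 0.2, len(oy)), np.full(len(oy), 0.01),
            0.3, 10.0, 400, seed=0,
        )
        prior_sd = 0.3
        assert np.all(es.draws.std(axis=1) <= prior_sd * 1.15)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            gpr_posterior(
                self.YEARS, np.zeros_like(self.YEARS),
                np.array([2000.0]), np.array([1.0]), np.array([0.0]),
                0.3, 10.0, 50, seed=0,
            )

    def test_ui_ordering(self):
        es = gpr_posterior(
            self.YEARS, np.zeros_like(self.YEARS), [], [], [], 0.3, 10.0, 100, 0
        )
        assert np.all(es.lower <= es.mean + 1e-9)
        assert np.all(es.mean - 1e-9 <= es.upper)


class TestComposition:
    def _obs_from_truth(self, truth, years, rng, noise=0.01):
        rows = []
        for loc in ["A", "B", "C"]:
            for y in years[::3]:
                i = int(y - years[0])
                rows.append(
                    {
                        "location": loc,
                        "year": float(y),
                        "value": float(
                            np.clip(truth[i] + rng.normal(0, noise), 1e-4, 0.99)
                        ),
                        "variance": noise**2,
                        "source_type": "survey",
                    }
                )
        return pd.DataFrame(rows)

    def test_dense_low_noise_recovery_within_one_percent(self):
        years = np.arange(1990, 2011)
        truth = 0.2 * 0.985 ** (years - 1990)
        rng = np.random.default_rng(0)
        rows = []
        for loc in ["A", "B", "C"]:
            for y in years:
                i = int(y - years[0])
                rows.append(
                    {
                        "location": loc,
                        "year": float(y),
                        "value": float(truth[i] * np.exp(rng.normal(0, 0.002))),
                        "variance": (0.002 * truth[i]) ** 2,
                        "source_type": "survey",
                    }
                )
        obs = pd.DataFrame(rows)
        cfg = STGPRConfig(transform="logit", n_draws=50, seed=0, eta=0.2, rho=8.0)
        series = stgpr_estimate(obs, _covs(years), HIER, cfg)
        for loc in ["A", "B", "C"]:
            np.testing.assert_allclose(series[loc].mean, truth, rtol=0.01)

    def test_identical_seeds_give_bit_identical_draws(self):
        years = np.arange(1990, 2011)
        truth = 0.15 * 0.99 ** (years - 1990)
        rng = np.random.default_rng(3)
        obs = self._obs_from_truth(truth, years, rng)
        cfg = STGPRConfig(transform="logit", n_draws=20, seed=9)
        s1 = stgpr_estimate(obs, _covs(years), HIER, cfg)
        s2 = stgpr_estimate(obs, _covs(years), HIER, cfg)
        for loc in s1:
            np.testing.assert_array_equal(s1[loc].draws, s2[loc].draws)

    def test_data_free_location_has_wider_ui(self):
        years = np.arange(1990, 2011)
        truth = 0.15 * 0.99 ** (years - 1990)
        rng = np.random.default_rng(4)
        obs = self._obs_from_truth(truth, years, rng)
        obs = obs[obs["location"] != "B"]  # B has no data
        cfg = STGPRConfig(transform="logit", n_draws=100, seed=1)
        series = stgpr_estimate(obs, _covs(years), HIER, cfg)
        width_a = float(np.mean(series["A"].upper - series["A"].lower))
        width_b = float(np.mean(series["B"].upper - series["B"].lower))
        assert width_b > width_a

    def test_back_transform_preserves_draw_order(self):
        v = np.array([-2.0, -1.0, 0.0, 1.0])
        for tf in ("logit", "log", "identity"):
            out = back_transform(v, tf)
            assert np.all(np.diff(out) > 0)

    def test_ui_coverage_calibrated_over_simulated_series(self):
        """95% UI covers the truth in 85-99% of location-years over 200
        simulated series drawn from the model family."""
        years = np.arange(1970.0, 2017.0)
        eta, rho = 0.3, 12.0
        K = _kernel_matrix(years, years, eta, rho, "matern52")
        L = np.linalg.cholesky(K + 1e-10 * np.eye(len(years)))
        rng = np.random.default_rng(123)
        covered = total = 0
        for s in range(200):
            truth = -2.0 + 0.01 * (years - 1990) + L @ rng.standard_normal(len(years))
            idx = rng.choice(len(years), 12, replace=False)
            sd = 0.15
            obs_vals = truth[idx] + sd * rng.standard_normal(12)
            es = gpr_posterior(
                years, -2.0 + 0.01 * (years - 1990), years[idx], obs_vals,
                np.full(12, sd**2), eta, rho, 200, seed=s,
            )
            covered += int(np.sum((truth >= es.lower) & (truth <= es.upper)))
            total += len(years)
        coverage = covered / total
        assert 0.85 <= coverage <= 0.99


class TestNonsamplingVariance:
    def test_noisy_source_assigned_larger_variance(self):
        rng = np.random.default_rng(0)
        years = np.arange(1990.0, 2010.0)
        truth = 0.1 * np.ones(len(years))
        rows = []
        for y, t in zip(years, truth):
            rows.append(
                {"location": "A", "year": y, "value": t * np.exp(rng.normal(0, 0.01)),
                 "variance": 1e-8, "source_type": "good"}
            )
            rows.append(
                {"location": "A", "year": y, "value": t * np.exp(rng.normal(0, 0.5)),
                 "variance": 1e-8, "source_type": "noisy"}
            )
        nsv = estimate_nonsampling_variance(pd.DataFrame(rows), "logit")
        assert nsv["noisy"] > 10 * nsv["good"]
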