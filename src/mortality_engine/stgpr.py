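"""Spatiotemporal Gaussian process regression (ST-GPR).

A generic three-stage estimator for location-year quantities (under-5
mortality, adult mortality, total fertility, stillbirth ratios):

1. a covariate prior — penalized linear regression with hierarchical
   (location within region) shrinkage of residual intercepts;
2. space-time residual smoothing — tricube-weighted averaging of residuals
   over time (bandwidth ``lambda_t``) and over the location hierarchy
   (own-location weight ``zeta``);
3. exact Gaussian process conditioning on the transformed scale with a
   Matérn-5/2 covariance (amplitude ``eta``, length-scale ``rho``) and
   heteroscedastic observation noise, producing draws and a 95% UI from
   their 2.5th/97.5th percentiles.

Kernel hyperparameters are preset per run rather than optimised; the
defaults are package choices, documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "STGPRConfig",
    "EstimateSeries",
    "fit_prior",
    "spacetime_smooth",
    "gpr_posterior",
    "stgpr_estimate",
    "estimate_nonsampling_variance",
    "transform_values",
    "back_transform",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform_values(values: np.ndarray, transform: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if transform == "logit":
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        return np.log(v / (1.0 - v))
    if transform == "log":
        return np.log(np.clip(v, 1e-300, None))
    if transform == "identity":
        return v
    raise ValueError(f"unknown transform {transform!r}")


def back_transform(values: np.ndarray, transform: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-v))
    if transform == "log":
        return np.exp(v)
    if transform == "identity":
        return v
    raise ValueError(f"unknown transform {transform!r}")


def transform_variance(
    values: np.ndarray, variances: np.ndarray, transform: str
) -> np.ndarray:
    """Delta-method variance on the transformed scale."""
    v = np.asarray(values, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    if transform == "logit":
        v = np.clip(v, 1e-6, 1 - 1e-6)
        deriv = 1.0 / (v * (1.0 - v))
    elif transform == "log":
        deriv = 1.0 / np.clip(v, 1e-300, None)
    else:
        deriv = np.ones_like(v)
    return s2 * deriv**2


@dataclass(frozen=True)
class STGPRConfig:
    transform: str = "logit"
    covariates: tuple[str, ...] = ()
    lambda_t: float = 12.0        # tricube time bandwidth, years
    zeta: float = 0.7             # own-location weight in [0, 1]
    omega: float | None = None    # optional age weight (unused for scalar series)
    kernel: str = "matern52"
    eta: float = 0.3              # GP amplitude on the transformed scale
    rho: float = 12.0             # GP length-scale, years
    n_draws: int = 100
    seed: int = 0
    shrinkage: float = 5.0        # pseudo-observations pulling levels to parent
    mean_smooth: float = 5.0      # tricube bandwidth smoothing the GP mean, years
    nonsampling_variance_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.lambda_t <= 0:
            raise ValueError("lambda_t must be positive")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if self.eta <= 0 or self.rho <= 0:
            raise ValueError("eta and rho must be positive")
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")


@dataclass(frozen=True)
class EstimateSeries:
    """Location-year series with a draw matrix and percentile-based UI."""

    location: str
    years: np.ndarray
    mean: np.ndarray
    draws: np.ndarray  # shape (n_years, n_draws)
    lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lower, upper = np.percentile(self.draws, [2.5, 97.5], axis=1)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def at(self, year: float) -> tuple[float, float, float]:
        i = int(np.nonzero(np.isclose(self.years, year))[0][0])
        return float(self.mean[i]), float(self.lower[i]), float(self.upper[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location": self.location,
                "year": self.years,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


# ---------------------------------------------------------------------------
# Stage 1: covariate prior with hierarchical shrinkage
# ---------------------------------------------------------------------------

def fit_prior(
    obs: pd.DataFrame,
    covariates: pd.DataFrame,
    hierarchy: pd.DataFrame,
    config: STGPRConfig,
) -> pd.DataFrame:
    """Covariate prior mean for every location-year in ``covariates``.

    ``obs``: location, year, value (transformed scale), variance.
    ``covariates``: location, year, one column per covariate name; must be
    complete for all target location-years.
    ``hierarchy``: location, region.

    The global fixed effects are a weighted least squares fit; residual
    location intercepts are shrunk toward their region mean and regions
    toward zero with ``config.shrinkage`` pseudo-observations, so data-free
    locations inherit the parent-level fit.
    """
    names = list(config.covariates)
    cov = covariates.copy()
    # observations may be dated at fractional years (period midpoints);
    # covariate lookup uses the nearest tabulated year
    cov["_yk"] = cov["year"].round().astype(int)
    obs = obs.copy()
    obs["_yk"] = obs["year"].round().astype(int)
    merged = obs.merge(
        cov.drop(columns="year"), on=["location", "_yk"], how="left", validate="m:1"
    )
    if merged[names].isna().any().any() if names else False:
        raise ValueError("covariates missing for some observed location-years")
    X = np.column_stack(
        [np.ones(len(merged))] + [merged[n].to_numpy(float) for n in names]
    )
    y = merged["value"].to_numpy(float)
    wts = 1.0 / np.clip(merged.get("variance", pd.Series(np.ones(len(merged)))), 1e-8, None)
    sw = np.sqrt(wts.to_numpy(float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient covariate design")

    # fixed effects and location intercepts fitted jointly by backfitting
    # (a Gauss-Seidel pass of the mixed model): without this, the densely
    # observed locations' levels would be absorbed into the slopes
    loc_codes, loc_inv = np.unique(merged["location"], return_inverse=True)
    loc_off = np.zeros(len(loc_codes))
    tau0 = config.shrinkage
    beta = np.zeros(X.shape[1])
    for _ in range(5):
        y_adj = y - loc_off[loc_inv]
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y_adj * sw, rcond=None)
        r = y - X @ beta
        num = np.bincount(loc_inv, weights=r, minlength=len(loc_codes))
        cnt = np.bincount(loc_inv, minlength=len(loc_codes))
        loc_off = num / (cnt + tau0)

    # region-level random slopes: ridge toward the global coefficients, so
    # regions with enough data get their own covariate-mortality gradient
    # while sparse regions inherit the global fit
    hier = hierarchy.set_index("location")["region"]
    merged["_region"] = merged["location"].map(hier)
    w_arr = wts.to_numpy(float)
    w_arr = w_arr / w_arr.mean()
    beta_region: dict = {}
    tau_slope = 10.0 * config.shrinkage
    for region, sub in merged.groupby("_region"):
        idx = sub.index.to_numpy()
        pos = merged.index.get_indexer(idx)
        if len(pos) < 4 * X.shape[1]:
            beta_region[region] = beta
            continue
        Xr, wr = X[pos], w_arr[pos]
        yr = (y - loc_off[loc_inv])[pos]
        XtWX = (Xr * wr[:, None]).T @ Xr
        D = np.diag(np.maximum(np.diag(XtWX) / max(len(pos), 1), 1e-8)) * tau_slope
        rhs = (Xr * wr[:, None]).T @ yr + D @ beta
        beta_region[region] = np.linalg.solve(XtWX + D, rhs)

    def _beta_for(region) -> np.ndarray:
        return beta_region.get(region, beta)

    resid = np.array(
        [
            y[i] - X[i] @ _beta_for(r)
            for i, r in enumerate(merged["_region"])
        ]
    )
    merged["_resid"] = resid
    tau = config.shrinkage
    reg_eff = {}
    for region, sub in merged.groupby("_region"):
        reg_eff[region] = sub["_resid"].sum() / (len(sub) + tau)
    loc_eff = {}
    for loc, sub in merged.groupby("location"):
        parent = reg_eff.get(hier.get(loc), 0.0)
        loc_eff[loc] = (sub["_resid"] - parent).sum() / (len(sub) + tau) + parent

    out = cov.drop(columns="_yk").copy()
    Xt = np.column_stack(
        [np.ones(len(out))] + [out[n].to_numpy(float) for n in names]
    )
    out["_region"] = out["location"].map(hier)
    fixed = np.array(
        [Xt[i] @ _beta_for(r) for i, r in enumerate(out["_region"])]
    )
    effect = out["location"].map(
        lambda l: loc_eff.get(l, reg_eff.get(hier.get(l), 0.0))
    )
    out["prior"] = fixed + effect.to_numpy(float)
    if not np.all(np.isfinite(out["prior"])):
        raise ValueError("non-finite prior produced")
    return out[["location", "year", "prior"]]


# ---------------------------------------------------------------------------
# Stage 2: space-time residual smoothing
# ---------------------------------------------------------------------------

def _tricube(dt: np.ndarray, bandwidth: float) -> np.ndarray:
    u = np.abs(dt) / bandwidth
    w = (1.0 - np.minimum(u, 1.0) ** 3) ** 3
    return np.where(u < 1.0, w, 0.0)


def spacetime_smooth(
    residuals: pd.DataFrame,
    hierarchy: pd.DataFrame,
    lambda_t: float,
    zeta: float,
    targets: pd.DataFrame | None = None,
    density_scale: float = 25.0,
) -> pd.DataFrame:
    """Tricube-weighted residual surface over location-years.

    ``residuals``: location, year, resid.  ``targets`` defaults to the full
    location x year grid spanned by the hierarchy and residual years.  The
    smoothed value is a convex combination of observed residuals: weight
    ``zeta`` on the own-location kernel average and ``1 - zeta`` on the
    same-region average (falling back across levels when a component has
    no data; zero where no residuals exist anywhere).  The own-location
    weight is scaled by data density, n / (n + density_scale), so sparsely
    observed locations borrow more strength from their region; set
    ``density_scale=0`` for a fixed zeta.
    """
    hier = hierarchy.set_index("location")["region"]
    if targets is None:
        years = np.arange(residuals["year"].min(), residuals["year"].max() + 1)
        targets = pd.DataFrame(
            [(l, y) for l in hierarchy["location"] for y in years],
            columns=["location", "year"],
        )
    res = residuals.copy()
    res["_region"] = res["location"].map(hier)
    out_vals = np.zeros(len(targets))
    by_loc = {l: g for l, g in res.groupby("location")}
    by_reg = {r: g for r, g in res.groupby("_region")}
    for i, (loc, year) in enumerate(zip(targets["location"], targets["year"])):
        own = by_loc.get(loc)
        region = hier.get(loc)
        reg = by_reg.get(region)
        if reg is not None:
            reg = reg[reg["location"] != loc]  # sibling locations only
        comp, wts = [], []
        if own is not None and len(own):
            w = _tricube(own["year"].to_numpy(float) - year, lambda_t)
            if w.sum() > 0:
                n_own = float(len(own))
                dens = (
                    n_own / (n_own + density_scale) if density_scale > 0 else 1.0
                )
                comp.append(np.average(own["resid"], weights=w))
                wts.append(zeta * dens)
        if reg is not None and len(reg):
            w = _tricube(reg["year"].to_numpy(float) - year, lambda_t)
            if w.sum() > 0:
                comp.append(np.average(reg["resid"], weights=w))
                wts.append(1.0 - zeta)
        if not comp and len(res):
            # nothing within bandwidth anywhere nearby: global kernel fallback
            w = _tricube(res["year"].to_numpy(float) - year, lambda_t)
            if w.sum() > 0:
                comp.append(np.average(res["resid"], weights=w))
                wts.append(1.0)
        if comp:
            wts = np.asarray(wts)
            out_vals[i] = float(np.dot(wts / wts.sum(), comp))
    out = targets.copy()
    out["smoothed"] = out_vals
    return out


# ---------------------------------------------------------------------------
# Stage 3: GP conditioning
# ---------------------------------------------------------------------------

def _matern52(dist: np.ndarray, rho: float) -> np.ndarray:
    s = np.sqrt(5.0) * dist / rho
    return (1.0 + s + s**2 / 3.0) * np.exp(-s)


def _kernel_matrix(a: np.ndarray, b: np.ndarray, eta: float, rho: float, kernel: str) -> np.ndarray:
    dist = np.abs(a[:, None] - b[None, :])
    if kernel == "matern52":
        return eta**2 * _matern52(dist, rho)
    if kernel == "rbf":
        return eta**2 * np.exp(-0.5 * (dist / rho) ** 2)
    raise ValueError(f"unknown kernel {kernel!r}")


def gpr_posterior(
    years: np.ndarray,
    prior_mean: np.ndarray,
    obs_years: np.ndarray,
    obs_values: np.ndarray,
    obs_variances: np.ndarray,
    eta: float,
    rho: float,
    n_draws: int,
    seed: int,
    kernel: str = "matern52",
    location: str = "",
    jitter: float = 1e-10,
) -> EstimateSeries:
    """Exact GP conditioning on the transformed scale.

    With no observations the posterior equals the prior mean with the prior
    covariance.  Draws are sampled from the posterior with a seeded
    generator; the UI is the 2.5th/97.5th percentile of the draws.
    """
    years = np.asarray(years, dtype=float)
    mu = np.asarray(prior_mean, dtype=float)
    Kss = _kernel_matrix(years, years, eta, rho, kernel)
    if len(obs_years) == 0:
        mean, cov = mu.copy(), Kss
    else:
        oy = np.asarray(obs_years, dtype=float)
        ov = np.asarray(obs_values, dtype=float)
        s2 = np.asarray(obs_variances, dtype=float)
        if np.any(s2 <= 0):
            raise ValueError("observation variances must be positive")
        mu_obs = np.interp(oy, years, mu)
        Koo = _kernel_matrix(oy, oy, eta, rho, kernel) + np.diag(s2)
        Kso = _kernel_matrix(years, oy, eta, rho, kernel)
        cho = None
        for eps in (0.0, jitter, 1e6 * jitter):
            try:
                cho = linalg.cho_factor(Koo + eps * np.eye(len(oy)), lower=True)
                break
            except linalg.LinAlgError:
                continue
        if cho is None:
            raise ValueError(
                "non-positive-definite observation covariance after jitter; "
                f"min variance {s2.min():.3g}, n={len(oy)}"
            )
        alpha = linalg.cho_solve(cho, ov - mu_obs)
        mean = mu + Kso @ alpha
        cov = Kss - Kso @ linalg.cho_solve(cho, Kso.T)
    cov = (cov + cov.T) / 2.0
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(cov + jitter * np.eye(len(years)))
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)[None, :]
    draws = mean[:, None] + A @ rng.standard_normal((len(years), n_draws))
    return EstimateSeries(location, years, mean, draws)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def stgpr_estimate(
    obs: pd.DataFrame,
    covariates: pd.DataFrame,
    hierarchy: pd.DataFrame,
    config: STGPRConfig,
    nonsampling_variance: dict[str, float] | None = None,
) -> dict[str, EstimateSeries]:
    """Full three-stage fit; returns one natural-scale series per location.

    ``obs``: location, year, value (natural scale), variance (natural
    scale), optional source_type.  ``covariates`` spans every target
    location-year.
    """
    t_obs = obs.copy()
    t_obs["value_nat"] = t_obs["value"]
    t_obs["value"] = transform_values(t_obs["value_nat"].to_numpy(), config.transform)
    var_nat = np.clip(
        t_obs.get("variance", pd.Series(np.zeros(len(t_obs)))).to_numpy(float),
        0.0,
        None,
    )
    nsv = np.full(len(t_obs), config.nonsampling_variance_floor)
    if nonsampling_variance and "source_type" in t_obs.columns:
        nsv = (
            t_obs["source_type"]
            .map(nonsampling_variance)
            .fillna(config.nonsampling_variance_floor)
            .to_numpy(float)
        )
    t_obs["variance"] = (
        transform_variance(t_obs["value_nat"].to_numpy(), var_nat, config.transform)
        + nsv
    )

    prior = fit_prior(t_obs, covariates, hierarchy, config)
    t_obs["_yk"] = t_obs["year"].round().astype(int)
    prior_k = prior.rename(columns={"year": "_yk"})
    merged = t_obs.merge(prior_k, on=["location", "_yk"], how="left")
    merged = merged[np.isfinite(merged["prior"])]
    merged["resid"] = merged["value"] - merged["prior"]
    smoothed = spacetime_smooth(
        merged[["location", "year", "resid"]],
        hierarchy,
        config.lambda_t,
        config.zeta,
        targets=prior[["location", "year"]],
    )
    stage2 = prior.merge(smoothed, on=["location", "year"])
    stage2["mean2"] = stage2["prior"] + stage2["smoothed"]
    if config.mean_smooth > 0:
        # the GP treats its mean function as exact, so year-to-year jitter
        # in the covariate prior must not reach it; a light tricube running
        # mean preserves trends while removing high-frequency noise
        parts = []
        for loc, sub in stage2.groupby("location"):
            sub = sub.sort_values("year").copy()
            yv = sub["year"].to_numpy(float)
            mv = sub["mean2"].to_numpy(float)
            out = np.empty_like(mv)
            for i, y0 in enumerate(yv):
                wt = _tricube(yv - y0, config.mean_smooth)
                if wt.sum() <= 0:
                    out[i] = mv[i]
                    continue
                # local linear fit avoids endpoint lag on trending series
                dx = yv - y0
                sw_ = wt.sum()
                xb = (wt * dx).sum() / sw_
                yb = (wt * mv).sum() / sw_
                sxx = (wt * (dx - xb) ** 2).sum()
                slope = (wt * (dx - xb) * (mv - yb)).sum() / sxx if sxx > 1e-12 else 0.0
                out[i] = yb - slope * xb
            sub["mean2"] = out
            parts.append(sub)
        stage2 = pd.concat(parts, ignore_index=True)

    out: dict[str, EstimateSeries] = {}
    for j, (loc, sub) in enumerate(stage2.groupby("location")):
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy(float)
        m2 = sub["mean2"].to_numpy(float)
        lobs = merged[merged["location"] == loc].sort_values("year")
        series_t = gpr_posterior(
            years,
            m2,
            lobs["year"].to_numpy(float),
            lobs["value"].to_numpy(float),
            lobs["variance"].to_numpy(float),
            config.eta,
            config.rho,
            config.n_draws,
            seed=int(np.random.SeedSequence([config.seed, j]).generate_state(1)[0] % (2**31)),
            kernel=config.kernel,
            location=str(loc),
        )
        draws_nat = back_transform(series_t.draws, config.transform)
        mean_nat = back_transform(series_t.mean, config.transform)
        out[str(loc)] = EstimateSeries(str(loc), years, mean_nat, draws_nat)
    return out


def estimate_nonsampling_variance(
    obs: pd.DataFrame,
    transform: str,
    floor: float = 1e-4,
) -> dict[str, float]:
    """Per-source-type non-sampling variance from cross-source replicate
    spread.

    Observations of the same location-year from different sources disagree
    by more than their sampling errors allow; the excess spread, pooled by
    source type, is that type's non-sampling variance on the transformed
    scale.  Types never co-observed with another source keep the floor.
    """
    df = obs.copy()
    df["_t"] = transform_values(df["value"].to_numpy(float), transform)
    df["_tv"] = transform_variance(
        df["value"].to_numpy(float),
        df.get("variance", pd.Series(np.zeros(len(df)))).to_numpy(float),
        transform,
    )
    types = sorted(set(df["source_type"].astype(str)))
    out: dict[str, float] = {t: floor for t in types}
    if len(df) < 6:
        return out

    years = df["year"].to_numpy(float)
    tvals = df["_t"].to_numpy(float)
    tv = df["_tv"].to_numpy(float)
    stypes = df["source_type"].astype(str).to_numpy()
    locs = df["location"].to_numpy()

    # robust temporal reference per location (running median over +-4 years,
    # all sources pooled), then precision-weighted refinement: a symmetric
    # cell split cannot attribute the spread when only two sources observe
    # a cell, but temporal smoothness can
    def references(weights: np.ndarray | None) -> np.ndarray:
        ref = np.full(len(df), np.nan)
        for loc in np.unique(locs):
            sel = locs == loc
            ys, ts = years[sel], tvals[sel]
            ws = weights[sel] if weights is not None else None
            for i in np.nonzero(sel)[0]:
                near = np.abs(ys - years[i]) <= 4.0
                if near.sum() < 2:
                    continue
                if ws is None:
                    ref[i] = float(np.median(ts[near]))
                else:
                    ref[i] = float(np.average(ts[near], weights=ws[near]))
        return ref

    ref = references(None)
    for _ in range(2):
        ok = np.isfinite(ref)
        dev2 = (tvals - ref) ** 2
        for stype in types:
            sel = (stypes == stype) & ok
            if sel.sum() >= 3:
                out[stype] = max(
                    float(np.clip(dev2[sel] - tv[sel], 0.0, None).mean()), floor
                )
        prec = 1.0 / (tv + np.array([out[s] for s in stypes]))
        ref = references(prec)
    return out
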