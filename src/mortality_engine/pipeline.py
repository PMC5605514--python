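"""End-to-end estimation pipeline.

Orchestrates the full flow on a set of input datasets (typically a
synthetic world): registration completeness -> survey estimation -> bias
adjustment -> ST-GPR for 5q0 and 45q15 -> model life table expansion ->
HIV overlay and reconciliation -> mortality shocks -> life tables and
summary metrics -> stillbirths -> SDI and expected mortality.  All
quantities are propagated at the draw level; 95% uncertainty intervals
are the 2.5th/97.5th percentiles of the draws.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from mortality_engine.demographic_core import (
    AgeSchedule,
    Sex,
    StandardPopulation,
    age_standardize,
    annualized_roc,
    build_abridged_lifetable,
)
from mortality_engine import model_lifetable as mlt
from mortality_engine import vr_completeness as vrc
from mortality_engine import survey_estimators as sve
from mortality_engine.stgpr import EstimateSeries, STGPRConfig, stgpr_estimate
from mortality_engine import stgpr as stgpr_mod
from mortality_engine.stillbirths import (
    DefinitionScalarTable,
    StillbirthObservation,
    standardize_definition,
)
from mortality_engine import sdi as sdi_mod
from mortality_engine.synthetic import (
    GRID,
    SyntheticWorld,
    hiv_relative_risk_pattern,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "OutputBundle",
    "run_pipeline",
    "compute_ui",
    "summarize_results",
    "sdg_projection",
]

N_AGE = len(GRID)
SEXES = ("male", "female")

#: SDG targets (per 1000 livebirths, to be met by 2030)
SDG_U5MR_TARGET = 25.0
SDG_NMR_TARGET = 12.0
SDG_TARGET_YEAR = 2030


@dataclass(frozen=True)
class PipelineConfig:
    n_draws: int = 100
    seed: int = 0
    output_dir: Path | None = None
    child_stgpr: STGPRConfig | None = None
    adult_stgpr: STGPRConfig | None = None
    sdi_limits: sdi_mod.SDILimits = field(default_factory=sdi_mod.SDILimits)
    complete_threshold: float = vrc.COMPLETE_THRESHOLD
    vr_smooth_window: int = 3
    hiv_cdr_floor: float = 5e-4       # CDR above this triggers the HIV regime

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("need at least 2 draws")


@dataclass
class OutputBundle:
    config: PipelineConfig
    years: np.ndarray
    hierarchy: pd.DataFrame
    completeness: pd.DataFrame
    observations: pd.DataFrame
    q5_series: dict[str, EstimateSeries]
    q45_series: dict[tuple[str, str], EstimateSeries]
    e0_draws: dict[tuple[str, str], np.ndarray]        # (n_years, n_draws)
    q5_final: dict[tuple[str, str], np.ndarray]
    q45_final: dict[tuple[str, str], np.ndarray]
    mx_mean: dict[tuple[str, str], np.ndarray]         # (n_years, 23)
    sbr_series: dict[str, EstimateSeries]
    sdi: pd.DataFrame
    expected: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    shock_report: pd.DataFrame | None = None


def compute_ui(draws: np.ndarray) -> tuple[float, float]:
    """95% UI: empirical 2.5th/97.5th percentiles with linear interpolation
    (numpy's default quantile rule)."""
    d = np.asarray(draws, float)
    if d.size == 0:
        raise ValueError("empty draw vector")
    lo, hi = np.percentile(d, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Stage 1: completeness
# ---------------------------------------------------------------------------

def _vr_mx(world_inputs, loc: str, sex: str) -> np.ndarray | None:
    """Observed (unadjusted) death rates from registered deaths, or None."""
    vr = world_inputs.vr_deaths
    sub = vr[(vr["location"] == loc) & (vr["sex"] == sex)]
    if not len(sub):
        return None
    years = world_inputs.years
    mat = np.full((len(years), N_AGE), np.nan)
    label_ix = {lab: i for i, lab in enumerate(GRID.labels)}
    yix = (sub["year"].to_numpy() - years[0]).astype(int)
    aix = sub["age_group"].map(label_ix).to_numpy()
    mat[yix, aix] = sub["registered_deaths"].to_numpy(float)
    pop = world_inputs.population[(loc, sex)]
    with np.errstate(invalid="ignore", divide="ignore"):
        return mat / pop


def assess_completeness(inputs, config: PipelineConfig) -> pd.DataFrame:
    """Adult DDM per census pair plus child VR/survey ratios, per location."""
    rows = []
    for loc in inputs.locations:
        pairs = [k for k in inputs.censuses if k[0] == loc]
        for (l, cy1) in sorted(pairs):
            cp = inputs.censuses[(l, cy1)]
            t1, t2 = int(cp.date1), int(cp.date2)
            vr = inputs.vr_deaths
            sub = vr[
                (vr["location"] == loc)
                & (vr["year"] >= t1)
                & (vr["year"] < t2)
            ]
            if not len(sub):
                continue
            mean_deaths = (
                sub.groupby("age_group")["registered_deaths"].sum()
                / max(len(set(sub["year"])), 1)
            ).reindex(GRID.labels).fillna(0.0)
            try:
                assess = vrc.ddm_completeness(
                    cp,
                    AgeSchedule(GRID, Sex.BOTH, mean_deaths.to_numpy()),
                    location=loc,
                    search_trims=True,
                )
            except ValueError:
                continue
            rows.append(
                {
                    "location": loc,
                    "period_start": t1,
                    "period_end": t2,
                    "c_ggb": assess.c_ggb,
                    "c_seg": assess.c_seg,
                    "c_hybrid": assess.c_hybrid,
                    "ggb_intercept": assess.ggb_intercept,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "location", "period_start", "period_end",
            "c_ggb", "c_seg", "c_hybrid", "ggb_intercept",
        ],
    )


def interpolate_adult_completeness(
    ddm: pd.DataFrame, loc: str, years: np.ndarray
) -> np.ndarray | None:
    """Per-year completeness from the census-pair estimates, interpolated
    between pair midpoints and linearly extrapolated at the ends."""
    sub = ddm[ddm["location"] == loc].sort_values("period_start")
    if not len(sub):
        return None
    mids = (sub["period_start"] + sub["period_end"]).to_numpy(float) / 2.0
    c = np.clip(sub["c_hybrid"].to_numpy(float), 0.05, 1.1)
    out = np.interp(years, mids, c)
    if len(mids) >= 2:
        slope0 = (c[1] - c[0]) / (mids[1] - mids[0])
        slope1 = (c[-1] - c[-2]) / (mids[-1] - mids[-2])
        before = years < mids[0]
        after = years > mids[-1]
        out[before] = c[0] + slope0 * (years[before] - mids[0])
        out[after] = c[-1] + slope1 * (years[after] - mids[-1])
    return np.clip(out, 0.05, 1.05)


def location_is_complete(ddm: pd.DataFrame, loc: str, threshold: float) -> bool:
    """Complete-VR classification at the location level: the mean of the
    capped hybrid completeness across census pairs reaches the threshold.
    A location-level decision avoids regime flapping from sampling noise in
    individual pair estimates near the threshold."""
    sub = ddm[ddm["location"] == loc]
    if not len(sub):
        return False
    return float(np.minimum(sub["c_hybrid"], 1.0).mean()) >= threshold


# ---------------------------------------------------------------------------
# Stage 2: survey estimation
# ---------------------------------------------------------------------------

def survey_child_observations(inputs) -> pd.DataFrame:
    """Direct (CBH) and indirect (SBH) dated 5q0 observations."""
    rows = []
    cbh = inputs.cbh
    if cbh is not None and len(cbh):
        for (loc, sy), sub in cbh.groupby(["location", "survey_year"]):
            for a, b in ((sy - 3, sy), (sy - 8, sy - 3), (sy - 13, sy - 8)):
                try:
                    q5, var = sve.cbh_direct_5q0(sub, (float(a), float(b)))
                except ValueError:
                    continue
                if not (0 < q5 < 1) or not np.isfinite(var):
                    continue
                rows.append(
                    {
                        "location": loc,
                        "year": (a + b) / 2.0,
                        "value": q5,
                        "variance": max(var, 1e-8),
                        "source_type": "cbh",
                    }
                )
    sbh = inputs.sbh
    if sbh is not None and len(sbh):
        for (loc, sy), sub in sbh.groupby(["location", "survey_year"]):
            try:
                est = sve.sbh_indirect_5q0(sub)
            except (ValueError, KeyError):
                continue
            for _, r in est.iterrows():
                if r["reference_year"] < inputs.years[0] or r["q5"] <= 0:
                    continue
                rows.append(
                    {
                        "location": loc,
                        "year": r["reference_year"],
                        "value": r["q5"],
                        # indirect estimates carry extra model variance
                        "variance": max(0.08 * r["q5"], 0.004) ** 2,
                        "source_type": "sbh",
                    }
                )
    return pd.DataFrame(rows)


def survey_adult_observations(inputs) -> pd.DataFrame:
    """Sibling-history 45q15 observations per sex."""
    rows = []
    sib = inputs.siblings
    if sib is None or not len(sib):
        return pd.DataFrame(rows)
    for (loc, sy), sub in sib.groupby(["location", "survey_year"]):
        for sex in SEXES:
            ssub = sub[sub["sex"] == sex]
            if not len(ssub):
                continue
            for a, b in ((sy - 5, sy), (sy - 10, sy - 5), (sy - 15, sy - 10)):
                try:
                    q45, var = sve.sibling_45q15(ssub, (float(a), float(b)))
                except ValueError:
                    continue
                if not (0 < q45 < 1) or not np.isfinite(var):
                    continue
                rows.append(
                    {
                        "location": loc,
                        "year": (a + b) / 2.0,
                        "sex": sex,
                        "value": q45,
                        "variance": max(var, 1e-8),
                        "source_type": "sibling",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 5-8: model life tables, HIV, shocks
# ---------------------------------------------------------------------------

def build_library(inputs, completeness_df: pd.DataFrame, config) -> mlt.EmpiricalLifeTableLibrary | None:
    """Empirical life table library from complete-VR location-years."""
    entries = []
    hier = inputs.hierarchy.set_index("location")["region"]
    for loc in inputs.locations:
        if not location_is_complete(completeness_df, loc, config.complete_threshold):
            continue  # only quality-screened complete-VR schedules qualify
        for sex in SEXES:
            mx_obs = _vr_mx(inputs, loc, sex)
            if mx_obs is None:
                continue
            for t, y in enumerate(inputs.years):
                if np.any(~np.isfinite(mx_obs[t])) or mx_obs[t][-1] <= 0:
                    continue
                sm = _smooth_mx(mx_obs, t, config.vr_smooth_window)
                lt = build_abridged_lifetable(
                    AgeSchedule(GRID, Sex(sex), sm), "constant_hazard"
                )
                lx_ext = _extend_lx(lt)
                row = {
                    "location": loc,
                    "region": hier.get(loc, ""),
                    "year": int(y),
                    "sex": sex,
                    "quality": "vr",
                }
                row.update(
                    {f"lx_{i}": lx_ext[i] for i in range(len(mlt.EXTENDED_AGES))}
                )
                entries.append(row)
    if not entries:
        return None
    return mlt.EmpiricalLifeTableLibrary(pd.DataFrame(entries))


def _smooth_mx(mx_obs: np.ndarray, t: int, window: int) -> np.ndarray:
    lo = max(0, t - window // 2)
    hi = min(mx_obs.shape[0], lo + window)
    block = mx_obs[lo:hi]
    with np.errstate(invalid="ignore"):
        out = np.nanmean(block, axis=0)
    return np.where(np.isfinite(out), out, 0.0)


def _extend_lx(lt) -> np.ndarray:
    """lx at EXTENDED_AGES from a 23-group life table.

    Survivorship between group boundaries interpolates log-linearly; beyond
    the open age the hazard is extrapolated on a Gompertz slope estimated
    from the 85-89 and 90-94 rates (a flat continuation would overstate
    extreme-age survival and inflate e0 at low mortality).
    """
    ages23 = GRID.starts
    logl = np.log(np.clip(lt.lx, 1e-300, None))
    lx = np.exp(np.interp(mlt.EXTENDED_AGES, ages23, logl))
    m85, m90 = max(lt.mx[-3], 1e-6), max(lt.mx[-2], 1e-6)
    b = np.clip(math.log(m90 / m85) / 5.0, 0.04, 0.16)
    tail = mlt.EXTENDED_AGES > 95.0
    x = mlt.EXTENDED_AGES[tail] - 95.0
    h95 = m90 * math.exp(b * 5.0)  # hazard at ~95 on the Gompertz line
    cumh = h95 / b * (np.exp(b * x) - 1.0)
    lx[tail] = lt.lx[-1] * np.exp(-cumh)
    return lx


def _completeness_series(inputs, ddm: pd.DataFrame, loc: str, config) -> tuple[np.ndarray, np.ndarray]:
    """(child, adult) completeness series used for VR adjustment."""
    years = inputs.years
    ny = len(years)
    c_adult = interpolate_adult_completeness(ddm, loc, years.astype(float))
    if c_adult is None:
        c_adult = np.zeros(ny)
    # child completeness: VR 5q0 vs survey 5q0 where both exist
    c_child = c_adult.copy()
    return c_child, c_adult


def hiv_q_contributions(
    cdr: np.ndarray, pop: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(added mx by age, q5 contribution, 45q15 contribution) per year."""
    rr = hiv_relative_risk_pattern()
    denom = (rr[None, :] * pop).sum(axis=1)
    scale = np.where(denom > 0, cdr * pop.sum(axis=1) / np.maximum(denom, 1e-300), 0.0)
    added = scale[:, None] * rr[None, :]
    widths = np.where(np.isfinite(GRID.widths), GRID.widths, 5.0)
    child = added[:, :4] * widths[None, :4]
    q5 = 1.0 - np.exp(-child.sum(axis=1))
    adult_sel = (GRID.starts >= 15) & (GRID.starts < 60)
    q45 = 1.0 - np.exp(-(added[:, adult_sel] * 5.0).sum(axis=1))
    return added, q5, q45


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    inputs: SyntheticWorld, config: PipelineConfig | None = None
) -> OutputBundle:
    """Run the full estimation flow on a world's observation datasets.

    Only the observation datasets, populations, covariates and exogenous
    HIV/shock inputs are consumed — never the truth surfaces.
    """
    if config is None:
        config = PipelineConfig()
    t_start = time.time()
    rng_root = np.random.SeedSequence([config.seed, 777])
    years = inputs.years.astype(float)
    ny = len(years)
    locations = list(inputs.locations) if hasattr(inputs, "locations") else list(
        inputs.config.locations
    )
    hierarchy = inputs.hierarchy[["location", "region"]]
    covs = inputs.covariates_frame()

    # ---- stage 1: completeness --------------------------------------------
    ddm = assess_completeness(inputs, config)

    # ---- stage 2: survey estimation ---------------------------------------
    child_obs = survey_child_observations(inputs)
    adult_obs = survey_adult_observations(inputs)

    # ---- stage 2b: VR-based observations, completeness-adjusted ------------
    vr_child_rows, vr_adult_rows = [], []
    vr_mx_store: dict[tuple[str, str], np.ndarray] = {}
    complete_vr: dict[tuple[str, str], np.ndarray] = {}
    for loc in locations:
        c_child, c_adult = _completeness_series(inputs, ddm, loc, config)
        loc_complete = location_is_complete(ddm, loc, config.complete_threshold)
        for sex in SEXES:
            mx_obs = _vr_mx(inputs, loc, sex)
            if mx_obs is None:
                complete_vr[(loc, sex)] = np.zeros(ny, bool)
                continue
            vr_mx_store[(loc, sex)] = mx_obs
            complete_flags = np.zeros(ny, bool)
            for t in range(ny):
                if np.any(~np.isfinite(mx_obs[t])):
                    continue
                adj_adult = max(min(c_adult[t], 1.0), 0.05)
                complete_flags[t] = loc_complete
                sm = _smooth_mx(mx_obs, t, config.vr_smooth_window)
                if sm[-1] <= 0:
                    complete_flags[t] = False
                    continue
                lt = build_abridged_lifetable(
                    AgeSchedule(GRID, Sex(sex), sm), "constant_hazard"
                )
                q5 = 1.0 - lt.lx[GRID.index_of_age(5.0)]
                q45 = 1.0 - lt.lx[GRID.index_of_age(60.0)] / lt.lx[
                    GRID.index_of_age(15.0)
                ]
                scale = 1.0 if loc_complete else 1.0 / adj_adult
                pop_tot = inputs.population[(loc, sex)][t].sum()
                q45_adj = min(1.0 - (1.0 - q45) ** scale, 0.95)
                q5_adj = min(1.0 - (1.0 - q5) ** scale, 0.95)
                stype = "vr" if loc_complete else "vr_adjusted"
                vr_var = max(q5 * (1 - q5) / max(pop_tot * 0.09, 1.0), 1e-9)
                vr_child_rows.append(
                    {
                        "location": loc,
                        "year": float(inputs.years[t]),
                        "sex": sex,
                        "value": q5_adj,
                        "variance": vr_var,
                        "source_type": stype,
                    }
                )
                a_var = max(q45 * (1 - q45) / max(pop_tot * 0.55, 1.0), 1e-9)
                vr_adult_rows.append(
                    {
                        "location": loc,
                        "year": float(inputs.years[t]),
                        "sex": sex,
                        "value": q45_adj,
                        "variance": a_var,
                        "source_type": stype,
                    }
                )
            complete_vr[(loc, sex)] = complete_flags

    vr_child = pd.DataFrame(vr_child_rows)
    vr_adult = pd.DataFrame(vr_adult_rows)

    # child observations are both-sex: average VR sexes, keeping the
    # source label (complete vs completeness-adjusted)
    if len(vr_child):
        vr_child_b = vr_child.groupby(
            ["location", "year", "source_type"], as_index=False
        ).agg(value=("value", "mean"), variance=("variance", "mean"))
    else:
        vr_child_b = pd.DataFrame(
            columns=["location", "year", "value", "variance", "source_type"]
        )

    # ---- stage 3a: move observations to HIV-free space ---------------------
    # The epidemic's fast rise and fall is poorly suited to smoothing on
    # the observation scale; instead the mechanistic HIV contribution
    # (CDR spread over the relative-risk age pattern) is removed from
    # every observation, the smooth HIV-free quantity is modelled, and
    # the reconciled HIV mortality is added back at the life table stage.
    cdr_by_loc = {
        loc: covs[covs["location"] == loc].sort_values("year")["hiv_cdr"].to_numpy()
        for loc in locations
    }
    q5_hiv_loc: dict[str, np.ndarray] = {}
    q45_hiv_loc: dict[tuple[str, str], np.ndarray] = {}
    for loc in locations:
        cdr = cdr_by_loc[loc]
        per_sex_q5 = []
        for sex in SEXES:
            _, q5h, q45h = hiv_q_contributions(cdr, inputs.population[(loc, sex)])
            q45_hiv_loc[(loc, sex)] = q45h
            per_sex_q5.append(q5h)
        q5_hiv_loc[loc] = (per_sex_q5[0] + per_sex_q5[1]) / 2.0

    def _to_hiv_free(df: pd.DataFrame, q_hiv: dict, key_sex: bool) -> pd.DataFrame:
        if not len(df):
            return df
        out = df.copy()
        vals = out["value"].to_numpy(float)
        adj = np.empty(len(out))
        for i, row in enumerate(out.itertuples()):
            t = int(np.clip(round(row.year - inputs.years[0]), 0, ny - 1))
            series = (
                q_hiv.get((row.location, row.sex))
                if key_sex
                else q_hiv.get(row.location)
            )
            qh = float(series[t]) if series is not None else 0.0
            H = -math.log(max(1.0 - vals[i], 1e-12))
            H_free = max(H + math.log(max(1.0 - qh, 1e-12)), 1e-9)
            adj[i] = 1.0 - math.exp(-H_free)
        out["value"] = adj
        return out

    child_obs = _to_hiv_free(child_obs, q5_hiv_loc, key_sex=False)
    vr_child_b = _to_hiv_free(vr_child_b, q5_hiv_loc, key_sex=False)
    adult_obs = _to_hiv_free(adult_obs, q45_hiv_loc, key_sex=True)
    vr_adult = _to_hiv_free(vr_adult, q45_hiv_loc, key_sex=True)

    # ---- stage 3: cross-source bias adjustment ----------------------------
    all_child = pd.concat([child_obs, vr_child_b], ignore_index=True)
    if len(all_child) and "cbh" in set(all_child["source_type"]):
        adjustable = all_child[all_child["source_type"].isin(["cbh", "sbh"])]
        adjusted, offsets = sve.source_bias_adjust(
            adjustable, reference_type="cbh", space="logit", hierarchy=hierarchy
        )
        all_child = pd.concat(
            [adjusted, all_child[~all_child["source_type"].isin(["cbh", "sbh"])]],
            ignore_index=True,
        )
    else:
        offsets = {}

    # ---- stage 4: ST-GPR --------------------------------------------------
    child_cfg = config.child_stgpr or STGPRConfig(
        transform="logit",
        covariates=("education", "log_ldi"),
        n_draws=config.n_draws,
        seed=config.seed,
        eta=0.25,
        rho=14.0,
        lambda_t=10.0,
        zeta=0.75,
    )
    adult_cfg = config.adult_stgpr or STGPRConfig(
        transform="logit",
        covariates=("education", "log_ldi"),
        n_draws=config.n_draws,
        seed=config.seed + 1,
        eta=0.25,
        rho=14.0,
        lambda_t=10.0,
        zeta=0.75,
    )
    child_nsv = stgpr_mod.estimate_nonsampling_variance(all_child, child_cfg.transform)
    q5_series = stgpr_estimate(
        all_child, covs, hierarchy, child_cfg, nonsampling_variance=child_nsv
    )

    q45_series: dict[tuple[str, str], EstimateSeries] = {}
    for sex in SEXES:
        sex_obs = pd.concat(
            [
                adult_obs[adult_obs["sex"] == sex] if len(adult_obs) else adult_obs,
                vr_adult[vr_adult["sex"] == sex] if len(vr_adult) else vr_adult,
            ],
            ignore_index=True,
        )
        # sibling histories are adjusted to registration-based estimates
        # where the two overlap (partial-VR locations)
        adult_ref = (
            "vr_adjusted"
            if "vr_adjusted" in set(sex_obs["source_type"])
            else "vr"
        )
        if adult_ref in set(sex_obs["source_type"]) and "sibling" in set(
            sex_obs["source_type"]
        ):
            adj, adult_offsets = sve.source_bias_adjust(
                sex_obs[sex_obs["source_type"].isin([adult_ref, "sibling"])],
                reference_type=adult_ref,
                space="logit",
                hierarchy=hierarchy,
            )
            sex_obs = pd.concat(
                [
                    adj[adj["source_type"] == "sibling"],
                    sex_obs[sex_obs["source_type"] != "sibling"],
                ],
                ignore_index=True,
            )
            offsets[f"sibling_{sex}"] = adult_offsets.get("sibling", 0.0)
        adult_nsv = stgpr_mod.estimate_nonsampling_variance(
            sex_obs, adult_cfg.transform
        )
        series = stgpr_estimate(
            sex_obs, covs, hierarchy, adult_cfg, nonsampling_variance=adult_nsv
        )
        for loc, s in series.items():
            q45_series[(loc, sex)] = s

    # sex ratios for splitting both-sex 5q0: per location where VR or CBH
    # carries child sex, with the cross-location median as fallback.
    # Registration undercount is sex-neutral, so the VR ratio is usable
    # even where registration is incomplete.
    q5_ratio_loc: dict[str, float] = {}
    if len(vr_child):
        merged = vr_child.pivot_table(
            index=["location", "year"], columns="sex", values="value"
        ).dropna()
        for loc, sub in merged.groupby(level="location"):
            q5_ratio_loc[str(loc)] = float(np.median(sub["male"] / sub["female"]))
    cbh = getattr(inputs, "cbh", None)
    if cbh is not None and len(cbh) and "sex" in cbh.columns:
        for loc, sub in cbh.groupby("location"):
            if loc in q5_ratio_loc:
                continue
            qs = {}
            for sex in SEXES:
                ssub = sub[sub["sex"] == sex]
                try:
                    qs[sex], _ = sve.cbh_direct_5q0(
                        ssub,
                        (float(sub["survey_year"].min() - 13),
                         float(sub["survey_year"].max())),
                    )
                except ValueError:
                    qs[sex] = np.nan
            if np.isfinite(qs.get("male", np.nan)) and qs.get("female", 0) > 0:
                q5_ratio_loc[str(loc)] = float(qs["male"] / qs["female"])
    q5_sex_ratio = (
        float(np.median(list(q5_ratio_loc.values()))) if q5_ratio_loc else 1.15
    )

    # ---- stages 5-8: model life tables, HIV, shocks, e0 -------------------
    library = build_library(inputs, ddm, config)
    rr = hiv_relative_risk_pattern()
    e0_draws: dict[tuple[str, str], np.ndarray] = {}
    q5_final: dict[tuple[str, str], np.ndarray] = {}
    q45_final: dict[tuple[str, str], np.ndarray] = {}
    mx_mean_store: dict[tuple[str, str], np.ndarray] = {}
    shock_reports = []
    draw_rngs = np.random.default_rng(rng_root)

    for loc in locations:
        q5_s = q5_series[loc]
        nathist = inputs.hiv_nathist.get(loc) if hasattr(inputs, "hiv_nathist") else None
        for sex in SEXES:
            pop = inputs.population[(loc, sex)]
            q45_s = q45_series[(loc, sex)]
            flags = complete_vr.get((loc, sex), np.zeros(ny, bool))
            loc_ratio = q5_ratio_loc.get(loc, q5_sex_ratio)
            ratio = loc_ratio if sex == "male" else 1.0
            split = 2.0 * ratio / (1.0 + loc_ratio)
            q5_draws = np.clip(q5_s.draws * split, 1e-6, 0.99)
            q45_draws = np.clip(q45_s.draws, 1e-6, 0.99)

            cdr = cdr_by_loc[loc]
            hiv_regime = (cdr.max() > config.hiv_cdr_floor) and not flags.all()
            # observations entered the ST-GPR in HIV-free space, so the
            # series draws are already HIV-free targets
            q5_fit, q45_fit = q5_draws, q45_draws
            if hiv_regime:
                added_mx, _, _ = hiv_q_contributions(cdr, pop)
                if nathist is not None:
                    added_nh, _, _ = hiv_q_contributions(nathist, pop)
                    added_recon = mlt.reconcile_hiv_draws(added_mx, added_nh)
                else:
                    added_recon = added_mx
            else:
                added_recon = np.zeros((ny, N_AGE))

            lx_draws = np.empty((ny, config.n_draws, len(mlt.EXTENDED_AGES)))
            mx23 = np.empty((ny, N_AGE))
            for t in range(ny):
                if flags[t]:
                    mx_obs = _smooth_mx(vr_mx_store[(loc, sex)], t, config.vr_smooth_window)
                    lt = build_abridged_lifetable(
                        AgeSchedule(GRID, Sex(sex), mx_obs), "constant_hazard"
                    )
                    lx_t = _extend_lx(lt)
                    # sampling noise on registered counts propagates to draws
                    deaths_t = mx_obs * pop[t]
                    se = np.sqrt(np.maximum(deaths_t, 1.0)) / np.maximum(pop[t], 1.0)
                    noise = draw_rngs.standard_normal((config.n_draws, N_AGE))
                    mx_d = np.clip(
                        mx_obs[None, :] + se[None, :] * noise, 1e-8, None
                    )
                    # rebuild lx draws from rate draws (vectorised, closed form)
                    lx_draws[t] = _lx_draws_from_mx(mx_d)
                    mx23[t] = mx_obs
                else:
                    if library is None:
                        raise ValueError(
                            "no empirical life tables available for the "
                            "model life table standard"
                        )
                    standard, _ = mlt.select_standard(
                        (float(np.median(q5_fit[t])), float(np.median(q45_fit[t]))),
                        loc,
                        float(years[t]),
                        library,
                        Sex(sex),
                        hierarchy=hierarchy,
                    )
                    fitted = mlt.fit_relational_many(
                        standard, q5_fit[t], q45_fit[t]
                    )
                    lx_draws[t] = fitted
                    mx23[t] = np.nan
                if hiv_regime and not flags[t]:
                    # overlay reconciled HIV rates onto the fitted draws
                    lx_draws[t] = _overlay_on_lx(lx_draws[t], added_recon[t])

            # shocks
            events = inputs.shock_events
            ev_loc = events[events["location"] == loc]
            shock_added = np.zeros(ny)
            if len(ev_loc):
                pop_tot_by_year = pop.sum(axis=1) * 2.0  # both sexes approx
                for _, ev in ev_loc.iterrows():
                    t = int(ev["year"] - inputs.years[0])
                    rate = ev["deaths"] / pop_tot_by_year[t]
                    included = (
                        rate > mlt.SHOCK_RATE_THRESHOLD
                        or ev["deaths"] > mlt.SHOCK_COUNT_THRESHOLD
                    )
                    shock_reports.append(
                        {
                            "location": loc,
                            "year": int(ev["year"]),
                            "cause": ev["cause"],
                            "deaths": float(ev["deaths"]),
                            "included": bool(included),
                            "sex": sex,
                        }
                    )
                    if included:
                        shock_added[t] += rate  # uniform added rate
            if shock_added.any():
                for t in np.nonzero(shock_added)[0]:
                    lx_draws[t] = _overlay_on_lx(
                        lx_draws[t], np.full(N_AGE, shock_added[t])
                    )

            key = (loc, sex)
            e0_mat = np.empty((ny, config.n_draws))
            q5_mat = np.empty((ny, config.n_draws))
            q45_mat = np.empty((ny, config.n_draws))
            for t in range(ny):
                e0_mat[t] = mlt.e0_from_lx_matrix(lx_draws[t])
                q5_mat[t], q45_mat[t] = mlt.summaries_from_lx_matrix(lx_draws[t])
            e0_draws[key] = e0_mat
            q5_final[key] = q5_mat
            q45_final[key] = q45_mat
            mx_mean_store[key] = _mx_mean_from_lx(lx_draws)

    # ---- stage 9: stillbirths ---------------------------------------------
    sbr_series = _stillbirth_stage(inputs, mx_mean_store, covs, hierarchy, config)

    # ---- stage 10: SDI and expected mortality ------------------------------
    sdi_df, expected_df = _sdi_stage(
        inputs, covs, mx_mean_store, e0_draws, config
    )

    bundle = OutputBundle(
        config=config,
        years=years,
        hierarchy=inputs.hierarchy,
        completeness=ddm,
        observations=pd.concat(
            [all_child.assign(parameter="5q0"),
             pd.concat([adult_obs, vr_adult], ignore_index=True).assign(parameter="45q15")],
            ignore_index=True,
        ),
        q5_series=q5_series,
        q45_series=q45_series,
        e0_draws=e0_draws,
        q5_final=q5_final,
        q45_final=q45_final,
        mx_mean=mx_mean_store,
        sbr_series=sbr_series,
        sdi=sdi_df,
        expected=expected_df,
        manifest={
            "seed": config.seed,
            "n_draws": config.n_draws,
            "runtime_s": round(time.time() - t_start, 2),
            "bias_offsets": offsets,
            "q5_sex_ratio": q5_sex_ratio,
        },
        shock_report=pd.DataFrame(shock_reports),
    )
    bundle.tables = summarize_results(bundle, inputs)
    if config.output_dir is not None:
        _write_outputs(bundle, config.output_dir)
    return bundle


def _lx_draws_from_mx(mx_d: np.ndarray) -> np.ndarray:
    """Survivorship draws at EXTENDED_AGES from 23-group rate draws."""
    widths = np.where(np.isfinite(GRID.widths), GRID.widths, 15.0)
    cumhaz = np.cumsum(mx_d * widths[None, :], axis=1)
    lx23 = np.concatenate(
        [np.ones((mx_d.shape[0], 1)), np.exp(-cumhaz[:, :-1])], axis=1
    )
    bounds = GRID.starts
    loghaz = np.log(np.clip(lx23, 1e-300, None))
    # vectorised interpolation in log-survivorship over group bounds
    out = np.exp(
        _interp_rows(mlt.EXTENDED_AGES, bounds, loghaz, mx_d[:, -1])
    )
    out[:, 0] = 1.0
    return np.minimum.accumulate(out, axis=1)


def _interp_rows(x_new, x_old, y_rows, tail_haz) -> np.ndarray:
    out = np.empty((y_rows.shape[0], len(x_new)))
    inside = x_new <= x_old[-1]
    idx = np.clip(np.searchsorted(x_old, x_new[inside], side="right") - 1, 0, len(x_old) - 2)
    x0, x1 = x_old[idx], x_old[idx + 1]
    frac = (x_new[inside] - x0) / np.maximum(x1 - x0, 1e-12)
    out[:, inside] = y_rows[:, idx] + (y_rows[:, idx + 1] - y_rows[:, idx]) * frac[None, :]
    beyond = ~inside
    if beyond.any():
        out[:, beyond] = (
            y_rows[:, -1][:, None]
            - tail_haz[:, None] * (x_new[beyond] - x_old[-1])[None, :]
        )
    return out


def _overlay_on_lx(lx_mat: np.ndarray, added_mx: np.ndarray) -> np.ndarray:
    """Add 23-group excess rates to survivorship draws via cumulative hazard."""
    bounds = GRID.starts
    widths = np.where(np.isfinite(GRID.widths), GRID.widths, 15.0)
    cum_added = np.concatenate([[0.0], np.cumsum(added_mx * widths)])
    # cumulative added hazard at EXTENDED_AGES
    bounds_ext = np.append(bounds, bounds[-1] + 15.0)
    cum_at = np.interp(mlt.EXTENDED_AGES, bounds_ext, cum_added)
    return lx_mat * np.exp(-cum_at)[None, :]


def _mx_mean_from_lx(lx_draws: np.ndarray) -> np.ndarray:
    """Mean 23-group rates from survivorship draws (all years)."""
    ny = lx_draws.shape[0]
    out = np.empty((ny, N_AGE))
    for t in range(ny):
        mean_lx = lx_draws[t].mean(axis=0)
        lt = mlt.lifetable_from_lx(mean_lx, GRID)
        out[t] = lt.mx
    return out


def _stillbirth_stage(inputs, mx_mean, covs, hierarchy, config):
    from mortality_engine.stillbirths import estimate_stillbirth_rate

    obs = inputs.stillbirth_obs
    if obs is None or not len(obs):
        return {}
    table = DefinitionScalarTable.default()
    rows = []
    for _, r in obs.iterrows():
        o = standardize_definition(
            StillbirthObservation(
                r["location"], float(r["year"]), float(r["rate"]), r["definition"]
            ),
            table,
        )
        rows.append({"location": o.location, "year": o.year, "rate": o.rate})
    std_obs = pd.DataFrame(rows)

    # NMR estimate series per location from the final mx surfaces
    years = inputs.years.astype(float)
    nmr_series: dict[str, EstimateSeries] = {}
    for loc in inputs.locations:
        m = (mx_mean[(loc, "male")] + mx_mean[(loc, "female")]) / 2.0
        nmr = 1000.0 * (1.0 - np.exp(-(m[:, 0] * 7 / 365 + m[:, 1] * 21 / 365)))
        nmr = np.clip(nmr, 0.1, None)
        # modest lognormal spread stands in for the propagated child draws
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 888, int(loc[1:])])
        )
        draws = nmr[:, None] * np.exp(
            rng.normal(0.0, 0.04, (len(years), config.n_draws))
        )
        nmr_series[loc] = EstimateSeries(loc, years, nmr, draws)

    ratio_rows = []
    for _, r in std_obs.iterrows():
        loc = r["location"]
        t = int(r["year"] - inputs.years[0])
        nmr_t = nmr_series[loc].mean[t]
        ratio = max(r["rate"] / max(nmr_t, 0.1), 1e-3)
        ratio_rows.append(
            {
                "location": loc,
                "year": float(r["year"]),
                "value": ratio,
                "variance": (0.1 * ratio) ** 2,
                "source_type": "survey",
            }
        )
    ratio_obs = pd.DataFrame(ratio_rows)
    births = pd.DataFrame(
        [
            {"location": loc, "year": float(y), "livebirths": inputs.births[loc][t]}
            for loc in inputs.locations
            for t, y in enumerate(inputs.years)
        ]
    )
    education = covs[["location", "year", "education"]].copy()
    education["year"] = education["year"].astype(float)
    sbr, _counts = estimate_stillbirth_rate(
        ratio_obs,
        education,
        nmr_series,
        births,
        hierarchy,
        STGPRConfig(
            transform="log",
            n_draws=config.n_draws,
            seed=config.seed + 5,
            eta=0.2,
            rho=14.0,
        ),
    )
    return sbr


def _sdi_stage(inputs, covs, mx_mean, e0_draws, config):
    rows = []
    for _, r in covs.iterrows():
        components = sdi_mod.SDIComponents(
            ldi=r["ldi"], education=r["education"], tfr=r["tfr"],
            limits=config.sdi_limits,
        )
        rows.append(
            {
                "location": r["location"],
                "year": r["year"],
                "sdi": sdi_mod.compute_sdi(components),
            }
        )
    sdi_df = pd.DataFrame(rows)
    ref_year = int(inputs.years[-1])
    sdi_2016 = sdi_df[sdi_df["year"] == ref_year]["sdi"].to_numpy()
    thresholds = sdi_mod.quintile_thresholds(sdi_2016)
    sdi_df["quintile"] = [
        sdi_mod.assign_quintile(s, thresholds) for s in sdi_df["sdi"]
    ]

    # expected mortality curves per age-sex on a thinned panel
    sdi_ix = sdi_df.set_index(["location", "year"])["sdi"]
    years_thin = [int(y) for y in inputs.years[::3]]
    expected_rows = []
    curves: dict[str, dict[str, sdi_mod.ExpectedCurve]] = {s: {} for s in SEXES}
    for sex in SEXES:
        for a, label in enumerate(GRID.labels):
            mxv, sdiv = [], []
            for loc in inputs.locations:
                mx = mx_mean[(loc, sex)]
                for y in years_thin:
                    t = int(y - inputs.years[0])
                    if np.isfinite(mx[t, a]) and mx[t, a] > 0:
                        mxv.append(mx[t, a])
                        sdiv.append(sdi_ix.get((loc, y), np.nan))
            mxv, sdiv = np.asarray(mxv), np.asarray(sdiv)
            ok = np.isfinite(mxv) & np.isfinite(sdiv)
            curves[sex][label] = sdi_mod.fit_expected_mortality(
                mxv[ok], sdiv[ok], label, Sex(sex),
                n_draws=config.n_draws, seed=config.seed + 11 + a,
            )

    for loc in inputs.locations:
        for sex in SEXES:
            for y in (1990, 2000, ref_year):
                if y < inputs.years[0]:
                    continue
                t = int(y - inputs.years[0])
                s = float(sdi_ix.get((loc, y), np.nan))
                if not np.isfinite(s):
                    continue
                mx_draw = np.stack(
                    [curves[sex][g].draws_at(s) for g in GRID.labels]
                )  # (23, n_draws)
                exp_e0 = mlt.e0_from_mx_matrix(mx_draw.T, GRID)
                res = sdi_mod.observed_minus_expected(
                    e0_draws[(loc, sex)][t], exp_e0, seed=config.seed
                )
                expected_rows.append(
                    {
                        "location": loc,
                        "sex": sex,
                        "year": y,
                        "sdi": s,
                        "observed_e0": float(e0_draws[(loc, sex)][t].mean()),
                        "expected_e0": float(exp_e0.mean()),
                        "difference": res.difference,
                        "lower": res.lower,
                        "upper": res.upper,
                        "significant": res.significant,
                    }
                )
    return sdi_df, pd.DataFrame(expected_rows)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def default_standard_population() -> StandardPopulation:
    with resources.files("mortality_engine.data").joinpath(
        "standard_population.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("age_group").reindex(GRID.labels)
    return StandardPopulation(GRID, df["weight"].to_numpy())


def sdg_projection(u5mr: float, roc_pct: float, from_year: int = 2016) -> bool:
    """Would the location meet the SDG U5MR target (<= 25 per 1000) by 2030,
    projecting the current annualised rate of change forward?"""
    projected = u5mr * math.exp(roc_pct / 100.0 * (SDG_TARGET_YEAR - from_year))
    return projected <= SDG_U5MR_TARGET


def summarize_results(bundle: OutputBundle, inputs) -> dict[str, pd.DataFrame]:
    """Headline tables: child/stillbirth levels, life expectancy, ASDR,
    sex gaps, annualised changes, SDG flags, observed-vs-expected."""
    std = default_standard_population()
    years = bundle.years
    y0, y1 = int(years[0]), int(years[-1])
    t1 = len(years) - 1
    t2000 = int(2000 - y0)
    rows = []
    for loc in inputs.locations:
        row = {"location": loc}
        for sex in SEXES:
            e0d = bundle.e0_draws[(loc, sex)]
            lo, hi = compute_ui(e0d[t1])
            row[f"e0_{sex}"] = float(e0d[t1].mean())
            row[f"e0_{sex}_lower"], row[f"e0_{sex}_upper"] = lo, hi
            row[f"q45_{sex}"] = float(bundle.q45_final[(loc, sex)][t1].mean())
            mx = bundle.mx_mean[(loc, sex)][t1]
            row[f"asdr_{sex}"] = age_standardize(
                AgeSchedule(GRID, Sex(sex), mx), std, per=1e5
            )
        row["sex_gap"] = row["e0_female"] - row["e0_male"]
        q5_b = float(
            (bundle.q5_final[(loc, "male")][t1] + bundle.q5_final[(loc, "female")][t1]).mean()
            / 2.0
        )
        q5_2000 = float(
            (bundle.q5_final[(loc, "male")][t2000] + bundle.q5_final[(loc, "female")][t2000]).mean()
            / 2.0
        )
        row["u5mr_per1000"] = 1000.0 * q5_b
        row["u5mr_roc_2000_pct"] = annualized_roc(
            max(q5_2000, 1e-6), max(q5_b, 1e-6), y1 - 2000
        )
        row["sdg_u5mr_met_2030"] = sdg_projection(
            row["u5mr_per1000"], row["u5mr_roc_2000_pct"], y1
        )
        if loc in bundle.sbr_series:
            s = bundle.sbr_series[loc]
            row["sbr_per1000"] = float(s.mean[t1])
        rows.append(row)
    levels = pd.DataFrame(rows)

    # under-5 death shares by region
    share_rows = []
    total_u5 = 0.0
    by_region = {}
    hier = inputs.hierarchy.set_index("location")["region"]
    for loc in inputs.locations:
        deaths_u5 = 0.0
        for sex in SEXES:
            pop_u5 = inputs.population[(loc, sex)][t1][:4]
            mx_u5 = bundle.mx_mean[(loc, sex)][t1][:4]
            deaths_u5 += float((pop_u5 * mx_u5).sum())
        region = hier.get(loc, "")
        by_region[region] = by_region.get(region, 0.0) + deaths_u5
        total_u5 += deaths_u5
    for region, d in sorted(by_region.items()):
        share_rows.append(
            {"region": region, "under5_deaths": d, "share_pct": 100.0 * d / total_u5}
        )
    shares = pd.DataFrame(share_rows)

    return {
        "levels": levels,
        "under5_shares": shares,
        "expected": bundle.expected,
        "completeness": bundle.completeness,
    }


def _write_outputs(bundle: OutputBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
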