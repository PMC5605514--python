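"""Synthetic worlds with known ground truth.

Generates miniature multi-location worlds emulating the data regimes the
estimation pipeline must handle: smooth age-specific mortality surfaces
over locations and years (built by Brass-relational perturbation of a
baseline standard, so the model life table family is well specified),
incomplete death registration with census pairs, complete and summary
birth histories, sibling survival histories in which only survivors can
report (so selection bias is real in the data), HIV epidemics concentrated
at ages 15-49, discrete mortality shocks, correlated covariates, and
stillbirth observations under heterogeneous definitions.

Every dataset is regenerable bit-identically from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from mortality_engine.demographic_core import (
    AgeGrid,
    AgeSchedule,
    Sex,
    build_abridged_lifetable,
)
from mortality_engine.model_lifetable import (
    EXTENDED_AGES,
    e0_from_lx_matrix,
    lifetable_from_lx,
)
from mortality_engine.vr_completeness import CensusPair

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "save_world",
    "WorldInputs",
    "baseline_standard",
    "stable_population",
    "hiv_relative_risk_pattern",
]

GRID = AgeGrid.gbd()
N_AGE = len(GRID)


# ---------------------------------------------------------------------------
# Baseline mortality standard
# ---------------------------------------------------------------------------

def _hazard(ages: np.ndarray, sex: Sex) -> np.ndarray:
    child = 0.085 * np.exp(-1.1 * ages)
    background = 0.0016
    senescent = 2.2e-5 * np.exp(0.098 * ages)
    if sex == Sex.MALE:
        return 1.08 * child + 1.6 * background + 1.35 * senescent
    return child + background + senescent


def baseline_standard(sex: Sex) -> np.ndarray:
    """Baseline survivorship at :data:`EXTENDED_AGES` (the world standard)."""
    fine = np.linspace(0.0, 110.0, 2201)
    h = _hazard(fine, sex)
    cum = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(fine))])
    return np.interp(EXTENDED_AGES, fine, np.exp(-cum))


def _logit_l(l: np.ndarray) -> np.ndarray:
    l = np.clip(l, 1e-12, 1 - 1e-12)
    return 0.5 * np.log((1.0 - l) / l)


def _brass(standard: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    out = np.empty_like(standard)
    out[0] = 1.0
    out[1:] = 1.0 / (1.0 + np.exp(2.0 * (alpha + beta * _logit_l(standard[1:]))))
    return np.minimum.accumulate(out)


def hiv_relative_risk_pattern() -> np.ndarray:
    """Relative risk of HIV death by GBD age group, peaked at ages 25-45."""
    mids = np.array(
        [g.start + (g.width if math.isfinite(g.width) else 5.0) / 2 for g in GRID]
    )
    adult = np.exp(-0.5 * ((mids - 33.0) / 9.0) ** 2)
    child = np.where(mids < 5.0, 0.25, 0.0)  # vertical transmission
    rr = adult + child
    return rr / rr.max()


def stable_population(
    mx: AgeSchedule,
    growth: float,
    size: float,
    date1: float,
    date2: float,
) -> tuple[CensusPair, AgeSchedule]:
    """Stable-population census pair and true mean annual deaths.

    The age distribution is proportional to exp(-growth * age) * nLx; deaths
    follow the age-specific rates.  Used as the oracle world for the death
    distribution methods.
    """
    lt = build_abridged_lifetable(mx, "constant_hazard")
    mids = np.where(
        np.isfinite(mx.grid.widths),
        mx.grid.starts + mx.grid.widths / 2,
        mx.grid.starts + 2.5,
    )
    n = np.exp(-growth * mids) * lt.Lx
    n = n / n.sum() * size
    T = date2 - date1
    pair = CensusPair(mx.grid, date1, date2, n, n * np.exp(growth * T))
    deaths = AgeSchedule(mx.grid, mx.sex, n * np.exp(growth * T / 2) * mx.values)
    return pair, deaths


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    Defaults mirror the two estimation regimes at toy scale: 12 locations
    in 3 regions over 1970-2016, four with complete registration, six with
    partial registration, and two with surveys only; two locations carry a
    generalised HIV epidemic.
    """

    seed: int = 0
    n_locations: int = 12
    n_regions: int = 3
    year_start: int = 1970
    year_end: int = 2016
    #: per-location data regime, cycled if shorter than n_locations
    roles: tuple[str, ...] = (
        "vr", "vr", "vr", "vr",
        "partial", "partial", "partial", "partial", "partial", "partial",
        "survey", "survey",
    )
    hiv_locations: tuple[str, ...] = ("L09", "L11")
    hiv_peak_cdr: float = 0.006          # deaths per person-year at epidemic peak
    hiv_peak_year: float = 2002.0
    hiv_width: float = 7.0
    e0_range: tuple[float, float] = (50.0, 85.0)
    shock_rate: float = 0.05             # events per location-year
    census_years: tuple[int, ...] = (1980, 1990, 2000, 2010)
    survey_interval: int = 5
    first_survey_year: int = 1987
    n_mothers: int = 5000
    n_respondents: int = 6000
    sibship_mean_size: float = 4.0
    sibship_frailty_sd: float = 0.30
    stillbirth_definition_mix: tuple[tuple[str, float], ...] = (
        ("28wk", 0.45), ("22wk", 0.15), ("24wk", 0.10),
        ("500g", 0.10), ("1000g", 0.10), ("none", 0.10),
    )
    stillbirth_noise_sd: float = 0.08
    covariate_noise_sd: float = 0.05

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def locations(self) -> list[str]:
        return [f"L{i:02d}" for i in range(self.n_locations)]

    def role_of(self, loc: str) -> str:
        i = int(loc[1:])
        return self.roles[i % len(self.roles)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    hierarchy: pd.DataFrame                      # location, region, role
    years: np.ndarray
    standard_lx: dict[str, np.ndarray]           # per sex
    # truth surfaces, keyed (location, sex_value): arrays (n_years, ...)
    truth_mx: dict[tuple[str, str], np.ndarray]          # with HIV, no shocks
    truth_mx_hiv_free: dict[tuple[str, str], np.ndarray]
    truth_e0: dict[tuple[str, str], np.ndarray]
    truth_e0_hiv_free: dict[tuple[str, str], np.ndarray]
    truth_q5: dict[tuple[str, str], np.ndarray]
    truth_q45: dict[tuple[str, str], np.ndarray]
    truth_lx: dict[tuple[str, str], np.ndarray]          # (n_years, EXTENDED_AGES)
    population: dict[tuple[str, str], np.ndarray]        # (n_years, 23)
    deaths: dict[tuple[str, str], np.ndarray]
    completeness: dict[str, np.ndarray]                  # per location, (n_years,)
    hiv_cdr: dict[str, np.ndarray]
    tfr: dict[str, np.ndarray]
    ldi: dict[str, np.ndarray]
    education: dict[str, np.ndarray]
    births: dict[str, np.ndarray]
    sbr: dict[str, np.ndarray]                           # per 1000 livebirths
    hiv_nathist: dict[str, np.ndarray]                   # natural-history CDR input
    shock_events: pd.DataFrame
    manifest: dict

    # observation datasets (filled by the simulate_* functions)
    vr_deaths: pd.DataFrame | None = None
    censuses: dict[tuple[str, int], CensusPair] = field(default_factory=dict)
    cbh: pd.DataFrame | None = None
    sbh: pd.DataFrame | None = None
    siblings: pd.DataFrame | None = None
    stillbirth_obs: pd.DataFrame | None = None

    @property
    def grid(self) -> AgeGrid:
        return GRID

    @property
    def locations(self) -> list[str]:
        return self.config.locations

    def year_index(self, year: float) -> int:
        return int(year - self.config.year_start)

    def truth_q5_both(self, loc: str) -> np.ndarray:
        qs = [self.truth_q5[(loc, s)] for s in ("male", "female")]
        return (qs[0] + qs[1]) / 2.0

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for loc in self.config.locations:
            for i, y in enumerate(self.years):
                rows.append(
                    {
                        "location": loc,
                        "year": int(y),
                        "ldi": self.ldi[loc][i],
                        "log_ldi": math.log(self.ldi[loc][i]),
                        "education": self.education[loc][i],
                        "tfr": self.tfr[loc][i],
                        "hiv_cdr": self.hiv_cdr[loc][i],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

FERTILITY_AGES = np.arange(15, 50)


def fertility_pattern() -> np.ndarray:
    """Normalised single-year age pattern of fertility (peak late 20s)."""
    f = np.exp(-0.5 * ((FERTILITY_AGES - 27.0) / 6.5) ** 2)
    return f / f.sum()


#: Fine age axis for the truth surfaces: neonatal sub-bounds then single years.
AGES_FINE = np.concatenate([[0.0, 7 / 365, 28 / 365], np.arange(1.0, 111.0)])
#: Positions of integer ages 0..110 on AGES_FINE.
_INT_POS = np.array([0] + list(range(3, 113)))
#: GBD group index for single-year ages 1..109 (age 0 split separately).
_GRP_SINGLE = np.empty(110, int)
_GRP_SINGLE[0] = 0
_GRP_SINGLE[1:5] = 3
for _a in range(5, 95):
    _GRP_SINGLE[_a] = 4 + (_a - 5) // 5
_GRP_SINGLE[95:] = 22


def _project_population(
    config: WorldConfig,
    logl_free: dict[str, np.ndarray],
    cdr: np.ndarray,
    rr: np.ndarray,
    tfr_series: np.ndarray,
    growth: float,
    size: float,
    rng,
) -> dict:
    """Closed-population cohort-component projection with annual steps.

    Produces exposure (person-years), deaths and births that satisfy the
    demographic accounting identities exactly, so registered deaths and
    census age distributions are mutually consistent — the assumption the
    death distribution methods rely on.
    """
    ny = len(tfr_series)
    male_share = 0.512
    H = {}
    for sex, logl in logl_free.items():
        la = logl[:, _INT_POS]                 # log-survival at integer ages
        H[sex] = la[:, :-1] - la[:, 1:]        # (ny, 110) interval hazards
    rr_single = np.empty(110)
    rr_single[0] = rr[0]
    rr_single[1:] = rr[_GRP_SINGLE[1:]]
    fert = fertility_pattern()

    N = {}
    for sex in ("male", "female"):
        l0 = np.exp(logl_free[sex][0][_INT_POS])
        w = np.exp(-growth * np.arange(111)) * l0
        share = male_share if sex == "male" else 1.0 - male_share
        N[sex] = w / w.sum() * size * share

    exposure = {s: np.zeros((ny, N_AGE)) for s in ("male", "female")}
    deaths_out = {s: np.zeros((ny, N_AGE)) for s in ("male", "female")}
    births_out = np.zeros(ny)
    hiv_scale = np.zeros(ny)
    bsub = np.array([0.0, 7 / 365, 28 / 365, 1.0])
    for t in range(ny):
        B = tfr_series[t] * float((fert * N["female"][15:50]).sum())
        births_out[t] = B
        N["male"][0] = B * male_share
        N["female"][0] = B * (1.0 - male_share)
        if cdr[t] > 0:
            both = N["male"] + N["female"]
            wsum = float((rr_single * both[:110]).sum() + rr[22] * both[110])
            hiv_scale[t] = cdr[t] * both.sum() / max(wsum, 1e-300)
        add = hiv_scale[t] * rr_single
        for sex in ("male", "female"):
            Ns = N[sex]
            h = H[sex][t] + add
            q = 1.0 - np.exp(-h)
            D = Ns[:110] * q
            E_single = Ns[:110] * (1.0 - q / 2.0)
            q_open = 1.0 - np.exp(-(h[109]))
            D_open = Ns[110] * q_open
            # neonatal sub-split of the age-0 cohort
            logl_t = logl_free[sex][t]
            cumh_sub = -logl_t[[0, 1, 2, 3]] + hiv_scale[t] * rr[0] * bsub
            s_sub = np.exp(-(cumh_sub - cumh_sub[0]))
            d_sub = Ns[0] * (s_sub[:-1] - s_sub[1:])
            e_sub = Ns[0] * (s_sub[:-1] + s_sub[1:]) / 2.0 * np.diff(bsub)
            deaths_out[sex][t, 0:3] = d_sub
            exposure[sex][t, 0:3] = e_sub
            np.add.at(deaths_out[sex][t], _GRP_SINGLE[1:], D[1:])
            np.add.at(exposure[sex][t], _GRP_SINGLE[1:], E_single[1:])
            deaths_out[sex][t, 22] += D_open
            exposure[sex][t, 22] += Ns[110] * (1.0 - q_open / 2.0)
            nxt = np.empty_like(Ns)
            nxt[0] = 0.0
            nxt[1:110] = Ns[0:109] - D[0:109]
            nxt[110] = Ns[109] - D[109] + Ns[110] - D_open
            N[sex] = nxt
    return {
        "exposure": exposure,
        "deaths": deaths_out,
        "births": births_out,
        "hiv_scale": hiv_scale,
    }


def _added_hazard_base() -> np.ndarray:
    """Cumulative RR-weighted hazard integral at EXTENDED_AGES for unit scale."""
    rr = hiv_relative_risk_pattern()
    starts = GRID.starts
    widths = np.where(np.isfinite(GRID.widths), GRID.widths, 15.0)
    cum = np.concatenate([[0.0], np.cumsum(rr * widths)])
    bounds = np.append(starts, starts[-1] + 15.0)
    return np.interp(EXTENDED_AGES, bounds, cum)


_ADDED_BASE = None


def _cumulative_added_hazard(hiv_scale: np.ndarray, rr: np.ndarray) -> np.ndarray:
    global _ADDED_BASE
    if _ADDED_BASE is None:
        _ADDED_BASE = _added_hazard_base()
    return hiv_scale[:, None] * _ADDED_BASE[None, :]


def _group_rates_from_lx_rows(lx_rows: np.ndarray) -> np.ndarray:
    """23-group central death rates from survivorship rows at EXTENDED_AGES."""
    ages = EXTENDED_AGES
    n_rows = lx_rows.shape[0]
    out = np.empty((n_rows, N_AGE))
    for g in range(N_AGE - 1):
        la, lb = lx_rows[:, g], lx_rows[:, g + 1]
        width = ages[g + 1] - ages[g]
        E = (la + lb) / 2.0 * width
        out[:, g] = (la - lb) / np.maximum(E, 1e-300)
    # open interval: trapezoid to the last tabulated age plus constant-
    # hazard tail
    tail = np.trapezoid(lx_rows[:, 22:], ages[22:], axis=1)
    l_last, l_prev = lx_rows[:, -1], lx_rows[:, -2]
    h_tail = -np.log(np.clip(l_last / np.clip(l_prev, 1e-300, None), 1e-12, 1.0)) / (
        ages[-1] - ages[-2]
    )
    E_open = tail + l_last / np.maximum(h_tail, 1e-6)
    out[:, 22] = lx_rows[:, 22] / np.maximum(E_open, 1e-300)
    return out


def _child_survival_curve(lx_ext: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fine (age, cumulative death probability) curve on [0, 5] years."""
    ages = np.array([0.0, 7 / 365, 28 / 365, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0])
    anchor = np.array([0.0, 7 / 365, 28 / 365, 1.0, 5.0])
    l_anchor = np.interp(anchor, EXTENDED_AGES, lx_ext)
    # log-linear interpolation of survivorship between tabulated child ages
    logl = np.interp(ages, anchor, np.log(np.clip(l_anchor, 1e-12, None)))
    return ages, 1.0 - np.exp(logl)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build truth surfaces and all observation datasets for a world."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    years = config.years
    ny = len(years)
    locs = config.locations
    regions = [f"R{i % config.n_regions}" for i in range(config.n_locations)]
    hierarchy = pd.DataFrame(
        {
            "location": locs,
            "region": regions,
            "role": [config.role_of(l) for l in locs],
        }
    )

    standard = {s.value: baseline_standard(s) for s in (Sex.MALE, Sex.FEMALE)}
    rr = hiv_relative_risk_pattern()

    truth_mx, truth_free, truth_e0, truth_q5, truth_q45 = {}, {}, {}, {}, {}
    truth_e0_free, truth_lx = {}, {}
    population, deaths = {}, {}
    completeness, hiv_cdr, tfr, ldi, education, births, sbr = (
        {}, {}, {}, {}, {}, {}, {},
    )
    tnorm = (years - years[0]) / (years[-1] - years[0])

    # regional level and trend effects keep siblings correlated
    region_level = {r: rng.normal(0.0, 0.18) for r in sorted(set(regions))}
    for i, loc in enumerate(locs):
        role = config.role_of(loc)
        base = {"vr": -0.28, "partial": 0.18, "survey": 0.38}[role]
        a0 = base + region_level[regions[i]] + rng.normal(0.0, 0.10)
        decline = rng.uniform(0.28, 0.50)
        beta = rng.uniform(0.92, 1.08)
        alpha_t = a0 - decline * tnorm + 0.02 * np.sin(tnorm * 6.0 + i)
        sex_gap = rng.uniform(0.05, 0.11)

        # HIV epidemic path
        if loc in config.hiv_locations:
            cdr = config.hiv_peak_cdr * np.exp(
                -0.5 * ((years - config.hiv_peak_year) / config.hiv_width) ** 2
            )
        else:
            cdr = np.zeros(ny)
        hiv_cdr[loc] = cdr

        growth = rng.uniform(0.012, 0.024)
        size = float(np.exp(rng.uniform(np.log(1.5e6), np.log(3e7))))

        # covariates correlated with the mortality level (needed for the
        # fertility-driven population projection below); covariate error is
        # smooth over time, as real covariates are themselves modelled series
        def smooth_noise(sd: float) -> np.ndarray:
            raw = rng.normal(0, sd, ny + 8)
            kernel = np.hanning(9)
            kernel /= np.sqrt((kernel**2).sum())
            return np.convolve(raw, kernel, mode="valid")[:ny]

        tfr[loc] = np.clip(
            6.8 + 2.2 * (alpha_t - alpha_t.mean()) - 3.6 * tnorm
            + smooth_noise(config.covariate_noise_sd),
            1.4,
            8.5,
        )
        ldi[loc] = np.exp(
            8.6 - 1.8 * alpha_t + 0.9 * tnorm + smooth_noise(config.covariate_noise_sd)
        )
        education[loc] = np.clip(
            7.5 - 5.5 * alpha_t + 4.5 * tnorm + smooth_noise(0.1), 0.5, 17.0
        )

        # --- HIV-free survivorship surfaces per sex ------------------------
        logl_free = {}
        alpha_used = {}
        lo_e, hi_e = config.e0_range
        for sex in (Sex.MALE, Sex.FEMALE):
            std = standard[sex.value]
            off = sex_gap / 2 if sex == Sex.MALE else -sex_gap / 2
            # clip the level parameter so HIV-free e0 stays in the
            # configured range (e0 is monotone decreasing in alpha)
            a_grid = np.linspace(-1.2, 1.2, 49)
            e0_grid = np.array(
                [lifetable_from_lx(_brass(std, a, beta), GRID, sex).e0 for a in a_grid]
            )
            a_hi = float(np.interp(-hi_e, -e0_grid, a_grid))
            a_lo = float(np.interp(-lo_e, -e0_grid, a_grid))
            av = np.clip(alpha_t + off, a_hi, a_lo)
            alpha_used[sex.value] = av
            ys = _logit_l(std[1:])
            lx_ext = np.empty((ny, len(EXTENDED_AGES)))
            lx_ext[:, 0] = 1.0
            lx_ext[:, 1:] = 1.0 / (
                1.0 + np.exp(2.0 * (av[:, None] + beta * ys[None, :]))
            )
            lx_ext = np.minimum.accumulate(lx_ext, axis=1)
            logl = np.log(np.clip(lx_ext, 1e-300, None))
            # interpolate to single-year ages (keeping neonatal sub-bounds)
            logl_free[sex.value] = np.stack(
                [np.interp(AGES_FINE, EXTENDED_AGES, row) for row in logl]
            )

        # --- cohort-component projection (closed population) ---------------
        proj = _project_population(
            config, logl_free, cdr, rr, tfr[loc], growth, size, rng
        )
        births[loc] = proj["births"]
        for sex in ("male", "female"):
            key = (loc, sex)
            population[key] = proj["exposure"][sex]
            deaths[key] = proj["deaths"][sex]
            with np.errstate(invalid="ignore", divide="ignore"):
                truth_mx[key] = np.where(
                    proj["exposure"][sex] > 0,
                    proj["deaths"][sex] / np.maximum(proj["exposure"][sex], 1e-300),
                    0.0,
                )
            # period truth from the total (HIV-inclusive) hazard surface
            cum_added = _cumulative_added_hazard(proj["hiv_scale"], rr)
            lx_tot = np.exp(
                np.stack(
                    [
                        np.interp(EXTENDED_AGES, AGES_FINE, row)
                        for row in logl_free[sex]
                    ]
                )
                - cum_added
            )
            truth_lx[key] = lx_tot
            truth_e0[key] = e0_from_lx_matrix(lx_tot)
            i5 = int(np.searchsorted(EXTENDED_AGES, 5.0))
            i15 = int(np.searchsorted(EXTENDED_AGES, 15.0))
            i60 = int(np.searchsorted(EXTENDED_AGES, 60.0))
            truth_q5[key] = 1.0 - lx_tot[:, i5]
            truth_q45[key] = 1.0 - lx_tot[:, i60] / lx_tot[:, i15]
            lx_free_ext = np.exp(
                np.stack(
                    [
                        np.interp(EXTENDED_AGES, AGES_FINE, row)
                        for row in logl_free[sex]
                    ]
                )
            )
            truth_e0_free[key] = e0_from_lx_matrix(lx_free_ext)
            truth_free[key] = _group_rates_from_lx_rows(lx_free_ext)

        # registration completeness trajectories
        if role == "vr":
            c = 0.97 + 0.02 * tnorm + rng.normal(0, 0.004, ny)
        elif role == "partial":
            c = 0.45 + 0.45 * tnorm + rng.normal(0, 0.02, ny)
        else:
            c = np.zeros(ny)
        completeness[loc] = np.clip(c, 0.0, 1.05)

        # stillbirth truth via the SBR:NMR ratio surface; the neonatal death
        # rate comes from the both-sex neonatal hazard segments
        nmr = 1000.0 * (
            1.0 - np.exp(
                -(
                    truth_mx[(loc, "male")][:, 0] * 7 / 365
                    + truth_mx[(loc, "male")][:, 1] * 21 / 365
                    + truth_mx[(loc, "female")][:, 0] * 7 / 365
                    + truth_mx[(loc, "female")][:, 1] * 21 / 365
                )
                / 2.0
            )
        )
        ratio = np.exp(0.55 - 0.035 * education[loc] + 0.22 * np.log(nmr / 15.0))
        sbr[loc] = ratio * nmr

    # shocks
    shock_rows = []
    srng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    for loc in locs:
        popall = population[(loc, "male")].sum(axis=1) + population[
            (loc, "female")
        ].sum(axis=1)
        n_events = srng.poisson(config.shock_rate, ny)
        for t in range(ny):
            for _ in range(n_events[t]):
                deaths_ev = float(
                    np.exp(srng.normal(np.log(popall[t] * 2e-5), 1.0))
                )
                cause = srng.choice(["conflict", "disaster", "transport", "epidemic"])
                shock_rows.append(
                    {
                        "location": loc,
                        "year": int(years[t]),
                        "cause": str(cause),
                        "deaths": max(deaths_ev, 1.0),
                    }
                )
    shock_events = pd.DataFrame(
        shock_rows, columns=["location", "year", "cause", "deaths"]
    )

    # fold shock deaths into the truth life expectancy (uniform added rate)
    for loc in locs:
        popall = population[(loc, "male")].sum(axis=1) + population[
            (loc, "female")
        ].sum(axis=1)
        ev = shock_events[shock_events["location"] == loc]
        if not len(ev):
            continue
        shock_rate = np.zeros(ny)
        for _, r in ev.iterrows():
            t = int(r["year"] - years[0])
            shock_rate[t] += r["deaths"] / popall[t]
        if not shock_rate.any():
            continue
        for sex in ("male", "female"):
            key = (loc, sex)
            lx_s = truth_lx[key] * np.exp(
                -shock_rate[:, None] * EXTENDED_AGES[None, :]
            )
            truth_e0[key] = e0_from_lx_matrix(lx_s)

    # natural-history model HIV estimates enter the pipeline as inputs;
    # emulate them as the true CDR with multiplicative noise
    nh_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
    hiv_nathist = {
        loc: hiv_cdr[loc] * np.exp(nh_rng.normal(0.0, 0.10, ny))
        for loc in locs
    }

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_locations": config.n_locations,
        "years": [int(years[0]), int(years[-1])],
    }
    world = SyntheticWorld(
        config=config,
        hierarchy=hierarchy,
        years=years,
        standard_lx=standard,
        truth_mx=truth_mx,
        truth_mx_hiv_free=truth_free,
        truth_e0=truth_e0,
        truth_e0_hiv_free=truth_e0_free,
        truth_q5=truth_q5,
        truth_q45=truth_q45,
        truth_lx=truth_lx,
        population=population,
        deaths=deaths,
        completeness=completeness,
        hiv_cdr=hiv_cdr,
        tfr=tfr,
        ldi=ldi,
        education=education,
        births=births,
        sbr=sbr,
        hiv_nathist=hiv_nathist,
        shock_events=shock_events,
        manifest=manifest,
    )
    simulate_vr(world)
    simulate_surveys(world)
    simulate_stillbirth_observations(world)
    return world


# ---------------------------------------------------------------------------
# Observation processes
# ---------------------------------------------------------------------------

def simulate_vr(world: SyntheticWorld, completeness=None) -> pd.DataFrame:
    """Registered deaths (binomially thinned) and intercensal census pairs."""
    config = world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rows = []
    comp = completeness or world.completeness
    for loc in config.locations:
        c = np.clip(comp[loc], 0.0, 1.0)
        if not c.any():
            continue
        for sex in ("male", "female"):
            true_d = world.deaths[(loc, sex)]
            for t, y in enumerate(world.years):
                if c[t] <= 0:
                    continue
                reg = rng.binomial(np.round(true_d[t]).astype(int), c[t])
                for a, lab in enumerate(GRID.labels):
                    rows.append(
                        {
                            "location": loc,
                            "year": int(y),
                            "sex": sex,
                            "age_group": lab,
                            "registered_deaths": int(reg[a]),
                        }
                    )
        usable = [
            cy for cy in config.census_years
            if config.year_start <= cy <= config.year_end
        ]
        for cy1, cy2 in zip(usable[:-1], usable[1:]):
            t1, t2 = world.year_index(cy1), world.year_index(cy2)
            pop1 = sum(world.population[(loc, s)][t1] for s in ("male", "female"))
            pop2 = sum(world.population[(loc, s)][t2] for s in ("male", "female"))
            world.censuses[(loc, cy1)] = CensusPair(
                GRID, float(cy1), float(cy2), pop1, pop2
            )
    world.vr_deaths = pd.DataFrame(
        rows,
        columns=["location", "year", "sex", "age_group", "registered_deaths"],
    )
    return world.vr_deaths


def _simulate_mothers(
    world: SyntheticWorld, loc: str, survey_year: int, n_mothers: int, rng
) -> pd.DataFrame:
    """Individual birth histories sampled from the true hazards."""
    fp = fertility_pattern()
    ages_at_survey = rng.integers(15, 50, n_mothers)
    rows_b, rows_m = [], []
    tfr_series = world.tfr[loc]
    child_curves = {}
    mother_ids = np.arange(n_mothers)
    # vectorised: for each mother-age-year cell decide a birth
    for a_idx, age in enumerate(FERTILITY_AGES):
        birth_years = survey_year - (ages_at_survey - age)
        valid = (ages_at_survey > age) & (birth_years >= world.years[0])
        if not valid.any():
            continue
        yi = np.clip(birth_years[valid] - world.years[0], 0, len(world.years) - 1)
        p = fp[a_idx] * tfr_series[yi]
        had_birth = rng.random(valid.sum()) < p
        for m, by in zip(mother_ids[valid][had_birth], birth_years[valid][had_birth]):
            rows_b.append((m, by))
    if not rows_b:
        return pd.DataFrame(
            columns=[
                "mother_id", "sex", "birth_date", "death_date",
                "survey_date", "weight",
            ]
        )
    bh = pd.DataFrame(rows_b, columns=["mother_id", "birth_year"])
    bh["birth_date"] = bh["birth_year"] + rng.random(len(bh))
    bh["sex"] = np.where(rng.random(len(bh)) < 0.512, "male", "female")
    yi = np.clip(bh["birth_year"].to_numpy() - world.years[0], 0, len(world.years) - 1)

    # per-birth death age from the sex-specific child survival curve
    death_age = np.full(len(bh), np.nan)
    u = rng.random(len(bh))
    sex_col = bh["sex"].to_numpy()
    for year_ix in np.unique(yi):
        for sex in ("male", "female"):
            if (year_ix, sex) not in child_curves:
                lx = _brass_child_lx(world, loc, sex, int(year_ix))
                child_curves[(year_ix, sex)] = _child_survival_curve(lx)
            ages_c, F = child_curves[(year_ix, sex)]
            sel = (yi == year_ix) & (sex_col == sex)
            if not sel.any():
                continue
            dies = u[sel] < F[-1]
            da = np.full(sel.sum(), np.nan)
            da[dies] = np.interp(u[sel][dies], F, ages_c)
            death_age[sel] = da
    bh["death_date"] = bh["birth_date"] + death_age
    survey_date = survey_year + 0.5
    bh.loc[bh["death_date"] > survey_date, "death_date"] = np.nan
    bh["survey_date"] = survey_date
    bh["weight"] = 1.0
    return bh[["mother_id", "sex", "birth_date", "death_date", "survey_date", "weight"]]


def _brass_child_lx(world: SyntheticWorld, loc: str, sex: str, year_ix: int) -> np.ndarray:
    """Reconstruct the fine lx consistent with the truth mx of a year."""
    mx = world.truth_mx[(loc, sex)][year_ix]
    # child ages only need the first four groups; integrate the hazard
    ages = EXTENDED_AGES
    lx = np.ones_like(ages)
    bounds = [0.0, 7 / 365, 28 / 365, 1.0, 5.0]
    cum = 0.0
    for i in range(4):
        cum += mx[i] * (bounds[i + 1] - bounds[i])
        lx[ages >= bounds[i + 1] - 1e-12] = np.exp(-cum)
    # continue with adult mortality so later interpolation stays sane
    cum_adult = cum
    for i in range(4, N_AGE - 1):
        cum_adult += mx[i] * GRID.widths[i]
        lx[ages >= GRID.starts[i] + GRID.widths[i] - 1e-12] = np.exp(-cum_adult)
    return lx


def simulate_surveys(world: SyntheticWorld, design=None) -> None:
    """Complete/summary birth histories and sibling histories."""
    config = world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    survey_years = list(
        range(config.first_survey_year, config.year_end + 1, config.survey_interval)
    )
    cbh_frames, sbh_rows, sib_frames = [], [], []
    for loc in config.locations:
        role = config.role_of(loc)
        if role == "vr":
            continue
        for sy in survey_years:
            lrng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 404, int(loc[1:]), sy])
            )
            bh = _simulate_mothers(world, loc, sy, config.n_mothers, lrng)
            bh.insert(0, "survey_year", sy)
            bh.insert(0, "location", loc)
            bh["source_type"] = "cbh"
            cbh_frames.append(bh)

            # summary birth histories: aggregate an independent sample
            bh2 = _simulate_mothers(world, loc, sy, config.n_mothers, lrng)
            if len(bh2):
                mage = lrng.integers(15, 50, config.n_mothers)
                bh2["mother_age"] = mage[bh2["mother_id"].to_numpy() % config.n_mothers]
                bh2["dead"] = np.isfinite(bh2["death_date"])
                for lo in range(15, 50, 5):
                    sel = (bh2["mother_age"] >= lo) & (bh2["mother_age"] < lo + 5)
                    sub = bh2[sel]
                    if not len(sub):
                        continue
                    sbh_rows.append(
                        {
                            "location": loc,
                            "survey_year": sy,
                            "mother_age_group": f"{lo}-{lo + 4}",
                            "ceb": int(len(sub)),
                            "cs": int((~sub["dead"]).sum()),
                            "survey_date": sy + 0.5,
                            "weight": 1.0,
                        }
                    )
            sib = _simulate_siblings(world, loc, sy, config, lrng)
            sib_frames.append(sib)
    world.cbh = (
        pd.concat(cbh_frames, ignore_index=True) if cbh_frames else pd.DataFrame()
    )
    world.sbh = pd.DataFrame(sbh_rows)
    world.siblings = (
        pd.concat(sib_frames, ignore_index=True) if sib_frames else pd.DataFrame()
    )


def _simulate_siblings(
    world: SyntheticWorld, loc: str, survey_year: int, config: WorldConfig, rng
) -> pd.DataFrame:
    """Sibships with survivor-only reporting (selection bias is real)."""
    n_target = config.n_respondents
    # oversample candidate sibships; only those with a surviving eligible
    # member aged 15-49 can appear
    n_sibships = int(n_target * 1.6)
    if n_sibships == 0:
        return pd.DataFrame(
            columns=[
                "location", "survey_year", "respondent_id", "sibship_size",
                "n_surviving", "sex", "birth_year", "death_year", "weight",
            ]
        )
    sizes = 1 + rng.poisson(config.sibship_mean_size - 1.0, n_sibships)
    total = sizes.sum()
    sibship_id = np.repeat(np.arange(n_sibships), sizes)
    anchor = rng.integers(survey_year - 49, survey_year - 15, n_sibships)
    birth_year = np.repeat(anchor, sizes) + rng.integers(-8, 9, total)
    sexes = rng.random(total) < 0.5
    frailty = np.exp(
        np.repeat(rng.normal(0.0, config.sibship_frailty_sd, n_sibships), sizes)
    )
    death_year = np.full(total, np.nan)
    alive = np.ones(total, bool)
    y0 = int(world.years[0])
    mx_m = world.truth_mx[(loc, "male")]
    mx_f = world.truth_mx[(loc, "female")]
    starts = GRID.starts
    for y in range(max(y0, int(birth_year.min())), survey_year + 1):
        t = min(max(y - y0, 0), len(world.years) - 1)
        age = y - birth_year
        active = alive & (age >= 0)
        if not active.any():
            continue
        gi = np.clip(np.searchsorted(starts, age[active], side="right") - 1, 0, N_AGE - 1)
        m = np.where(sexes[active], mx_m[t][gi], mx_f[t][gi]) * frailty[active]
        q = 1.0 - np.exp(-np.clip(m, 0.0, 5.0))
        dies = rng.random(active.sum()) < q
        idx = np.nonzero(active)[0][dies]
        alive[idx] = False
        death_year[idx] = y + rng.random(idx.size)

    age_at_survey = survey_year - birth_year
    eligible = alive & (age_at_survey >= 15) & (age_at_survey < 50)
    S = np.bincount(sibship_id[eligible], minlength=n_sibships)
    # respondents are sampled from *individual* surviving eligible persons,
    # so a sibship's chance of being reported is proportional to S — the
    # selection bias the Gakidou-King 1/S weight corrects.  Two respondents
    # from one sibship yield two (legitimate) duplicate reports.
    pool = np.nonzero(eligible)[0]
    if pool.size == 0:
        return pd.DataFrame(
            columns=[
                "location", "survey_year", "respondent_id", "sibship_size",
                "n_surviving", "sex", "birth_year", "death_year", "weight",
            ]
        )
    respondents = rng.choice(pool, size=min(n_target, pool.size), replace=False)
    frames = []
    members_of = {}
    order = np.argsort(sibship_id, kind="stable")
    sorted_ids = sibship_id[order]
    starts_ix = np.searchsorted(sorted_ids, np.arange(n_sibships))
    ends_ix = np.searchsorted(sorted_ids, np.arange(n_sibships), side="right")
    rows_idx, resp_col = [], []
    for r_i, person in enumerate(respondents):
        j = sibship_id[person]
        mem = order[starts_ix[j]:ends_ix[j]]
        rows_idx.append(mem)
        resp_col.append(np.full(mem.size, r_i))
    rows_idx = np.concatenate(rows_idx)
    resp_col = np.concatenate(resp_col)
    out = pd.DataFrame(
        {
            "location": loc,
            "survey_year": survey_year,
            "respondent_id": resp_col,
            "sibship_size": sizes[sibship_id[rows_idx]],
            "n_surviving": S[sibship_id[rows_idx]],
            "sex": np.where(sexes[rows_idx], "male", "female"),
            "birth_year": birth_year[rows_idx].astype(float),
            "death_year": death_year[rows_idx],
            "weight": 1.0,
        }
    )
    return out


def simulate_stillbirth_observations(world: SyntheticWorld, mix=None) -> pd.DataFrame:
    """Stillbirth observations under a heterogeneous definition mix."""
    config = world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    mix = mix or config.stillbirth_definition_mix
    labels = [d for d, _ in mix]
    probs = np.array([w for _, w in mix])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("definition mixture weights must sum to 1")
    from mortality_engine.stillbirths import DefinitionScalarTable

    scalars = DefinitionScalarTable.default().scalars
    rows = []
    for loc in config.locations:
        for t, y in enumerate(world.years):
            if t % 3:
                continue
            definition = labels[int(rng.choice(len(labels), p=probs))]
            noise = math.exp(rng.normal(0.0, config.stillbirth_noise_sd))
            observed = world.sbr[loc][t] / scalars[definition] * noise
            rows.append(
                {
                    "location": loc,
                    "year": int(y),
                    "rate": observed,
                    "definition": definition,
                    "source_type": "survey",
                }
            )
    world.stillbirth_obs = pd.DataFrame(rows)
    return world.stillbirth_obs


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_world(world: SyntheticWorld, outdir) -> None:
    """Write the observation datasets and pipeline inputs as tidy CSVs.

    Truth surfaces are written too (``truth.csv``) so that recovery checks
    can run from disk; the pipeline itself never reads them.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.hierarchy.to_csv(out / "hierarchy.csv", index=False)
    world.vr_deaths.to_csv(out / "vr_deaths.csv", index=False)
    world.cbh.to_csv(out / "cbh.csv", index=False)
    world.sbh.to_csv(out / "sbh.csv", index=False)
    world.siblings.to_csv(out / "siblings.csv", index=False)
    world.stillbirth_obs.to_csv(out / "stillbirth_obs.csv", index=False)
    world.shock_events.to_csv(out / "shock_events.csv", index=False)
    world.covariates_frame().to_csv(out / "covariates.csv", index=False)

    rows = []
    for (loc, cy), cp in sorted(world.censuses.items()):
        for a, lab in enumerate(GRID.labels):
            rows.append(
                {
                    "location": loc, "date1": cp.date1, "date2": cp.date2,
                    "age_group": lab, "pop1": cp.pop1[a], "pop2": cp.pop2[a],
                }
            )
    pd.DataFrame(rows).to_csv(out / "censuses.csv", index=False)

    pop_rows, truth_rows = [], []
    for loc in world.config.locations:
        for sex in ("male", "female"):
            key = (loc, sex)
            for t, y in enumerate(world.years):
                for a, lab in enumerate(GRID.labels):
                    pop_rows.append(
                        {
                            "location": loc, "year": int(y), "sex": sex,
                            "age_group": lab,
                            "population": world.population[key][t, a],
                        }
                    )
                truth_rows.append(
                    {
                        "location": loc, "year": int(y), "sex": sex,
                        "e0": world.truth_e0[key][t],
                        "q5": world.truth_q5[key][t],
                        "q45": world.truth_q45[key][t],
                    }
                )
    pd.DataFrame(pop_rows).to_csv(out / "population.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    pd.DataFrame(
        [
            {"location": loc, "year": int(y),
             "livebirths": world.births[loc][t],
             "hiv_nathist_cdr": world.hiv_nathist[loc][t]}
            for loc in world.config.locations
            for t, y in enumerate(world.years)
        ]
    ).to_csv(out / "births_hiv.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(world.manifest, fh, indent=2)


class WorldInputs:
    """Pipeline inputs loaded back from a saved world directory."""

    def __init__(self, indir):
        from pathlib import Path

        d = Path(indir)

        def _read(name: str) -> pd.DataFrame:
            try:
                return pd.read_csv(d / name)
            except pd.errors.EmptyDataError:
                return pd.DataFrame()

        self.hierarchy = _read("hierarchy.csv")
        self.vr_deaths = _read("vr_deaths.csv")
        self.cbh = _read("cbh.csv")
        self.sbh = _read("sbh.csv")
        self.siblings = _read("siblings.csv")
        self.stillbirth_obs = _read("stillbirth_obs.csv")
        self.shock_events = _read("shock_events.csv")
        self._covariates = _read("covariates.csv")
        with open(d / "manifest.json") as fh:
            self.manifest = json.load(fh)
        y0, y1 = self.manifest["years"]
        self.years = np.arange(y0, y1 + 1)
        self.locations = sorted(set(self.hierarchy["location"]))

        pop = pd.read_csv(d / "population.csv")
        self.population = {}
        order = {lab: i for i, lab in enumerate(GRID.labels)}
        for (loc, sex), sub in pop.groupby(["location", "sex"]):
            mat = np.zeros((len(self.years), N_AGE))
            mat[
                (sub["year"].to_numpy() - y0).astype(int),
                sub["age_group"].map(order).to_numpy(),
            ] = sub["population"].to_numpy(float)
            self.population[(loc, sex)] = mat

        bh = pd.read_csv(d / "births_hiv.csv")
        self.births, self.hiv_nathist = {}, {}
        for loc, sub in bh.groupby("location"):
            sub = sub.sort_values("year")
            self.births[loc] = sub["livebirths"].to_numpy(float)
            self.hiv_nathist[loc] = sub["hiv_nathist_cdr"].to_numpy(float)

        cen = pd.read_csv(d / "censuses.csv")
        from mortality_engine.vr_completeness import CensusPair

        self.censuses = {}
        for (loc, d1), sub in cen.groupby(["location", "date1"]):
            sub = sub.set_index("age_group").reindex(GRID.labels)
            self.censuses[(loc, int(d1))] = CensusPair(
                GRID, float(d1), float(sub["date2"].iloc[0]),
                sub["pop1"].to_numpy(float), sub["pop2"].to_numpy(float),
            )

    def covariates_frame(self) -> pd.DataFrame:
        return self._covariates.copy()
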