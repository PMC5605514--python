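"""Socio-demographic Index (SDI) and development-expected mortality.

SDI is the geometric mean of three components rescaled to [0, 1] on fixed
scales: lag-distributed income per capita (log scale), mean years of
education in the population aged 15+, and total fertility rate (inverted —
lower fertility scores higher).  Locations are grouped into quintiles of
the 2016 SDI distribution.

Expected mortality treats SDI as the index variable: for each age-sex
group, log death rates are fitted against SDI by Gaussian process
regression with a linear prior, giving an expected rate curve on [0, 1].
Evaluating all 23 age-group curves at a location's SDI yields an expected
life table and expected life expectancy at birth (E0); draw-level
comparison of observed and expected E0 flags locations performing
significantly better or worse than their development level alone would
predict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from mortality_engine.demographic_core import (
    AgeGrid,
    AgeSchedule,
    LifeTable,
    Sex,
)
from mortality_engine.stgpr import gpr_posterior

logger = logging.getLogger(__name__)

__all__ = [
    "SDILimits",
    "SDIComponents",
    "compute_sdi",
    "assign_quintile",
    "quintile_thresholds",
    "ExpectedCurve",
    "fit_expected_mortality",
    "expected_lifetable",
    "observed_minus_expected",
    "QUINTILE_LABELS",
]

QUINTILE_LABELS = ("low", "low-middle", "middle", "high-middle", "high")


@dataclass(frozen=True)
class SDILimits:
    """Fixed rescaling limits per component (package defaults, documented
    in the methods note; not the canonical GBD limits)."""

    ldi_min: float = 250.0        # income per capita, floor of observed range
    ldi_max: float = 60000.0      # plateau of the income-health relationship
    edu_min: float = 0.0          # years of schooling, age 15+
    edu_max: float = 17.0
    tfr_min: float = 1.5          # plateau (most favourable) fertility
    tfr_max: float = 8.0          # least favourable fertility


@dataclass(frozen=True)
class SDIComponents:
    ldi: float          # lag-distributed income per capita
    education: float    # mean years of schooling, age 15+
    tfr: float          # total fertility rate
    limits: SDILimits = field(default_factory=SDILimits)

    def __post_init__(self) -> None:
        if min(self.ldi, self.education, self.tfr) < 0:
            raise ValueError("components must be non-negative")


def _rescale(value: float, lo: float, hi: float, log: bool = False) -> float:
    if log:
        value, lo, hi = math.log(max(value, 1e-12)), math.log(lo), math.log(hi)
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def compute_sdi(components: SDIComponents) -> float:
    """Geometric mean of the rescaled components; TFR is inverted."""
    lim = components.limits
    ldi = _rescale(components.ldi, lim.ldi_min, lim.ldi_max, log=True)
    edu = _rescale(components.education, lim.edu_min, lim.edu_max)
    tfr = 1.0 - _rescale(components.tfr, lim.tfr_min, lim.tfr_max)
    return float((ldi * edu * tfr) ** (1.0 / 3.0))


def quintile_thresholds(sdi_2016: np.ndarray) -> np.ndarray:
    """Quintile cut points from a reference-year SDI distribution."""
    return np.quantile(np.asarray(sdi_2016, float), [0.2, 0.4, 0.6, 0.8])


def assign_quintile(sdi: float, thresholds: np.ndarray) -> str:
    """Quintile label; a value exactly at a threshold joins the upper band."""
    t = np.asarray(thresholds, float)
    if t.shape != (4,) or np.any(np.diff(t) <= 0):
        raise ValueError("need 4 strictly increasing thresholds")
    return QUINTILE_LABELS[int(np.searchsorted(t, sdi, side="right"))]


@dataclass(frozen=True)
class ExpectedCurve:
    """Expected death rate for one age-sex group as a function of SDI."""

    age_group: str
    sex: Sex
    sdi_grid: np.ndarray
    log_rate_mean: np.ndarray
    log_rate_draws: np.ndarray          # (n_grid, n_draws)
    monotone_violation: bool = False

    def __call__(self, sdi: float) -> float:
        s = float(np.clip(sdi, 0.0, 1.0))
        if s != sdi:
            logger.warning("SDI %.3f outside [0, 1]; clipped", sdi)
        return float(np.exp(np.interp(s, self.sdi_grid, self.log_rate_mean)))

    def draws_at(self, sdi: float) -> np.ndarray:
        s = float(np.clip(sdi, 0.0, 1.0))
        idx = np.searchsorted(self.sdi_grid, s)
        idx = min(idx, len(self.sdi_grid) - 1)
        return np.exp(self.log_rate_draws[idx])


def fit_expected_mortality(
    mx_values: np.ndarray,
    sdi_values: np.ndarray,
    age_group: str,
    sex: Sex,
    eta: float = 0.3,
    rho: float = 0.35,
    n_draws: int = 100,
    seed: int = 0,
    grid_size: int = 101,
) -> ExpectedCurve:
    """GP fit of log death rate against SDI with a linear prior.

    Requires at least 20 (location-year) pairs.  After fitting, the curve
    is checked for monotone non-increase in SDI; violations are flagged
    (mortality should fall as development rises, with no crossover between
    SDI levels).
    """
    mx = np.asarray(mx_values, float)
    sdi = np.asarray(sdi_values, float)
    if mx.size != sdi.size or mx.size < 20:
        raise ValueError("need at least 20 paired (mx, SDI) observations")
    if np.any(mx <= 0):
        raise ValueError("death rates must be positive for a log-scale fit")
    y = np.log(mx)
    X = np.column_stack([np.ones_like(sdi), sdi])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = float(np.var(y - X @ beta)) or 1e-6

    grid = np.linspace(0.0, 1.0, grid_size)
    prior = beta[0] + beta[1] * grid
    # bin duplicate SDI values to keep the GP system small and well posed
    order = np.argsort(sdi)
    series = gpr_posterior(
        grid,
        prior,
        sdi[order],
        y[order],
        np.full(mx.size, resid_var),
        eta=eta,
        rho=rho,
        n_draws=n_draws,
        seed=seed,
        location=f"{age_group}:{sex.value}",
    )
    increases = np.diff(series.mean)
    violation = bool(np.any(increases > 1e-6))
    return ExpectedCurve(age_group, sex, grid, series.mean, series.draws, violation)


def expected_lifetable(
    sdi: float,
    curves: dict[str, ExpectedCurve],
    grid: AgeGrid | None = None,
    sex: Sex = Sex.BOTH,
) -> LifeTable:
    """Life table of expected rates at a given SDI (all 23 groups needed)."""
    if grid is None:
        grid = AgeGrid.gbd()
    missing = [g for g in grid.labels if g not in curves]
    if missing:
        raise ValueError(f"missing expected curves for age groups: {missing}")
    mx = np.array([curves[g](sdi) for g in grid.labels])
    from mortality_engine.demographic_core import build_abridged_lifetable

    return build_abridged_lifetable(AgeSchedule(grid, sex, mx))


@dataclass(frozen=True)
class ObservedMinusExpected:
    difference: float
    lower: float
    upper: float
    significant: bool
    draws: np.ndarray


def observed_minus_expected(
    observed_e0_draws: np.ndarray,
    expected_e0_draws: np.ndarray,
    seed: int = 0,
) -> ObservedMinusExpected:
    """Draw-level observed minus expected E0 with percentile significance.

    Unequal draw counts are reconciled by seeded resampling of the shorter
    vector; the difference is significant when the 95% UI excludes zero.
    """
    obs = np.asarray(observed_e0_draws, float)
    exp = np.asarray(expected_e0_draws, float)
    if obs.size == 0 or exp.size == 0:
        raise ValueError("empty draw vectors")
    if obs.size != exp.size:
        rng = np.random.default_rng(seed)
        n = max(obs.size, exp.size)
        if obs.size < n:
            obs = rng.choice(obs, n, replace=True)
        else:
            exp = rng.choice(exp, n, replace=True)
    diff = obs - exp
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return ObservedMinusExpected(
        difference=float(diff.mean()),
        lower=float(lo),
        upper=float(hi),
        significant=bool(lo > 0 or hi < 0),
        draws=diff,
    )
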