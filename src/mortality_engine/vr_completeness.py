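"""Completeness of death registration.

Adult completeness is assessed with two death distribution methods (DDM)
applied to a pair of census age distributions and the registered deaths
between them:

* Generalized growth balance (GGB): in a closed population the rate of
  entry into the open age segment x+ equals the growth rate plus the death
  rate of that segment.  Regressing the partial birth rate minus the growth
  rate on the partial (registered) death rate gives a slope of 1/c, where c
  is registration completeness; the intercept measures relative coverage
  change between the two censuses.
* Synthetic extinct generations (SEG): the population at each age is
  reconstructed from the registered deaths of cohorts above that age,
  inflated by age-specific growth; the ratio of the death-reconstructed
  population to the census population estimates c.

The hybrid estimate applies the GGB coverage-change correction to the
second census before running SEG, which is the headline value used
downstream.  Child completeness compares registered 5q0 to a survey
reference, and overall completeness is simply registered deaths divided by
estimated all-age deaths, with values above 0.95 labelled "complete".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mortality_engine.demographic_core import AgeGrid, AgeSchedule

__all__ = [
    "CensusPair",
    "GGBResult",
    "SEGResult",
    "CompletenessAssessment",
    "OverallCompleteness",
    "ggb_completeness",
    "seg_completeness",
    "ddm_completeness",
    "child_vr_completeness",
    "overall_completeness",
    "COMPLETE_THRESHOLD",
]

COMPLETE_THRESHOLD = 0.95
#: Figure-style completeness bands (percent): below 80, 80-95, above 95.
COMPLETENESS_BANDS = ((0.80, "<80"), (0.95, "80-95"), (math.inf, ">95"))


@dataclass(frozen=True)
class CensusPair:
    """Two census age distributions on the same grid, dated in decimal years."""

    grid: AgeGrid
    date1: float
    date2: float
    pop1: np.ndarray
    pop2: np.ndarray

    def __post_init__(self) -> None:
        if self.date2 <= self.date1:
            raise ValueError("second census must postdate the first")
        for name in ("pop1", "pop2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.grid),):
                raise ValueError(f"{name} length does not match grid")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, arr)

    @property
    def interval(self) -> float:
        return self.date2 - self.date1


@dataclass(frozen=True)
class GGBResult:
    completeness: float
    intercept: float
    rmse: float
    points: pd.DataFrame  # per-age regression diagnostics
    trim: tuple[float, float]


@dataclass(frozen=True)
class SEGResult:
    completeness: float
    ratios: pd.DataFrame
    trim: tuple[float, float]
    growth_correction: float | None = None


@dataclass(frozen=True)
class OverallCompleteness:
    raw: float
    capped: float
    complete: bool
    over_registration: bool
    band: str


@dataclass(frozen=True)
class CompletenessAssessment:
    location: str
    year_range: tuple[float, float]
    c_ggb: float
    c_seg: float
    c_hybrid: float
    ggb_intercept: float
    trim: tuple[float, float]
    c_child: float | None = None
    c_overall: OverallCompleteness | None = None

    @property
    def headline(self) -> float:
        return self.c_hybrid


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Total least squares line y = a + b x; both axes carry error.

    Returns (intercept, slope, rmse of orthogonal residuals).
    """
    xm, ym = x.mean(), y.mean()
    u = np.column_stack([x - xm, y - ym])
    _, s, vt = np.linalg.svd(u, full_matrices=False)
    if s[0] == 0:
        raise ValueError("singular regression: no variation in inputs")
    direction = vt[0]
    if abs(direction[0]) < 1e-12:
        raise ValueError("singular regression: vertical TLS line")
    slope = direction[1] / direction[0]
    intercept = ym - slope * xm
    resid = s[1] / math.sqrt(len(x)) if s.size > 1 else 0.0
    return intercept, slope, float(resid)


def _segment_quantities(
    censuses: CensusPair, deaths: np.ndarray
) -> pd.DataFrame:
    """Per-exact-age cumulated quantities shared by GGB and SEG.

    ``deaths`` are mean annual registered deaths per age group over the
    intercensal period.
    """
    grid = censuses.grid
    starts = grid.starts
    widths = grid.widths
    T = censuses.interval
    n1, n2 = censuses.pop1, censuses.pop2
    nbar = np.sqrt(n1 * n2)

    rows = []
    for i in range(1, len(grid)):  # exact ages 5, 10, ... (open start last)
        x = starts[i]
        N1p, N2p = n1[i:].sum(), n2[i:].sum()
        py = T * math.sqrt(N1p * N2p)
        growth = math.log(N2p / N1p) / T
        # persons turning exact age x per year: average density of the two
        # adjacent groups, geometric-mean population
        dens_below = nbar[i - 1] / widths[i - 1]
        dens_above = nbar[i] / widths[i] if np.isfinite(widths[i]) else nbar[i] / 5.0
        entries = 0.5 * (dens_below + dens_above)
        d_rate = deaths[i:].sum() * T / py
        rows.append(
            {
                "age": x,
                "entry_rate": entries * T / py,
                "growth_rate": growth,
                "death_rate": d_rate,
                "lhs": entries * T / py - growth,
            }
        )
    return pd.DataFrame(rows)


def _check_inputs(censuses: CensusPair, deaths: AgeSchedule, trim) -> np.ndarray:
    if deaths.grid != censuses.grid:
        raise ValueError("deaths and censuses must share an age grid")
    d = deaths.values
    starts = censuses.grid.starts
    in_trim = (starts >= trim[0]) & (starts < trim[1])
    if d[in_trim].sum() <= 0:
        raise ValueError("zero registered deaths in trim ages")
    if in_trim.sum() < 4:
        raise ValueError("need at least 4 age points in trim")
    return d


def ggb_completeness(
    censuses: CensusPair,
    registered_deaths: AgeSchedule,
    trim: tuple[float, float] = (15.0, 75.0),
) -> GGBResult:
    """Generalized growth balance estimate of adult registration completeness."""
    d = _check_inputs(censuses, registered_deaths, trim)
    pts = _segment_quantities(censuses, d)
    sel = (pts["age"] >= trim[0]) & (pts["age"] <= trim[1])
    sub = pts[sel]
    if len(sub) < 4:
        raise ValueError("need at least 4 age points in trim")
    intercept, slope, rmse = _orthogonal_fit(
        sub["death_rate"].to_numpy(), sub["lhs"].to_numpy()
    )
    if slope <= 0:
        raise ValueError("non-positive GGB slope; registration data inconsistent")
    return GGBResult(1.0 / slope, intercept, rmse, pts, trim)


def seg_completeness(
    censuses: CensusPair,
    registered_deaths: AgeSchedule,
    trim: tuple[float, float] = (15.0, 75.0),
    growth_correction: float | None = None,
) -> SEGResult:
    """Synthetic extinct generations estimate of completeness.

    ``growth_correction`` is the GGB intercept (relative census coverage
    change per year); when supplied, the second census is rescaled by
    exp(-delta * T) before reconstruction (the hybrid GGB-SEG method).
    """
    d = _check_inputs(censuses, registered_deaths, trim)
    grid = censuses.grid
    if growth_correction is not None:
        censuses = CensusPair(
            grid,
            censuses.date1,
            censuses.date2,
            censuses.pop1,
            censuses.pop2 * math.exp(-growth_correction * censuses.interval),
        )
    T = censuses.interval
    n1, n2 = censuses.pop1, censuses.pop2
    nbar = np.sqrt(n1 * n2)
    starts, widths = grid.starts, grid.widths
    with np.errstate(divide="ignore"):
        growth = np.log(n2 / n1) / T  # age-specific growth rates

    # midpoints; give the open interval a nominal 5-year midpoint offset
    mids = np.where(np.isfinite(widths), starts + widths / 2.0, starts[-1] + 2.5)

    def pop_at_exact_age(x: float) -> float:
        above = mids >= x
        return float(np.sum(d[above] * np.exp(growth[above] * (mids[above] - x))))

    rows = []
    for i in range(1, len(grid) - 1):
        x, w = starts[i], widths[i]
        nhat = 0.5 * (pop_at_exact_age(x) + pop_at_exact_age(x + w)) * w
        rows.append({"age": x, "estimated": nhat, "census": nbar[i]})
    ratios = pd.DataFrame(rows)
    ratios["ratio"] = ratios["estimated"] / ratios["census"]
    sel = (ratios["age"] >= trim[0]) & (ratios["age"] <= trim[1])
    c = float(ratios.loc[sel, "ratio"].mean())
    if c <= 0:
        raise ValueError("non-positive SEG completeness")
    return SEGResult(c, ratios, trim, growth_correction)


def _trim_candidates(lo=5.0, hi=85.0) -> list[tuple[float, float]]:
    out = []
    for a in np.arange(lo, 45, 5.0):
        for b in np.arange(a + 30, hi + 1, 5.0):
            out.append((float(a), float(b)))
    return out


def ddm_completeness(
    censuses: CensusPair,
    registered_deaths: AgeSchedule,
    location: str = "",
    trim: tuple[float, float] | None = None,
    search_trims: bool = False,
) -> CompletenessAssessment:
    """GGB, SEG, and hybrid completeness; optionally search for the trim
    window minimising the GGB orthogonal-regression RMSE."""
    if trim is None:
        trim = (15.0, 75.0)
    if search_trims:
        best, best_rmse = trim, math.inf
        for cand in _trim_candidates():
            try:
                res = ggb_completeness(censuses, registered_deaths, cand)
            except ValueError:
                continue
            if res.rmse < best_rmse:
                best, best_rmse = cand, res.rmse
        trim = best
    ggb = ggb_completeness(censuses, registered_deaths, trim)
    seg = seg_completeness(censuses, registered_deaths, trim)
    hybrid = seg_completeness(
        censuses, registered_deaths, trim, growth_correction=ggb.intercept
    )
    return CompletenessAssessment(
        location=location,
        year_range=(censuses.date1, censuses.date2),
        c_ggb=ggb.completeness,
        c_seg=seg.completeness,
        c_hybrid=hybrid.completeness,
        ggb_intercept=ggb.intercept,
        trim=trim,
    )


def child_vr_completeness(
    vr_5q0: pd.Series, reference_5q0: pd.Series, window: int = 5
) -> pd.Series:
    """Per-year ratio of registered to reference child mortality risk,
    smoothed by a centred rolling median of ``window`` years."""
    years = vr_5q0.index.intersection(reference_5q0.index)
    if len(years) == 0:
        raise ValueError("no overlapping years between VR and reference 5q0")
    ratio = (vr_5q0.loc[years] / reference_5q0.loc[years]).sort_index()
    if window > 1:
        ratio = ratio.rolling(window, center=True, min_periods=1).median()
    return ratio


def completeness_band(capped: float) -> str:
    for ub, label in COMPLETENESS_BANDS:
        if capped < ub:
            return label
    return COMPLETENESS_BANDS[-1][1]  # pragma: no cover


def overall_completeness(
    registered_allage: float, estimated_allage: float
) -> OverallCompleteness:
    """Registered / estimated all-age deaths; raw ratio plus capped value.

    Location-years with a capped value above 0.95 are labelled complete.
    """
    if estimated_allage <= 0:
        raise ValueError("estimated all-age deaths must be positive")
    raw = registered_allage / estimated_allage
    capped = min(raw, 1.0)
    return OverallCompleteness(
        raw=raw,
        capped=capped,
        complete=capped >= COMPLETE_THRESHOLD,
        over_registration=raw > 1.0,
        band=completeness_band(capped),
    )
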