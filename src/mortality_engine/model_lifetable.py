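"""Model life table system: from (5q0, 45q15) to full age schedules.

In locations without complete registration, age-specific mortality is
expanded from two summary parameters — under-5 mortality 5q0 and adult
mortality 45q15 — plus the crude death rate due to HIV.  A standard
survivorship schedule is selected from an empirical life table library by
proximity in (logit 5q0, logit 45q15) space (discounted by distance in the
location hierarchy and in time), and a two-parameter Brass logit
relational model

    Y(x) = alpha + beta * Y_s(x),      Y(x) = 0.5 * ln((1 - l(x)) / l(x))

is solved so the resulting life table reproduces both targets exactly.
HIV excess mortality is overlaid proportionally to a relative-risk age
pattern so that added deaths equal CDR x population, demographic and
natural-history HIV estimates are reconciled by averaging, and fatal
discontinuities (shocks) exceeding one death per million population or
100 deaths are added to the final rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from mortality_engine.demographic_core import (
    AgeGrid,
    AgeSchedule,
    LifeTable,
    Sex,
)

__all__ = [
    "EXTENDED_AGES",
    "EmpiricalLifeTableLibrary",
    "RelationalFit",
    "HIVInputs",
    "ShockEvent",
    "select_standard",
    "fit_relational",
    "fit_relational_many",
    "lifetable_from_lx",
    "hiv_overlay",
    "reconcile_hiv",
    "apply_shocks",
    "summary_from_lx",
    "e0_from_lx_matrix",
    "summaries_from_lx_matrix",
    "e0_from_mx_matrix",
]

#: Exact ages at which standard survivorship schedules are tabulated.
EXTENDED_AGES = np.array(
    [0.0, 7 / 365, 28 / 365, 1.0]
    + [float(a) for a in range(5, 111, 5)]
)


def _logit_l(l: np.ndarray) -> np.ndarray:
    l = np.clip(l, 1e-12, 1 - 1e-12)
    return 0.5 * np.log((1.0 - l) / l)


def _inv_logit_l(y: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(2.0 * y))


def summary_from_lx(ages: np.ndarray, lx: np.ndarray) -> tuple[float, float]:
    """(5q0, 45q15) from a survivorship schedule on exact ages."""
    l5 = np.interp(5.0, ages, lx)
    l15 = np.interp(15.0, ages, lx)
    l60 = np.interp(60.0, ages, lx)
    return 1.0 - l5, 1.0 - l60 / l15


@dataclass(frozen=True)
class EmpiricalLifeTableLibrary:
    """Catalogue of quality-screened survivorship schedules.

    ``entries``: DataFrame with columns location, region, year, sex,
    quality, and lx_0 ... lx_110 at :data:`EXTENDED_AGES` (l0 = 1).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("empty life table library")
        cols = [c for c in self.entries.columns if c.startswith("lx_")]
        if len(cols) != len(EXTENDED_AGES):
            raise ValueError("library entries must tabulate all extended ages")

    def lx_matrix(self, sex: Sex) -> tuple[pd.DataFrame, np.ndarray]:
        sub = self.entries[self.entries["sex"] == sex.value]
        if len(sub) == 0:
            raise ValueError(f"library has no entries for sex {sex.value}")
        cols = [c for c in sub.columns if c.startswith("lx_")]
        return sub.reset_index(drop=True), sub[cols].to_numpy(float)


@dataclass(frozen=True)
class RelationalFit:
    alpha: float
    beta: float
    standard_lx: np.ndarray
    fitted_lx: np.ndarray
    achieved_5q0: float
    achieved_45q15: float


def select_standard(
    target: tuple[float, float],
    location: str,
    year: float,
    library: EmpiricalLifeTableLibrary,
    sex: Sex,
    k: int = 10,
    time_scale: float = 20.0,
    space_discount: float = 0.5,
    hierarchy: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Weighted standard from the k nearest library entries.

    Distance is Euclidean in (logit 5q0, logit 45q15); each entry's weight
    is 1/(distance + eps) multiplied by a proximity factor that prefers
    entries close in the hierarchy (same location > same region > other)
    and in time.  An entry exactly at the target from the same
    location-year receives weight one (ties broken by recency).  Returns
    the standard lx schedule (average of logit-lx) and the weight table.
    """
    q5_t, q45_t = target
    sub, lx = library.lx_matrix(sex)
    if len(sub) < k:
        k = len(sub)
    qs = np.array([summary_from_lx(EXTENDED_AGES, row) for row in lx])
    def lg(p):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))
    d = np.hypot(lg(qs[:, 0]) - lg(q5_t), lg(qs[:, 1]) - lg(q45_t))

    same_loc = (sub["location"] == location).to_numpy()
    if hierarchy is not None and "region" in sub.columns:
        region = (
            hierarchy.set_index("location")["region"].get(location)
            if location in set(hierarchy["location"])
            else None
        )
        same_reg = (sub["region"] == region).to_numpy()
    else:
        same_reg = np.zeros(len(sub), bool)
    proximity = np.where(same_loc, 1.0, np.where(same_reg, space_discount, space_discount**2))
    proximity = proximity * np.exp(-np.abs(sub["year"].to_numpy(float) - year) / time_scale)

    exact = same_loc & (sub["year"].to_numpy(float) == year) & (d < 1e-12)
    weights = proximity / (d + 1e-6)
    order = np.argsort(-weights, kind="stable")
    keep = order[:k]
    w = np.zeros(len(sub))
    if exact.any():
        w[np.nonzero(exact)[0][np.argmax(sub["year"].to_numpy(float)[exact])]] = 1.0
    else:
        w[keep] = weights[keep]
        w = w / w.sum()
    standard = _inv_logit_l((w[:, None] * _logit_l(lx)).sum(axis=0))
    standard[0] = 1.0
    table = sub.assign(weight=w, distance=d)[
        ["location", "year", "sex", "weight", "distance"]
    ]
    return standard, table.sort_values("weight", ascending=False).head(k)


def _fitted_lx(standard: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    ys = _logit_l(standard[1:])  # l0 = 1 excluded from the transform
    lx = np.empty_like(standard)
    lx[0] = 1.0
    lx[1:] = _inv_logit_l(alpha + beta * ys)
    # survivorship must be non-increasing; enforce against rounding wiggle
    return np.minimum.accumulate(lx)


def fit_relational(
    standard_lx: np.ndarray,
    target_5q0: float,
    target_45q15: float,
    beta_bounds: tuple[float, float] = (0.25, 4.0),
) -> RelationalFit:
    """Solve the Brass logit relational model for both summary targets.

    For a fixed slope beta the intercept alpha is determined directly by
    the 5q0 target (Y(5) = alpha + beta * Ys(5)); the slope is then found
    by root-finding on the achieved 45q15.  When the targets equal the
    standard's own, the identity (alpha=0, beta=1) is returned.
    """
    if not (0.0 < target_5q0 < 1.0):
        raise ValueError(f"target 5q0 must lie in (0, 1), got {target_5q0}")
    if not (0.0 < target_45q15 < 1.0):
        raise ValueError(f"target 45q15 must lie in (0, 1), got {target_45q15}")
    ages = EXTENDED_AGES
    ys5 = float(_logit_l(np.array([np.interp(5.0, ages, standard_lx)]))[0])
    y5_t = float(_logit_l(np.array([1.0 - target_5q0]))[0])

    def q45(beta: float) -> float:
        alpha = y5_t - beta * ys5
        lx = _fitted_lx(standard_lx, alpha, beta)
        return summary_from_lx(ages, lx)[1]

    lo, hi = beta_bounds
    f_lo, f_hi = q45(lo) - target_45q15, q45(hi) - target_45q15
    if f_lo * f_hi > 0:
        raise ValueError(
            "45q15 target infeasible for this standard within beta bounds: "
            f"q45({lo})={f_lo + target_45q15:.4f}, q45({hi})={f_hi + target_45q15:.4f}, "
            f"target={target_45q15:.4f}"
        )
    beta = optimize.brentq(
        lambda b: q45(b) - target_45q15, lo, hi, xtol=1e-12, rtol=1e-15
    )
    alpha = y5_t - beta * ys5
    lx = _fitted_lx(standard_lx, alpha, beta)
    a5q0, a45q15 = summary_from_lx(ages, lx)
    if abs(a5q0 - target_5q0) > 1e-6 or abs(a45q15 - target_45q15) > 1e-6:
        raise ValueError(
            f"relational fit failed to converge: achieved ({a5q0}, {a45q15})"
        )
    return RelationalFit(alpha, beta, standard_lx, lx, a5q0, a45q15)


def fit_relational_many(
    standard_lx: np.ndarray,
    targets_5q0: np.ndarray,
    targets_45q15: np.ndarray,
    beta_bounds: tuple[float, float] = (0.25, 4.0),
    iterations: int = 60,
) -> np.ndarray:
    """Vectorised bisection version of :func:`fit_relational` for draws.

    Returns fitted lx, shape (n_targets, len(EXTENDED_AGES)).
    """
    ages = EXTENDED_AGES
    q5 = np.clip(np.asarray(targets_5q0, float), 1e-9, 1 - 1e-9)
    q45 = np.clip(np.asarray(targets_45q15, float), 1e-9, 1 - 1e-9)
    ys = _logit_l(standard_lx[1:])
    ys5 = float(_logit_l(np.array([np.interp(5.0, ages, standard_lx)]))[0])
    y5_t = _logit_l(1.0 - q5)

    i15 = int(np.searchsorted(ages, 15.0))
    i60 = int(np.searchsorted(ages, 60.0))

    def achieved_q45(beta: np.ndarray) -> np.ndarray:
        alpha = y5_t - beta * ys5
        y = alpha[:, None] + beta[:, None] * ys[None, :]
        lx = _inv_logit_l(y)
        l15, l60 = lx[:, i15 - 1], lx[:, i60 - 1]
        return 1.0 - l60 / l15

    lo = np.full(q5.shape, beta_bounds[0])
    hi = np.full(q5.shape, beta_bounds[1])
    f_lo = achieved_q45(lo) - q45
    infeasible_lo = f_lo > 0  # even the flattest slope overshoots
    for _ in range(iterations):
        mid = (lo + hi) / 2.0
        f_mid = achieved_q45(mid) - q45
        take_lo = f_mid < 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    beta = (lo + hi) / 2.0
    beta = np.where(infeasible_lo, beta_bounds[0], beta)
    alpha = y5_t - beta * ys5
    y = alpha[:, None] + beta[:, None] * ys[None, :]
    out = np.empty((len(q5), len(ages)))
    out[:, 0] = 1.0
    out[:, 1:] = _inv_logit_l(y)
    return np.minimum.accumulate(out, axis=1)


def lifetable_from_lx(
    lx_ext: np.ndarray, grid: AgeGrid, sex: Sex = Sex.BOTH
) -> LifeTable:
    """Abridged life table on ``grid`` from survivorship at EXTENDED_AGES.

    Person-years within each group are trapezoidal integrals of lx over the
    fine tabulation; the open interval is closed with a constant hazard
    taken from the last tabulated segment.
    """
    ages = EXTENDED_AGES
    starts = grid.starts
    widths = grid.widths
    n = len(grid)
    # fine grid for trapezoids: union of tabulated ages and group bounds
    fine = np.unique(np.concatenate([ages, starts[np.isfinite(starts)]]))
    lfine = np.interp(fine, ages, lx_ext)

    lx = np.interp(starts, ages, lx_ext)
    mx = np.empty(n)
    ax = np.empty(n)
    qx = np.empty(n)
    dx = np.empty(n)
    Lx = np.empty(n)
    for i in range(n - 1):
        a, b = starts[i], starts[i] + widths[i]
        seg = (fine >= a - 1e-12) & (fine <= b + 1e-12)
        Lx[i] = float(np.trapezoid(lfine[seg], fine[seg]))
        dx[i] = lx[i] - np.interp(b, ages, lx_ext)
        qx[i] = dx[i] / lx[i] if lx[i] > 0 else 1.0
        mx[i] = dx[i] / Lx[i] if Lx[i] > 0 else 0.0
        lnext = lx[i] - dx[i]
        ax[i] = (
            (Lx[i] - widths[i] * lnext) / dx[i] if dx[i] > 1e-14 else widths[i] / 2
        )
    # open interval: trapezoid over the tabulated tail plus constant-hazard
    # closure beyond the last tabulated age
    a = starts[-1]
    seg = fine >= a - 1e-12
    tail_L = float(np.trapezoid(lfine[seg], fine[seg]))
    l_last = lx_ext[-1]
    if l_last > 0:
        h_tail = -math.log(
            max(lx_ext[-1] / max(lx_ext[-2], 1e-300), 1e-12)
        ) / (ages[-1] - ages[-2])
        tail_L += l_last / max(h_tail, 1e-6)
    l_open = lx[-1]
    Lx[-1] = max(tail_L, 1e-300)
    dx[-1] = l_open
    qx[-1] = 1.0
    mx[-1] = l_open / Lx[-1] if l_open > 0 else 1.0
    ax[-1] = Lx[-1] / l_open if l_open > 0 else 0.0
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(grid, sex, mx, ax, qx, lx, dx, Lx, Tx, ex)


# ---------------------------------------------------------------------------
# HIV operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HIVInputs:
    """Crude death rate due to HIV plus its age pattern of relative risk."""

    cdr: float                       # HIV deaths per person-year, all ages
    relative_risk: AgeSchedule       # RR_a >= 0
    population: AgeSchedule

    def __post_init__(self) -> None:
        if self.cdr < 0:
            raise ValueError("CDR must be non-negative")
        if self.cdr > 0 and self.relative_risk.values.sum() <= 0:
            raise ValueError("CDR > 0 requires a non-zero relative-risk pattern")


def hiv_overlay(mx_hiv_free: AgeSchedule, hiv: HIVInputs) -> AgeSchedule:
    """Add HIV excess mortality proportional to the relative-risk pattern.

    The added age-specific rates are scaled so total added deaths equal
    CDR x total population; every rate is weakly increased.
    """
    if hiv.cdr == 0:
        return mx_hiv_free
    rr = hiv.relative_risk.values
    pop = hiv.population.values
    denom = float((rr * pop).sum())
    if denom <= 0:
        raise ValueError("relative risk and population do not overlap")
    scale = hiv.cdr * pop.sum() / denom
    return mx_hiv_free.with_values(mx_hiv_free.values + scale * rr)


def reconcile_hiv(
    demographic_estimate: AgeSchedule, natural_history_estimate: AgeSchedule
) -> AgeSchedule:
    """Element-wise average of the two HIV mortality estimates."""
    if demographic_estimate.grid != natural_history_estimate.grid:
        raise ValueError("grid mismatch")
    return demographic_estimate.with_values(
        (demographic_estimate.values + natural_history_estimate.values) / 2.0
    )


def reconcile_hiv_draws(demographic: np.ndarray, natural_history: np.ndarray) -> np.ndarray:
    """Draw-level averaging; linear, so the mean of means equals the mean."""
    return (demographic + natural_history) / 2.0


# ---------------------------------------------------------------------------
# Fatal discontinuities
# ---------------------------------------------------------------------------

#: Inclusion rule: death rate above one per million, or more than 100 deaths.
SHOCK_RATE_THRESHOLD = 1e-6
SHOCK_COUNT_THRESHOLD = 100.0


@dataclass(frozen=True)
class ShockEvent:
    location: str
    year: int
    cause: str                        # conflict / disaster / transport / epidemic
    deaths: float
    deaths_low: float | None = None
    deaths_high: float | None = None
    age_distribution: np.ndarray | None = None  # optional, sums to 1

    def __post_init__(self) -> None:
        if self.deaths <= 0:
            raise ValueError("shock deaths must be positive")


def apply_shocks(
    mx: AgeSchedule,
    events: list[ShockEvent],
    population: AgeSchedule,
) -> tuple[AgeSchedule, pd.DataFrame]:
    """Add included shock deaths to the rates; report exclusions with reason.

    An event is included iff deaths / total population exceeds one per
    million, or deaths exceed 100.  Included deaths are converted to added
    age-specific rates using the event's age distribution (default:
    proportional to population, i.e. a uniform added rate).
    """
    if np.any(population.values <= 0):
        raise ValueError("population must be positive")
    pop = population.values
    total_pop = pop.sum()
    added = np.zeros_like(pop)
    report = []
    for ev in events:
        rate = ev.deaths / total_pop
        included = rate > SHOCK_RATE_THRESHOLD or ev.deaths > SHOCK_COUNT_THRESHOLD
        reason = (
            "included"
            if included
            else "below both thresholds"
        )
        report.append(
            {
                "location": ev.location,
                "year": ev.year,
                "cause": ev.cause,
                "deaths": ev.deaths,
                "all_age_rate": rate,
                "included": included,
                "reason": reason,
            }
        )
        if not included:
            continue
        if ev.age_distribution is not None:
            dist = np.asarray(ev.age_distribution, float)
            dist = dist / dist.sum()
        else:
            dist = pop / total_pop
        added += ev.deaths * dist / pop
    return mx.with_values(mx.values + added), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# Vectorised draw-level summaries
# ---------------------------------------------------------------------------

def e0_from_lx_matrix(lx_mat: np.ndarray) -> np.ndarray:
    """Life expectancy at birth for each row of survivorship draws.

    Trapezoidal person-years over :data:`EXTENDED_AGES` plus a
    constant-hazard closure beyond the last tabulated age.
    """
    ages = EXTENDED_AGES
    L = np.trapezoid(lx_mat, ages, axis=1)
    l_last, l_prev = lx_mat[:, -1], lx_mat[:, -2]
    h_tail = -np.log(np.clip(l_last / np.clip(l_prev, 1e-300, None), 1e-12, 1.0)) / (
        ages[-1] - ages[-2]
    )
    return L + l_last / np.maximum(h_tail, 1e-6)


def summaries_from_lx_matrix(lx_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(5q0, 45q15) per row of survivorship draws at EXTENDED_AGES."""
    ages = EXTENDED_AGES
    i5 = int(np.searchsorted(ages, 5.0))
    i15 = int(np.searchsorted(ages, 15.0))
    i60 = int(np.searchsorted(ages, 60.0))
    return 1.0 - lx_mat[:, i5], 1.0 - lx_mat[:, i60] / lx_mat[:, i15]


def e0_from_mx_matrix(mx_mat: np.ndarray, grid: AgeGrid) -> np.ndarray:
    """Life expectancy at birth per row of 23-group rate draws.

    Greville conversion with mid-interval ax (constant-hazard ax for the
    wide child groups), matching the abridged life table construction to
    well under 0.1 year for smooth schedules.
    """
    m = np.clip(np.asarray(mx_mat, float), 1e-12, None)
    n = grid.widths
    closed = np.isfinite(n)
    nc = n[closed]
    mc = m[:, closed]
    with np.errstate(over="ignore"):
        e = np.exp(-nc[None, :] * mc)
    ax = 1.0 / mc - nc[None, :] * e / np.clip(1.0 - e, 1e-300, None)
    qx = nc[None, :] * mc / (1.0 + (nc[None, :] - ax) * mc)
    qx = np.clip(qx, 0.0, 1.0)
    lx = np.concatenate(
        [np.ones((m.shape[0], 1)), np.cumprod(1.0 - qx, axis=1)], axis=1
    )
    dx = lx[:, :-1] - lx[:, 1:]
    Lx = nc[None, :] * lx[:, 1:] + ax * dx
    L_open = lx[:, -1] / m[:, -1]
    return Lx.sum(axis=1) + L_open
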