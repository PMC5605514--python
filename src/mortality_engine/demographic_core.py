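"""Life table construction and summary mortality metrics.

This module is the demographic backbone of the estimation pipeline: the
23-group GBD age grid, abridged life table construction from age-specific
death rates (nMx), span probabilities of death such as 5q0 and 45q15,
age-standardised rates, and the comparative-change statistics (annualised
rates of change, percent declines, convergence correlations) used when
summarising results.

Conventions
-----------
* Ages and interval widths are in years; the three sub-year infant groups
  (early neonatal 0-6 days, late neonatal 7-27 days, post-neonatal 28-364
  days) carry day-denominated widths converted to year units.
* The open interval (95+) uses the standard closure nLx = lx / Mx, so
  ex(95) = 1 / M95.
* Annualised rates of change follow the continuous-growth convention
  ln(v1/v0) / years, expressed in percent per year.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeGroup",
    "AgeGrid",
    "Sex",
    "AgeSchedule",
    "LifeTable",
    "StandardPopulation",
    "NaxRule",
    "build_abridged_lifetable",
    "probability_of_death",
    "age_standardize",
    "annualized_roc",
    "comparative_change",
    "convergence_correlation",
    "round_printed",
]

DAYS_PER_YEAR = 365.0


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    BOTH = "both"


@dataclass(frozen=True)
class AgeGroup:
    label: str
    start: float            # exact age at start, years
    width: float            # interval width in years; inf for open interval

    @property
    def is_open(self) -> bool:
        return math.isinf(self.width)

    @property
    def midpoint(self) -> float:
        if self.is_open:
            raise ValueError("open interval has no midpoint")
        return self.start + self.width / 2.0


@dataclass(frozen=True)
class AgeGrid:
    """Ordered, contiguous, half-open age groups ending in an open interval."""

    groups: tuple[AgeGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty age grid")
        if not self.groups[-1].is_open:
            raise ValueError("last group must be the open interval")
        for g in self.groups[:-1]:
            if g.is_open:
                raise ValueError("only the last group may be open")
            if g.width <= 0:
                raise ValueError(f"non-positive width in group {g.label}")
        for a, b in zip(self.groups[:-1], self.groups[1:]):
            if not math.isclose(a.start + a.width, b.start, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"gap or overlap between {a.label} and {b.label}")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def starts(self) -> np.ndarray:
        return np.array([g.start for g in self.groups])

    @property
    def widths(self) -> np.ndarray:
        return np.array([g.width for g in self.groups])

    @property
    def boundaries(self) -> np.ndarray:
        """Exact ages at the closed-group boundaries (length n, starts)."""
        return self.starts

    def index_of_age(self, age: float) -> int:
        starts = self.starts
        hits = np.nonzero(np.isclose(starts, age, atol=1e-9))[0]
        if hits.size == 0:
            raise ValueError(f"age {age} is not a boundary of this grid")
        return int(hits[0])

    @staticmethod
    def gbd() -> "AgeGrid":
        """The 23-group GBD grid used throughout the pipeline."""
        groups = [
            AgeGroup("early_neonatal", 0.0, 7 / DAYS_PER_YEAR),
            AgeGroup("late_neonatal", 7 / DAYS_PER_YEAR, 21 / DAYS_PER_YEAR),
            AgeGroup("post_neonatal", 28 / DAYS_PER_YEAR, 337 / DAYS_PER_YEAR),
            AgeGroup("1_to_4", 1.0, 4.0),
        ]
        for start in range(5, 95, 5):
            groups.append(AgeGroup(f"{start}_to_{start + 4}", float(start), 5.0))
        groups.append(AgeGroup("95_plus", 95.0, math.inf))
        grid = AgeGrid(tuple(groups))
        assert len(grid) == 23
        return grid

    @staticmethod
    def five_year(open_age: int = 95) -> "AgeGrid":
        """Plain 0-4, 5-9, ... grid used by the death distribution methods."""
        groups = [AgeGroup(f"{s}_to_{s + 4}", float(s), 5.0) for s in range(0, open_age, 5)]
        groups.append(AgeGroup(f"{open_age}_plus", float(open_age), math.inf))
        return AgeGrid(tuple(groups))


def _as_values(values: Sequence[float] | np.ndarray, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.any(arr < 0):
        raise ValueError("values must be non-negative")
    return arr


@dataclass(frozen=True)
class AgeSchedule:
    """Per-age-group vector of rates (per person-year) or counts."""

    grid: AgeGrid
    sex: Sex
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_values(self.values, len(self.grid)))

    def with_values(self, values: np.ndarray) -> "AgeSchedule":
        return AgeSchedule(self.grid, self.sex, values)

    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights for direct standardisation; normalised to sum to one."""

    grid: AgeGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = _as_values(self.weights, len(self.grid))
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        w = w / total
        if abs(w.sum() - 1.0) > 1e-12:  # pragma: no cover - numerically unreachable
            raise ValueError("weight normalisation failed")
        object.__setattr__(self, "weights", w)

    @staticmethod
    def from_csv(path) -> "StandardPopulation":
        df = pd.read_csv(path)
        grid = AgeGrid.gbd()
        df = df.set_index("age_group").reindex(grid.labels)
        if df["weight"].isna().any():
            missing = df.index[df["weight"].isna()].tolist()
            raise ValueError(f"standard population missing groups: {missing}")
        return StandardPopulation(grid, df["weight"].to_numpy())


class NaxRule(str, enum.Enum):
    MIDPOINT = "midpoint"
    CONSTANT_HAZARD = "constant_hazard"
    COALE_DEMENY = "coale_demeny"


@dataclass(frozen=True)
class LifeTable:
    grid: AgeGrid
    sex: Sex
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.ex[0])

    def survivorship_at(self, age: float) -> float:
        """lx at an exact grid-boundary age."""
        return float(self.lx[self.grid.index_of_age(age)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": self.grid.labels,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )


def _constant_hazard_ax(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Mean time lived in the interval by those dying, exponential survival."""
    out = n / 2.0
    pos = m > 1e-12
    mp, npos = m[pos], n[pos]
    with np.errstate(over="ignore"):
        e = np.exp(-npos * mp)
    out[pos] = 1.0 / mp - npos * e / (1.0 - e)
    return out


def _coale_demeny_under5_ax(m0: float, sex: Sex) -> tuple[float, float]:
    """Coale-Demeny 1a0 and 4a1 as functions of the infant death rate."""
    if sex == Sex.MALE:
        a0 = 0.330 if m0 >= 0.107 else 0.045 + 2.684 * m0
        a1 = 1.352 if m0 >= 0.107 else 1.651 - 2.816 * m0
    elif sex == Sex.FEMALE:
        a0 = 0.350 if m0 >= 0.107 else 0.053 + 2.800 * m0
        a1 = 1.361 if m0 >= 0.107 else 1.522 - 1.518 * m0
    else:  # both sexes: average of the sex-specific coefficients
        am, _ = _coale_demeny_under5_ax(m0, Sex.MALE)
        af, _ = _coale_demeny_under5_ax(m0, Sex.FEMALE)
        _, bm = _coale_demeny_under5_ax(m0, Sex.MALE)
        _, bf = _coale_demeny_under5_ax(m0, Sex.FEMALE)
        return (am + af) / 2.0, (bm + bf) / 2.0
    return a0, a1


def _nax(mx: np.ndarray, grid: AgeGrid, sex: Sex, rule: NaxRule) -> np.ndarray:
    n = grid.widths.copy()
    closed = ~np.isinf(n)
    ax = np.empty(len(grid))
    if rule == NaxRule.MIDPOINT:
        ax[closed] = n[closed] / 2.0
    elif rule == NaxRule.CONSTANT_HAZARD:
        ax[closed] = _constant_hazard_ax(mx[closed], n[closed])
    elif rule == NaxRule.COALE_DEMENY:
        ax[closed] = _constant_hazard_ax(mx[closed], n[closed])
        # mortality-dependent ax for ages 1-4 where the grid carries that group
        starts = grid.starts
        under1 = closed & (starts < 1.0)
        if under1.any():
            exposure = n[under1]
            m0 = float((mx[under1] * exposure).sum() / exposure.sum())
            _, a1 = _coale_demeny_under5_ax(m0, sex)
            one_to_four = np.isclose(starts, 1.0) & np.isclose(n, 4.0)
            ax[one_to_four] = a1
    else:  # pragma: no cover - enum exhausted
        raise ValueError(rule)
    ax[~closed] = np.nan  # set from Mx below
    return ax


def build_abridged_lifetable(
    mx: AgeSchedule,
    nax_rule: NaxRule | str = NaxRule.COALE_DEMENY,
    radix: float = 1.0,
) -> LifeTable:
    """Construct an abridged life table from age-specific death rates.

    Closed intervals use the Greville/Chiang conversion
    nqx = n*nMx / (1 + (n - nax)*nMx); the open interval takes qx = 1 and
    nLx = lx / Mx.

    Raises
    ------
    ValueError
        If any rate is negative or the open-interval rate is zero (the
        open-interval expectancy would be undefined).
    """
    rule = NaxRule(nax_rule)
    grid = mx.grid
    m = mx.values.copy()
    if m[-1] <= 0:
        raise ValueError("undefined open-interval expectancy: open-interval rate is 0")
    n = grid.widths
    closed = ~np.isinf(n)
    ax = _nax(m, grid, mx.sex, rule)

    qx = np.empty_like(m)
    denom = 1.0 + (n[closed] - ax[closed]) * m[closed]
    qx[closed] = n[closed] * m[closed] / denom
    qx[closed] = np.clip(qx[closed], 0.0, 1.0)
    qx[-1] = 1.0

    lx = np.empty_like(m)
    lx[0] = radix
    lx[1:] = radix * np.cumprod(1.0 - qx[:-1])
    dx = np.empty_like(m)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]

    # person-years: survivors to the end plus partial years from the dying
    Lx = np.empty_like(m)
    idx_closed = np.nonzero(closed)[0]
    l_next = np.append(lx[1:], 0.0)
    Lx[idx_closed] = (
        n[idx_closed] * l_next[idx_closed] + ax[idx_closed] * dx[idx_closed]
    )
    Lx[-1] = lx[-1] / m[-1]
    ax[-1] = np.inf if lx[-1] == 0 else Lx[-1] / max(dx[-1], 1e-300)

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(grid, mx.sex, m, ax, qx, lx, dx, Lx, Tx, ex)


def probability_of_death(lt: LifeTable, x: float, n: float) -> float:
    """nqx over [x, x+n), both boundaries required to lie on the grid.

    ``probability_of_death(lt, 15, 45)`` is the adult mortality rate 45q15
    = 1 - l60/l15; ``probability_of_death(lt, 0, 5)`` is 5q0.
    """
    i = lt.grid.index_of_age(x)
    j = lt.grid.index_of_age(x + n)
    if j <= i:
        raise ValueError("span must be positive")
    if lt.lx[i] <= 0:
        raise ValueError(f"no survivors at age {x}")
    return float(1.0 - lt.lx[j] / lt.lx[i])


def age_standardize(
    rates: AgeSchedule, std: StandardPopulation, per: float = 1.0
) -> float:
    """Directly standardised rate: sum of weights * rates, scaled by ``per``."""
    if rates.grid != std.grid:
        raise ValueError("age grid mismatch between rates and standard population")
    return float(np.dot(std.weights, rates.values) * per)


def annualized_roc(v0: float, v1: float, years: float) -> float:
    """Annualised rate of change, percent per year: 100 * ln(v1/v0) / years."""
    if v0 <= 0 or v1 <= 0:
        raise ValueError("rates must be positive for a log rate of change")
    if years <= 0:
        raise ValueError("duration must be positive")
    return 100.0 * math.log(v1 / v0) / years


def comparative_change(v0: float, v1: float, mode: str) -> float:
    """Percent decline 100*(v0-v1)/v0, ratio v1/v0, or difference v1-v0."""
    if mode == "percent_decline":
        if v0 == 0:
            raise ValueError("zero denominator")
        return 100.0 * (v0 - v1) / v0
    if mode == "ratio":
        if v0 == 0:
            raise ValueError("zero denominator")
        return v1 / v0
    if mode == "difference":
        return v1 - v0
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CorrelationResult:
    correlation: float
    lower: float
    upper: float
    undefined: bool = False
    n: int = 0


def convergence_correlation(
    start_levels: Iterable[float],
    changes: Iterable[float],
    n_boot: int = 1000,
    seed: int | None = 0,
    ci: float = 0.95,
) -> CorrelationResult:
    """Pearson correlation between starting mortality levels and changes.

    A negative correlation between (log) starting level and the annualised
    rate of change indicates relative convergence: high-mortality locations
    improving faster.  The interval is a seeded location bootstrap.
    """
    x = np.asarray(list(start_levels), dtype=float)
    y = np.asarray(list(changes), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-d vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 locations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, undefined=True, n=x.size)
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.pearsonr(xb, yb).statistic
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return CorrelationResult(r, float(lo), float(hi), n=x.size)


def round_printed(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching the convention of printed tables."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
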