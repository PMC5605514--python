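"""Survey-based mortality estimators.

Three estimators turn household-survey microdata into mortality
observations:

* ``cbh_direct_5q0`` — direct under-5 mortality from complete birth
  histories using a synthetic cohort over age segments (the standard
  DHS-style calculation), with a jackknife-over-mothers sampling variance.
* ``sbh_indirect_5q0`` — indirect under-5 mortality from summary birth
  histories (children ever born / surviving by maternal age group),
  Brass-style: the proportion dead per maternal age group is scaled by a
  coefficient-table multiplier and assigned a reference date before the
  survey.  The coefficient table is a versioned fixture, not hard-coded.
* ``sibling_45q15`` — adult mortality (45q15) from sibling survival
  histories with the Gakidou-King selection-bias reweighting (each
  sibship weighted by 1/S, the number of surviving reporting-eligible
  siblings, since a sibship's chance of being reported is proportional to
  S) and an optional zero-reporter correction for sibships with no
  surviving member to report them.

``source_bias_adjust`` removes systematic per-source-type offsets against
a reference source in log/logit space.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "cbh_direct_5q0",
    "sbh_indirect_5q0",
    "sibling_45q15",
    "sibling_death_rate",
    "source_bias_adjust",
    "default_sbh_coefficients",
    "CBH_AGE_SEGMENTS_MONTHS",
]

#: Age-segment boundaries in months for the synthetic-cohort calculation.
CBH_AGE_SEGMENTS_MONTHS = (0, 1, 3, 6, 12, 24, 36, 48, 60)

#: Adult age bands (start ages) used to assemble 45q15 from rates.
ADULT_BANDS = tuple(range(15, 60, 5))


# ---------------------------------------------------------------------------
# Complete birth histories
# ---------------------------------------------------------------------------

def _segment_counts(
    records: pd.DataFrame, period: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (mother, segment) deaths and numbers at risk.

    A child is at risk in a segment if it reaches the segment's start age
    inside the period window and is not right-censored by the interview
    before the segment ends; children censored mid-segment are excluded
    from that segment.
    """
    t0, t1 = period
    birth = records["birth_date"].to_numpy(float)
    death = records["death_date"].to_numpy(float)
    survey = records["survey_date"].to_numpy(float)
    w = records.get("weight", pd.Series(np.ones(len(records)))).to_numpy(float)
    mother = records["mother_id"].to_numpy()

    bounds = np.array(CBH_AGE_SEGMENTS_MONTHS, dtype=float) / 12.0
    n_seg = len(bounds) - 1
    mothers, minv = np.unique(mother, return_inverse=True)
    D = np.zeros((len(mothers), n_seg))
    N = np.zeros((len(mothers), n_seg))
    age_at_death = np.where(np.isnan(death), np.inf, death - birth)
    for s in range(n_seg):
        lo, hi = bounds[s], bounds[s + 1]
        entry = birth + lo
        exit_ = birth + hi
        in_window = (entry >= t0) & (entry < t1)
        survives_seg = age_at_death >= hi
        dies_in_seg = (age_at_death >= lo) & (age_at_death < hi)
        death_time = birth + age_at_death
        observed = np.where(
            dies_in_seg, death_time <= survey, exit_ <= survey
        )
        at_risk = in_window & observed & (survives_seg | dies_in_seg)
        died = at_risk & dies_in_seg
        np.add.at(N[:, s], minv[at_risk], w[at_risk])
        np.add.at(D[:, s], minv[died], w[died])
    return D, N, mothers


def cbh_direct_5q0(
    records: pd.DataFrame, period: tuple[float, float]
) -> tuple[float, float]:
    """Direct 5q0 from complete birth histories over a calendar window.

    Parameters
    ----------
    records : DataFrame with columns mother_id, birth_date, death_date
        (NaN while alive), survey_date, and optional weight (decimal years).
    period : (start, end) calendar window.

    Returns
    -------
    (5q0, sampling variance) — variance by leave-one-mother-out jackknife.
    """
    D, N, mothers = _segment_counts(records, period)
    tot_D, tot_N = D.sum(axis=0), N.sum(axis=0)
    if tot_N.sum() == 0:
        raise ValueError("no exposure-contributing records in the period")

    def q5(dd: np.ndarray, nn: np.ndarray) -> float:
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(nn > 0, dd / np.maximum(nn, 1e-300), 0.0)
        return float(1.0 - np.prod(1.0 - q))

    est = q5(tot_D, tot_N)
    m = len(mothers)
    if m < 2:
        return est, float("nan")
    loo = np.array([q5(tot_D - D[i], tot_N - N[i]) for i in range(m)])
    var = (m - 1) / m * float(np.sum((loo - loo.mean()) ** 2))
    return est, var


# ---------------------------------------------------------------------------
# Summary birth histories
# ---------------------------------------------------------------------------

def default_sbh_coefficients() -> pd.DataFrame:
    """Versioned coefficient table mapping proportion-dead to dated 5q0."""
    with resources.files("mortality_engine.data").joinpath(
        "sbh_coefficients.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def sbh_indirect_5q0(
    records: pd.DataFrame, coefficients: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Indirect 5q0 estimates from summary birth histories.

    ``records`` carries mother_age_group (e.g. "20-24"), ceb, cs,
    survey_date and optional weight.  Each maternal age group yields one
    dated estimate: 5q0 = multiplier * proportion dead, referenced
    time_shift years before the survey (younger mothers' children are more
    recent, so their estimates have smaller shifts).
    """
    if coefficients is None:
        coefficients = default_sbh_coefficients()
    coef = coefficients.set_index("age_group")
    w = records.get("weight", pd.Series(np.ones(len(records)))).to_numpy(float)
    df = records.assign(_w=w)
    rows = []
    for group, sub in df.groupby("mother_age_group"):
        ceb = float((sub["ceb"] * sub["_w"]).sum())
        cs = float((sub["cs"] * sub["_w"]).sum())
        if ceb <= 0:
            continue
        if group not in coef.index:
            raise KeyError(f"coefficient table missing maternal age group {group!r}")
        pd_dead = 1.0 - cs / ceb
        k = float(coef.loc[group, "multiplier"])
        shift = float(coef.loc[group, "time_shift"])
        survey = float(np.average(sub["survey_date"], weights=sub["_w"]))
        rows.append(
            {
                "mother_age_group": group,
                "reference_year": survey - shift,
                "q5": min(k * pd_dead, 1.0),
                "proportion_dead": pd_dead,
                "ceb": ceb,
            }
        )
    if not rows:
        raise ValueError("no maternal age group with children ever born")
    return pd.DataFrame(rows).sort_values("reference_year", ignore_index=True)


# ---------------------------------------------------------------------------
# Sibling histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiblingCorrections:
    selection: bool = True
    zero_reporter: bool = True


def _zero_reporter_p0(
    S_obs: np.ndarray, weights: np.ndarray, b: int
) -> float | None:
    """Probability that a size-b sibship has no surviving eligible member.

    Observed sibships are size-biased in S (a sibship is reported with
    probability proportional to its survivors), so the underlying survivor-
    count distribution is recovered as p(s) ~ p_obs(s)/s for s >= 1 and a
    beta-binomial is fitted to it; its mass at zero is the unobservable
    share.  The beta-binomial allows within-sibship survival correlation
    (shared environment), which a plain binomial would understate.
    """
    from scipy.stats import betabinom

    s_vals = np.arange(1, b + 1)
    counts = np.array(
        [float(weights[S_obs == s].sum()) for s in s_vals]
    )
    if counts.sum() <= 0 or (counts > 0).sum() < 2:
        return None
    p_tilde = counts / s_vals          # undo the size bias
    p_tilde = p_tilde / p_tilde.sum()

    # two-stage vectorised grid search over the (alpha, beta) shape params
    def _best(a_grid: np.ndarray, b_grid: np.ndarray) -> tuple[float, float]:
        A, Bp = np.meshgrid(a_grid, b_grid, indexing="ij")
        a_flat, b_flat = A.ravel()[:, None], Bp.ravel()[:, None]
        q = betabinom.pmf(s_vals[None, :], b, a_flat, b_flat)
        tot = q.sum(axis=1, keepdims=True)
        ok = tot[:, 0] > 1e-12
        loss = np.full(a_flat.shape[0], np.inf)
        loss[ok] = np.sum((p_tilde[None, :] - q[ok] / tot[ok]) ** 2, axis=1)
        i = int(np.argmin(loss))
        return float(a_flat[i, 0]), float(b_flat[i, 0])

    a0, b0 = _best(np.logspace(-1.0, 2.0, 25), np.logspace(-1.2, 1.5, 25))
    a1, b1 = _best(
        a0 * np.logspace(-0.18, 0.18, 9), b0 * np.logspace(-0.18, 0.18, 9)
    )
    return float(betabinom.pmf(0, b, a1, b1))


def _sibling_exposure(
    sib: pd.DataFrame, period: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Deaths and person-years per 5-year adult band for each sibling row."""
    t0, t1 = period
    birth = sib["birth_year"].to_numpy(float)
    death = sib["death_year"].to_numpy(float)
    dead = np.isfinite(death)
    end_obs = np.where(dead, death, np.inf)
    n = len(sib)
    D = np.zeros((n, len(ADULT_BANDS)))
    E = np.zeros((n, len(ADULT_BANDS)))
    for j, a in enumerate(ADULT_BANDS):
        seg_start = np.maximum(birth + a, t0)
        seg_end = np.minimum(np.minimum(birth + a + 5, t1), end_obs)
        exp_years = np.clip(seg_end - seg_start, 0.0, None)
        E[:, j] = exp_years
        died_here = (
            dead
            & (death >= birth + a)
            & (death < birth + a + 5)
            & (death >= t0)
            & (death < t1)
        )
        D[died_here, j] = 1.0
    return D, E


def _q_from_rates(m: np.ndarray) -> float:
    """45q15 from 5-year age-specific death rates (mid-interval ax)."""
    q = 5.0 * m / (1.0 + 2.5 * m)
    q = np.clip(q, 0.0, 1.0)
    return float(1.0 - np.prod(1.0 - q))


def _poisson_loglinear(num: np.ndarray, den: np.ndarray, x: np.ndarray) -> np.ndarray | None:
    """Poisson IRLS for log m = b0 + b1 x with exposure offsets; fitted m."""
    b = np.array([math.log(max(num.sum() / den.sum(), 1e-8)), 0.05])
    X = np.column_stack([np.ones(len(x)), x])
    for _ in range(25):
        mu = den * np.exp(X @ b)
        z = X @ b + (num - mu) / np.maximum(mu, 1e-12)
        W = mu
        XtWX = (X * W[:, None]).T @ X
        XtWz = (X * W[:, None]).T @ z
        try:
            b_new = np.linalg.solve(XtWX + 1e-10 * np.eye(2), XtWz)
        except np.linalg.LinAlgError:
            return None
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = np.clip(b_new, [-12.0, -0.2], [2.0, 0.25])
    return b


def _gompertz_band_rates(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Credibility-blended band rates: raw where exposure is adequate,
    log-linear-in-age (Gompertz) extrapolation where it is thin.

    A short reporting window yields a handful of deaths spread over nine
    age bands; the oldest bands (which dominate 45q15) often carry almost
    no exposure, and their raw rates are zero or wild.  The fit is
    anchored on ages 30+ so a young-adult epidemic hump does not distort
    the old-age extrapolation; each band then blends its raw rate with the
    fitted rate according to the deaths it can statistically support.
    """
    ages = np.array(ADULT_BANDS, float) + 2.5
    with np.errstate(invalid="ignore", divide="ignore"):
        m_raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    old = (ages >= 30.0) & (den > 0)
    if old.sum() >= 3 and num[old].sum() > 0:
        fit_sel = old
    elif (den > 0).sum() >= 3 and num.sum() > 0:
        fit_sel = den > 0
    else:
        return m_raw
    xc = ages[fit_sel] - ages[fit_sel].mean()
    b = _poisson_loglinear(num[fit_sel], den[fit_sel], xc)
    if b is None:
        return m_raw
    m_fit = np.exp(b[0] + b[1] * (ages - ages[fit_sel].mean()))
    # credibility: a band with >= ~4 expected deaths mostly speaks for itself
    expected = den * m_fit
    z = expected / (expected + 4.0)
    return z * m_raw + (1.0 - z) * m_fit


def _gk_weighted_counts(
    reports: pd.DataFrame,
    period: tuple[float, float],
    corrections: SiblingCorrections,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(num, den, per-row D, per-row E, gk weights) after corrections."""
    S = reports["n_surviving"].to_numpy(float)
    if np.any(S < 1):
        raise ValueError("observed report with S = 0 is impossible by construction")
    w = reports.get("weight", pd.Series(np.ones(len(reports)))).to_numpy(float)
    gk = w / S if corrections.selection else w

    D, E = _sibling_exposure(reports, period)
    if E.sum() <= 0:
        raise ValueError("no adult exposure in the period")
    num = gk @ D
    den = gk @ E

    if corrections.zero_reporter:
        B = reports["sibship_size"].to_numpy(float)
        dead = np.isfinite(reports["death_year"].to_numpy(float))
        for b in np.unique(B):
            b_int = int(b)
            if b_int < 2:
                continue  # singleton sibships cannot be all-dead and reported
            sel = B == b
            p0 = _zero_reporter_p0(
                reports.loc[sel, "n_surviving"].to_numpy(float),
                w[sel],
                b_int,
            )
            if p0 is None or p0 <= 0 or p0 >= 0.9:
                continue
            dead_sel = sel & dead
            dead_mass = gk[dead_sel].sum()
            if dead_mass <= 0:
                continue
            # expected unobserved dead persons, profiled on observed deaths
            n_sibships = gk[sel].sum() / b  # GK-weighted sibship count
            extra_persons = n_sibships * p0 / (1.0 - p0) * b
            scale = extra_persons / dead_mass
            num += scale * (gk[dead_sel] @ D[dead_sel])
            den += scale * (gk[dead_sel] @ E[dead_sel])
    return num, den, D, E, gk


def sibling_45q15(
    reports: pd.DataFrame,
    period: tuple[float, float],
    corrections: SiblingCorrections = SiblingCorrections(),
    age_smooth: str = "gompertz",
    n_jackknife_groups: int = 30,
) -> tuple[float, float]:
    """Adult mortality 45q15 from sibling survival reports.

    ``reports`` has one row per listed sibling (respondents list
    themselves): respondent_id, birth_year, death_year (NaN if alive),
    optional weight, and per-respondent columns n_surviving (S, surviving
    reporting-eligible siblings including the respondent) and sibship_size
    (B).  The Gakidou-King selection correction weights each report by
    1/S; the zero-reporter correction adds the expected contribution of
    all-dead sibships, estimated parametrically from the observed
    sibship-size/survival distribution.  Band rates are smoothed with an
    exposure-offset Poisson Gompertz fit (``age_smooth="none"`` keeps the
    raw band rates); the variance is a delete-one-group jackknife over
    respondent groups.
    """
    if len(reports) == 0:
        raise ValueError("no sibling reports")
    num, den, D, E, gk = _gk_weighted_counts(reports, period, corrections)

    def assemble(nn: np.ndarray, dd: np.ndarray) -> float:
        if age_smooth == "gompertz":
            m = _gompertz_band_rates(nn, dd)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(dd > 0, nn / np.maximum(dd, 1e-300), 0.0)
        return _q_from_rates(m)

    est = assemble(num, den)

    # delete-one-group jackknife over respondents for the sampling variance
    resp = reports["respondent_id"].to_numpy()
    uresp, rinv = np.unique(resp, return_inverse=True)
    R = len(uresp)
    if R < 2:
        return est, float("nan")
    G = min(n_jackknife_groups, R)
    group_of = rinv % G
    numG = np.zeros((G, len(ADULT_BANDS)))
    denG = np.zeros((G, len(ADULT_BANDS)))
    np.add.at(numG, group_of, gk[:, None] * D)
    np.add.at(denG, group_of, gk[:, None] * E)
    tot_n, tot_d = numG.sum(axis=0), denG.sum(axis=0)
    loo = np.empty(G)
    for g in range(G):
        loo[g] = assemble(tot_n - numG[g], tot_d - denG[g])
    var = (G - 1) / G * float(np.sum((loo - loo.mean()) ** 2))
    return est, var


def sibling_death_rate(
    reports: pd.DataFrame,
    period: tuple[float, float],
    corrections: SiblingCorrections = SiblingCorrections(selection=True, zero_reporter=False),
) -> float:
    """GK-weighted crude adult death rate (deaths per person-year, ages
    15-59) over the period.

    When every surviving eligible sibling is interviewed, the 1/S weights
    make this identically equal to the census death rate of the sibling
    population: a sibship with S survivors is reported S times, each with
    weight 1/S, so each sibship contributes exactly once.
    """
    num, den, *_ = _gk_weighted_counts(reports, period, corrections)
    total_e = den.sum()
    if total_e <= 0:
        raise ValueError("no adult exposure in the period")
    return float(num.sum() / total_e)


# ---------------------------------------------------------------------------
# Cross-source bias adjustment
# ---------------------------------------------------------------------------

def _transform(values: np.ndarray, space: str) -> np.ndarray:
    if space == "logit":
        v = np.clip(values, 1e-12, 1 - 1e-12)
        return np.log(v / (1 - v))
    if space == "log":
        return np.log(np.clip(values, 1e-300, None))
    return values


def _back(values: np.ndarray, space: str) -> np.ndarray:
    if space == "logit":
        return 1.0 / (1.0 + np.exp(-values))
    if space == "log":
        return np.exp(values)
    return values


def source_bias_adjust(
    observations: pd.DataFrame,
    reference_type: str,
    space: str = "logit",
    hierarchy: pd.DataFrame | None = None,
    allow_pooling: bool = True,
    match_window: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Remove per-source-type additive offsets against the reference source.

    For every non-reference observation, the nearest-in-time reference
    observation from the same location within ``match_window`` years is
    its comparison point (observations are dated at period midpoints, so
    exact year matches are rare); the offset is the mean difference in
    transformed space over those pairs.  A source type with no overlap
    anywhere falls back to the pooled (all-location) offset when
    ``allow_pooling``, otherwise it passes through unadjusted with a
    warning.  Reference observations are returned unchanged.
    """
    obs = observations.copy()
    if reference_type not in set(obs["source_type"]):
        raise ValueError(f"reference source type {reference_type!r} absent")
    obs["_t"] = _transform(obs["value"].to_numpy(float), space)
    ref = obs[obs["source_type"] == reference_type]
    ref_by_loc = {
        loc: sub.sort_values("year") for loc, sub in ref.groupby("location")
    }
    offsets: dict[str, float] = {reference_type: 0.0}
    for stype, sub in obs.groupby("source_type"):
        if stype == reference_type:
            continue
        diffs = []
        for _, row in sub.iterrows():
            r = ref_by_loc.get(row["location"])
            if r is None or not len(r):
                continue
            dt = np.abs(r["year"].to_numpy(float) - float(row["year"]))
            j = int(np.argmin(dt))
            if dt[j] <= match_window:
                diffs.append(row["_t"] - float(r["_t"].iloc[j]))
        if diffs:
            offsets[stype] = float(np.mean(diffs))
        elif allow_pooling:
            # hierarchy-level pooled fallback: global mean difference
            pooled = sub["_t"].mean() - ref["_t"].mean()
            offsets[stype] = float(pooled)
            logger.warning(
                "source type %s has no overlap with %s; using pooled offset",
                stype,
                reference_type,
            )
        else:
            offsets[stype] = 0.0
            warnings.warn(
                f"source type {stype!r} has no overlap with reference and "
                "pooling is disabled; passing through unadjusted",
                stacklevel=2,
            )
    shift = obs["source_type"].map(offsets).to_numpy(float)
    obs["value"] = _back(obs["_t"].to_numpy() - shift, space)
    return obs.drop(columns=["_t"]), offsets
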