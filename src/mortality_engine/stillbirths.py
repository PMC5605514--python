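"""Stillbirth estimation.

Source data define a stillbirth variously (fetal death after 20, 22, 24,
26, or 28 weeks' gestation, or weighing at least 500 g or 1000 g, or with
no stated definition).  Observations are standardised to the >=28-week
reference definition with multiplicative scalars, then the ratio of the
stillbirth rate (SBR, per 1000 livebirths) to the neonatal mortality rate
(NMR) is modelled on the log scale with ST-GPR — covariates: maternal
educational attainment and a spline in log NMR — and SBR is recovered at
draw level as ratio x NMR.

The shipped scalar table is a versioned package fixture; swap in
alternative scalars via :class:`DefinitionScalarTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from importlib import resources

import numpy as np
import pandas as pd

from mortality_engine.stgpr import (
    EstimateSeries,
    STGPRConfig,
    stgpr_estimate,
)

__all__ = [
    "StillbirthObservation",
    "DefinitionScalarTable",
    "REFERENCE_DEFINITION",
    "standardize_definition",
    "estimate_stillbirth_rate",
    "nmr_spline_basis",
]

REFERENCE_DEFINITION = "28wk"
KNOWN_DEFINITIONS = ("20wk", "22wk", "24wk", "26wk", "28wk", "500g", "1000g", "none")


@dataclass(frozen=True)
class StillbirthObservation:
    location: str
    year: float
    rate: float                      # stillbirths per 1000 livebirths
    definition: str
    source_type: str = "survey"
    no_definition_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("stillbirth rate must be non-negative")
        if self.definition not in KNOWN_DEFINITIONS:
            raise ValueError(f"unknown stillbirth definition {self.definition!r}")


@dataclass(frozen=True)
class DefinitionScalarTable:
    """Multiplicative scalars mapping each definition to the reference."""

    scalars: dict[str, float]
    reference: str = REFERENCE_DEFINITION

    def __post_init__(self) -> None:
        if self.scalars.get(self.reference) != 1.0:
            raise ValueError("scalar for the reference definition must be 1")

    @staticmethod
    def default() -> "DefinitionScalarTable":
        with resources.files("mortality_engine.data").joinpath(
            "stillbirth_definition_scalars.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
        return DefinitionScalarTable(dict(zip(df["definition"], df["scalar"])))


def standardize_definition(
    obs: StillbirthObservation, table: DefinitionScalarTable | None = None
) -> StillbirthObservation:
    """Rescale an observation to the reference definition (idempotent)."""
    if table is None:
        table = DefinitionScalarTable.default()
    if obs.definition == table.reference:
        return obs
    if obs.definition not in table.scalars:
        raise KeyError(f"scalar table missing definition {obs.definition!r}")
    return dc_replace(
        obs,
        rate=obs.rate * table.scalars[obs.definition],
        definition=table.reference,
        no_definition_adjusted=obs.definition == "none",
    )


def nmr_spline_basis(log_nmr: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural-spline-style basis for the non-linear NMR term.

    Piecewise-linear hinge basis with interior knots at the terciles; cheap,
    monotone-friendly, and rank-stable on small panels.
    """
    x = np.asarray(log_nmr, dtype=float)
    if knots is None:
        knots = np.quantile(x, [1 / 3, 2 / 3])
    cols = [x] + [np.clip(x - k, 0.0, None) for k in np.atleast_1d(knots)]
    return np.column_stack(cols)


def estimate_stillbirth_rate(
    ratio_obs: pd.DataFrame,
    education: pd.DataFrame,
    nmr: dict[str, EstimateSeries],
    births: pd.DataFrame,
    hierarchy: pd.DataFrame,
    config: STGPRConfig | None = None,
) -> tuple[dict[str, EstimateSeries], pd.DataFrame]:
    """Estimate SBR per location-year via the SBR:NMR ratio model.

    Parameters
    ----------
    ratio_obs : location, year, value (= SBR/NMR), variance, source_type.
    education : location, year, education (years, women of reproductive age).
    nmr : per-location NMR series (per 1000 livebirths) with draws.
    births : location, year, livebirths.
    config : ST-GPR settings; the transform is forced to log.

    Returns
    -------
    (sbr_series, counts) where ``sbr_series`` maps location to an
    SBR :class:`EstimateSeries` (per 1000 livebirths; draws are the
    element-wise product of ratio and NMR draws) and ``counts`` is a tidy
    frame of stillbirth counts in thousands.
    """
    if config is None:
        config = STGPRConfig(transform="log")
    elif config.transform != "log":
        config = dc_replace(config, transform="log")

    covs = education.copy()
    nmr_mean = {
        (loc, y): m
        for loc, s in nmr.items()
        for y, m in zip(s.years, s.mean)
    }
    covs["_lognmr"] = [
        np.log(max(nmr_mean.get((l, y), np.nan), 1e-6))
        for l, y in zip(covs["location"], covs["year"])
    ]
    if covs["_lognmr"].isna().any():
        raise ValueError("NMR series missing for some covariate location-years")
    basis = nmr_spline_basis(covs["_lognmr"].to_numpy())
    names = ["education"] + [f"nmr_s{i}" for i in range(basis.shape[1])]
    for i in range(basis.shape[1]):
        covs[f"nmr_s{i}"] = basis[:, i]
    config = dc_replace(config, covariates=tuple(names))

    ratio_fit = stgpr_estimate(ratio_obs, covs, hierarchy, config)

    sbr: dict[str, EstimateSeries] = {}
    rows = []
    births_ix = births.set_index(["location", "year"])["livebirths"]
    for loc, ratio_series in ratio_fit.items():
        nser = nmr[loc]
        if not np.array_equal(nser.years, ratio_series.years):
            raise ValueError(f"year grids differ for {loc}")
        n_draws = min(ratio_series.draws.shape[1], nser.draws.shape[1])
        draws = ratio_series.draws[:, :n_draws] * nser.draws[:, :n_draws]
        mean = ratio_series.mean * nser.mean
        series = EstimateSeries(loc, ratio_series.years, mean, draws)
        sbr[loc] = series
        for i, y in enumerate(series.years):
            lb = float(births_ix.get((loc, y), np.nan))
            rows.append(
                {
                    "location": loc,
                    "year": y,
                    "sbr": series.mean[i],
                    "sbr_lower": series.lower[i],
                    "sbr_upper": series.upper[i],
                    "stillbirths_thousands": series.mean[i] / 1000.0 * lb / 1000.0,
                }
            )
    return sbr, pd.DataFrame(rows)
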