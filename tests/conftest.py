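"""Shared fixtures: session-scoped synthetic worlds and pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from mortality_engine.demographic_core import AgeGrid
from mortality_engine.pipeline import PipelineConfig, run_pipeline
from mortality_engine.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions: 12 locations, 1970-2016."""
    return generate_world(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def default_bundle(default_world):
    return run_pipeline(default_world, PipelineConfig(n_draws=100, seed=0))


@pytest.fixture(scope="session")
def small_world():
    """A miniature world for fast integration tests."""
    return generate_world(
        WorldConfig(
            seed=11,
            n_locations=6,
            n_regions=2,
            year_start=1980,
            year_end=2005,
            roles=("vr", "vr", "partial", "partial", "survey", "partial"),
            hiv_locations=("L03",),
            census_years=(1985, 1990, 1995, 2000),
            first_survey_year=1990,
            n_mothers=800,
            n_respondents=900,
        )
    )


@pytest.fixture(scope="session")
def small_bundle(small_world):
    return run_pipeline(small_world, PipelineConfig(n_draws=20, seed=11))


def hazard_oracle(hazard, grid: AgeGrid | None = None, max_age: float = 130.0):
    """Fine-grained life table oracle for a continuous hazard function.

    Integrates survival on a 0.02-year grid (brute force, independent of
    the abridged machinery) and also returns the exposure-weighted
    abridged group rates implied by the same hazard, so the abridged
    construction can be checked against the exact e0.
    """
    if grid is None:
        grid = AgeGrid.gbd()
    # dense sub-year resolution for the neonatal groups
    fine = np.unique(
        np.concatenate([np.linspace(0.0, 1.0, 2001), np.arange(1.0, max_age, 0.02)])
    )
    h = hazard(fine)
    cum = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(fine))])
    l = np.exp(-cum)
    e0_exact = float(np.trapezoid(l, fine))

    m_group = np.empty(len(grid))
    for i, g in enumerate(grid):
        a = g.start
        b = g.start + g.width if np.isfinite(g.width) else max_age
        sel = (fine >= a - 1e-12) & (fine <= b + 1e-12)
        exposure = np.trapezoid(l[sel], fine[sel])
        deaths = l[sel][0] - l[sel][-1]
        m_group[i] = deaths / exposure if exposure > 0 else float(hazard(np.array([a]))[0])
    return e0_exact, m_group
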