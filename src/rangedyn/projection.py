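"""Stochastic forward projection of occupancy under environmental scenarios.

Starting from the observed 2003 range, occupancy is simulated in 25-year
steps (2028, 2053, 2078, 2103). At each step the neighborhood occupancy D
is recomputed from the current simulated state, the habitat suitability H
is evaluated on that step's scenario environment, the transition
probability q follows the fitted persistence-colonization model (at a
fixed parameter point, by default the posterior medians), and the new
state is a Bernoulli draw per cell. Repeating the simulation (default
1,000 replicates) gives a per-cell occupancy frequency per step; cells
whose frequency exceeds a sensitivity-derived threshold form the
*potential distribution*, whose area is tracked over time.

Scenario bundles group members by driver: baseline (no change), land-use
change only, climate change only, and combined. Group-level summaries
average member frequencies and report 95% percentile bands of member
areas.

Each replicate draws from its own RNG stream derived from
(seed, replicate index), so results are bit-reproducible and adding
replicates never reshuffles earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, transition_probability
from .grid import CellGrid, EnvTable, NeighborhoodSpec, OccupancyField, neighborhood_weights
from .habitat import HabitatModel, suitability

logger = logging.getLogger("rangedyn")

STEP_YEARS = (2028, 2053, 2078, 2103)
SCENARIO_GROUPS = ("baseline", "lu_only", "cl_only", "lucl")

#: published sensitivity-95% threshold on the occupancy frequency
DEFAULT_THRESHOLD = 0.1725


@dataclass(frozen=True)
class ScenarioBundle:
    """A scenario group: members map step-year -> environmental table."""

    group: str
    members: dict[str, dict[int, EnvTable]]

    def __post_init__(self):
        if self.group not in SCENARIO_GROUPS:
            raise ValueError(f"group must be one of {SCENARIO_GROUPS}")
        if not self.members:
            raise ValueError("bundle needs at least one member")
        for mid, steps in self.members.items():
            missing = [y for y in STEP_YEARS if y not in steps]
            if missing:
                raise ValueError(f"member '{mid}' missing step years {missing}")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ProjectionConfig:
    replicates: int = 1000
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    dispersal: NeighborhoodSpec = field(
        default_factory=lambda: NeighborhoodSpec(radius_km=100, weight_exponent=2)
    )

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class ProjectionResult:
    """Per-step occupancy frequencies and potential-distribution areas."""

    step_years: tuple[int, ...]
    frequencies: dict[int, np.ndarray]  # step year -> per-cell freq in [0,1]
    areas_km2: dict[int, float]
    replicates: int
    threshold: float

    def area_series(self) -> pd.Series:
        return pd.Series({y: self.areas_km2[y] for y in self.step_years})


def potential_area(
    frequencies: np.ndarray, threshold: float, cell_areas: np.ndarray
) -> float:
    """Total area (km^2) of cells with occupancy frequency strictly > threshold."""
    freq = np.asarray(frequencies, dtype=float)
    areas = np.asarray(cell_areas, dtype=float)
    return float(areas[freq > threshold].sum())


def percent_change(area_scenario: float, area_baseline: float) -> float:
    """Signed percent change of a scenario area over baseline, to 1 decimal."""
    if area_baseline <= 0:
        raise ValueError("baseline area must be positive")
    return round(100.0 * (area_scenario - area_baseline) / area_baseline, 1)


def project_scenario(
    model: HabitatModel,
    params: DynamicsParams,
    occ2003: OccupancyField,
    grid: CellGrid,
    member_env: dict[int, EnvTable],
    config: ProjectionConfig,
) -> ProjectionResult:
    """Monte-Carlo forward simulation of one scenario member.

    The dispersal covariate at the first step comes from the observed 2003
    occupancy; afterwards from the simulated state of the previous step.
    The habitat model here carries no autocovariate (the selected models
    had none); a formula with one is rejected rather than silently fed a
    stale autocovariate.
    """
    if model.formula.autocov is not None:
        raise ValueError("projection does not support autocovariate habitat models")
    missing = [y for y in STEP_YEARS if y not in member_env]
    if missing:
        raise ValueError(f"scenario member missing step environment for {missing}")
    if occ2003.n != grid.n:
        raise ValueError("occupancy does not align with grid")

    W = neighborhood_weights(grid, config.dispersal)
    h_by_step = {
        y: suitability(model, member_env[y], grid).h for y in STEP_YEARS
    }
    counts = {y: np.zeros(grid.n, dtype=np.int64) for y in STEP_YEARS}
    x0 = occ2003.x.astype(float)
    for rep in range(config.replicates):
        rng = np.random.default_rng([config.seed, rep])
        state = x0
        for year in STEP_YEARS:
            d = np.clip(W @ state, 0.0, 1.0)
            q = transition_probability(params, state, d, h_by_step[year])
            state = (rng.random(grid.n) < q).astype(float)
            counts[year] += state.astype(np.int64)

    freqs = {y: counts[y] / config.replicates for y in STEP_YEARS}
    areas = {
        y: potential_area(freqs[y], config.threshold, grid.area_km2)
        for y in STEP_YEARS
    }
    return ProjectionResult(
        step_years=STEP_YEARS,
        frequencies=freqs,
        areas_km2=areas,
        replicates=config.replicates,
        threshold=config.threshold,
    )


@dataclass
class GroupSummary:
    """Scenario-group aggregate: mean surfaces and area band per step."""

    group: str
    mean_frequencies: dict[int, np.ndarray]
    mean_area_km2: dict[int, float]
    area_band_km2: dict[int, tuple[float, float]]  # 2.5 / 97.5 percentiles
    member_areas: pd.DataFrame  # columns: member, year, area_km2


def project_bundle(
    model: HabitatModel,
    params: DynamicsParams,
    occ2003: OccupancyField,
    grid: CellGrid,
    bundle: ScenarioBundle,
    config: ProjectionConfig,
) -> dict[str, ProjectionResult]:
    """Project every member of a bundle (one RNG stream family per member)."""
    results = {}
    for k, (mid, steps) in enumerate(sorted(bundle.members.items())):
        member_cfg = ProjectionConfig(
            replicates=config.replicates,
            threshold=config.threshold,
            seed=int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2**31)),
            dispersal=config.dispersal,
        )
        results[mid] = project_scenario(model, params, occ2003, grid, steps, member_cfg)
    return results


def aggregate_group(
    group: str, results: dict[str, ProjectionResult]
) -> GroupSummary:
    """Cell-wise mean frequency and per-step area mean + 95% percentile band."""
    if not results:
        raise ValueError("no member results to aggregate")
    step_years = next(iter(results.values())).step_years
    mean_freq = {
        y: np.mean([r.frequencies[y] for r in results.values()], axis=0)
        for y in step_years
    }
    rows = [
        {"member": mid, "year": y, "area_km2": r.areas_km2[y]}
        for mid, r in sorted(results.items())
        for y in step_years
    ]
    frame = pd.DataFrame(rows)
    mean_area, band = {}, {}
    for y in step_years:
        areas = frame.loc[frame["year"] == y, "area_km2"].to_numpy()
        mean_area[y] = float(areas.mean())
        # order-statistic percentiles: for ensembles of <= 40 members the
        # 95% band spans every member by construction
        band[y] = (
            float(np.percentile(areas, 2.5, method="lower")),
            float(np.percentile(areas, 97.5, method="higher")),
        )
    return GroupSummary(
        group=group,
        mean_frequencies=mean_freq,
        mean_area_km2=mean_area,
        area_band_km2=band,
        member_areas=frame,
    )
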