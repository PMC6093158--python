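"""Synthetic landscapes, occupancy histories, and scenario bundles.

The national survey data behind the sika deer analysis are not publicly
distributable, so every stage of the pipeline is exercised on synthetic
landscapes that reproduce the *statistical structure* the method assumes:

* a regular ~5-km grid with a north/south region split (Hokkaido vs the
  other islands),
* spatially autocorrelated snow covariates with a strong latitudinal
  gradient (kernel-smoothed Gaussian noise; the correlation length is the
  kernel bandwidth),
* compositional land use (forest / wasteland / agriculture / built-up,
  closing to <= 1 with an implicit "other" remainder) built by softmax of
  correlated fields,
* 1978 occupancy drawn from the published habitat logistic model and a
  2003 occupancy drawn from the published persistence-colonization
  parameters, so parameter-recovery tests have known generating values,
* future scenario bundles that move snow (climate members) and transfer
  built-up/agricultural land into wasteland (land-abandonment members),
  mass-conservingly, in four 25-year steps.

All generators are pure functions of (config, seed). The default extent,
124 x 124 = 15,376 cells, mirrors the real survey's 15,256; tests use
smaller grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .dynamics import DynamicsParams, transition_probability
from .grid import CellGrid, DEFAULT_CELL_AREA_KM2, EnvTable, NeighborhoodSpec, OccupancyField, neighborhood_occupancy
from .habitat import HabitatModel, suitability
from .projection import STEP_YEARS, ScenarioBundle
from .selection import DataBundle

logger = logging.getLogger("rangedyn")


@dataclass(frozen=True)
class LandscapeConfig:
    """Synthetic landscape geometry, covariate fields and 1978->2003 drift.

    Snow cover period runs from ~`scp_south` days in the south to
    ~`scp_north` in the north with spatially correlated noise; between the
    epochs it declines by `scp_decline_days` on average (the observed
    direction of change in Japan over 1978-2003). Land-use change combines
    suburban urbanization (forest/agriculture -> built-up near built-up
    concentrations) with rural land abandonment (agriculture ->
    wasteland).
    """

    n_rows: int = 124
    n_cols: int = 124
    spacing_km: float = 5.0
    hokkaido_fraction: float = 0.22
    corr_length_km: float = 50.0
    seed: int = 0
    # snow
    scp_south: float = 15.0
    scp_north: float = 180.0
    scp_noise: float = 35.0
    msd_per_scp_day: float = 1.2
    msd_noise: float = 25.0
    # topography
    sl_mean: float = 12.0
    sl_noise: float = 8.0
    # land use: softmax base logits over (fr, ws, ag, bt, other)
    landuse_logits: tuple[float, ...] = (1.6, -1.2, 0.6, -1.2, -0.6)
    landuse_noise: float = 0.8
    # drift 1978 -> 2003
    scp_decline_days: float = 12.0
    msd_decline_cm: float = 10.0
    urbanization_rate: float = 0.25
    abandonment_rate: float = 0.15

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.corr_length_km <= 0:
            raise ValueError("correlation length must be positive")


def _smooth_field(shape, rng, corr_cells: float) -> np.ndarray:
    """Kernel-smoothed standard-normal field (unit variance, mean ~0)."""
    raw = rng.standard_normal(shape)
    f = gaussian_filter(raw, sigma=corr_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(
    config: LandscapeConfig,
) -> tuple[CellGrid, EnvTable, EnvTable]:
    """Regular grid plus 1978 and 2003 environmental tables."""
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    shape = (nr, nc)
    corr_cells = config.corr_length_km / config.spacing_km

    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    x = (cols * config.spacing_km).ravel()
    y = (rows * config.spacing_km).ravel()
    lat_frac = (rows / (nr - 1)).ravel()  # 0 = south, 1 = north
    region = np.where(
        lat_frac >= 1 - config.hokkaido_fraction, "hokkaido", "other"
    ).astype(object)
    grid = CellGrid(
        cell_id=np.arange(nr * nc),
        x_km=x,
        y_km=y,
        region=region,
        area_km2=np.full(nr * nc, DEFAULT_CELL_AREA_KM2),
    )

    # climate: latitudinal gradient + correlated noise
    f_scp = _smooth_field(shape, rng, corr_cells).ravel()
    scp78 = np.clip(
        config.scp_south
        + (config.scp_north - config.scp_south) * lat_frac
        + config.scp_noise * f_scp,
        0.0,
        366.0,
    )
    f_msd = _smooth_field(shape, rng, corr_cells).ravel()
    msd78 = np.clip(
        config.msd_per_scp_day * scp78 + config.msd_noise * f_msd, 0.0, None
    )

    # topography
    f_sl = _smooth_field(shape, rng, corr_cells).ravel()
    sl = np.clip(config.sl_mean + config.sl_noise * f_sl, 0.0, 45.0)

    # compositional land use via softmax of correlated fields
    logits = np.stack(
        [
            base + config.landuse_noise * _smooth_field(shape, rng, corr_cells).ravel()
            for base in config.landuse_logits
        ]
    )
    ex = np.exp(logits - logits.max(axis=0, keepdims=True))
    probs = ex / ex.sum(axis=0, keepdims=True)
    fr78, ws78, ag78, bt78 = probs[0], probs[1], probs[2], probs[3]

    env1978 = EnvTable(
        epoch="1978", scp=scp78, msd=msd78, fr=fr78, ws=ws78, ag=ag78, bt=bt78, sl=sl
    )

    # drift to 2003: snow decline (spatially variable), urbanization in
    # suburban cells, abandonment elsewhere; land-use transfers conserve
    # the four-category total per cell.
    f_drift = _smooth_field(shape, rng, corr_cells).ravel()
    scp03 = np.clip(scp78 - (config.scp_decline_days + 5.0 * f_drift), 0.0, 366.0)
    msd03 = np.clip(msd78 - (config.msd_decline_cm + 4.0 * f_drift), 0.0, None)

    suburban = bt78 > np.quantile(bt78, 0.8)
    take_fr = np.where(suburban, config.urbanization_rate * 0.5 * fr78, 0.0)
    take_ag = np.where(suburban, config.urbanization_rate * ag78, 0.0)
    abandoned = np.where(~suburban, config.abandonment_rate * ag78, 0.0)
    fr03 = fr78 - take_fr
    ag03 = ag78 - take_ag - abandoned
    bt03 = bt78 + take_fr + take_ag
    ws03 = ws78 + abandoned
    env2003 = EnvTable(
        epoch="2003", scp=scp03, msd=msd03, fr=fr03, ws=ws03, ag=ag03, bt=bt03, sl=sl
    )
    return grid, env1978, env2003


def simulate_initial_occupancy(
    model: HabitatModel,
    env1978: EnvTable,
    grid: CellGrid,
    seed: int | None = None,
    autocov_d: np.ndarray | None = None,
) -> OccupancyField:
    """Independent Bernoulli(logistic(H_i)) draws per cell."""
    rng = np.random.default_rng(seed)
    h = suitability(model, env1978, grid, autocov_d=autocov_d).h
    x = (rng.random(grid.n) < expit(h)).astype(np.int8)
    return OccupancyField(year="1978", x=x)


def simulate_transition(
    params: DynamicsParams,
    occ1978: OccupancyField,
    d: np.ndarray,
    h2003: np.ndarray,
    seed: int | None = None,
) -> OccupancyField:
    """One persistence-colonization step: Bernoulli(q_i) per cell."""
    rng = np.random.default_rng(seed)
    q = transition_probability(params, occ1978.x, d, h2003)
    x = (rng.random(occ1978.n) < q).astype(np.int8)
    return OccupancyField(year="2003", x=x)


def generate_bundle(
    config: LandscapeConfig,
    habitat_model: HabitatModel,
    params: DynamicsParams,
    dispersal: NeighborhoodSpec,
    seed: int | None = None,
    surface_epoch: int = 2003,
) -> DataBundle:
    """Landscape + occupancy history generated from known parameter values.

    The 2003 occupancy is simulated from the transition model using the
    dispersal covariate of the 1978 occupancy and the suitability surface
    of ``surface_epoch`` — the generating candidate that selection tests
    try to recover.
    """
    ss = np.random.SeedSequence(seed)
    s_occ78, s_occ03 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    grid, env1978, env2003 = generate_landscape(config)
    occ1978 = simulate_initial_occupancy(habitat_model, env1978, grid, seed=s_occ78)
    d = neighborhood_occupancy(occ1978, grid, dispersal)
    env_surface = {1978: env1978, 2003: env2003}[int(surface_epoch)]
    h = suitability(habitat_model, env_surface, grid).h
    occ2003 = simulate_transition(params, occ1978, d, h, seed=s_occ03)
    return DataBundle(
        grid=grid, env1978=env1978, env2003=env2003, occ1978=occ1978, occ2003=occ2003
    )


# ---------------------------------------------------------------------------
# future scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendConfig:
    """Per-step future trends and scenario-group member counts.

    Climate members differ in velocity (multipliers on the per-step snow
    decline, emulating slower/faster circulation models); land-use members
    differ in abandonment intensity. Member counts default to the study's
    1 / 9 / 4 / 36 design (the combined group crosses the two sets).
    """

    scp_step_decline_days: float = 8.0
    msd_step_decline_cm: float = 6.0
    abandonment_step_rate: float = 0.05
    n_lu_members: int = 9
    n_cl_members: int = 4

    def __post_init__(self):
        if self.n_lu_members < 1 or self.n_cl_members < 1:
            raise ValueError("member counts must be >= 1")
        if not 0 <= self.abandonment_step_rate < 1:
            raise ValueError("abandonment rate must lie in [0, 1)")


def _member_multipliers(n: int) -> np.ndarray:
    if n == 1:
        return np.array([1.0])
    return np.linspace(0.5, 1.5, n)


def _apply_trends(
    env: EnvTable,
    epoch: str,
    cl_mult: float,
    lu_mult: float,
    trends: TrendConfig,
) -> EnvTable:
    """One 25-year step: snow decline (climate) and abandonment (land use)."""
    scp = np.clip(env.scp - cl_mult * trends.scp_step_decline_days, 0.0, 366.0)
    msd = np.clip(env.msd - cl_mult * trends.msd_step_decline_cm, 0.0, None)
    rate = lu_mult * trends.abandonment_step_rate
    moved_bt = rate * env.bt
    moved_ag = rate * env.ag
    bt = env.bt - moved_bt
    ag = env.ag - moved_ag
    ws = env.ws + moved_bt + moved_ag
    if np.any(ws > 1) or np.any(bt < 0) or np.any(ag < 0):
        logger.warning("land-use trend clipped to keep proportions in [0, 1]")
        ws, bt, ag = np.clip(ws, 0, 1), np.clip(bt, 0, 1), np.clip(ag, 0, 1)
    return env.replace(epoch=epoch, scp=scp, msd=msd, ws=ws, bt=bt, ag=ag)


def _member_steps(
    env2003: EnvTable, cl_mult: float, lu_mult: float, trends: TrendConfig
) -> dict[int, EnvTable]:
    steps = {}
    current = env2003
    for year in STEP_YEARS:
        current = _apply_trends(current, str(year), cl_mult, lu_mult, trends)
        steps[year] = current
    return steps


def generate_scenarios(
    env2003: EnvTable, trends: TrendConfig | None = None
) -> dict[str, ScenarioBundle]:
    """The four scenario groups: baseline, lu_only, cl_only, lucl."""
    trends = trends or TrendConfig()
    lu_mults = _member_multipliers(trends.n_lu_members)
    cl_mults = _member_multipliers(trends.n_cl_members)

    baseline = ScenarioBundle(
        group="baseline",
        members={"bl": {y: env2003.replace(epoch=str(y)) for y in STEP_YEARS}},
    )
    lu_only = ScenarioBundle(
        group="lu_only",
        members={
            f"lu{j}": _member_steps(env2003, 0.0, m, trends)
            for j, m in enumerate(lu_mults)
        },
    )
    cl_only = ScenarioBundle(
        group="cl_only",
        members={
            f"cl{k}": _member_steps(env2003, m, 0.0, trends)
            for k, m in enumerate(cl_mults)
        },
    )
    lucl = ScenarioBundle(
        group="lucl",
        members={
            f"lu{j}cl{k}": _member_steps(env2003, mc, ml, trends)
            for j, ml in enumerate(lu_mults)
            for k, mc in enumerate(cl_mults)
        },
    )
    return {
        "baseline": baseline,
        "lu_only": lu_only,
        "cl_only": cl_only,
        "lucl": lucl,
    }


# ---------------------------------------------------------------------------
# hand-checkable fixture
# ---------------------------------------------------------------------------

#: fixed RNG seed of the shipped fixture — part of the fixture definition
_FIXTURE_SEED = 68451


def make_fixture() -> DataBundle:
    """Tiny deterministic landscape (68 cells) with hand-checkable geometry.

    Layout: an 8 x 8 block at 5-km spacing near the origin (top two rows
    flagged Hokkaido); a detached 3-cell west-east line at x = 1000 km
    whose middle cell has exactly one occupied neighbor at 5 km and one
    empty neighbor at 10 km (so its neighborhood occupancy is 0.5, 2/3 and
    0.8 under equal, inverse and inverse-squared weighting); and one
    isolated cell at x = 2000 km (neighborhood occupancy 0 by convention).
    """
    from .habitat import load_reference_habitat_model
    from .dynamics import DynamicsParams

    xs, ys, regions = [], [], []
    for r in range(8):
        for c in range(8):
            xs.append(c * 5.0)
            ys.append(r * 5.0)
            regions.append("hokkaido" if r >= 6 else "other")
    # detached line cluster: occupied at 1000, focal at 1005, empty at 1015
    # (focal sees them at 5 km and 10 km)
    for cx in (1000.0, 1005.0, 1015.0):
        xs.append(cx)
        ys.append(0.0)
        regions.append("other")
    xs.append(2000.0)  # isolated cell
    ys.append(0.0)
    regions.append("other")
    n = len(xs)
    grid = CellGrid(
        cell_id=np.arange(n),
        x_km=np.array(xs),
        y_km=np.array(ys),
        region=np.array(regions, dtype=object),
        area_km2=np.full(n, DEFAULT_CELL_AREA_KM2),
    )

    rng = np.random.default_rng(_FIXTURE_SEED)
    lat = np.array(ys) / 35.0
    scp78 = np.clip(20.0 + 160.0 * lat + 10.0 * rng.standard_normal(n), 0, 366)
    msd78 = np.clip(1.1 * scp78 + 8.0 * rng.standard_normal(n), 0, None)
    sl = np.clip(12.0 + 6.0 * rng.standard_normal(n), 0, 45)
    fr = np.full(n, 0.60) + 0.05 * rng.standard_normal(n)
    ws = np.full(n, 0.05)
    ag = np.full(n, 0.20) + 0.03 * rng.standard_normal(n)
    bt = np.full(n, 0.05)
    fr, ag = np.clip(fr, 0, 0.65), np.clip(ag, 0, 0.25)
    env1978 = EnvTable(
        epoch="1978", scp=scp78, msd=msd78, fr=fr, ws=ws, ag=ag, bt=bt, sl=sl
    )
    env2003 = env1978.replace(
        epoch="2003",
        scp=np.clip(scp78 - 12.0, 0, 366),
        msd=np.clip(msd78 - 10.0, 0, None),
        ws=ws + 0.05 * ag,
        ag=ag * 0.95,
    )

    model = load_reference_habitat_model()
    occ78 = simulate_initial_occupancy(model, env1978, grid, seed=_FIXTURE_SEED)
    x = occ78.x.copy()
    x[n - 4 : n] = (1, 0, 0, 0)  # line cluster (occupied, focal, empty), isolated
    occ78 = OccupancyField(year="1978", x=x)

    params = DynamicsParams(
        phi0=-0.04, phi_d=5.94, phi_h=0.50, gam0=-1.34, gam_d=8.28, gam_h=0.64
    )
    spec = NeighborhoodSpec(radius_km=10, weight_exponent=2)
    d = neighborhood_occupancy(occ78, grid, spec)
    h03 = suitability(model, env2003, grid).h
    occ03 = simulate_transition(params, occ78, d, h03, seed=_FIXTURE_SEED + 1)
    return DataBundle(
        grid=grid, env1978=env1978, env2003=env2003, occ1978=occ78, occ2003=occ03
    )
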