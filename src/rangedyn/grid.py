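"""Gridded landscape data model and neighborhood-occupancy covariates.

The analysis operates on a national survey mesh of ~5 x 5 km cells. Each
cell carries projected centroid coordinates in km, a region flag separating
Hokkaido from the three southern main islands (the Hokkaido sika deer
subspecies tolerates deeper snow, so climate effects differ by region), a
cell area, per-epoch environmental covariates, and binary presence/absence
of sika deer per survey year.

Distances are planar Euclidean on the projected km coordinates; at a 5-km
mesh scale the error versus geodesic distance is negligible and real-data
users are expected to pre-project their coordinates.

The central spatial covariate is the *neighborhood occupancy* ``D``: the
distance-weighted proportion of occupied cells within a radius of the focal
cell, a proxy for immigration pressure (probability of dispersal). The
focal cell is excluded from its own neighborhood, and ``D`` is a weighted
mean, so ``D`` is always in [0, 1] and coefficients are comparable across
neighborhood radii. A cell with no neighbor inside the radius gets
``D = 0`` (and a logged warning): no occupied neighbors, no immigration
pressure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

logger = logging.getLogger("rangedyn")

#: Default cell area: 351.8e3 km^2 of national coverage over 15,256 mesh cells.
DEFAULT_CELL_AREA_KM2 = 23.06

REGIONS = ("hokkaido", "other")

#: Environmental covariate columns, in canonical order.
ENV_COLUMNS = ("scp", "msd", "fr", "ws", "ag", "bt", "sl")

#: Land-use proportion columns (must close to <= 1 with an implicit remainder).
LANDUSE_COLUMNS = ("fr", "ws", "ag", "bt")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGrid:
    """Cell geometry: ids, projected centroids (km), region flag, area (km^2)."""

    cell_id: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    region: np.ndarray
    area_km2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "cell_id", np.asarray(self.cell_id, dtype=np.int64))
        object.__setattr__(self, "x_km", np.asarray(self.x_km, dtype=float))
        object.__setattr__(self, "y_km", np.asarray(self.y_km, dtype=float))
        object.__setattr__(self, "region", np.asarray(self.region, dtype=object))
        area = np.asarray(self.area_km2, dtype=float)
        if area.ndim == 0:
            area = np.full(self.cell_id.shape, float(area))
        object.__setattr__(self, "area_km2", area)
        n = self.cell_id.size
        if n < 1:
            raise ValueError("grid must contain at least one cell")
        if np.unique(self.cell_id).size != n:
            raise ValueError("cell ids must be unique")
        for name in ("x_km", "y_km", "area_km2"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with cell_id (length {n})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.area_km2 <= 0):
            raise ValueError("cell areas must be positive")
        bad = set(self.region) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.cell_id.size

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x_km, self.y_km])

    @property
    def is_other(self) -> np.ndarray:
        """Indicator for the non-Hokkaido region (Hokkaido is the reference)."""
        return (self.region != "hokkaido").astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "x_km": self.x_km,
                "y_km": self.y_km,
                "region": self.region,
                "area_km2": self.area_km2,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellGrid":
        return cls(
            cell_id=df["cell_id"].to_numpy(),
            x_km=df["x_km"].to_numpy(),
            y_km=df["y_km"].to_numpy(),
            region=df["region"].to_numpy(),
            area_km2=df["area_km2"].to_numpy(),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CellGrid":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class EnvTable:
    """Per-cell environmental covariates for one epoch.

    scp: snow cover period (days/yr, 0-366); msd: maximum snow depth (cm);
    fr/ws/ag/bt: proportions of forest, wasteland, agricultural and built-up
    land in [0, 1] closing to <= 1 (remainder = other uses); sl: mean slope
    inclination (degrees).
    """

    epoch: str
    scp: np.ndarray
    msd: np.ndarray
    fr: np.ndarray
    ws: np.ndarray
    ag: np.ndarray
    bt: np.ndarray
    sl: np.ndarray

    def __post_init__(self):
        n = None
        for name in ENV_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if n is None:
                n = arr.size
            if arr.shape != (n,):
                raise ValueError(f"{name} misaligned: expected length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.scp < 0) or np.any(self.scp > 366):
            raise ValueError("scp must lie in [0, 366] days")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")
        if np.any(self.sl < 0):
            raise ValueError("sl must be non-negative")
        for name in LANDUSE_COLUMNS:
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
        closure = self.fr + self.ws + self.ag + self.bt
        if np.any(closure > 1 + 1e-9):
            raise ValueError("land-use proportions exceed closure (fr+ws+ag+bt > 1)")

    @property
    def n(self) -> int:
        return self.scp.size

    def column(self, name: str) -> np.ndarray:
        if name not in ENV_COLUMNS:
            raise KeyError(f"unknown environmental covariate '{name}'")
        return getattr(self, name)

    def replace(self, **columns) -> "EnvTable":
        data = {name: getattr(self, name) for name in ENV_COLUMNS}
        epoch = columns.pop("epoch", self.epoch)
        data.update(columns)
        return EnvTable(epoch=epoch, **data)

    def to_frame(self, cell_id: np.ndarray | None = None) -> pd.DataFrame:
        if cell_id is None:
            cell_id = np.arange(self.n)
        df = pd.DataFrame({"cell_id": cell_id, "epoch": self.epoch})
        for name in ENV_COLUMNS:
            df[name] = getattr(self, name)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch: str | None = None) -> "EnvTable":
        if epoch is None:
            epochs = df["epoch"].unique()
            if len(epochs) != 1:
                raise ValueError("frame holds multiple epochs; pass epoch=")
            epoch = str(epochs[0])
        else:
            df = df[df["epoch"].astype(str) == str(epoch)]
        df = df.sort_values("cell_id")
        return cls(epoch=str(epoch), **{c: df[c].to_numpy() for c in ENV_COLUMNS})

    def write_csv(self, path, cell_id: np.ndarray | None = None) -> None:
        self.to_frame(cell_id).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, epoch: str | None = None) -> "EnvTable":
        return cls.from_frame(pd.read_csv(path), epoch=epoch)


@dataclass(frozen=True)
class OccupancyField:
    """Binary presence/absence of the species per cell for one survey year."""

    year: str
    x: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.x)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("occupancy values must be 0 or 1")
        object.__setattr__(self, "x", arr.astype(np.int8))
        object.__setattr__(self, "year", str(self.year))

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def prevalence(self) -> float:
        return float(self.x.mean())

    def to_frame(self, cell_id: np.ndarray | None = None) -> pd.DataFrame:
        if cell_id is None:
            cell_id = np.arange(self.n)
        return pd.DataFrame({"cell_id": cell_id, "year": self.year, "present": self.x})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, year: str | None = None) -> "OccupancyField":
        if year is None:
            years = df["year"].unique()
            if len(years) != 1:
                raise ValueError("frame holds multiple years; pass year=")
            year = str(years[0])
        else:
            df = df[df["year"].astype(str) == str(year)]
        df = df.sort_values("cell_id")
        return cls(year=str(year), x=df["present"].to_numpy())

    def write_csv(self, path, cell_id: np.ndarray | None = None) -> None:
        self.to_frame(cell_id).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, year: str | None = None) -> "OccupancyField":
        return cls.from_frame(pd.read_csv(path), year=year)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighborhood radius (km) and distance-weighting exponent.

    weight_exponent 0 = equal weights, 1 = inverse distance, 2 = inverse
    squared distance. The candidate radii used in model selection are
    {10, 25, 50, 75, 100} km (autocovariates are restricted to {10, 25}).
    """

    radius_km: float
    weight_exponent: int

    def __post_init__(self):
        if not self.radius_km > 0:
            raise ValueError("radius_km must be positive")
        if self.weight_exponent not in (0, 1, 2):
            raise ValueError("weight_exponent must be 0, 1 or 2")
        object.__setattr__(self, "radius_km", float(self.radius_km))
        object.__setattr__(self, "weight_exponent", int(self.weight_exponent))

    @property
    def weight_label(self) -> str:
        return {0: "equal", 1: "inverse", 2: "inverse-squared"}[self.weight_exponent]


WEIGHT_LABELS = {0: "equal", 1: "inverse", 2: "inverse-squared"}


# ---------------------------------------------------------------------------
# neighbor index and neighborhood occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborIndex:
    """CSR-style neighbor lists: for cell i, neighbors are
    ``indices[indptr[i]:indptr[i+1]]`` at distances ``distances[...]`` km.
    Focal cells are excluded; the relation is symmetric by construction."""

    radius_km: float
    n: int
    indptr: np.ndarray
    indices: np.ndarray
    distances: np.ndarray

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.indices[sl], self.distances[sl]

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.indptr)


def build_neighbor_index(grid: CellGrid, radius_km: float) -> NeighborIndex:
    """All pairs of cells with centroid distance in (0, radius_km]."""
    if not radius_km > 0:
        raise ValueError("radius_km must be positive")
    coords = grid.coords
    tree = cKDTree(coords)
    # query_ball_point radius is inclusive; pad for float round-off then
    # filter exactly below.
    pairs = tree.query_pairs(r=radius_km * (1 + 1e-12), output_type="ndarray")
    if pairs.size:
        d = np.sqrt(((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2).sum(axis=1))
        keep = (d > 0) & (d <= radius_km)
        pairs, d = pairs[keep], d[keep]
    else:
        d = np.empty(0)
    # symmetrize
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if pairs.size else np.empty(0, int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if pairs.size else np.empty(0, int)
    dist = np.concatenate([d, d])
    order = np.argsort(rows, kind="stable")
    rows, cols, dist = rows[order], cols[order], dist[order]
    indptr = np.zeros(grid.n + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    indptr = np.cumsum(indptr)
    return NeighborIndex(
        radius_km=float(radius_km),
        n=grid.n,
        indptr=indptr,
        indices=cols.astype(np.int64),
        distances=dist,
    )


def neighborhood_weights(
    grid: CellGrid,
    spec: NeighborhoodSpec,
    index: NeighborIndex | None = None,
) -> sparse.csr_matrix:
    """Row-normalized sparse weight operator W with D = W @ x.

    Rows of cells with an empty neighborhood are all-zero, giving D = 0.
    """
    if index is None:
        index = build_neighbor_index(grid, spec.radius_km)
    elif index.radius_km != spec.radius_km:
        raise ValueError("neighbor index radius does not match spec radius")
    if spec.weight_exponent == 0:
        w = np.ones_like(index.distances)
    else:
        w = index.distances ** (-float(spec.weight_exponent))
    W = sparse.csr_matrix(
        (w, index.indices, index.indptr), shape=(grid.n, grid.n)
    )
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    empty = row_sums == 0
    if empty.any():
        logger.warning(
            "%d cell(s) have no neighbor within %.1f km; their D is set to 0",
            int(empty.sum()), spec.radius_km,
        )
    inv = np.where(empty, 0.0, 1.0 / np.where(empty, 1.0, row_sums))
    return sparse.diags(inv) @ W


def neighborhood_occupancy(
    occ: OccupancyField,
    grid: CellGrid,
    spec: NeighborhoodSpec,
    index: NeighborIndex | None = None,
    weights: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Distance-weighted proportion of occupied neighbors, D in [0, 1]."""
    if occ.n != grid.n:
        raise ValueError(
            f"occupancy length {occ.n} does not match grid size {grid.n}"
        )
    if weights is None:
        weights = neighborhood_weights(grid, spec, index=index)
    d = weights @ occ.x.astype(float)
    # guard against tiny float excursions outside [0, 1]
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# temporal interpolation
# ---------------------------------------------------------------------------

def interpolate_timeseries(
    observations: Sequence[tuple[float, float]], target_year: float
) -> float:
    """Inverse-distance-in-time weighted interpolation of a covariate.

    Land-use proportions are published for a handful of census years; the
    survey epochs fall between them. The interpolated value uses ALL
    observation years with weights 1/|target - year|; an exact match on an
    observed year returns that value exactly.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("need at least one observation")
    years = np.asarray([float(y) for y, _ in obs])
    values = np.asarray([float(v) for _, v in obs])
    if not np.all(np.isfinite(values)):
        raise ValueError("observation values must be finite")
    dt = np.abs(years - float(target_year))
    hit = dt == 0
    if hit.any():
        return float(values[hit][0])
    w = 1.0 / dt
    return float(np.sum(w * values) / np.sum(w))
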