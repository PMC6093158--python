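"""Habitat-suitability logistic models and suitability-change decomposition.

Habitat suitability H is the log-odds linear predictor of a logistic
regression of first-survey presence/absence on environmental covariates:

    logit(q_i) = alpha + beta_1 x_1i + ... + beta_J x_Ji
    H_i        = alpha + beta_1 x_1i + ... + beta_J x_Ji   (per epoch)

Candidate formulas cross three blocks — land use (FR, WS, AG, AG^2, BT),
climate (snow cover period SCP or maximum snow depth MSD, never both, each
with a region main effect and a climate x region interaction; Hokkaido is
the reference region), topography (mean slope SL) — giving 2 x 2 x 3 = 12
formulas, and optionally an autologistic neighborhood-occupancy covariate
(radius 10 or 25 km x three weightings), giving 12 x 7 = 84.

The agricultural proportion enters with a second-order term (AG^2): deer
respond unimodally to agriculture, preferring forest-farmland ecotones over
both closed forest and pure farmland. Covariates are unstandardized (days,
proportions, degrees), so coefficients read directly in natural units.

Because the linear predictor has no climate x land-use product terms, the
change in suitability between two epochs splits exactly into a climate
block and a land-use block (time-invariant region, slope and autocovariate
terms cancel):

    dH_total = dH_climate + dH_landuse.

Cells are cross-classified by the sign of dH_total and by which block
dominates in absolute value; independence of the two classifications is
tested with a continuity-corrected (Yates) chi-square.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from .grid import CellGrid, EnvTable, NeighborhoodSpec, OccupancyField, neighborhood_occupancy

logger = logging.getLogger("rangedyn")

CLIMATE_CHOICES = ("none", "scp", "msd")
LANDUSE_TERMS = ("fr", "ws", "ag", "ag2", "bt")
AUTOCOV_RADII_KM = (10.0, 25.0)


@dataclass(frozen=True)
class HabitatFormula:
    """One candidate habitat model: which covariate blocks enter."""

    include_lu: bool
    climate: str
    include_topo: bool
    autocov: NeighborhoodSpec | None = None

    def __post_init__(self):
        if self.climate not in CLIMATE_CHOICES:
            raise ValueError(f"climate must be one of {CLIMATE_CHOICES}")
        if self.autocov is not None and self.autocov.radius_km not in AUTOCOV_RADII_KM:
            raise ValueError("autocovariate radius must be 10 or 25 km")

    @property
    def terms(self) -> tuple[str, ...]:
        out = ["intercept"]
        if self.climate != "none":
            out += [self.climate, "rgn_other", f"{self.climate}_x_rgn"]
        if self.include_lu:
            out += list(LANDUSE_TERMS)
        if self.include_topo:
            out += ["sl"]
        if self.autocov is not None:
            out += ["autocov"]
        return tuple(out)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def label(self) -> str:
        parts = []
        if self.include_lu:
            parts.append("LU")
        if self.climate != "none":
            parts.append(f"CL[{self.climate.upper()}]")
        if self.include_topo:
            parts.append("TOPO")
        if self.autocov is not None:
            parts.append(
                f"AC[{self.autocov.radius_km:g}km,{self.autocov.weight_label}]"
            )
        return "~" + (" + ".join(parts) if parts else "1")


def enumerate_habitat_formulas(with_autocov: bool = False) -> list[HabitatFormula]:
    """The 12 base formulas, or all 84 when crossed with autocovariates."""
    base = [
        HabitatFormula(include_lu=lu, climate=cl, include_topo=topo)
        for lu in (True, False)
        for cl in CLIMATE_CHOICES
        for topo in (True, False)
    ]
    if not with_autocov:
        return base
    autocovs: list[NeighborhoodSpec | None] = [None] + [
        NeighborhoodSpec(radius_km=r, weight_exponent=p)
        for r in AUTOCOV_RADII_KM
        for p in (0, 1, 2)
    ]
    return [
        HabitatFormula(f.include_lu, f.climate, f.include_topo, autocov=ac)
        for f in base
        for ac in autocovs
    ]


# ---------------------------------------------------------------------------
# design matrix / fitting / prediction
# ---------------------------------------------------------------------------

def design_matrix(
    formula: HabitatFormula,
    env: EnvTable,
    grid: CellGrid,
    autocov_d: np.ndarray | None = None,
) -> np.ndarray:
    """Columns in ``formula.terms`` order; intercept first."""
    if env.n != grid.n:
        raise ValueError("environmental table does not align with grid")
    cols = []
    for term in formula.terms:
        if term == "intercept":
            cols.append(np.ones(grid.n))
        elif term in ("scp", "msd"):
            cols.append(env.column(term))
        elif term == "rgn_other":
            cols.append(grid.is_other)
        elif term.endswith("_x_rgn"):
            cols.append(env.column(term[:3]) * grid.is_other)
        elif term == "ag2":
            cols.append(env.ag**2)
        elif term in ("fr", "ws", "ag", "bt", "sl"):
            cols.append(env.column(term))
        elif term == "autocov":
            if autocov_d is None:
                raise ValueError(
                    "formula includes an autocovariate but no 'autocov' vector "
                    "was supplied"
                )
            cols.append(np.asarray(autocov_d, dtype=float))
        else:  # pragma: no cover
            raise KeyError(term)
    return np.column_stack(cols)


@dataclass(frozen=True)
class HabitatModel:
    """Fitted habitat logistic model: formula, MLE coefficients, metadata."""

    formula: HabitatFormula
    coefficients: dict[str, float]
    stderr: dict[str, float]
    loglik: float
    n: int

    def __post_init__(self):
        if tuple(self.coefficients) != self.formula.terms:
            raise ValueError("coefficient names must match formula terms exactly")
        vals = np.array(list(self.coefficients.values()))
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    def to_json(self, path) -> None:
        payload = {
            "formula": {
                "include_lu": self.formula.include_lu,
                "climate": self.formula.climate,
                "include_topo": self.formula.include_topo,
                "autocov": None
                if self.formula.autocov is None
                else {
                    "radius_km": self.formula.autocov.radius_km,
                    "weight_exponent": self.formula.autocov.weight_exponent,
                },
            },
            "coefficients": self.coefficients,
            "stderr": self.stderr,
            "loglik": self.loglik,
            "n": self.n,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HabitatModel":
        with open(path) as fh:
            payload = json.load(fh)
        f = payload["formula"]
        ac = f.get("autocov")
        formula = HabitatFormula(
            include_lu=f["include_lu"],
            climate=f["climate"],
            include_topo=f["include_topo"],
            autocov=None if ac is None else NeighborhoodSpec(**ac),
        )
        return cls(
            formula=formula,
            coefficients=dict(payload["coefficients"]),
            stderr=dict(payload.get("stderr", {})),
            loglik=float(payload.get("loglik", np.nan)),
            n=int(payload.get("n", 0)),
        )


@dataclass(frozen=True)
class SuitabilitySurface:
    """Per-cell habitat suitability H (log-odds scale) for one epoch."""

    epoch: str
    h: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.h, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("suitability values must be finite")
        object.__setattr__(self, "h", arr)
        object.__setattr__(self, "epoch", str(self.epoch))

    @property
    def n(self) -> int:
        return self.h.size


def fit_habitat(
    occ: OccupancyField,
    env: EnvTable,
    grid: CellGrid,
    formula: HabitatFormula,
) -> HabitatModel:
    """Maximum-likelihood logistic fit of first-survey occupancy.

    The autocovariate, when present, is the neighborhood occupancy of the
    SAME survey's presences (autologistic regression).
    """
    if occ.n != grid.n:
        raise ValueError("occupancy does not align with grid")
    y = occ.x.astype(float)
    if y.min() == y.max():
        raise ValueError("response is all-0 or all-1; logistic MLE undefined")
    autocov_d = None
    if formula.autocov is not None:
        autocov_d = neighborhood_occupancy(occ, grid, formula.autocov)
    X = design_matrix(formula, env, grid, autocov_d=autocov_d)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise RuntimeError(
            f"logistic fit failed for {formula.label()}: {exc}"
        ) from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(
            f"logistic fit diverged for {formula.label()} (possible separation)"
        )
    names = formula.terms
    return HabitatModel(
        formula=formula,
        coefficients={k: float(v) for k, v in zip(names, res.params)},
        stderr={k: float(v) for k, v in zip(names, res.bse)},
        loglik=float(res.llf),
        n=int(y.size),
    )


def suitability(
    model: HabitatModel,
    env: EnvTable,
    grid: CellGrid,
    autocov_d: np.ndarray | None = None,
) -> SuitabilitySurface:
    """Log-odds linear predictor H for one epoch (NOT logistic-transformed)."""
    X = design_matrix(model.formula, env, grid, autocov_d=autocov_d)
    return SuitabilitySurface(epoch=env.epoch, h=X @ model.beta)


# ---------------------------------------------------------------------------
# suitability-change decomposition
# ---------------------------------------------------------------------------

CLIMATE_BLOCK = ("scp", "msd", "scp_x_rgn", "msd_x_rgn")
LANDUSE_BLOCK = LANDUSE_TERMS


@dataclass(frozen=True)
class ChangeDecomposition:
    """Per-cell suitability change split into climate and land-use blocks."""

    dh_total: np.ndarray
    dh_climate: np.ndarray
    dh_landuse: np.ndarray
    #: 2x2 counts, rows (|LU|>|CL|, |LU|<|CL|) x cols (increased, decreased)
    table: np.ndarray
    chi2: float
    pvalue: float

    @property
    def n_increased(self) -> int:
        return int(self.table[:, 0].sum())

    @property
    def n_decreased(self) -> int:
        return int(self.table[:, 1].sum())

    @property
    def pct_increased(self) -> float:
        n = self.table.sum()
        return 100.0 * self.n_increased / n

    @property
    def pct_decreased(self) -> float:
        n = self.table.sum()
        return 100.0 * self.n_decreased / n


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table."""
    stat, p, _, _ = chi2_contingency(np.asarray(table), correction=True)
    return float(stat), float(p)


def decompose_change(
    model: HabitatModel,
    env1978: EnvTable,
    env2003: EnvTable,
    grid: CellGrid,
    autocov_d: np.ndarray | None = None,
) -> ChangeDecomposition:
    """Split dH between two epochs into climate and land-use fractions.

    The autocovariate (when the formula has one) is computed from the
    first-survey occupancy and is the SAME in both surfaces, so it cancels
    from the difference, as do the region main effect, slope and intercept.
    """
    if env1978.n != env2003.n or env1978.n != grid.n:
        raise ValueError("epoch tables misaligned with grid")
    X78 = design_matrix(model.formula, env1978, grid, autocov_d=autocov_d)
    X03 = design_matrix(model.formula, env2003, grid, autocov_d=autocov_d)
    beta = model.beta
    terms = model.formula.terms
    dX = X03 - X78
    dh_total = dX @ beta
    cl_idx = [i for i, t in enumerate(terms) if t in CLIMATE_BLOCK]
    lu_idx = [i for i, t in enumerate(terms) if t in LANDUSE_BLOCK]
    dh_climate = dX[:, cl_idx] @ beta[cl_idx] if cl_idx else np.zeros(grid.n)
    dh_landuse = dX[:, lu_idx] @ beta[lu_idx] if lu_idx else np.zeros(grid.n)

    increased = dh_total > 0
    abs_lu, abs_cl = np.abs(dh_landuse), np.abs(dh_climate)
    lu_dominant = abs_lu >= abs_cl  # ties (measure zero) go to the LU row
    n_ties = int((abs_lu == abs_cl).sum())
    if n_ties:
        logger.info("%d cell(s) with |dH_LU| == |dH_CL| assigned to LU>CL", n_ties)
    table = np.array(
        [
            [int((lu_dominant & increased).sum()), int((lu_dominant & ~increased).sum())],
            [int((~lu_dominant & increased).sum()), int((~lu_dominant & ~increased).sum())],
        ]
    )
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p = yates_chi2(table)
    else:  # degenerate margin (e.g. identical epochs)
        chi2, p = float("nan"), float("nan")
    return ChangeDecomposition(
        dh_total=dh_total,
        dh_climate=dh_climate,
        dh_landuse=dh_landuse,
        table=table,
        chi2=chi2,
        pvalue=p,
    )


# ---------------------------------------------------------------------------
# shipped reference coefficients
# ---------------------------------------------------------------------------

def load_reference_habitat_model() -> HabitatModel:
    """The published best habitat model for sika deer in Japan.

    Logistic coefficients estimated from the 1978 national survey
    (LU + CL[SCP] + TOPO, no autocovariate, Hokkaido as reference region).
    Shipped as a fixture so synthetic landscapes can be seeded with a
    realistic suitability structure.
    """
    ref = resources.files("rangedyn.data").joinpath("sika_habitat_coefficients.json")
    with resources.as_file(ref) as path:
        return HabitatModel.from_json(path)
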