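"""Pipeline orchestration: configuration, stage execution, validation.

``run_pipeline`` executes the full analysis in the order the method runs:
(optionally) simulate data -> fit habitat models -> evaluate/select
candidates by WAIC -> fit the transition model for the selected candidate
-> decompose the 1978->2003 suitability change -> project the four
scenario groups -> summarize. Every stage writes its artifacts into the
output directory and the final manifest lists each artifact with a sha256
checksum, the seed, and package versions, so a rerun with the same config
is verifiably identical.

A single top-level seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import DynamicsParams, sensitivity_threshold, transition_probability
from .grid import CellGrid, ENV_COLUMNS, EnvTable, LANDUSE_COLUMNS, NeighborhoodSpec, OccupancyField
from .habitat import HabitatFormula, decompose_change, enumerate_habitat_formulas
from .projection import ProjectionConfig, aggregate_group, project_bundle
from .selection import CandidateSpec, DataBundle, evaluate_candidates, select_best
from .synthetic import LandscapeConfig, TrendConfig, generate_bundle, generate_scenarios

logger = logging.getLogger("rangedyn")

_STAGES = (
    "simulate",
    "fit_habitat",
    "select",
    "fit_dynamics",
    "decompose",
    "project",
    "summarize",
)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    output_dir: str = "rangedyn_out"
    seed: int = 0
    # data source: either synthetic generation or CSV paths
    simulate: bool = True
    landscape: dict = field(default_factory=dict)  # LandscapeConfig overrides
    cells_csv: str | None = None
    env_csv: str | None = None  # long format, epochs '1978' and '2003'
    occupancy_csv: str | None = None  # long format, years '1978' and '2003'
    # candidate budget
    candidate_radii_km: list = field(default_factory=lambda: [10.0, 25.0])
    candidate_weights: list = field(default_factory=lambda: [2])
    candidate_epochs: list = field(default_factory=lambda: [1978, 2003])
    with_autocov: bool = False
    max_candidates: int = 24
    # MCMC settings
    chains: int = 3
    iterations: int = 1000
    burnin: int = 100
    # projection settings
    replicates: int = 200
    threshold: float | None = None  # None -> sensitivity-95% threshold
    trends: dict = field(default_factory=dict)  # TrendConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31)
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_bundle(config: PipelineConfig) -> DataBundle:
    """Load the input tables referenced by the config (non-synthetic runs)."""
    for name in ("cells_csv", "env_csv", "occupancy_csv"):
        path = getattr(config, name)
        if path is None:
            raise StageError("simulate", f"config.{name} is not set")
        if not Path(path).exists():
            raise StageError("simulate", f"missing input file: {path}")
    grid = CellGrid.read_csv(config.cells_csv)
    env_df = pd.read_csv(config.env_csv)
    occ_df = pd.read_csv(config.occupancy_csv)
    return DataBundle(
        grid=grid,
        env1978=EnvTable.from_frame(env_df, epoch="1978"),
        env2003=EnvTable.from_frame(env_df, epoch="2003"),
        occ1978=OccupancyField.from_frame(occ_df, year="1978"),
        occ2003=OccupancyField.from_frame(occ_df, year="2003"),
    )


def simulate_stage(config: PipelineConfig) -> DataBundle:
    from .habitat import load_reference_habitat_model

    model = load_reference_habitat_model()
    ref = DynamicsParams(
        phi0=-0.04, phi_d=5.94, phi_h=0.50, gam0=-1.34, gam_d=8.28, gam_h=0.64
    )
    land_cfg = LandscapeConfig(
        **{**config.landscape, "seed": config.stage_seed("simulate")}
    )
    dispersal = NeighborhoodSpec(radius_km=25, weight_exponent=2)
    return generate_bundle(
        land_cfg, model, ref, dispersal, seed=config.stage_seed("simulate")
    )


def candidate_subset(config: PipelineConfig) -> list[CandidateSpec]:
    formulas = enumerate_habitat_formulas(with_autocov=config.with_autocov)
    # prefer richer formulas first so the default budget includes the
    # full LU + CL + TOPO model used by the reference analysis
    formulas = sorted(formulas, key=lambda f: -f.n_terms)
    cands = [
        CandidateSpec(
            formula=f,
            surface_epoch=int(e),
            dispersal=NeighborhoodSpec(radius_km=float(r), weight_exponent=int(p)),
        )
        for f in formulas
        for e in config.candidate_epochs
        for r in config.candidate_radii_km
        for p in config.candidate_weights
    ]
    return cands[: config.max_candidates]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the output manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path):
        artifacts.append(path)
        return path

    # --- data ---
    try:
        if config.simulate:
            bundle = simulate_stage(config)
        else:
            bundle = load_bundle(config)
        bundle.grid.write_csv(emit(out / "cells.csv"))
        env_frames = [
            bundle.env1978.to_frame(bundle.grid.cell_id),
            bundle.env2003.to_frame(bundle.grid.cell_id),
        ]
        pd.concat(env_frames).to_csv(emit(out / "env.csv"), index=False)
        occ_frames = [
            bundle.occ1978.to_frame(bundle.grid.cell_id),
            bundle.occ2003.to_frame(bundle.grid.cell_id),
        ]
        pd.concat(occ_frames).to_csv(emit(out / "occupancy.csv"), index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # --- candidate evaluation & selection (habitat fits are cached inside) ---
    try:
        cands = candidate_subset(config)
        table = evaluate_candidates(
            bundle,
            cands,
            chains=config.chains,
            iterations=config.iterations,
            burnin=config.burnin,
            seed=config.stage_seed("select"),
        )
        table.write_csv(emit(out / "ranking.csv"))
        best = select_best(table)
        best.habitat_model.to_json(emit(out / "habitat_model.json"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select", exc) from exc

    # --- dynamics artifacts for the selected candidate ---
    try:
        fit = best.fit
        fit.write_posterior_csv(emit(out / "posterior.csv"))
        with open(emit(out / "dynamics_summary.json"), "w") as fh:
            json.dump(fit.summary_dict(), fh, indent=2)
    except Exception as exc:
        raise StageError("fit_dynamics", exc) from exc

    # --- suitability-change decomposition ---
    try:
        dec = decompose_change(
            best.habitat_model, bundle.env1978, bundle.env2003, bundle.grid
        )
        pd.DataFrame(
            {
                "cell_id": bundle.grid.cell_id,
                "dh_total": dec.dh_total,
                "dh_climate": dec.dh_climate,
                "dh_landuse": dec.dh_landuse,
            }
        ).to_csv(emit(out / "decomposition.csv"), index=False)
        with open(emit(out / "decomposition_test.json"), "w") as fh:
            json.dump(
                {
                    "table": dec.table.tolist(),
                    "chi2": dec.chi2,
                    "pvalue": dec.pvalue,
                    "n_increased": dec.n_increased,
                    "n_decreased": dec.n_decreased,
                    "pct_increased": dec.pct_increased,
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise StageError("decompose", exc) from exc

    # --- projection under the four scenario groups ---
    try:
        params = fit.medians
        q = transition_probability(
            params,
            bundle.occ1978.x,
            # D and H of the selected candidate
            _selected_d(bundle, best),
            _selected_h(bundle, best),
        )
        threshold = config.threshold
        if threshold is None:
            threshold = sensitivity_threshold(
                np.asarray(q)[bundle.occ2003.x == 1], 0.95
            )
            threshold = float(min(max(threshold, 1e-6), 1 - 1e-6))
        trends = TrendConfig(**config.trends)
        bundles = generate_scenarios(bundle.env2003, trends)
        proj_cfg = ProjectionConfig(
            replicates=config.replicates,
            threshold=threshold,
            seed=config.stage_seed("project"),
            dispersal=best.spec.dispersal,
        )
        area_rows = []
        group_summaries = {}
        for gname, sb in bundles.items():
            results = project_bundle(
                best.habitat_model, params, bundle.occ2003, bundle.grid, sb, proj_cfg
            )
            summary = aggregate_group(gname, results)
            group_summaries[gname] = summary
            df = summary.member_areas.copy()
            df.insert(0, "group", gname)
            area_rows.append(df)
        pd.concat(area_rows).to_csv(emit(out / "areas.csv"), index=False)
        freq_rows = []
        for gname, summary in group_summaries.items():
            for y, f in summary.mean_frequencies.items():
                freq_rows.append(
                    pd.DataFrame(
                        {
                            "group": gname,
                            "year": y,
                            "cell_id": bundle.grid.cell_id,
                            "frequency": f,
                        }
                    )
                )
        pd.concat(freq_rows).to_csv(emit(out / "frequencies.csv"), index=False)

        base_end = group_summaries["baseline"].mean_area_km2[2103]
        pct = {
            g: None
            if base_end <= 0
            else round(100.0 * (s.mean_area_km2[2103] - base_end) / base_end, 1)
            for g, s in group_summaries.items()
        }
        with open(emit(out / "scenario_summary.json"), "w") as fh:
            json.dump(
                {
                    "threshold": threshold,
                    "mean_area_km2": {
                        g: {str(y): a for y, a in s.mean_area_km2.items()}
                        for g, s in group_summaries.items()
                    },
                    "area_band_km2": {
                        g: {str(y): list(b) for y, b in s.area_band_km2.items()}
                        for g, s in group_summaries.items()
                    },
                    "pct_change_2103_vs_baseline": pct,
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise StageError("project", exc) from exc

    # --- manifest ---
    try:
        manifest = {
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "artifacts": {
                str(p.relative_to(out)): _sha256(p) for p in artifacts
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise StageError("summarize", exc) from exc
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest


def _selected_d(bundle: DataBundle, best) -> np.ndarray:
    from .grid import neighborhood_occupancy

    return neighborhood_occupancy(bundle.occ1978, bundle.grid, best.spec.dispersal)


def _selected_h(bundle: DataBundle, best) -> np.ndarray:
    from .habitat import suitability

    return suitability(
        best.habitat_model, bundle.env(best.spec.surface_epoch), bundle.grid
    ).h


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Check the type invariants of input CSVs; empty list = all hold.

    ``paths`` maps table kind ('cells', 'env', 'occupancy') to a CSV path.
    Violations name the offending cell and rule.
    """
    report: list[str] = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"{kind}: unreadable file {path}")
    if "cells" in paths:
        df = pd.read_csv(paths["cells"])
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            report.append(f"cells: duplicate cell_id {dup}")
        for col in ("x_km", "y_km", "area_km2"):
            bad = df.index[~np.isfinite(df[col])]
            for i in bad:
                report.append(f"cells: cell {df.loc[i, 'cell_id']}: non-finite {col}")
        for i in df.index[df["area_km2"] <= 0]:
            report.append(f"cells: cell {df.loc[i, 'cell_id']}: area_km2 <= 0")
        bad_region = ~df["region"].isin(["hokkaido", "other"])
        for i in df.index[bad_region]:
            report.append(
                f"cells: cell {df.loc[i, 'cell_id']}: unknown region "
                f"'{df.loc[i, 'region']}'"
            )
    if "env" in paths:
        df = pd.read_csv(paths["env"])
        closure = df[list(LANDUSE_COLUMNS)].sum(axis=1)
        for i in df.index[closure > 1 + 1e-9]:
            report.append(
                f"env: cell {df.loc[i, 'cell_id']} epoch {df.loc[i, 'epoch']}: "
                f"land-use proportions sum to {closure[i]:.3f} > 1"
            )
        for col in ENV_COLUMNS:
            vals = df[col]
            bad = ~np.isfinite(vals)
            if col in LANDUSE_COLUMNS:
                bad |= (vals < 0) | (vals > 1)
            elif col == "scp":
                bad |= (vals < 0) | (vals > 366)
            else:
                bad |= vals < 0
            for i in df.index[bad]:
                report.append(
                    f"env: cell {df.loc[i, 'cell_id']} epoch {df.loc[i, 'epoch']}: "
                    f"invalid {col} = {vals[i]}"
                )
    if "occupancy" in paths:
        df = pd.read_csv(paths["occupancy"])
        bad = ~df["present"].isin([0, 1])
        for i in df.index[bad]:
            report.append(
                f"occupancy: cell {df.loc[i, 'cell_id']} year {df.loc[i, 'year']}: "
                f"present = {df.loc[i, 'present']} not in {{0,1}}"
            )
    return report
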