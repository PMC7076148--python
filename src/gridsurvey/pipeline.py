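"""End-to-end pipeline: frame -> stratify -> size -> sample -> report.

A run is fully described by a :class:`RunConfig` (inputs, grid, covariates,
stratification and simulation parameters, master seed, output directory).
``run_pipeline`` executes the stages in order, writes every artifact in
plain formats (CSV tables, GeoJSON geometries, JSON diagnostics) and a run
manifest that echoes the config, the seed and the row counts — the manifest
alone suffices to reproduce the run.  Identical config + seed produces
byte-identical CSV artifacts.

Randomness discipline: the master seed is split into named substreams, one
per stage (stratification, KS simulation, final draw), so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import compute_probabilities, draw_sample
from .grid import SettledCellFrame, build_frame
from .io import frame_to_csv, frame_to_geojson, points_to_geojson, read_geotiff
from .sizing import allocate_sizes, simulate_ks_curve
from .stratify import (
    CovariateRaster,
    assign_strata,
    extract_covariates,
    fit_pca,
    kmeans_scan,
    suggest_k,
)
from .synthetic import make_fixture

logger = logging.getLogger("gridsurvey")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "default_n_grid"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic named substream: stable across platforms and runs."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def default_n_grid(n_max: int = 500) -> list[int]:
    """Dense at small n where the curve moves fast, sparser further out."""
    grid = list(range(1, min(21, n_max + 1)))
    grid += list(range(25, min(101, n_max + 1), 5))
    grid += list(range(110, min(201, n_max + 1), 10))
    grid += list(range(225, n_max + 1, 25))
    return sorted(set(g for g in grid if g <= n_max))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``fixture`` names a bundled synthetic landscape, or
    ``mask_path``/``population_path``/``covariates`` point at GeoTIFF inputs
    on a shared grid (``covariates``: list of {path, name, kind}).
    """

    out_dir: str
    fixture: str | None = None
    mask_path: str | None = None
    population_path: str | None = None
    covariates: list[dict] = field(default_factory=list)
    pca_threshold: float = 0.9
    k: int = 3
    k_scan: list[int] = field(default_factory=lambda: list(range(1, 11)))
    n_starts: int = 25
    n_grid: list[int] | None = None
    reps: int = 100
    ks_threshold: float = 0.15
    draw_method: str = "systematic"
    seed: int = 0

    def validate(self) -> None:
        if self.fixture is None and (self.mask_path is None or self.population_path is None):
            raise ValueError("config needs either a fixture name or mask + population paths")
        if self.fixture is not None and self.mask_path is not None:
            raise ValueError("give a fixture or raster paths, not both")
        if not 0 < self.pca_threshold <= 1:
            raise ValueError("pca_threshold must lie in (0, 1]")
        if not 0 < self.ks_threshold < 1:
            raise ValueError("ks_threshold must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.draw_method not in ("systematic", "multinomial"):
            raise ValueError("draw_method must be 'systematic' or 'multinomial'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _load_inputs(config: RunConfig) -> tuple[SettledCellFrame, list[CovariateRaster]]:
    if config.fixture is not None:
        land = make_fixture(config.fixture, seed=stage_seed(config.seed, "landscape"))
        return land.frame(), land.covariates
    mask, grid = read_geotiff(config.mask_path)
    population, pgrid = read_geotiff(config.population_path)
    if pgrid != grid:
        raise ValueError("mask and population rasters are on different grids")
    frame = build_frame(mask.astype(bool), population, grid)
    rasters = []
    for spec in config.covariates:
        arr, cgrid = read_geotiff(spec["path"])
        if cgrid != grid:
            raise ValueError(f"covariate {spec['name']!r} is on a different grid")
        rasters.append(
            CovariateRaster(name=spec["name"], array=arr, kind=spec.get("kind", "continuous"))
        )
    return frame, rasters


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "complete": False,
    }
    stage = "frame"
    try:
        frame, rasters = _load_inputs(config)
        frame.require_nonempty("pipeline")
        frame_to_csv(frame, out / "frame.csv")
        frame_to_geojson(frame, out / "frame.geojson")
        logger.info("frame: %d settled cells", frame.m)
        manifest["stages"]["frame"] = {"settled_cells": frame.m}

        stage = "stratify"
        stack = extract_covariates(frame, rasters)
        pca = fit_pca(stack, config.pca_threshold)
        scan = kmeans_scan(
            pca.scores,
            k_range=[k for k in config.k_scan if k <= frame.m],
            seed=stage_seed(config.seed, "kmeans-scan"),
            n_starts=config.n_starts,
        )
        strat = assign_strata(
            pca.scores,
            k=config.k,
            seed=stage_seed(config.seed, "strata"),
            n_starts=config.n_starts,
            populations=frame.populations,
        )
        pd.DataFrame({"cell_id": frame.cell_ids, "stratum": strat.labels}).to_csv(
            out / "stratification.csv", index=False
        )
        _write_json(
            out / "stratification_diagnostics.json",
            {
                "pca": {
                    "q": pca.q,
                    "cumulative_variance": pca.cumulative_variance,
                    "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                    "dropped_columns": pca.dropped_columns,
                },
                "scan": {
                    "k": scan.k_values.tolist(),
                    "wss": scan.wss.tolist(),
                    "explained_share": scan.explained_share.tolist(),
                },
                "elbow_candidates": suggest_k(scan) if len(scan.k_values) >= 3 else [],
                "k": strat.k,
                "stratum_counts": strat.counts().tolist(),
            },
        )
        logger.info("stratify: k=%d, counts=%s", strat.k, strat.counts().tolist())
        manifest["stages"]["stratify"] = {
            "k": strat.k,
            "pca_components": pca.q,
            "stratum_counts": strat.counts().tolist(),
        }

        stage = "size"
        n_grid = config.n_grid or default_n_grid()
        max_m = int(min(np.bincount(strat.labels, minlength=strat.k)))
        curves = simulate_ks_curve(
            frame,
            strat,
            n_grid=n_grid,
            reps=config.reps,
            seed=stage_seed(config.seed, "ks-sim"),
        )
        pd.concat([c.to_table() for c in curves.values()], ignore_index=True).to_csv(
            out / "ks_curves.csv", index=False
        )
        selection = allocate_sizes(curves, config.ks_threshold)
        _write_json(out / "size_selection.json", selection.to_dict())
        if not selection.all_achieved:
            bad = [s for s, e in selection.entries.items() if not e.achieved]
            raise RuntimeError(
                f"KS threshold {config.ks_threshold} not achievable in strata {bad}; "
                "extend n_grid or relax the threshold"
            )
        n_by_stratum = {s: e.n for s, e in selection.entries.items()}
        logger.info("size: selected %s (threshold %.3g)", n_by_stratum, config.ks_threshold)

        stage = "sample"
        # The simulation may demand more cells than a small stratum holds
        # (it draws with replacement); the field design cannot, so such a
        # stratum is taken as a census: every positive-population cell,
        # pi_S = n_S / m_S <= 1.
        counts_by_stratum = {
            s: int((strat.labels == s).sum()) for s in range(strat.k)
        }
        pos_by_stratum = {
            s: int(((strat.labels == s) & (frame.populations > 0)).sum())
            for s in range(strat.k)
        }
        capped = {}
        n_draw = {}
        for s, n in n_by_stratum.items():
            limit = counts_by_stratum[s]
            if config.draw_method == "systematic":
                limit = min(limit, pos_by_stratum[s])
            n_draw[s] = min(n, limit)
            if n_draw[s] < n:
                capped[s] = limit
                logger.warning(
                    "stratum %d: selected n=%d exceeds the %d available cells; "
                    "taking the stratum as a census", s, n, limit,
                )
        manifest["stages"]["size"] = {
            "n_by_stratum": {str(s): int(n) for s, n in n_by_stratum.items()},
            "n_drawn_by_stratum": {str(s): int(n) for s, n in n_draw.items()},
            "capped_to_census": {str(s): int(n) for s, n in capped.items()},
            "max_stratum_feasible": max_m,
        }
        scheme = compute_probabilities(frame, strat, n_draw)
        scheme.cells.to_csv(out / "scheme.csv", index=False)
        draw = draw_sample(
            scheme, method=config.draw_method, seed=stage_seed(config.seed, "draw")
        )
        sampled = draw.records.merge(
            frame.cells[["cell_id", "centroid_lon", "centroid_lat", "population"]],
            on="cell_id",
        )
        sampled.to_csv(out / "sample.csv", index=False)
        points_to_geojson(sampled, out / "sample.geojson")
        logger.info("sample: %d cells drawn (%s)", len(draw.records), config.draw_method)
        manifest["stages"]["sample"] = {
            "method": config.draw_method,
            "rows": int(len(draw.records)),
            "total_draws": int(draw.records["multiplicity"].sum()),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["complete"] = True
    _write_json(out / "manifest.json", manifest)
    return manifest
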