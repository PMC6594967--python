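"""End-to-end pipeline orchestration and artifact export.

``run_pipeline`` executes ingest → grid → diversity → band/depth
aggregation → environment collation → model selection on either a
synthetic world (generated in-process) or file-based inputs, and writes
every figure-data table as CSV plus GeoJSON cell maps and a JSON run
manifest. All randomness flows from one master seed recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import grid as gr
from . import models as md
from . import occurrences as oc
from . import synthetic as sy
from .trends import fit_trend

log = logging.getLogger("hexdiv")


@dataclass
class PipelineConfig:
    out_dir: str = "hexdiv_out"
    # file-based inputs (optional; when absent a synthetic world is used)
    occurrences_path: str | None = None
    synonyms_path: str | None = None
    traits_path: str | None = None
    raster_dir: str | None = None
    ocean_mask_path: str | None = None
    # analysis options
    target_area_km2: float = 50_000.0
    band_width_deg: float = 5.0
    depth_interval_m: float = 100.0
    shallow_deep_threshold_m: float = 500.0
    es_m: int = 50
    es_mode: str = "samples"
    bootstrap_B: int = 200
    seed: int = 0
    fit_models: bool = True
    # synthetic-world options (used when occurrences_path is None)
    synthetic: dict = field(default_factory=dict)
    n_records: int = 20_000

    def validate(self) -> None:
        for name in ("target_area_km2", "band_width_deg", "depth_interval_m",
                     "shallow_deep_threshold_m", "es_m", "bootstrap_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.es_mode not in ("samples", "records"):
            raise ValueError("es_mode must be 'samples' or 'records'")
        if self.shallow_deep_threshold_m % self.depth_interval_m not in (0.0,):
            log.warning("shallow/deep threshold %s is not a multiple of the depth interval %s",
                        self.shallow_deep_threshold_m, self.depth_interval_m)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # -- stage: ingest ------------------------------------------------------
    try:
        if config.occurrences_path:
            records = oc.read_occurrences(config.occurrences_path)
            synonyms = oc.SynonymTable.read_csv(config.synonyms_path) \
                if config.synonyms_path else None
            records, counts = oc.clean_pipeline(records, synonyms)
            truth = None
            rasters = {}
            if config.raster_dir:
                for fn in sorted(os.listdir(config.raster_dir)):
                    if fn.endswith(".asc"):
                        r = gr.EnvRaster.read_ascii(os.path.join(config.raster_dir, fn))
                        rasters[r.name or fn[:-4]] = r
            ocean_mask = gr.EnvRaster.read_ascii(config.ocean_mask_path) \
                if config.ocean_mask_path else None
        else:
            params = sy.GeneratorParams(**{"seed": config.seed, **config.synthetic})
            truth = sy.generate_world(params)
            raw = sy.sample_occurrences(truth, config.n_records, seed=config.seed)
            records, counts = oc.clean_pipeline(raw, None, bbox=params.bbox)
            rasters = truth.env_rasters
            ocean_mask = truth.ocean_mask
        manifest["stages"]["ingest"] = counts
        log.info("ingest: %s", counts)
    except Exception as exc:  # noqa: BLE001 - stage name propagated
        raise RuntimeError(f"stage ingest failed: {exc}") from exc

    bbox = truth.params.bbox if truth is not None else gr.STUDY_BBOX

    # -- stage: grid --------------------------------------------------------
    try:
        grid = gr.build_hex_grid(config.target_area_km2, bbox)
        gr.grid_to_geojson_file(grid, os.path.join(config.out_dir, "grid.geojson"))
        manifest["stages"]["grid"] = {"n_cells": len(grid.cells),
                                      "mean_area_km2": float(np.mean([c.spherical_area
                                                                      for c in grid.cells]))}
    except Exception as exc:
        raise RuntimeError(f"stage grid failed: {exc}") from exc

    # -- stage: diversity ---------------------------------------------------
    try:
        cell_divs = dv.cell_diversity(
            records, grid, m=config.es_m, mode=config.es_mode,
            B=config.bootstrap_B, seed=config.seed,
            depth_threshold=config.shallow_deep_threshold_m)
        cell_df = pd.DataFrame([dataclasses.asdict(c) for c in cell_divs])
        cell_df.to_csv(os.path.join(config.out_dir, "cell_diversity.csv"), index=False)
        _cells_geojson(grid, cell_divs, os.path.join(config.out_dir, "cell_map.geojson"))
        manifest["stages"]["diversity"] = {
            "n_cells": len(grid.cells),
            "cells_with_records": int(sum(1 for c in cell_divs
                                          if c.stratum == "all" and c.R > 0)),
        }
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc

    # -- stage: band/depth aggregation --------------------------------------
    try:
        band_rows = []
        for stratum in ("all", "shallow", "deep"):
            bands = dv.band_diversity(records, cell_divs, grid, ocean_mask,
                                      stratum=stratum, width=config.band_width_deg,
                                      depth_threshold=config.shallow_deep_threshold_m)
            band_rows += [dataclasses.asdict(b) for b in bands]
        band_df = pd.DataFrame(band_rows)
        band_df.to_csv(os.path.join(config.out_dir, "band_diversity.csv"), index=False)

        depth_divs = dv.depth_profile(records, grid, m=config.es_m,
                                      width=config.depth_interval_m)
        depth_df = pd.DataFrame([dataclasses.asdict(d) for d in depth_divs])
        depth_df.to_csv(os.path.join(config.out_dir, "depth_profile.csv"), index=False)

        trends = {}
        sub = band_df[(band_df["stratum"] == "all") & band_df["mean_es50"].notna()]
        if len(sub) >= 7:
            mid = np.array([np.mean(b) for b in sub["band_lat"]])
            t = fit_trend(mid, sub["mean_es50"].to_numpy(), "polynomial", 6)
            trends["band_es50_poly6"] = {"coefficients": t.coefficients.tolist(),
                                         "r_squared": t.r_squared}
        dsub = depth_df[(depth_df["records"] > 0) & (depth_df["gamma"] > 0)]
        if len(dsub) >= 2:
            mid = np.array([np.mean(d) for d in dsub["depth"]]) + 1.0
            t = fit_trend(mid, dsub["gamma"].to_numpy(), "logarithmic")
            trends["depth_gamma_log"] = {"coefficients": t.coefficients.tolist(),
                                         "r_squared": t.r_squared}
        with open(os.path.join(config.out_dir, "trends.json"), "w") as fh:
            json.dump(trends, fh, indent=2)
        manifest["stages"]["aggregation"] = {"bands": int(band_df["band"].nunique()),
                                             "depth_intervals_with_records":
                                                 int((depth_df["records"] > 0).sum())}
    except Exception as exc:
        raise RuntimeError(f"stage aggregation failed: {exc}") from exc

    # -- stage: model selection ---------------------------------------------
    try:
        if config.fit_models and truth is not None:
            sel_frames = []
            for stratum in ("shallow", "deep"):
                table = md.build_cell_table(records, grid, truth, stratum=stratum)
                if len(table) < 30:
                    log.warning("stratum %s: only %d cells, skipping models",
                                stratum, len(table))
                    continue
                for response in ("species_count", "es50"):
                    tbl = table if response == "species_count" else table.dropna(subset=["es50"])
                    if len(tbl) < 30:
                        continue
                    fits = []
                    for spec in md.build_candidate_set(response, stratum):
                        try:
                            fits.append(md.fit_nb_smooth(spec, tbl))
                        except (ValueError, np.linalg.LinAlgError) as exc:
                            log.warning("fit failed (%s/%s/%s): %s", response,
                                        stratum, spec.label, exc)
                    sel = md.selection_table(fits)
                    df = sel.to_frame()
                    df.insert(0, "response", response)
                    df.insert(1, "stratum", stratum)
                    sel_frames.append(df)
            if sel_frames:
                pd.concat(sel_frames).to_csv(
                    os.path.join(config.out_dir, "model_selection.csv"), index=False)
                manifest["stages"]["models"] = {"tables": len(sel_frames)}
        else:
            manifest["stages"]["models"] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"stage models failed: {exc}") from exc

    manifest["outputs"] = sorted(os.listdir(config.out_dir))
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _cells_geojson(grid: gr.HexGrid, cell_divs, path) -> None:
    by_cell: dict[str, dict] = {}
    for c in cell_divs:
        by_cell.setdefault(c.cell_id, {})[c.stratum] = c
    gj = grid.to_geojson()
    for feat in gj["features"]:
        cid = feat["properties"]["cell_id"]
        for stratum, c in by_cell.get(cid, {}).items():
            feat["properties"][f"records_{stratum}"] = c.R
            feat["properties"][f"alpha_{stratum}"] = c.alpha
            feat["properties"][f"es50_{stratum}"] = c.es50
    with open(path, "w") as fh:
        json.dump(gj, fh)
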