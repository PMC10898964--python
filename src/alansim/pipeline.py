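"""Scenario orchestration: twin -> simulation -> slices -> walks.

A scenario YAML describes a street scene (fixture parameters), the
simulation settings, the slice heights and the walker sweep; `run_scenario`
executes every (lamp type, spacing) cell and writes a manifest with
checksums so runs are reproducible and auditable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import SimConfig, run_simulation
from .errors import ConfigurationError
from .fixtures import StreetScenario, make_street_scene, toy_lamp_library
from .twin import file_sha256, save_scene, write_geotiff
from .walker import WalkConfig, cut_margins, log_plane, run_ensemble, threshold_ladder

log = logging.getLogger("alansim")


@dataclass
class ScenarioConfig:
    """Validated scenario configuration (see `from_yaml`)."""

    seed: int = 0
    packets_per_source: int = 1_000_000
    voxel_size: float = 1.0
    lamp_types: list = field(default_factory=lambda: ["HPS"])
    lamp_spacings: list = field(default_factory=lambda: [32.0])
    scenario_kwargs: dict = field(default_factory=dict)
    slice_heights: list = field(default_factory=lambda: [0.0, 4.0, 10.0])
    walk_thresholds: np.ndarray = field(default_factory=threshold_ladder)
    walk_heights: list = field(default_factory=lambda: [0.0, 4.0, 10.0])
    walk_weights: tuple = (0.5, 0.2, 0.1, 0.2)
    walk_walkers: int = 100_000
    walk_max_iterations: int = 1000
    walk_margin_m: float = 0.0
    output_dir: Path = Path("alansim-out")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, base=Path(path).parent)

    @classmethod
    def from_dict(cls, doc: dict, base: Path = Path(".")) -> "ScenarioConfig":
        if not isinstance(doc, dict):
            raise ConfigurationError("scenario config must be a mapping")
        scen = dict(doc.get("scenario") or {})
        walk = dict(doc.get("walk") or {})
        thresholds = walk.get("thresholds")
        if thresholds is None:
            ladder = threshold_ladder()
        elif isinstance(thresholds, dict):
            ladder = threshold_ladder(thresholds.get("start", -10.0),
                                      thresholds.get("stop", -5.0),
                                      thresholds.get("step", 0.5))
        else:
            ladder = np.asarray(thresholds, dtype=float)
        lamp_types = scen.pop("lamp_types", None) or [scen.pop("lamp_type", "HPS")]
        spacings = scen.pop("lamp_spacings", None) or [scen.pop("lamp_spacing_m", 32.0)]
        known = set(StreetScenario.__dataclass_fields__)
        unknown = set(scen) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(doc.get("seed", 0)),
            packets_per_source=int(doc.get("packets_per_source", 1_000_000)),
            voxel_size=float(doc.get("voxel_size", 1.0)),
            lamp_types=list(lamp_types),
            lamp_spacings=[float(s) for s in spacings],
            scenario_kwargs=scen,
            slice_heights=[float(h) for h in doc.get("slice_heights", [0.0, 4.0, 10.0])],
            walk_thresholds=ladder,
            walk_heights=[float(h) for h in walk.get("heights", doc.get("slice_heights", [0.0]))],
            walk_weights=tuple(walk.get("weights", (0.5, 0.2, 0.1, 0.2))),
            walk_walkers=int(walk.get("walkers", 100_000)),
            walk_max_iterations=int(walk.get("max_iterations", 1000)),
            walk_margin_m=float(walk.get("margin_m", 0.0)),
            output_dir=base / doc.get("output_dir", "alansim-out"),
        )
        for lt in cfg.lamp_types:
            if lt not in toy_lamp_library():
                raise ConfigurationError(f"unknown lamp type {lt!r}")
        return cfg

    def config_hash(self) -> str:
        doc = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_scenario(config: ScenarioConfig) -> dict:
    """Run every (lamp type, spacing) cell of a scenario; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "cells": [],
        "files": {},
    }

    def register(path: Path):
        manifest["files"][str(path.relative_to(out))] = file_sha256(path)

    for lamp_type, spacing in product(config.lamp_types, config.lamp_spacings):
        cell_name = f"{lamp_type}_s{spacing:g}"
        cell_dir = out / cell_name
        cell_dir.mkdir(exist_ok=True)
        t0 = time.perf_counter()
        scenario = StreetScenario(lamp_type=lamp_type, lamp_spacing_m=spacing,
                                  voxel_size_m=config.voxel_size,
                                  **config.scenario_kwargs)
        scene, sources, meta = make_street_scene(scenario)
        sim = SimConfig(
            bounds_min=[0.0, 0.0, 0.0],
            bounds_max=[scenario.road_length_m, scenario.domain_depth_m,
                        scenario.domain_height_m],
            voxel_size=config.voxel_size,
            n_packets=config.packets_per_source,
            seed=config.seed,
        )
        log.info("cell %s: %d sources x %d packets", cell_name, len(sources), sim.n_packets)
        scene_path = cell_dir / "scene.zip"
        save_scene(scene, scene_path)
        register(scene_path)
        grid = run_simulation(scene, sources, sim)
        grid_path = cell_dir / "grid.nc"
        grid.to_netcdf(grid_path, seed=config.seed, n_packets=sim.n_packets)
        register(grid_path)

        walks = {}
        for h in config.slice_heights:
            plane = grid.slice_isoheight(h)
            tif = cell_dir / f"slice_h{h:g}.tif"
            write_geotiff(plane, tif, origin=(0.0, 0.0), cell_size=config.voxel_size)
            register(tif)
        margin_cells = int(round(config.walk_margin_m / config.voxel_size))
        for h in config.walk_heights:
            plane = grid.slice_isoheight(h)
            logp = cut_margins(log_plane(plane), margin_cells)
            for thr in config.walk_thresholds:
                wc = WalkConfig(weights=config.walk_weights, threshold=float(thr),
                                max_iterations=config.walk_max_iterations,
                                n_walkers=config.walk_walkers,
                                margin_m=config.walk_margin_m)
                summary = run_ensemble(logp, wc, config.seed)
                walks[f"h{h:g}_t{thr:g}"] = {
                    "height_m": h,
                    "threshold_dex": float(thr),
                    "success_rate": summary.success_rate,
                    "n_success": summary.n_success,
                    "n_walkers": wc.n_walkers,
                    "mean_steps": float(summary.steps.mean()),
                }
        walks_path = cell_dir / "walks.json"
        walks_path.write_text(json.dumps(walks, indent=2, sort_keys=True))
        register(walks_path)
        manifest["cells"].append({
            "name": cell_name,
            "lamp_type": lamp_type,
            "spacing_m": spacing,
            "n_sources": len(sources),
            "packets_per_source": sim.n_packets,
            "stats": grid.stats,
            "runtime_s": round(time.perf_counter() - t0, 3),
        })
        log.info("cell %s done in %.1fs (stats %s)", cell_name,
                 manifest["cells"][-1]["runtime_s"], grid.stats)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
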