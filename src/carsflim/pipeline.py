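"""End-to-end orchestration: simulate -> fit -> refine -> classify.

`run_pipeline` executes the HS-CARS branch (and optionally the FLIM
branch) of the analysis on synthetic scenes described by a declarative
TOML/dict configuration, persisting every intermediate artifact plus a
provenance record sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import carsclf, carsfit, flimclf, flimfeat, io, refine, synth
from .exceptions import CarsFlimError

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cars": {
        "enabled": True,
        "classes": ["control", "lnp"],
        "image_shape": [48, 48],
        "n_cells": 2,
        "images_per_class": 1,
        "droplet_density": 2.0,
        "snr_db": 20.0,
        "axis_points": 120,
        "max_pixels_per_image": 150,
        "n_estimators": 100,
        "train_fraction": 0.8,
        "model_seeds": [0],
    },
    "flim": {
        "enabled": False,
        "groups": {"control": {"coloc_rho": 0.2, "rho_drift_per_hour": 0.0},
                   "sam_gfp_lnp": {"coloc_rho": 0.2, "rho_drift_per_hour": 0.12}},
        "image_shape": [96, 96],
        "n_cells": 3,
        "hours": [0, 2, 4, 6],
        "n_trials": 50,
        "top_k": 5,
        "compartment": "cytoplasm",
    },
}


def load_config(path) -> dict:
    """Load a TOML configuration, filling unset keys from DEFAULT_CONFIG."""
    import tomllib

    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(config.get(section), dict):
            config[section].update(values)
        else:
            config[section] = values
    return config


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise CarsFlimError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("cars")
def _run_cars(config: dict, out: Path, seed: int) -> dict:
    cfg = config["cars"]
    axis = synth.make_axis(n_points=cfg["axis_points"])
    ss = np.random.SeedSequence([seed, 1])
    image_seeds = ss.generate_state(len(cfg["classes"]) * cfg["images_per_class"]) % (2**31)

    feature_images, refined_masks, groups = [], [], {}
    ratios = []
    i = 0
    for cls in cfg["classes"]:
        spec = synth.class_spec(cls)
        noise_sd = synth.noise_sd_for_snr(spec, axis, cfg["snr_db"])
        for j in range(cfg["images_per_class"]):
            scene = synth.SceneSpec(
                image_shape=tuple(cfg["image_shape"]),
                n_cells=cfg["n_cells"],
                droplet_density=cfg["droplet_density"],
                noise_sd=noise_sd,
                seed=int(image_seeds[i]),
            )
            sim = synth.simulate_hypercube(spec, scene, axis)
            cube = carsfit.Hypercube(sim.cube, axis)
            image_id = f"{cls}_{j}"
            io.write_hypercube(out / f"cube_{image_id}.tif", cube)
            io.write_labels(out / f"cells_{image_id}.tif", sim.cell_mask)

            mask = sim.cell_mask > 0
            # budget: subsample the cell mask deterministically if too large
            ys, xs = np.nonzero(mask)
            cap = cfg["max_pixels_per_image"]
            if ys.size > cap:
                pick = np.random.default_rng(int(image_seeds[i])).choice(ys.size, cap, replace=False)
                sub = np.zeros_like(mask)
                sub[ys[pick], xs[pick]] = True
                mask = sub
            fi = carsfit.fit_hypercube(cube, mask)
            io.write_feature_image(out / f"features_{image_id}.csv", fi)

            ratio = refine.lipid_protein_ratio(cube, sim.cell_mask > 0)
            ratios.append((fi, ratio, sim.cell_mask > 0, image_id))
            groups[image_id] = cls
            i += 1

    for fi, ratio, cellmask, image_id in ratios:
        refined = refine.refine_mask(ratio, cellmask)
        refined_masks.append(refined.mask)
        feature_images.append(fi)

    ds = carsclf.assemble_dataset(
        feature_images, refined_masks, groups, image_ids=[r[3] for r in ratios]
    )
    train, test = carsclf.split_train_test(ds, cfg["train_fraction"], seed=seed)
    reports = {}
    for mseed in cfg["model_seeds"]:
        model = carsclf.train_classifier(train, n_estimators=cfg["n_estimators"], seed=mseed)
        rep = carsclf.build_report(model, test, seed=mseed, split_sizes=(len(train), len(test)))
        rep.to_json(out / f"cars_report_seed{mseed}.json")
        reports[str(mseed)] = json.loads(rep.to_json())
    return {"n_pixels": len(ds), "reports": reports}


@_stage("flim")
def _run_flim(config: dict, out: Path, seed: int) -> dict:
    cfg = config["flim"]
    tables = []
    for gi, (group, pars) in enumerate(sorted(cfg["groups"].items())):
        spec = synth.FlimSceneSpec(
            n_cells=cfg["n_cells"],
            coloc_rho=pars.get("coloc_rho", 0.2),
            rho_drift_per_hour=pars.get("rho_drift_per_hour", 0.0),
            hours=tuple(cfg["hours"]),
            seed=seed * 1000 + gi,
        )
        scene = synth.simulate_flim_scene(spec, tuple(cfg["image_shape"]))
        for hour, channels in scene.channels.items():
            records = flimfeat.derive_compartments(
                scene.cell_mask, scene.nucleus_mask, group=group, hour=hour
            )
            tables.append(flimfeat.build_feature_table(records, channels, clean=False))
    import pandas as pd

    table = pd.concat(tables, ignore_index=True)
    table = table[table["compartment"] == cfg["compartment"]].reset_index(drop=True)
    # clean pooled table: drop NaN / zero-variance feature columns
    meta = [c for c in ("cell_id", "compartment", "group", "hour") if c in table.columns]
    drop = [c for c in table.columns if c not in meta
            and (table[c].isna().any() or np.nanstd(table[c].to_numpy()) == 0)]
    table = table.drop(columns=drop)
    io.write_table(out / "flim_features.csv", table)
    report = flimclf.cross_validate(
        table, n_trials=cfg["n_trials"], top_k=cfg["top_k"], seed=seed
    )
    (out / "flim_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report.to_dict()


def run_pipeline(config: dict | None = None, out_dir="pipeline_out", seed: int | None = None) -> Path:
    """Run the configured pipeline end to end; returns the output directory.

    All intermediate artifacts (cubes, masks, feature tables, reports)
    are persisted under ``out_dir`` together with ``provenance.json``.
    """
    config = json.loads(json.dumps(config if config is not None else DEFAULT_CONFIG))
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: dict = {}
    if config.get("cars", {}).get("enabled", False):
        results["cars"] = _run_cars(config, out, seed)
    if config.get("flim", {}).get("enabled", False):
        results["flim"] = _run_flim(config, out, seed)

    provenance = {
        "config": config,
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2))
    return out
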