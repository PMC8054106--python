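"""File-based pipeline: estimate -> fit -> validate -> report.

Each stage reads the previous stage's delimited-text outputs, so runs
are resumable and auditable.  A JSON manifest written atomically at the
end of a run records the configuration snapshot, SHA-256 digests of the
inputs, per-stage timings and record counts; a later rerun skips a
stage when its inputs' digests are unchanged and its outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml

from . import graph as graph_mod
from . import survey as survey_mod
from .model import SpatioTemporalGPR, predict_surface
from .reporting import change_metrics_posterior, octile_rank
from .validation import cv_metrics, holdout_split

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULTS = {
    "factor_id": "factor",
    "holdout_fraction": 0.10,
    "n_iter": 110_000,
    "burn_in": 10_000,
    "thin": 10,
    "seed": 0,
    "higher_is_better": True,
    "natural_scale": True,
}


class PipelineConfig(dict):
    """Config mapping with defaults; file values overridden by kwargs."""

    def __init__(self, **kwargs):
        merged = {**DEFAULTS, **{k: v for k, v in kwargs.items() if v is not None}}
        super().__init__(merged)
        for key in ("adjacency", "out_dir", "years"):
            if key not in self:
                raise ValueError(f"pipeline config requires '{key}'")
        if "microdata" not in self and "observations" not in self:
            raise ValueError(
                "pipeline config requires 'microdata' or 'observations'"
            )


def load_config(path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        file_cfg = yaml.safe_load(fh) or {}
    file_cfg.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**file_cfg)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _previous_manifest(out_dir: Path):
    p = out_dir / "manifest.json"
    if p.exists():
        try:
            return json.loads(p.read_text())
        except json.JSONDecodeError:
            return None
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Pre-flight checks all referenced inputs before any stage runs, so a
    missing file never leaves partial outputs behind.
    """
    out_dir = Path(config["out_dir"])
    inputs = {"adjacency": config["adjacency"]}
    if "microdata" in config:
        inputs["microdata"] = config["microdata"]
    else:
        inputs["observations"] = config["observations"]
    missing = [str(p) for p in inputs.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"pipeline inputs not found: {missing}")
    out_dir.mkdir(parents=True, exist_ok=True)

    digests = {k: _digest(v) for k, v in inputs.items()}
    prev = _previous_manifest(out_dir)
    reusable = bool(
        prev
        and prev.get("input_digests") == digests
        and prev.get("config") == dict(config)
    )

    manifest = {
        "config": dict(config),
        "input_digests": digests,
        "seed": config["seed"],
        "version": _version(),
        "stages": {},
    }
    years = tuple(range(int(config["years"][0]), int(config["years"][1]) + 1))
    rg = graph_mod.read_adjacency(config["adjacency"])

    def stage(name, outputs, fn):
        paths = [out_dir / o for o in outputs]
        if reusable and all(p.exists() for p in paths) and name in prev["stages"]:
            manifest["stages"][name] = {**prev["stages"][name], "skipped": True}
            return
        t0 = time.perf_counter()
        try:
            counts = fn(paths)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "records": counts,
            "skipped": False,
        }

    # -- estimate ------------------------------------------------------
    def do_estimate(paths):
        if "microdata" in config:
            micro = survey_mod.read_microdata(config["microdata"])
            obs = survey_mod.estimate_observations(
                micro, config.get("survey_years")
            )
        else:
            obs = survey_mod.read_observations(config["observations"])
        survey_mod.write_observations(obs, paths[0])
        return int(len(obs))

    stage("estimate", ["observations.csv"], do_estimate)

    obs = survey_mod.read_observations(out_dir / "observations.csv")
    data = survey_mod.assemble_dataset(obs, rg, years)

    # -- fit + predict -------------------------------------------------
    def do_fit(paths):
        est = SpatioTemporalGPR(
            n_iter=int(config["n_iter"]),
            burn_in=int(config["burn_in"]),
            thin=int(config["thin"]),
            seed=int(config["seed"]),
        ).fit(data)
        np.savez_compressed(paths[0], **est.draws_)
        est.surface_.to_frame().to_csv(paths[1], index=False)
        return est.draws_["alpha"].shape[0]

    stage("fit", ["draws.npz", "surface.csv"], do_fit)

    # -- validate ------------------------------------------------------
    def do_validate(paths):
        train, test = holdout_split(
            data, float(config["holdout_fraction"]), int(config["seed"])
        )
        est = SpatioTemporalGPR(
            n_iter=int(config["n_iter"]),
            burn_in=int(config["burn_in"]),
            thin=int(config["thin"]),
            seed=int(config["seed"]) + 1,
        ).fit(train)
        report = cv_metrics(test, est.surface_)
        report.to_frame(
            factor_id=config["factor_id"], seed=config["seed"]
        ).to_csv(paths[0], index=False)
        return report.n_held_out

    stage("validate", ["cv_report.csv"], do_validate)

    # -- report --------------------------------------------------------
    def do_report(paths):
        draws = np.load(out_dir / "draws.npz")
        surface = predict_surface(draws, rg.region_ids, years)
        start_year = int(config.get("start_year", years[0]))
        end_year = int(config.get("end_year", years[-1]))
        t0, t1 = years.index(start_year), years.index(end_year)
        # national series: unweighted region mean per draw, percent scale
        nat = 100.0 * surface.draws.mean(axis=1)
        change = change_metrics_posterior(
            nat[:, t0],
            nat[:, t1],
            factor_id=config["factor_id"],
            start_year=start_year,
            end_year=end_year,
        )
        change.to_frame().to_csv(paths[0], index=False)
        octiles = octile_rank(
            100.0 * surface.mean[:, t1],
            factor_id=config["factor_id"],
            region_ids=rg.region_ids,
            higher_is_better=bool(config["higher_is_better"]),
            natural_scale=bool(config["natural_scale"]),
        )
        octiles.to_frame().to_csv(paths[1], index=False)
        return len(rg.region_ids)

    stage("report", ["change_report.csv", "octile_table.csv"], do_report)

    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, out_dir / "manifest.json")
    return manifest


def _version() -> str:
    try:
        return metadata.version("prevsmooth")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"
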