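"""End-to-end orchestration: generate/load -> classify -> proxies ->
hexagons -> correlations -> models -> report.

A single YAML-able config drives the run; every stage writes its outputs
under the run directory and the manifest records per-stage record counts
and timings. Re-running with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import io as rio
from . import mobility, model, proxies, stats, synthetic, tessellation
from .types import ExposureModelParams, Landscape, trace_dataframe

log = logging.getLogger("roadproxy")

CONFIG_VERSION = 1

DEFAULT_CONFIG: dict = {
    "version": CONFIG_VERSION,
    "mode": "synthetic",  # synthetic | real
    "seed": 0,
    "paths": {  # real mode only
        "roads": None, "population": None, "villages": None,
        "buildings": None, "traces": None,
    },
    "synthetic": {
        "extent": [0.0, 0.0, 10000.0, 10000.0],
        "n_highways": 2,
        "n_main": 3,
        "n_villages": 12,
        "n_buildings_per_village": 8,
        "cell_size": 100.0,
        "n_participants": 24,
        "minutes_per_participant": 600,
        "background": 15.0,
        "traffic_amplitude": 40.0,
        "traffic_decay_length": 250.0,
        "indoor_attenuation": 0.6,
        "noise_sigma_log": 0.3,
        "step_range": [60.0, 110.0],
    },
    "mobility": {
        "threshold_m_per_min": 100.0,
        "gap_cutoff_min": 5.0,
        # when false, building validation is skipped and the speed rule
        # alone decides the final label
        "use_building_validation": True,
    },
    "tessellation": {
        "width_m": 5000.0,
    },
    "model": {
        "unit": "village",  # village | reading
        "ntree": 50,
        "n_folds": 3,
        "bias_bin_width": 20.0,
        "n_boot": 1000,
    },
    "n_strata": 1,
}

STAGES = ("inputs", "classify", "proxies", "hexagons", "correlations", "models", "report")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults and range-check; raises ConfigError naming each bad field."""
    cfg = _deep_update(DEFAULT_CONFIG, config or {})
    errors: list[str] = []
    if cfg["mode"] not in ("synthetic", "real"):
        errors.append(f"mode: unknown value {cfg['mode']!r} (allowed: synthetic, real)")
    if cfg.get("seed") is None:
        cfg["seed"] = DEFAULT_CONFIG["seed"]
        log.info("config: missing seed, default %d injected", cfg["seed"])
    if cfg["tessellation"]["width_m"] <= 0:
        errors.append("tessellation.width_m: must be > 0")
    if cfg["mobility"]["threshold_m_per_min"] <= 0:
        errors.append("mobility.threshold_m_per_min: must be > 0")
    if cfg["mobility"]["gap_cutoff_min"] <= 0:
        errors.append("mobility.gap_cutoff_min: must be > 0")
    syn = cfg["synthetic"]
    for key in ("n_highways", "n_main", "n_villages", "n_buildings_per_village"):
        if syn[key] < 0:
            errors.append(f"synthetic.{key}: must be >= 0")
    if syn["cell_size"] <= 0:
        errors.append("synthetic.cell_size: must be > 0")
    if not 0 < syn["indoor_attenuation"] <= 1:
        errors.append("synthetic.indoor_attenuation: must be in (0, 1]")
    if cfg["model"]["unit"] not in ("village", "reading"):
        errors.append("model.unit: unknown value (allowed: village, reading)")
    if cfg["model"]["ntree"] < 1:
        errors.append("model.ntree: must be >= 1")
    if cfg["model"]["n_folds"] < 2:
        errors.append("model.n_folds: must be >= 2")
    if cfg["n_strata"] < 1:
        errors.append("n_strata: must be >= 1")
    if cfg["mode"] == "real":
        for key, p in cfg["paths"].items():
            if p is None:
                errors.append(f"paths.{key}: required in real mode")
            elif not Path(p).exists():
                errors.append(f"paths.{key}: {p} does not exist")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path | None) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    return validate_config(raw or {})


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``manifest.json``). On stage failure, partial outputs are kept next to
    a FAILED marker naming the stage."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": [], "outputs": {}}
    seed = int(cfg["seed"])

    def record(stage, t0, **counts):
        entry = {"stage": stage, "seconds": round(time.time() - t0, 3), **counts}
        manifest["stages"].append(entry)
        log.info("stage %s: %s", stage, counts)

    try:
        # ---- inputs -------------------------------------------------------
        t0 = time.time()
        syn = cfg["synthetic"]
        if cfg["mode"] == "synthetic":
            landscape = synthetic.generate_landscape(
                seed=seed,
                extent=tuple(syn["extent"]),
                n_highways=syn["n_highways"],
                n_main=syn["n_main"],
                n_villages=syn["n_villages"],
                n_buildings_per_village=syn["n_buildings_per_village"],
                cell_size=syn["cell_size"],
            )
            params = ExposureModelParams(
                background=syn["background"],
                traffic_amplitude=syn["traffic_amplitude"],
                traffic_decay_length=syn["traffic_decay_length"],
                indoor_attenuation=syn["indoor_attenuation"],
                noise_sigma_log=syn["noise_sigma_log"],
                seed=seed,
            )
            readings = synthetic.simulate_traces(
                landscape, params,
                n_participants=syn["n_participants"],
                minutes_per_participant=syn["minutes_per_participant"],
                step_range=tuple(syn["step_range"]),
            )
            manifest["outputs"].update(rio.write_landscape(landscape, outdir / "landscape"))
            rio.write_traces_csv(readings, outdir / "traces.csv")
            manifest["outputs"]["traces"] = str(outdir / "traces.csv")
        else:
            landscape = _load_real_landscape(cfg)
            readings = rio.read_traces_csv(cfg["paths"]["traces"])
        record("inputs", t0, n_readings=len(readings), n_villages=len(landscape.villages),
               n_roads=len(landscape.roads.segments), n_buildings=len(landscape.buildings))

        # ---- classify -----------------------------------------------------
        t0 = time.time()
        if cfg["mobility"]["use_building_validation"]:
            coverage = landscape.extent_polygon
        else:
            coverage = Polygon()  # empty: every reading uncovered, speed rule decides
        classified, cm = mobility.classify_readings(
            readings, landscape.buildings, coverage=coverage,
            threshold=cfg["mobility"]["threshold_m_per_min"],
            gap_cutoff=cfg["mobility"]["gap_cutoff_min"],
        )
        outdoor = mobility.filter_outdoor(classified)
        (outdir / "confusion_matrix.json").write_text(json.dumps(cm.to_dict(), indent=2))
        cls_df = trace_dataframe([c.reading for c in classified])
        cls_df["speed_m_min"] = [c.speed for c in classified]
        cls_df["speed_label"] = [c.speed_label for c in classified]
        cls_df["building_label"] = [c.building_label for c in classified]
        cls_df["final_label"] = [c.final_label for c in classified]
        cls_df.to_csv(outdir / "classified.csv", index=False, float_format="%.6f")
        manifest["outputs"]["classified"] = str(outdir / "classified.csv")
        manifest["outputs"]["confusion_matrix"] = str(outdir / "confusion_matrix.json")
        if not outdoor:
            raise StageFailure("classify", "no outdoor readings remain after filtering "
                               "(check mobility.threshold_m_per_min and the building data)")
        record("classify", t0, n_in=len(classified), n_outdoor=len(outdoor))

        # ---- village exposure + proxies -----------------------------------
        t0 = time.time()
        exposure = _village_exposure(outdoor, landscape, syn)
        ptable = proxies.proxy_table(landscape)
        ptable.to_csv(outdir / "village_proxies.csv", index=False, float_format="%.6f")
        exposure.to_csv(outdir / "village_pm25.csv", index=False, float_format="%.6f")
        manifest["outputs"]["village_proxies"] = str(outdir / "village_proxies.csv")
        manifest["outputs"]["village_pm25"] = str(outdir / "village_pm25.csv")
        if exposure.empty:
            raise StageFailure("proxies", "no villages with outdoor readings")
        record("proxies", t0, n_villages=len(ptable), n_with_exposure=len(exposure))

        # ---- hexagons -----------------------------------------------------
        t0 = time.time()
        hexes = tessellation.make_hex_grid(landscape.extent, width=cfg["tessellation"]["width_m"])
        vr = ptable.merge(exposure, on="village_id")
        centroids = {v.id: (v.centroid.x, v.centroid.y) for v in landscape.villages}
        vr["x"] = [centroids[v][0] for v in vr["village_id"]]
        vr["y"] = [centroids[v][1] for v in vr["village_id"]]
        vdf = vr.rename(columns={"wrnd_kmkm2": "wrnd", "em_km": "em", "eh_km": "eh"})
        aggs = tessellation.aggregate_to_hex(hexes, vdf)
        aggs = tessellation.assign_classes(aggs)
        tessellation.hex_table(aggs).to_csv(outdir / "hex_aggregates.csv", index=False,
                                            float_format="%.6f")
        manifest["outputs"]["hex_aggregates"] = str(outdir / "hex_aggregates.csv")
        record("hexagons", t0, n_hexes=len(aggs))

        # ---- correlations -------------------------------------------------
        t0 = time.time()
        strata_map = _strata(vr["village_id"], cfg["n_strata"])
        corr = stats.correlation_matrix(ptable, exposure, strata=strata_map)
        stats.correlation_table(corr).to_csv(outdir / "correlations.csv", index=False,
                                             float_format="%.6f")
        manifest["outputs"]["correlations"] = str(outdir / "correlations.csv")
        record("correlations", t0, n_results=len(corr))

        # ---- models -------------------------------------------------------
        t0 = time.time()
        mdata, mstrata = _model_data(cfg, vr, outdoor, landscape)
        results = model.run_model_suite(
            mdata, strata=mstrata, ntree=cfg["model"]["ntree"],
            n_folds=cfg["model"]["n_folds"], seed=seed,
        )
        model.metrics_table(results).to_csv(outdir / "model_metrics.csv", index=False,
                                            float_format="%.6f")
        manifest["outputs"]["model_metrics"] = str(outdir / "model_metrics.csv")
        imps = [
            {"stratum": r.spec.stratum, **r.importances}
            for r in results if r.importances is not None
        ]
        pd.DataFrame(imps).to_csv(outdir / "feature_importance.csv", index=False,
                                  float_format="%.6f")
        manifest["outputs"]["feature_importance"] = str(outdir / "feature_importance.csv")
        combined_global = next(r for r in results
                               if r.spec.stratum == "global" and r.spec.name == "Combined")
        profile = model.binned_bias(
            combined_global.oof_predictions, combined_global.targets,
            bin_width=cfg["model"]["bias_bin_width"],
            n_boot=cfg["model"]["n_boot"], seed=seed,
        )
        model.bias_profile_table(profile).to_csv(outdir / "bias_profile.csv", index=False,
                                                 float_format="%.6f")
        manifest["outputs"]["bias_profile"] = str(outdir / "bias_profile.csv")
        record("models", t0, n_models=len(results))

        # ---- report -------------------------------------------------------
        t0 = time.time()
        manifest["n_stages_completed"] = len(manifest["stages"]) + 1
        record("report", t0, n_outputs=len(manifest["outputs"]))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    except StageFailure as exc:
        (outdir / "FAILED").write_text(str(exc))
        raise
    except Exception as exc:  # annotate with the running stage
        stage = STAGES[min(len(manifest["stages"]), len(STAGES) - 1)]
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}")
        raise StageFailure(stage, exc) from exc


def _load_real_landscape(cfg: dict) -> Landscape:
    paths = cfg["paths"]
    roads = rio.read_roads_geojson(paths["roads"])
    population = rio.read_population_asc(paths["population"])
    villages = rio.read_villages_geojson(paths["villages"])
    buildings = rio.read_buildings_geojson(paths["buildings"])
    return Landscape(
        extent=population.extent, roads=roads, population=population,
        villages=villages, buildings=buildings,
    )


def _home_villages(pids, landscape: Landscape) -> dict[str, str]:
    """participant_id -> home village id, using the generator's round-robin
    rule (participant index mod number of villages). Falls back to the
    participant's position in the sorted id list when ids are not of the
    generated ``p<index>`` form."""
    n_v = len(landscape.villages)
    out = {}
    for pos, pid in enumerate(sorted(pids)):
        try:
            idx = int(str(pid).lstrip("p"))
        except ValueError:
            idx = pos
        out[pid] = landscape.villages[idx % n_v].id
    return out


def _village_exposure(outdoor, landscape: Landscape, syn: dict) -> pd.DataFrame:
    """Mean outdoor PM2.5 per village, via the participants' home villages."""
    pid_village = _home_villages({r.participant_id for r in outdoor}, landscape)
    df = pd.DataFrame(
        [(pid_village[r.participant_id], r.pm25) for r in outdoor],
        columns=["village_id", "pm25"],
    )
    out = df.groupby("village_id", as_index=False).agg(pm25=("pm25", "mean"),
                                                       n=("pm25", "size"))
    return out


def _strata(village_ids, n_strata: int) -> dict[str, str] | None:
    if n_strata <= 1:
        return None
    ids = sorted(set(village_ids))
    return {v: f"region{(i % n_strata) + 1}" for i, v in enumerate(ids)}


def _model_data(cfg, vr: pd.DataFrame, outdoor, landscape):
    """Observation table for the RF suite; village-level means by default,
    per-reading with inherited village proxies when model.unit=reading."""
    strata_map = _strata(vr["village_id"], cfg["n_strata"])
    if cfg["model"]["unit"] == "village":
        data = vr.rename(columns={"pm25": "pm25"})[
            ["village_id", "wrnd_kmkm2", "em_km", "eh_km", "pm25"]
        ].dropna().reset_index(drop=True)
    else:
        pid_village = _home_villages({r.participant_id for r in outdoor}, landscape)
        base = vr.set_index("village_id")[["wrnd_kmkm2", "em_km", "eh_km"]]
        rows = [
            (pid_village[r.participant_id], r.pm25) for r in outdoor
            if pid_village[r.participant_id] in base.index
        ]
        df = pd.DataFrame(rows, columns=["village_id", "pm25"])
        data = df.join(base, on="village_id").dropna().reset_index(drop=True)
    strata = None
    if strata_map:
        strata = [strata_map[v] for v in data["village_id"]]
    return data, strata
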