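"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: generate/load the city (``synth``), place sample points
(``sample``), obtain per-image class-fraction summaries (``summarize`` — the
synthetic renderer by default, or masks through a segmentation backend),
build zones and aggregate (``aggregate``), and fit/evaluate models
(``model``). Each stage writes plain-text artifacts into the output
directory and is skipped when its outputs already exist, so a run can resume
after deleting only downstream files. A manifest records the configuration
snapshot, the seed, per-stage timestamps, and a SHA-256 digest of every
artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import aggregation, modeling, sampler, synthetic_city
from .geo_io import load_network, save_network, write_feature_collection
from .segmentation import FEATURES_BY_TARGET, frame_to_summaries, summaries_to_frame

STAGES = ("synth", "sample", "summarize", "aggregate", "model")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "city": {"grid_n": 10, "block_m": 150.0},
    "sampling": {"spacing_m": 150.0},
    "zones": {"n": 48, "radius_m": 300.0, "metric": "l1_diamond"},
    "model": {
        "families": ["linear", "gbt", "svm"],
        "k": 5,
        "sidewalk_tau": aggregation.DEFAULT_SIDEWALK_TAU,
        "intersection_buffers": {
            "pedestrians": 1000.0,
            "bicycles": 1000.0,
            "vehicles": 500.0,
        },
    },
}

_CSV_FLOAT = "%.12g"


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(
    config: Optional[dict] = None,
    out_dir: str | Path = "streetscape_run",
    stages: Optional[Sequence[str]] = None,
    force: bool = False,
) -> dict:
    """Run the requested stages (all by default) and return the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = list(stages) if stages else list(STAGES)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")

    manifest: dict = {
        "config": cfg,
        "seed": cfg["seed"],
        "stages": {},
        "artifacts": {},
    }

    city_cfg = synthetic_city.CityConfig(seed=cfg["seed"], **cfg.get("city", {}))
    city = None  # built lazily; cheap relative to rendering

    def record(stage: str, paths: Sequence[Path], cached: bool) -> None:
        manifest["stages"][stage] = {
            "cached": cached,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        for p in paths:
            manifest["artifacts"][p.name] = _digest(p)

    def need(stage: str, *paths: Path) -> bool:
        if stage not in wanted:
            return False
        return force or not all(p.exists() for p in paths)

    net_path = out / "net.geojson"
    points_path = out / "points.geojson"
    summaries_path = out / "summaries.csv"
    zones_path = out / "zones.geojson"
    feats_path = out / "zone_features.csv"
    truth_path = out / "truth.csv"
    results_path = out / "results.csv"
    best_path = out / "best_results.csv"
    confusion_path = out / "sidewalk_confusion.csv"

    # --- synth -------------------------------------------------------------
    if need("synth", net_path):
        city = synthetic_city.gen_city(city_cfg)
        save_network(city.network, net_path)
        record("synth", [net_path], cached=False)
    elif "synth" in wanted:
        record("synth", [net_path], cached=True)

    def get_city() -> synthetic_city.SyntheticCity:
        nonlocal city
        if city is None:
            city = synthetic_city.gen_city(city_cfg)
        return city

    # --- sample ------------------------------------------------------------
    if need("sample", points_path):
        if not net_path.exists():
            raise PipelineError("sample", f"missing upstream {net_path.name}")
        network = load_network(net_path)
        points = sampler.sample_points(
            network, spacing_m=cfg["sampling"]["spacing_m"]
        )
        sampler.write_points(points, points_path, network.crs_id)
        record("sample", [points_path], cached=False)
    elif "sample" in wanted:
        record("sample", [points_path], cached=True)

    # --- summarize ---------------------------------------------------------
    if need("summarize", summaries_path):
        if not points_path.exists():
            raise PipelineError("summarize", f"missing upstream {points_path.name}")
        points = sampler.read_points(points_path)
        summaries = synthetic_city.render_summaries(points, get_city())
        summaries_to_frame(summaries).to_csv(
            summaries_path, index=False, float_format=_CSV_FLOAT
        )
        record("summarize", [summaries_path], cached=False)
    elif "summarize" in wanted:
        record("summarize", [summaries_path], cached=True)

    # --- aggregate ---------------------------------------------------------
    if need("aggregate", zones_path, feats_path, truth_path):
        for up in (points_path, summaries_path):
            if not up.exists():
                raise PipelineError("aggregate", f"missing upstream {up.name}")
        points = sampler.read_points(points_path)
        summaries = frame_to_summaries(pd.read_csv(summaries_path))
        c = get_city()
        zcfg = cfg["zones"]
        centroids = synthetic_city.gen_zone_centroids(
            city_cfg, zcfg["n"], zcfg["radius_m"]
        )
        zones = [
            aggregation.build_zone(
                (row.x, row.y), zcfg["radius_m"], zcfg["metric"],
                network=c.network, zone_id=row.id,
            )
            for row in centroids.itertuples(index=False)
        ]
        feats = []
        for z in zones:
            vec = aggregation.aggregate_zone(
                aggregation.assign_images(points, z, summaries), z
            )
            if vec is None:
                continue
            feats.append(
                {"zone_id": z.zone_id, "n_points": vec.n_points,
                 "n_images": vec.n_images, **vec.features}
            )
        pd.DataFrame(feats).to_csv(feats_path, index=False, float_format=_CSV_FLOAT)

        zone_truth = synthetic_city.zone_truth_table(c, zones)
        inter = c.intersections
        inter_truth = pd.concat(
            [
                pd.DataFrame(
                    {"id": inter["id"], "target_name": t, "value": inter[t]}
                )
                for t in ("pedestrians", "bicycles", "vehicles")
            ]
        )
        pd.concat([zone_truth, inter_truth]).to_csv(
            truth_path, index=False, float_format=_CSV_FLOAT
        )
        write_feature_collection(
            (
                {
                    "type": "Feature",
                    "geometry": mapping(z.polygon),
                    "properties": {
                        "zone_id": z.zone_id, "kind": z.kind,
                        "radius_m": z.radius_m, "metric": z.metric,
                    },
                }
                for z in zones
            ),
            zones_path,
            c.network.crs_id,
        )
        record("aggregate", [zones_path, feats_path, truth_path], cached=False)
    elif "aggregate" in wanted:
        record("aggregate", [zones_path, feats_path, truth_path], cached=True)

    # --- model -------------------------------------------------------------
    if need("model", results_path, best_path):
        for up in (feats_path, truth_path, summaries_path, points_path):
            if not up.exists():
                raise PipelineError("model", f"missing upstream {up.name}")
        results, confusion = _model_stage(cfg, out)
        results.to_csv(results_path, index=False, float_format=_CSV_FLOAT)
        best = (
            results.sort_values(["target", "rmse", "family"])
            .groupby("target", sort=True)
            .head(1)
            .reset_index(drop=True)
        )
        best.to_csv(best_path, index=False, float_format=_CSV_FLOAT)
        confusion.to_csv(confusion_path, index=False, float_format=_CSV_FLOAT)
        record("model", [results_path, best_path, confusion_path], cached=False)
    elif "model" in wanted:
        record("model", [results_path, best_path, confusion_path], cached=True)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _model_stage(cfg: dict, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    seed = cfg["seed"]
    mcfg = cfg["model"]
    families = mcfg["families"]
    k = mcfg["k"]

    points = sampler.read_points(out / "points.geojson")
    summaries = frame_to_summaries(pd.read_csv(out / "summaries.csv"))
    feats = pd.read_csv(out / "zone_features.csv")
    truth = pd.read_csv(out / "truth.csv", dtype={"id": str})

    rows = []

    # postal-code targets on the fixed zone set
    zone_targets = ("trees", "sidewalk_length", "traffic_lights", "traffic_signs")
    for target in zone_targets:
        tvals = truth[truth["target_name"] == target].set_index("id")["value"]
        joined = feats.merge(
            tvals.rename("target"), left_on="zone_id", right_index=True
        )
        cols = list(FEATURES_BY_TARGET[target])
        X, y = joined[cols], joined["target"]
        if y.std(ddof=1) == 0:
            continue
        xstats = modeling.StandardizationStats.fit(X, source="train_city")
        ystats = modeling.StandardizationStats.fit(
            y.to_frame("target"), source="train_city"
        )
        Xs = modeling.standardize(X, xstats)
        ys = modeling.standardize(y.to_frame("target"), ystats)["target"]
        for fam in families:
            fit = modeling.fit_cv(Xs, ys, family=fam, k=k, seed=seed,
                                  target_name=target)
            rows.append(dict(target=target, family=fam, buffer_m="",
                             rmse=fit.cv_rmse, r2=fit.cv_r2, mae=fit.cv_mae,
                             n=fit.n))

    # intersection targets at fixed per-target buffer sizes
    pframe = pd.DataFrame(
        {"point_id": [p.point_id for p in points],
         "x": [p.coord[0] for p in points],
         "y": [p.coord[1] for p in points]}
    )
    sframe = summaries_to_frame(summaries)
    # intersection anchor coordinates and truth come from the generated city
    city_cfg = synthetic_city.CityConfig(seed=seed, **cfg.get("city", {}))
    city = synthetic_city.gen_city(city_cfg)
    inter = city.intersections
    for target, buffer_m in mcfg["intersection_buffers"].items():
        cols = list(FEATURES_BY_TARGET[target])
        img_feats = _image_features(sframe, cols)
        y = inter.set_index("id")[target]
        ys = (y - y.mean()) / y.std(ddof=1)
        zone_feats, ok_ids = _buffer_means(
            inter[["id", "x", "y"]], pframe, img_feats, buffer_m
        )
        Xs_raw = zone_feats[cols]
        xstats = modeling.StandardizationStats.fit(Xs_raw, source="train_city")
        Xs = modeling.standardize(Xs_raw, xstats)
        yy = ys.loc[ok_ids].reset_index(drop=True)
        for fam in families:
            fit = modeling.fit_cv(Xs, yy, family=fam, k=k, seed=seed,
                                  target_name=target, buffer_m=buffer_m)
            rows.append(dict(target=target, family=fam, buffer_m=buffer_m,
                             rmse=fit.cv_rmse, r2=fit.cv_r2, mae=fit.cv_mae,
                             n=fit.n))

    # sidewalk segment classification against municipal truth
    labels = aggregation.label_segments(points, summaries, tau=mcfg["sidewalk_tau"])
    truth_labels = {
        sid: val for sid, val in city.sidewalk_truth.items() if sid in labels
    }
    pred_labels = {sid: bool(labels[sid]) for sid in truth_labels}
    confusion = modeling.sidewalk_accuracy(pred_labels, truth_labels)
    confusion_df = pd.DataFrame(
        [
            dict(tp=confusion.tp, fp=confusion.fp, tn=confusion.tn,
                 fn=confusion.fn, sensitivity=confusion.sensitivity,
                 specificity=confusion.specificity)
        ]
    )
    return pd.DataFrame(rows), confusion_df


def _image_features(sframe: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    df = sframe[["point_id"]].copy()
    for c in cols:
        if c == "cyclist":
            df[c] = sframe["bicycle"] + sframe["rider"]
        elif c == "vehicle":
            df[c] = (
                sframe["road"] + sframe["car"] + sframe["truck"]
                + sframe["motorcycle"]
            )
        else:
            df[c] = sframe[c]
    return df


def _buffer_means(
    anchors: pd.DataFrame,
    point_coords: pd.DataFrame,
    image_features: pd.DataFrame,
    radius_m: float,
) -> tuple[pd.DataFrame, list[str]]:
    feat_cols = [c for c in image_features.columns if c != "point_id"]
    pts = point_coords.merge(image_features, on="point_id")
    pxy = pts[["x", "y"]].to_numpy(float)
    pfeat = pts[feat_cols].to_numpy(float)
    axy = anchors[["x", "y"]].to_numpy(float)
    d = np.hypot(axy[:, [0]] - pxy[None, :, 0], axy[:, [1]] - pxy[None, :, 1])
    member = d <= radius_m
    counts = member.sum(axis=1)
    ok = counts > 0
    means = (member[ok] @ pfeat) / counts[ok, None]
    ids = anchors["id"].astype(str).to_numpy()[ok].tolist()
    return pd.DataFrame(means, columns=feat_cols), ids
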