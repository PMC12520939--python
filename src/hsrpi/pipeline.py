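"""End-to-end orchestration: simulate → unmix → phenotype → classify → evaluate.

One YAML config drives all stages; a single global seed is fanned out into
per-stage child seeds through ``numpy.random.SeedSequence([seed, stage])``
so any stage can be re-run in isolation.  Every intermediate artifact is
written to disk, hashed into the run manifest, and reproducible
byte-for-byte for a fixed config + seed (the manifest itself carries
timestamps; the data artifacts do not).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .classification import autoscale, fit_oplsda, save_model
from .evaluation import class_metrics, confusion_matrix, cross_validate, resubstitution_metrics
from .phenotyping import FEATURE_TABLE_COLUMNS, extract_features, match_cells_to_truth, segment_cells
from .spectral_library import default_axis, default_library
from .synthetic_data import (
    CohortConfig,
    LEUKEMIA_CLASSES,
    generate_cohort,
    load_default_profiles,
    load_field,
)
from .unmixing import ChemicalMaps, UnmixConfig, unmix_image

__all__ = ["default_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "unmix", "phenotype", "classify", "evaluate")


def default_config() -> dict:
    """Default 6-leukemia-class benchmark configuration."""
    return {
        "simulate": {
            "classes": list(LEUKEMIA_CLASSES),
            "cells_per_class": 30,
            "image_size": [192, 192],
            "cells_per_field": 10,
            "noise_sigma": 0.02,
            "background_level": 0.0,
            "patient_cv": 0.10,
            "n_channels": 64,
        },
        "unmix": {"lambda": 1e-3, "nonnegative": True, "max_iter": 1000, "tol": 1e-8},
        "phenotype": {"min_area": 30, "threshold": "otsu"},
        "classify": {"a": None, "a_ortho": None},
        "evaluate": {"k": 7},
    }


def _stage_seed(seed: int, stage: str) -> int:
    child = np.random.SeedSequence([int(seed), _STAGES.index(stage)])
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) for k, v in base.items()}
    for stage, params in (override or {}).items():
        out.setdefault(stage, {}).update(params or {})
    return out


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path, seed: int = 42) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    ``config`` may be a YAML path, a dict of per-stage overrides merged
    onto :func:`default_config`, or None for pure defaults.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(default_config(), config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": int(seed),
        "config": cfg,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    artifacts: dict[str, str] = {}

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": _stage_seed(seed, stage) if stage == "simulate" else None,
            "outputs": {p.name: _sha256(p) for p in paths},
        }
        artifacts.update({p.name: str(p) for p in paths})

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    sim = cfg["simulate"]
    library = default_library(default_axis(int(sim.get("n_channels", 64))))
    cohort_cfg = CohortConfig(
        classes=load_default_profiles(sim["classes"]),
        cells_per_class=int(sim["cells_per_class"]),
        image_size=tuple(sim["image_size"]),
        cells_per_field=int(sim["cells_per_field"]),
        noise_sigma=float(sim["noise_sigma"]),
        background_level=float(sim["background_level"]),
        patient_cv=float(sim["patient_cv"]),
        seed=_stage_seed(seed, "simulate"),
    )
    data_dir = out / "cohort"
    cohort = generate_cohort(cohort_cfg, data_dir, library)
    record("simulate", t0, [data_dir / "truth.csv", data_dir / "manifest.json"])
    logger.info("simulate: %d fields, %d cells", len(cohort["fields"]),
                cohort_cfg.cells_per_class * len(sim["classes"]))

    # --- unmix + phenotype (per field) --------------------------------------
    t0 = time.time()
    un = cfg["unmix"]
    ucfg = UnmixConfig(
        lambda_=float(un["lambda"]), nonnegative=bool(un["nonnegative"]),
        max_iter=int(un["max_iter"]), tol=float(un["tol"]),
    )
    truth = pd.read_csv(data_dir / "truth.csv").set_index("cell_id")
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    ph = cfg["phenotype"]
    feature_frames = []
    map_paths = []
    for entry in cohort["fields"]:
        cube, truth_mask = load_field(data_dir, entry)
        maps = unmix_image(cube, library, ucfg)
        stem = Path(entry["image"]).stem
        mpath = maps_dir / f"{stem}_maps.tif"
        tifffile.imwrite(mpath, maps.maps.astype(np.float32), photometric="minisblack")
        tifffile.imwrite(maps_dir / f"{stem}_residual.tif", maps.residual.astype(np.float32))
        map_paths += [mpath, maps_dir / f"{stem}_residual.tif"]

        mask = segment_cells(maps, min_area=int(ph["min_area"]), threshold=ph["threshold"])
        matches = match_cells_to_truth(mask, truth_mask)
        id_to_class = {
            int(r.cell_id): str(truth.loc[int(r.truth_id), "class"])
            for r in matches.itertuples()
            if r.truth_id > 0
        }
        feats = extract_features(mask, maps, class_labels=id_to_class, source_image=entry["image"])
        feats = feats[feats["class"] != ""]  # drop unmatched segments
        feature_frames.append(feats)
    run_meta = {"lambda": ucfg.lambda_, "nonnegative": ucfg.nonnegative,
                "max_iter": ucfg.max_iter, "tol": ucfg.tol}
    (maps_dir / "unmix_meta.json").write_text(json.dumps(run_meta, sort_keys=True))
    record("unmix", t0, [maps_dir / "unmix_meta.json"])

    features = pd.concat(feature_frames, ignore_index=True)
    features["cell_id"] = np.arange(1, len(features) + 1)
    features_path = out / "features.csv"
    features[FEATURE_TABLE_COLUMNS].to_csv(features_path, index=False, float_format="%.8g")
    record("phenotype", t0, [features_path])

    # --- classify (full-data model) -----------------------------------------
    t0 = time.time()
    cl = cfg["classify"]
    A = cl["a"] if cl["a"] else None
    A_ortho = None if cl["a_ortho"] is None else int(cl["a_ortho"])
    model = fit_oplsda(
        autoscale(features[FEATURE_TABLE_COLUMNS[3:]].to_numpy(float)),
        features["class"].tolist(), A=A, A_ortho=A_ortho,
    )
    model_path = out / "model.json"
    save_model(model, model_path)
    record("classify", t0, [model_path])

    # --- evaluate ------------------------------------------------------------
    t0 = time.time()
    ev = cfg["evaluate"]
    cm_cv, met_cv = cross_validate(
        features, k=int(ev["k"]), A=A, A_ortho=A_ortho,
        seed=_stage_seed(seed, "evaluate"),
    )
    cm_fit, met_fit = resubstitution_metrics(features, A=A, A_ortho=A_ortho)
    metrics = {
        "n_cells": int(len(features)),
        "cross_validated": {
            "k": int(ev["k"]),
            "confusion": {"classes": cm_cv.classes, "counts": cm_cv.counts.tolist()},
            **met_cv.as_dict(),
        },
        "resubstitution": {
            "confusion": {"classes": cm_fit.classes, "counts": cm_fit.counts.tolist()},
            **met_fit.as_dict(),
        },
    }
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    cm_cv.to_frame().to_csv(out / "confusion_cv.csv")
    record("evaluate", t0, [metrics_path, out / "confusion_cv.csv"])

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
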