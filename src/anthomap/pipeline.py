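"""End-to-end study orchestration.

simulate -> calibrate -> segment -> preprocess -> select -> train ->
evaluate -> map, as one seed-controlled run. ``run_study`` executes a
configured subset of the selector x model grid and returns (optionally
writes) the evaluation table, per-scene map statistics and the model
bundles; ``grid`` is the full four-selector x two-model table.

All stage seeds derive from the master seed by fixed offsets, so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .bundle import ModelBundle
from .calibrate import calibrate, mean_spectrum, remove_stalk, sample_pixels, segment_fruit
from .mapping import map_statistics, predict_map, render_map
from .models import evaluate, fit_ga_elm, fit_ga_lssvm, split_dataset
from .preprocess import crop_window, snv, snv_array
from .sae import train_sae
from .selection import SelectionResult, cars_select, spa_select
from .types import SpectralMatrix

log = logging.getLogger("anthomap")

SELECTORS = ("none", "spa", "cars", "sae")
MODELS = ("elm", "lssvm")


@dataclass
class StudyConfig:
    """One run of the synthetic study pipeline."""

    n_per_variety: int = 90
    seed: int = 0
    shape: tuple[int, int] = (120, 120)
    n_pixels: int = 400  # ROI pixels sampled per scene for SAE training
    selectors: tuple[str, ...] = SELECTORS
    models: tuple[str, ...] = MODELS
    train_fraction: float = 0.7
    spa_max_vars: int = 25
    cars_runs: int = 50
    cars_cv_folds: int = 10
    sae_h: int = 13
    sae_epochs: int = 40
    sae_batch: int = 200
    sae_lr: float = 0.001
    sae_max_rows: int | None = None  # subsample of the pixel matrix; None = all
    elm_hidden: int = 90
    elm_generations: int = 300
    lssvm_generations: int = 200
    ga_population: int = 20
    map_model: str | None = None  # "selector-model" key; None = best by RMSEP
    out_dir: str | None = None

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def features_digest(self) -> str:
        """Cache key for the simulate+extract stages only."""
        payload = {k: getattr(self, k) for k in ("n_per_variety", "seed", "shape", "n_pixels")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class StudyFeatures:
    """Per-sample mean spectra, pooled pixel spectra and reference labels."""

    mean_spectra: SpectralMatrix  # n_samples x p, raw reflectance
    pixel_matrix: SpectralMatrix  # n_samples * n_pixels x p
    y: np.ndarray  # assay content, mg/g
    strata: np.ndarray  # variety_stage labels
    reference: pd.DataFrame


def extract_features(study: synthetic.Study, n_pixels: int = 400, seed: int = 0) -> StudyFeatures:
    """Calibrate and segment every scene; collect ROI mean spectra and
    ``n_pixels`` randomly sampled ROI pixel spectra per scene."""
    rng = np.random.default_rng(seed)
    means, pixels, pixel_ids = [], [], []
    t0 = time.time()
    for i, spec in enumerate(study.specs):
        raw, white, dark, _ = study.scene(i)
        refl = calibrate(raw, white, dark)
        roi = remove_stalk(refl, segment_fruit(refl))
        means.append(mean_spectrum(refl, roi).values[0])
        px = sample_pixels(refl, roi, n=n_pixels, seed=rng)
        pixels.append(px.values)
        pixel_ids.extend(f"{spec.sample_id}:{r}" for r in px.row_ids)
        if (i + 1) % 30 == 0:
            log.info("extracted %d/%d scenes (%.1fs)", i + 1, len(study), time.time() - t0)
    wl = study.wavelengths
    ref = study.reference
    return StudyFeatures(
        mean_spectra=SpectralMatrix(wl, np.vstack([m[None] for m in means]),
                                    row_ids=list(ref["sample_id"])),
        pixel_matrix=SpectralMatrix(wl, np.vstack(pixels), row_ids=pixel_ids),
        y=ref["content_mg_g"].to_numpy(),
        strata=(ref["variety"] + "_" + ref["stage"]).to_numpy(),
        reference=ref,
    )


def _fit_selector(name, X_train, y_train, pixel_snv, config: StudyConfig, seed: int):
    """Returns (SelectionResult | None, SaeModel | None)."""
    if name == "none":
        return None, None
    if name == "spa":
        return spa_select(X_train, y_train, max_vars=config.spa_max_vars, seed=seed), None
    if name == "cars":
        return cars_select(X_train, y_train, n_runs=config.cars_runs,
                           cv_folds=config.cars_cv_folds, seed=seed), None
    if name == "sae":
        rows = pixel_snv
        if config.sae_max_rows is not None and rows.shape[0] > config.sae_max_rows:
            keep = np.random.default_rng(seed).choice(
                rows.shape[0], config.sae_max_rows, replace=False
            )
            rows = rows[keep]
        model = train_sae(
            rows, h=config.sae_h, epochs=config.sae_epochs,
            batch=config.sae_batch, lr=config.sae_lr, seed=seed,
        )
        return None, model
    raise ValueError(f"unknown selector {name!r}")


def run_study(config: StudyConfig) -> dict:
    """Execute the configured pipeline; returns a results dict with the
    evaluation table, bundles, selection results and map statistics."""
    t_start = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1-2: simulate + extract (cached if a run dir is given)
    cache = out_dir / f"features_{config.features_digest()}.npz" if out_dir else None
    study = synthetic.generate_study(config.n_per_variety, config.seed, config.shape)
    if cache and cache.exists():
        log.info("resuming: loading cached features %s", cache.name)
        z = np.load(cache, allow_pickle=False)
        feats = StudyFeatures(
            mean_spectra=SpectralMatrix(z["wl"], z["means"], list(study.reference["sample_id"])),
            pixel_matrix=SpectralMatrix(z["wl"], z["pixels"]),
            y=z["y"],
            strata=z["strata"].astype(str),
            reference=study.reference,
        )
    else:
        feats = extract_features(study, n_pixels=config.n_pixels, seed=config.seed + 1)
        if cache:
            np.savez_compressed(
                cache, wl=feats.mean_spectra.wavelengths,
                means=feats.mean_spectra.values,
                pixels=feats.pixel_matrix.values.astype(np.float32),
                y=feats.y, strata=feats.strata.astype("U"),
            )
    log.info("features ready: %d samples, %d pixel spectra (%.1fs)",
             feats.mean_spectra.n, feats.pixel_matrix.n, time.time() - t_start)

    # -- stage 3: preprocess
    X_snv = snv(crop_window(feats.mean_spectra))
    wl = X_snv.wavelengths
    pixel_snv = snv_array(crop_window(feats.pixel_matrix).values)

    # -- stage 4: split
    train_idx, test_idx = split_dataset(
        X_snv.values, feats.y, strata=feats.strata,
        train_fraction=config.train_fraction, seed=config.seed + 2,
    )
    Xtr, Xte = X_snv.values[train_idx], X_snv.values[test_idx]
    ytr, yte = feats.y[train_idx], feats.y[test_idx]

    # -- stage 5-6: selector x model grid
    results, bundles, selections, cv_rmse = {}, {}, {}, {}
    sel_cache: dict[str, tuple] = {}
    for sel_name in config.selectors:
        if sel_name not in sel_cache:
            t0 = time.time()
            sel_cache[sel_name] = _fit_selector(
                sel_name, Xtr, ytr, pixel_snv, config, config.seed + 3
            )
            log.info("selector %s ready (%.1fs)", sel_name, time.time() - t0)
        sel_res, sae_model = sel_cache[sel_name]
        if sel_res is not None:
            selections[sel_name] = sel_res
        if sel_name in ("spa", "cars"):
            ftr, fte = Xtr[:, sel_res.indices], Xte[:, sel_res.indices]
        elif sel_name == "sae":
            ftr, fte = sae_model.encode(Xtr), sae_model.encode(Xte)
        else:
            ftr, fte = Xtr, Xte
        for model_name in config.models:
            t0 = time.time()
            if model_name == "elm":
                model, path = fit_ga_elm(
                    ftr, ytr, n_hidden=config.elm_hidden,
                    generations=config.elm_generations,
                    population=config.ga_population, seed=config.seed + 4,
                )
            else:
                model, path = fit_ga_lssvm(
                    ftr, ytr, generations=config.lssvm_generations,
                    population=config.ga_population, seed=config.seed + 4,
                )
            report = evaluate(model, ftr, ytr, fte, yte)
            key = f"{sel_name}-{model_name}"
            results[key] = report
            cv_rmse[key] = path[-1] if path else float("nan")
            bundles[key] = ModelBundle(
                wavelengths=wl, model=model, selector_type=sel_name,
                model_type=model_name,
                indices=None if sel_res is None else sel_res.indices,
                sae_model=sae_model,
                meta={"config_digest": config.digest(), "seed": config.seed,
                      "n_features": int(ftr.shape[1]), "ga_path_final": path[-1] if path else None},
            )
            log.info("%s: R2p=%.3f RMSEP=%.3f (%.1fs)", key,
                     report.r2_test, report.rmse_test, time.time() - t0)

    # -- stage 7: per-pixel mapping on one scene per variety x stage.
    # The deep-feature kernel bundle is the designated mapping model when
    # present: the encoder was trained on pixel spectra (so single-pixel
    # inputs are in-distribution) and the RBF machine extends the
    # mean-spectrum calibration smoothly, where an interpolating ELM
    # output layer is unbounded off the training manifold.
    if config.map_model:
        map_key = config.map_model
    elif "sae-lssvm" in results:
        map_key = "sae-lssvm"
    elif "sae-elm" in results:
        map_key = "sae-elm"
    else:
        map_key = min(results, key=lambda k: results[k].rmse_test)
    map_bundle = bundles[map_key]
    map_stats = []
    seen = set()
    for i, spec in enumerate(study.specs):
        cell = (spec.variety, spec.stage)
        if cell in seen:
            continue
        seen.add(cell)
        raw, white, dark, truth = study.scene(i)
        refl = calibrate(raw, white, dark)
        roi = remove_stalk(refl, segment_fruit(refl))
        pm = predict_map(refl, roi, map_bundle)
        stats = map_statistics(pm, truth)
        stats.update(sample_id=spec.sample_id, variety=spec.variety, stage=spec.stage,
                     mean_predicted=pm.mean_content, true_mean=truth.sample_mean_content)
        map_stats.append(stats)
        if out_dir:
            render_map(pm, out_dir / f"map_{spec.sample_id}.png", scale=(0.0, 4.5),
                       title=f"{spec.variety} {spec.stage}")

    out = {
        "config": asdict(config),
        "eval": {k: dict(r.as_dict(), cv_rmse=cv_rmse[k]) for k, r in results.items()},
        "reports": results,
        "bundles": bundles,
        "selections": selections,
        "map_model": map_key,
        "map_stats": map_stats,
        "n_pixel_rows": int(feats.pixel_matrix.n),
        "split": {"train": train_idx.tolist(), "test": test_idx.tolist()},
        "runtime_s": time.time() - t_start,
    }
    if out_dir:
        manifest = {
            "config": asdict(config), "digest": config.digest(),
            "eval": out["eval"], "map_model": map_key,
            "map_stats": map_stats, "runtime_s": out["runtime_s"],
            "stage_seeds": {"study": config.seed, "extract": config.seed + 1,
                            "split": config.seed + 2, "selector": config.seed + 3,
                            "ga": config.seed + 4},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        pd.DataFrame({k: v for k, v in out["eval"].items()}).T.to_csv(out_dir / "eval_grid.csv")
        for key, b in bundles.items():
            b.save(out_dir / f"bundle_{key}.h5")
    return out


def grid(config: StudyConfig | None = None, **overrides) -> dict:
    """The full selector x model table (the study's model-comparison
    analogue). Accepts field overrides of the default config."""
    base = asdict(config) if config else {}
    base.update(overrides)
    base["selectors"] = tuple(base.get("selectors", SELECTORS))
    base["models"] = tuple(base.get("models", MODELS))
    return run_study(StudyConfig(**base))
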