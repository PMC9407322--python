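"""End-to-end experiment orchestration.

Flow: simulate (or load a CSV) -> crop -> stratified split -> MSC (reference
from the training set) -> oversample the training set -> wavelength
selection on the (balanced) training set -> tune the classifier -> train ->
evaluate on the untouched test set.  Every stage receives its own seed
derived from the master seed through a fixed counter scheme, so switching
one stage on or off never shifts another stage's randomness.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import joblib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import evaluate, models, oversample as ovs, preprocess, varselect
from .dataset import SimConfig, SpectraSet, generate_spectra, stratified_split
from .evaluate import MetricsReport
from .optimize import RsaParams

logger = logging.getLogger(__name__)

# fixed stage indices of the master-seed derivation scheme
_STAGE_KEYS = {
    "simulate": 0,
    "split": 1,
    "oversample": 2,
    "varselect": 3,
    "tune": 4,
    "model": 5,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable under stage toggling)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and echoes config."""


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    class_counts: tuple[int, int, int] = (200, 302, 98)
    n_bands: int = 934
    band_range: tuple[float, float] = (400.0, 1100.0)
    scatter_mult: float = 0.15
    scatter_add: float = 0.02
    noise_sd: tuple[float, float, float] = (0.010, 0.018, 0.055)


class OversampleSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["none", "ros", "smote", "blsmote", "adasyn"] = "blsmote"
    k_neighbors: int = 5
    m_neighbors: int = 5


class VarselectSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["none", "cars", "spa"] = "cars"
    runs: int = 50
    folds: int = 5
    max_components: int = 10
    n_min: int = 5
    n_max: int = 20


class OptimizerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["mrsa", "rsa", "ga", "pso", "grid"] = "mrsa"
    n_candidates: int = 20
    max_iters: int = 50
    folds: int = 5
    bounds: tuple[float, float] = models.PARAM_BOUNDS
    # grid mode only
    c_grid: Optional[list[float]] = None
    g_grid: Optional[list[float]] = None


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulation: Optional[SimulationSettings] = Field(default_factory=SimulationSettings)
    input_csv: Optional[str] = None
    crop: tuple[float, float] = (400.0, 1100.0)
    msc: bool = True
    train_fraction: float = 0.7
    oversample: OversampleSettings = Field(default_factory=OversampleSettings)
    varselect: VarselectSettings = Field(default_factory=VarselectSettings)
    model: Literal["svm", "plsda"] = "svm"
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check_source(self):
        if self.simulation is None and self.input_csv is None:
            raise ValueError("either simulation settings or input_csv must be given")
        return self

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw or {})


def _log_stage(name: str, seed, t0: float, **shapes) -> None:
    extras = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s seed=%s elapsed=%.2fs %s", name, seed, time.time() - t0, extras)


def _stage(name: str, cfg: ExperimentConfig):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(
                    f"stage {name!r} failed: {exc}\nconfig: "
                    f"{cfg.model_dump_json()}"
                ) from exc
            return False

    return _Ctx()


def prepare_data(cfg: ExperimentConfig):
    """Run every stage up to (and including) wavelength selection.

    Returns a dict with train/test matrices ready for model tuning; the test
    reflectance is only transformed with statistics learned on training data.
    """
    with _stage("simulate", cfg):
        t0 = time.time()
        if cfg.input_csv is not None:
            data = SpectraSet.from_csv(cfg.input_csv)
            sim_seed = None
        else:
            sim_seed = derive_seed(cfg.seed, "simulate")
            sim = cfg.simulation
            data = generate_spectra(SimConfig(
                class_counts=sim.class_counts, n_bands=sim.n_bands,
                band_range=sim.band_range, scatter_mult=sim.scatter_mult,
                scatter_add=sim.scatter_add, noise_sd=sim.noise_sd,
                seed=sim_seed,
            ))
        _log_stage("simulate", sim_seed, t0, n=data.n_samples, bands=data.n_bands)

    with _stage("crop", cfg):
        t0 = time.time()
        data = preprocess.crop_wavelengths(data, *cfg.crop)
        _log_stage("crop", None, t0, bands=data.n_bands)

    with _stage("split", cfg):
        t0 = time.time()
        split_seed = derive_seed(cfg.seed, "split")
        train, test = stratified_split(data, cfg.train_fraction, seed=split_seed)
        _log_stage("split", split_seed, t0, train=train.n_samples, test=test.n_samples)

    msc_ref = None
    if cfg.msc:
        with _stage("msc", cfg):
            t0 = time.time()
            msc_ref = preprocess.msc_fit(train)
            train = preprocess.msc_apply(train, msc_ref)
            test = preprocess.msc_apply(test, msc_ref)
            _log_stage("msc", None, t0)

    with _stage("oversample", cfg):
        t0 = time.time()
        ov_seed = derive_seed(cfg.seed, "oversample")
        train_bal = ovs.oversample(train, ovs.OversampleConfig(
            method=cfg.oversample.method,
            k_neighbors=cfg.oversample.k_neighbors,
            m_neighbors=cfg.oversample.m_neighbors,
            seed=ov_seed,
        ))
        _log_stage("oversample", ov_seed, t0, balanced=train_bal.n_samples)

    selection = None
    band_idx = np.arange(train_bal.n_bands)
    if cfg.varselect.method != "none":
        with _stage("varselect", cfg):
            t0 = time.time()
            vs_seed = derive_seed(cfg.seed, "varselect")
            vs = cfg.varselect
            if vs.method == "cars":
                selection = varselect.cars_select(
                    train_bal.reflectance, train_bal.labels,
                    runs=vs.runs, folds=vs.folds, seed=vs_seed,
                    max_components=vs.max_components,
                )
            else:
                selection = varselect.spa_select(
                    train_bal.reflectance, train_bal.labels,
                    n_min=vs.n_min, n_max=vs.n_max, folds=vs.folds, seed=vs_seed,
                )
            band_idx = selection.selected_indices
            _log_stage("varselect", vs_seed, t0, bands=band_idx.size)

    return {
        "train": train,
        "train_balanced": train_bal,
        "test": test,
        "band_indices": band_idx,
        "selection": selection,
        "msc_reference": msc_ref,
        "wavelengths": train_bal.wavelengths[band_idx],
    }


def _tune_and_train(cfg: ExperimentConfig, prepared: dict, method: str | None = None):
    """Tune (if applicable) and train the configured model on prepared data."""
    train_bal = prepared["train_balanced"]
    band_idx = prepared["band_indices"]
    X = train_bal.reflectance[:, band_idx]
    y = train_bal.labels.astype(str)
    opt = cfg.optimizer
    tune_seed = derive_seed(cfg.seed, "tune")

    if cfg.model == "plsda":
        trained = models.plsda_train(X, y, folds=opt.folds, seed=tune_seed)
        trained.feature_indices = band_idx
        return trained, None, None

    if (method or opt.method) == "grid":
        c_grid = opt.c_grid or list(2.0 ** np.arange(-2, 9))
        g_grid = opt.g_grid or list(2.0 ** np.arange(-2, 9))
        params = models.grid_search_cg(X, y, c_grid, g_grid,
                                       folds=opt.folds, seed=tune_seed)
        result = None
    else:
        rsa = RsaParams(n_candidates=opt.n_candidates, max_iters=opt.max_iters,
                        seed=tune_seed)
        params, result = models.tune_svm(
            X, y, optimizer=method or opt.method, params=rsa,
            folds=opt.folds, bounds=opt.bounds,
        )
    trained = models.svm_train(X, y, params, feature_indices=band_idx)
    return trained, params, result


def run_experiment(cfg: ExperimentConfig) -> tuple[MetricsReport, dict]:
    """Execute the full flow; returns the test-set report and artifacts dict."""
    prepared = prepare_data(cfg)

    with _stage("tune", cfg):
        t0 = time.time()
        trained, params, result = _tune_and_train(cfg, prepared)
        _log_stage("tune", derive_seed(cfg.seed, "tune"), t0,
                   params=None if params is None else (params.c, params.g))

    with _stage("evaluate", cfg):
        t0 = time.time()
        test = prepared["test"]
        y_pred = trained.predict(test.reflectance[:, prepared["band_indices"]])
        cm = evaluate.confusion(test.labels.astype(str), y_pred)
        rep = evaluate.report(cm)
        _log_stage("evaluate", None, t0, accuracy=f"{rep.accuracy:.4f}")

    artifacts = {
        "prepared": prepared,
        "trained": trained,
        "svm_params": params,
        "optimizer_result": result,
        "report": rep,
    }

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        prepared["train_balanced"].to_csv(out / "train_balanced.csv")
        prepared["test"].to_csv(out / "test.csv")
        with open(out / "bands.json", "w") as fh:
            json.dump({
                "indices": prepared["band_indices"].tolist(),
                "wavelengths": prepared["wavelengths"].tolist(),
            }, fh, indent=2)
        rep.to_json(out / "metrics.json")
        if result is not None:
            pd.DataFrame({
                "iteration": np.arange(1, result.trace.size + 1),
                "best_fitness": result.trace,
            }).to_csv(out / "trace.csv", index=False)
        sidecar = {
            "family": trained.family,
            "classes": [str(c) for c in trained.classes],
            "feature_indices": prepared["band_indices"].tolist(),
        }
        if params is not None:
            sidecar["params"] = {"c": params.c, "g": params.g}
        with open(out / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        joblib.dump(trained.model, out / "model.bin")

    return rep, artifacts


def compare_optimizers(cfg: ExperimentConfig, methods: list[str]) -> pd.DataFrame:
    """Tune/train/evaluate one model per optimizer on identical data and folds.

    Emits one row per method: method, c, g, accuracy, recall, precision,
    f1, kappa (percent scale, 2 dp).
    """
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    prepared = prepare_data(cfg)
    rows = []
    for method in methods:
        trained, params, result = _tune_and_train(cfg, prepared, method=method)
        test = prepared["test"]
        y_pred = trained.predict(test.reflectance[:, prepared["band_indices"]])
        rep = evaluate.report(evaluate.confusion(test.labels.astype(str), y_pred))
        rows.append({
            "method": method,
            "c": None if params is None else round(params.c, 2),
            "g": None if params is None else round(params.g, 2),
            "accuracy": evaluate.round_percent(rep.accuracy),
            "recall": evaluate.round_percent(rep.macro_recall),
            "precision": evaluate.round_percent(rep.macro_precision),
            "f1": evaluate.round_percent(rep.macro_f1),
            "kappa": evaluate.round_percent(rep.kappa_paper),
            "cv_fitness": None if result is None else result.best_fitness,
        })
    df = pd.DataFrame(rows)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "comparison.csv", index=False)
    return df
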