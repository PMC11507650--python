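"""End-to-end origin-classification pipeline.

Stage order: load/generate -> (optional per-class subsampling) -> SPXY
split on the raw spectra -> pretreatment (MSC reference fit on training
rows only by default) -> wavelength selection on training rows ->
classifier training -> one-vs-rest evaluation on the held-out test rows.
Every stage draws its randomness from the single pipeline seed, so a
full run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import read_spectra_csv
from .metrics import ClassificationReport, evaluate
from .models import ClassifierSpec, grid_search, predict, train_classifier
from .partition import PartitionResult, spxy_split
from .preprocess import MSCReference, fit_msc_reference, msc, savitzky_golay, snv
from .select import SelectionResult, boss_select, cars_select, encode_labels, uve_select
from .synthetic import DEFAULT_CLASS_NAMES, SpectraSet, SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ablate_dataset_size"]

logger = logging.getLogger("crabspec")

_PRETREATMENTS = ("none", "msc", "snv", "sg")
_SELECTIONS = ("none", "cars", "boss", "uve")
_MODELS = ("svm", "bp", "cnn")


@dataclass
class PipelineConfig:
    """Configuration of one factorial cell (pretreat x select x model)."""

    synthetic: SyntheticConfig | None = None
    csv_path: str | None = None
    pretreatment: str = "msc"
    sg_window: int = 15
    sg_polyorder: int = 3
    selection: str = "cars"
    selection_params: Mapping = field(default_factory=dict)
    model: str = "svm"
    model_hyperparameters: Mapping = field(default_factory=dict)
    grid_search: bool = False
    grids: Mapping[str, Sequence] = field(default_factory=dict)
    n_train: int | None = None  # default: ~79.5% of samples (310 of 390)
    folds: int = 5
    fit_on: str = "train"  # "train" (leakage-free) | "all" (strict replication)
    subsample_per_class: int | None = None
    class_order: Sequence[str] = DEFAULT_CLASS_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pretreatment not in _PRETREATMENTS:
            raise ValueError(f"pretreatment must be one of {_PRETREATMENTS}")
        if self.selection not in _SELECTIONS:
            raise ValueError(f"selection must be one of {_SELECTIONS}")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.fit_on not in ("train", "all"):
            raise ValueError("fit_on must be 'train' or 'all'")
        if self.synthetic is None and self.csv_path is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


@dataclass
class PipelineResult:
    """Bundle of everything one pipeline run produced."""

    config: PipelineConfig
    report: ClassificationReport
    partition: PartitionResult
    selection: SelectionResult | None
    msc_reference: MSCReference | None
    classifier_spec: ClassifierSpec
    selected_wavenumbers: np.ndarray
    timings: dict[str, float]

    def to_dict(self, include_timings: bool = True) -> dict:
        cfg = self.config
        sel = None
        if self.selection is not None:
            sel = {
                "method": self.selection.method,
                "selected_idx": self.selection.selected_idx.tolist(),
                "selected_wavenumbers": self.selected_wavenumbers.tolist(),
                "n_selected": int(self.selection.selected_idx.size),
                "rmsecv_trajectory": self.selection.rmsecv_trajectory.tolist(),
                "best_iteration": int(self.selection.best_iteration),
            }
        out = {
            "config": {
                "pretreatment": cfg.pretreatment,
                "selection": cfg.selection,
                "model": cfg.model,
                "n_train": cfg.n_train,
                "fit_on": cfg.fit_on,
                "subsample_per_class": cfg.subsample_per_class,
                "seed": cfg.seed,
                "class_order": list(cfg.class_order),
            },
            "partition": {
                "train_idx": self.partition.train_idx.tolist(),
                "test_idx": self.partition.test_idx.tolist(),
            },
            "selection": sel,
            "classifier": {
                "family": self.classifier_spec.family,
                "hyperparameters": dict(self.classifier_spec.hyperparameters),
            },
            "metrics": self.report.to_dict(),
        }
        if include_timings:
            out["timings"] = self.timings
        return out

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _load(config: PipelineConfig) -> SpectraSet:
    if config.csv_path is not None:
        return read_spectra_csv(config.csv_path)
    return generate_dataset(config.synthetic)


def _subsample(spectra: SpectraSet, per_class: int, seed: int) -> SpectraSet:
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in np.unique(spectra.labels):
        rows = np.nonzero(spectra.labels == cls)[0]
        if per_class > rows.size:
            raise ValueError(
                f"subsample_per_class={per_class} exceeds the {rows.size} samples of class {cls!r}"
            )
        chosen = rows if per_class == rows.size else rng.choice(rows, per_class, replace=False)
        keep.extend(np.sort(chosen).tolist())
    return spectra.subset(sorted(keep))


def _pretreat(config: PipelineConfig, X_fit: np.ndarray, X_apply: np.ndarray, sample_ids):
    """Fit any pretreatment state on X_fit; transform X_apply."""
    if config.pretreatment == "none":
        return X_apply, None
    if config.pretreatment == "msc":
        ref = fit_msc_reference(X_fit)
        return msc(X_apply, ref), ref
    if config.pretreatment == "snv":
        return snv(X_apply, sample_ids), None
    return savitzky_golay(X_apply, config.sg_window, config.sg_polyorder), None


def _select(config: PipelineConfig, X_tr: np.ndarray, y_tr: np.ndarray) -> SelectionResult | None:
    params = dict(config.selection_params)
    params.setdefault("folds", config.folds)
    params.setdefault("seed", config.seed)
    if config.selection == "none":
        return None
    if config.selection == "cars":
        return cars_select(X_tr, y_tr, **params)
    if config.selection == "boss":
        return boss_select(X_tr, y_tr, **params)
    return uve_select(X_tr, y_tr, **params)


def run_pipeline(config: PipelineConfig, spectra: SpectraSet | None = None) -> PipelineResult:
    """Execute the full pipeline for one configuration."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    data = spectra if spectra is not None else _load(config)
    if config.subsample_per_class is not None:
        data = _subsample(data, config.subsample_per_class, config.seed)
    timings["load"] = time.perf_counter() - t0
    logger.info("data: %d samples x %d wavelengths (site=%s)", data.n_samples, len(data.grid), data.site)

    n = data.n_samples
    n_train = config.n_train if config.n_train is not None else int(round(n * 310 / 390))
    if not 2 <= n_train < n:
        raise ValueError(f"n_train={n_train} out of range for {n} samples")

    t = time.perf_counter()
    part = spxy_split(data.absorbance, data.labels, n_train)
    timings["split"] = time.perf_counter() - t
    logger.info("SPXY split: %d train / %d test", part.train_idx.size, part.test_idx.size)

    t = time.perf_counter()
    X_fit = data.absorbance[part.train_idx] if config.fit_on == "train" else data.absorbance
    X_all, msc_ref = _pretreat(config, X_fit, data.absorbance, data.sample_ids)
    timings["pretreat"] = time.perf_counter() - t

    X_tr, X_te = X_all[part.train_idx], X_all[part.test_idx]
    labels_tr = data.labels[part.train_idx]
    labels_te = data.labels[part.test_idx]
    y_tr = encode_labels(labels_tr, config.class_order)

    t = time.perf_counter()
    if config.fit_on == "train":
        selection = _select(config, X_tr, y_tr)
    else:
        selection = _select(config, X_all, encode_labels(data.labels, config.class_order))
    timings["select"] = time.perf_counter() - t
    if selection is not None:
        sel_idx = selection.selected_idx
        logger.info("%s selected %d wavelengths", selection.method, sel_idx.size)
    else:
        sel_idx = np.arange(X_tr.shape[1])
    wavenumbers = data.grid.values[sel_idx]

    t = time.perf_counter()
    family = config.model.upper()
    if config.grid_search and config.grids:
        spec = grid_search(
            family, config.grids, X_tr[:, sel_idx], labels_tr,
            folds=config.folds, seed=config.seed,
        )
    else:
        spec = ClassifierSpec(family=family, hyperparameters=dict(config.model_hyperparameters), seed=config.seed)
    clf = train_classifier(X_tr[:, sel_idx], labels_tr, spec, class_order=config.class_order)
    timings["train"] = time.perf_counter() - t

    t = time.perf_counter()
    preds = predict(clf, X_te[:, sel_idx])
    report = evaluate(labels_te, preds, config.class_order)
    timings["evaluate"] = time.perf_counter() - t
    logger.info("test accuracy: %.2f%%", 100 * report.acc)

    return PipelineResult(
        config=config,
        report=report,
        partition=part,
        selection=selection,
        msc_reference=msc_ref,
        classifier_spec=spec,
        selected_wavenumbers=wavenumbers,
        timings=timings,
    )


def ablate_dataset_size(
    config: PipelineConfig, sizes: Sequence[int], spectra: SpectraSet | None = None
) -> dict[int, PipelineResult]:
    """Re-run the pipeline on seeded per-class subsamples of the dataset."""
    data = spectra if spectra is not None else _load(config)
    results: dict[int, PipelineResult] = {}
    for size in sizes:
        cfg = replace(config, subsample_per_class=int(size))
        results[int(size)] = run_pipeline(cfg, spectra=data)
    return results
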