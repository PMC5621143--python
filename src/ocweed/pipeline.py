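"""End-to-end orchestration: scene -> features -> one-class training ->
whole-scene classification -> accuracy assessment.

The protocol mirrors the calibration design the detectors are built for:
a balanced two-class sample (default 1434 pixels per class) is drawn from
the labelled scene, split 70/30 stratified per class, features are z-scored
by the training *target* rows, and the chosen detector is fitted on those
target rows only — the "other vegetation" training rows are never seen by
any detector (one-class discipline).  Evaluation uses the held-out 30%.

Model files are versioned JSON carrying the detector parameters, the
standardization map and provenance (seed, config digest), so training runs
with identical configs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ocweed import autoencoder as ae_mod
from ocweed import oc_pca, oc_som, svdd as svdd_mod
from ocweed.errors import ConfigurationError, FormatError, InputError
from ocweed.evaluation import ConfusionTable, MetricsReport, confusion, metrics
from ocweed.features import (
    FeatureTable, SplitSpec, Standardization,
    apply_standardization, assemble_features, balanced_sample, split,
    standardize, DEFAULT_PER_CLASS,
)
from ocweed.scene_sim import (
    LabelRaster, MultibandScene, NODATA, OTHER, TARGET,
    SceneConfig, read_labels, read_scene, simulate_scene, write_labels,
)

MODEL_FORMAT = "ocweed-model"
MODEL_VERSION = 1

DETECTOR_ALIASES = {
    "ocsvm": "ocsvm", "svdd": "ocsvm",
    "ocsom": "ocsom", "som": "ocsom",
    "autoencoder": "autoencoder", "ae": "autoencoder",
    "ocpca": "ocpca", "pca": "ocpca",
}

_CONFIG_TYPES = {
    "ocsvm": svdd_mod.SvddConfig,
    "ocsom": oc_som.SomConfig,
    "autoencoder": ae_mod.AeConfig,
    "ocpca": oc_pca.PcaConfig,
}

_MODEL_TYPES = {
    "ocsvm": svdd_mod.SvddModel,
    "ocsom": oc_som.SomModel,
    "autoencoder": ae_mod.AeModel,
    "ocpca": oc_pca.PcaModel,
}


def canonical_detector(name: str) -> str:
    key = str(name).lower()
    if key not in DETECTOR_ALIASES:
        raise ConfigurationError(
            f"unknown detector {name!r}; choose from ocsvm, ocsom, autoencoder, ocpca"
        )
    return DETECTOR_ALIASES[key]


def fit_detector(name: str, train_targets: FeatureTable, config=None):
    """Fit one detector on (standardized) target-class training rows."""
    name = canonical_detector(name)
    if config is None:
        config = _CONFIG_TYPES[name]()
    if name == "ocsvm":
        return svdd_mod.fit_svdd(train_targets, config)
    if name == "ocsom":
        model = oc_som.train_som(train_targets, config)
        return oc_som.calibrate_som(model, train_targets)
    if name == "autoencoder":
        return ae_mod.fit_ae(train_targets, config)
    return oc_pca.fit_pca(train_targets, config)


def classify_detector(name: str, model, table: FeatureTable) -> np.ndarray:
    name = canonical_detector(name)
    if name == "ocsvm":
        return svdd_mod.classify_svdd(model, table)
    if name == "ocsom":
        return oc_som.classify_som(model, table)
    if name == "autoencoder":
        return ae_mod.classify_ae(model, table)
    return oc_pca.classify_pca(model, table)


@dataclasses.dataclass
class RunConfig:
    """One training run: detector choice, sampling/split protocol, paths."""

    detector: str = "ocsvm"
    detector_config: Optional[object] = None
    split: SplitSpec = None
    per_class: int = DEFAULT_PER_CLASS
    seed: int = 0
    scene_path: Optional[str] = None
    labels_path: Optional[str] = None
    model_path: Optional[str] = None
    output_path: Optional[str] = None

    def __post_init__(self):
        self.detector = canonical_detector(self.detector)
        if self.split is None:
            self.split = SplitSpec(seed=self.seed)
        if self.detector_config is not None:
            expected = _CONFIG_TYPES[self.detector]
            if not isinstance(self.detector_config, expected):
                raise ConfigurationError(
                    f"detector_config must be a {expected.__name__} "
                    f"for detector {self.detector!r}"
                )


def _config_digest(config: RunConfig) -> str:
    det = config.detector_config
    payload = {
        "detector": config.detector,
        "detector_config": None if det is None else dataclasses.asdict(det),
        "per_class": config.per_class,
        "seed": config.seed,
        "split": dataclasses.asdict(config.split),
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_model(model, detector: str, path, standardization: Standardization,
               provenance: Optional[dict] = None) -> None:
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "detector": canonical_detector(detector),
        "standardization": standardization.to_dict(),
        "standardization_digest": standardization.digest(),
        "model": model.to_dict(),
        "provenance": provenance or {},
    }
    _atomic_write_text(Path(path), json.dumps(payload, sort_keys=True))


def load_model(path):
    """Returns (detector name, model object, standardization)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: cannot read model file ({exc})") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not an {MODEL_FORMAT} file")
    name = canonical_detector(payload["detector"])
    st = Standardization.from_dict(payload["standardization"])
    model = _MODEL_TYPES[name].from_dict(payload["model"])
    model.standardization = st
    return name, model, st


def prepare_calibration(
    features: FeatureTable, per_class: int, seed: int, split_spec: SplitSpec
) -> dict:
    """Balanced sample -> stratified split -> standardize on train targets."""
    sample = balanced_sample(features, per_class, seed)
    train, test = split(sample, split_spec)
    st = standardize(train.class_rows(TARGET))
    return {
        "sample": sample,
        "train": apply_standardization(train, st),
        "test": apply_standardization(test, st),
        "standardization": st,
    }


def train_on_scene(
    scene: MultibandScene, labels: LabelRaster, config: RunConfig
) -> dict:
    """In-memory training: returns model, standardization, tables, report."""
    features = assemble_features(scene, labels)
    cal = prepare_calibration(features, config.per_class, config.seed, config.split)
    train_targets = cal["train"].class_rows(TARGET)
    model = fit_detector(config.detector, train_targets, config.detector_config)
    rejected = classify_detector(config.detector, model, train_targets)
    report = {
        "detector": config.detector,
        "n_pixels": len(features),
        "n_sample": len(cal["sample"]),
        "n_train": len(cal["train"]),
        "n_test": len(cal["test"]),
        "n_train_targets": len(train_targets),
        "training_rejection_rate": float(np.mean(rejected == OTHER)),
        "config_digest": _config_digest(config),
        "seed": config.seed,
    }
    return {"model": model, "standardization": cal["standardization"],
            "train": cal["train"], "test": cal["test"], "report": report}


def run_train(config: RunConfig) -> dict:
    """File-based training stage: reads scene + labels, writes the model."""
    for role, p in (("scene", config.scene_path), ("labels", config.labels_path)):
        if p is None or not Path(p).exists():
            raise InputError(f"train stage: {role} path {p!r} does not exist")
    scene = read_scene(config.scene_path)
    labels = read_labels(config.labels_path)
    result = train_on_scene(scene, labels, config)
    if config.model_path:
        save_model(
            result["model"], config.detector, config.model_path,
            result["standardization"], provenance=result["report"],
        )
    return result


def classify_scene(
    detector: str, model, standardization: Standardization,
    scene: MultibandScene,
) -> LabelRaster:
    """Classify every valid pixel of a scene; nodata pixels get code 0.

    Feature scoring is chunked inside the detectors, so mosaics of ~10^6
    pixels are processed within modest memory.
    """
    features = assemble_features(scene)
    table = apply_standardization(features, standardization)
    codes = classify_detector(detector, model, table)
    out = np.zeros(scene.shape, dtype=np.uint8)
    idx = features.pixel_index
    out[idx[:, 0], idx[:, 1]] = codes
    return LabelRaster(out)


def run_classify(model_path, scene_path, output_path=None) -> LabelRaster:
    """File-based classification stage: model JSON + scene TIFF -> label raster."""
    detector, model, st = load_model(model_path)
    scene = read_scene(scene_path) if not isinstance(scene_path, MultibandScene) \
        else scene_path
    predicted = classify_scene(detector, model, st, scene)
    if output_path:
        write_labels(predicted, output_path)
    return predicted


def run_evaluate(
    predicted: LabelRaster, truth: LabelRaster,
    test_mask: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Confusion-table metrics over labelled pixels (optionally masked).

    When ``test_mask`` is given, only those pixels enter the table —
    reproducing a held-out-pixels validation protocol; otherwise every pixel
    labelled in the truth raster is scored.
    """
    if predicted.shape != truth.shape:
        raise InputError(
            f"prediction shape {predicted.shape} != truth shape {truth.shape}"
        )
    keep = (truth.labels != NODATA) & (predicted.labels != NODATA)
    if test_mask is not None:
        test_mask = np.asarray(test_mask, dtype=bool)
        if test_mask.shape != truth.shape:
            raise InputError("test mask shape does not match rasters")
        keep &= test_mask
    table = confusion(truth.labels[keep], predicted.labels[keep])
    return metrics(table)


def evaluate_on_table(detector: str, model, test: FeatureTable) -> MetricsReport:
    """Metrics on a held-out labelled feature table (the 30% protocol)."""
    codes = classify_detector(detector, model, test)
    return metrics(confusion(test.labels, codes))


def benchmark(
    scene_config: Optional[SceneConfig] = None,
    per_class: int = DEFAULT_PER_CLASS,
    split_spec: Optional[SplitSpec] = None,
    detector_configs: Optional[dict] = None,
    seed: int = 0,
    detectors: tuple = ("ocsvm", "ocsom", "autoencoder", "ocpca"),
) -> dict:
    """Train and evaluate all detectors on one synthetic scene.

    Returns {detector: {"metrics": MetricsReport, "report": dict}} using the
    held-out 30% of the balanced calibration sample.
    """
    scene_config = scene_config or SceneConfig(seed=seed)
    split_spec = split_spec or SplitSpec(seed=seed)
    detector_configs = detector_configs or {}
    scene, labels = simulate_scene(scene_config)
    features = assemble_features(scene, labels)
    cal = prepare_calibration(features, per_class, seed, split_spec)
    train_targets = cal["train"].class_rows(TARGET)
    results = {}
    for name in detectors:
        name = canonical_detector(name)
        model = fit_detector(name, train_targets, detector_configs.get(name))
        results[name] = {
            "metrics": evaluate_on_table(name, model, cal["test"]),
            "model": model,
        }
    return results


def benchmark_table(results: dict) -> str:
    """Aligned text report across detectors, one contingency block each."""
    titles = {"ocsvm": "OC-SVM", "ocsom": "OC-SOM",
              "autoencoder": "Autoencoder", "ocpca": "OC-PCA"}
    blocks = [res["metrics"].to_text(titles.get(name, name))
              for name, res in results.items()]
    return "\n\n".join(blocks)
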