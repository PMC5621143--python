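"""Per-pixel feature extraction and calibration-set handling.

Each pixel is described by a 4-vector: green, red and NIR reflectance plus a
texture band computed as the local variance of NIR in a 7 x 7 moving window.
From a labelled scene a balanced two-class calibration sample is drawn
(1434 pixels per class by default, 2868 in total) and split 70/30 into
training and test sets, stratified per class.  All detectors are fitted on
standardized features; the z-scoring map is computed from target-class
training rows only and recorded so the identical affine map is applied at
classification time.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional

import numpy as np
from scipy import ndimage

from ocweed.errors import DataError, InputError, ParameterError
from ocweed.scene_sim import LabelRaster, MultibandScene, NODATA, OTHER, TARGET

FEATURE_NAMES = ("green", "red", "nir", "texture")
DEFAULT_TEXTURE_WINDOW = 7
DEFAULT_PER_CLASS = 1434


def _window_sum(arr: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window)
    out = ndimage.correlate1d(arr, kernel, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel, axis=1, mode="reflect")


def local_variance(band: np.ndarray, window: int = DEFAULT_TEXTURE_WINDOW) -> np.ndarray:
    """Population variance of ``band`` in a ``window x window`` moving window.

    Edges are reflect-padded (edge value included, as in ``np.pad`` mode
    ``symmetric``).  NaN marks nodata: such pixels are excluded from every
    window statistic, and a pixel whose whole window is nodata stays NaN.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    band = np.asarray(band, dtype=np.float64)
    valid = ~np.isnan(band)
    x = np.where(valid, band, 0.0)
    cnt = _window_sum(valid.astype(np.float64), window)
    s1 = _window_sum(x, window)
    s2 = _window_sum(x * x, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean * mean
    var = np.maximum(var, 0.0)  # guard tiny negative rounding
    var[cnt < 0.5] = np.nan
    return var


@dataclasses.dataclass
class Standardization:
    """Per-feature affine map (x - mean) / sd fitted on training targets."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if np.any(self.sd <= 0):
            raise DataError("standardization requires strictly positive sd per feature")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.mean, 12).tobytes())
        h.update(np.round(self.sd, 12).tobytes())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(mean=d["mean"], sd=d["sd"])


@dataclasses.dataclass
class FeatureTable:
    """N x 4 per-pixel feature matrix with optional labels and provenance."""

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    pixel_index: Optional[np.ndarray] = None
    standardization: Optional[Standardization] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(FEATURE_NAMES))
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise InputError("labels length does not match feature rows")
            if self.labels.size and not np.isin(self.labels, (TARGET, OTHER)).all():
                raise InputError("feature-table labels must be 1 (target) or 2 (other)")
        if self.pixel_index is not None:
            self.pixel_index = np.asarray(self.pixel_index)
            if self.pixel_index.shape[0] != self.values.shape[0]:
                raise InputError("pixel_index length does not match feature rows")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values[rows],
            labels=None if self.labels is None else self.labels[rows],
            pixel_index=None if self.pixel_index is None else self.pixel_index[rows],
            standardization=self.standardization,
        )

    def class_rows(self, code: int) -> "FeatureTable":
        if self.labels is None:
            raise InputError("feature table carries no labels")
        return self.take(np.flatnonzero(self.labels == code))


def assemble_features(
    scene: MultibandScene,
    labels: Optional[LabelRaster] = None,
    texture_window: int = DEFAULT_TEXTURE_WINDOW,
) -> FeatureTable:
    """Build the per-pixel feature table for a scene, in raster scan order.

    The texture column is the local variance of the NIR band.  Nodata pixels
    (and, when labels are given, pixels labelled 0) are dropped.
    """
    if labels is not None and labels.shape != scene.shape:
        raise InputError(
            f"labels shape {labels.shape} does not match scene {scene.shape}"
        )
    texture = local_variance(scene.nir.astype(np.float64), texture_window)
    keep = ~scene.nodata_mask
    if labels is not None:
        keep &= labels.labels != NODATA
    rows, cols = np.nonzero(keep)
    values = np.column_stack([
        scene.green[rows, cols].astype(np.float64),
        scene.red[rows, cols].astype(np.float64),
        scene.nir[rows, cols].astype(np.float64),
        texture[rows, cols],
    ])
    lab = labels.labels[rows, cols] if labels is not None else None
    return FeatureTable(values=values, labels=lab,
                        pixel_index=np.column_stack([rows, cols]))


def balanced_sample(table: FeatureTable, per_class: int, seed: int) -> FeatureTable:
    """Draw ``per_class`` rows per class without replacement (seeded)."""
    if table.labels is None:
        raise InputError("balanced sampling requires a labelled feature table")
    if per_class == 0:
        return table.take(np.array([], dtype=int))
    rng = np.random.default_rng(seed)
    chosen = []
    for code in (TARGET, OTHER):
        idx = np.flatnonzero(table.labels == code)
        if idx.size < per_class:
            raise DataError(
                f"class {code} has only {idx.size} pixels, {per_class} requested"
            )
        chosen.append(rng.choice(idx, size=per_class, replace=False))
    rows = np.sort(np.concatenate(chosen))
    return table.take(rows)


@dataclasses.dataclass
class SplitSpec:
    """Train/test split specification: 70% training by default."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise InputError("train_fraction must lie strictly between 0 and 1")


def split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split; rounding is per class, remainder to test.

    On the balanced 2 x 1434 calibration sample at fraction 0.70 this yields
    1004 + 1004 = 2008 training and 860 test pixels.
    """
    if table.labels is None:
        raise InputError("splitting requires a labelled feature table")
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for code in np.unique(table.labels):
        idx = np.flatnonzero(table.labels == code)
        n = idx.size
        k = int(np.floor(spec.train_fraction * n + 0.5))  # round half-up
        k = min(max(k, 1), n - 1)  # both sides non-empty per class
        perm = rng.permutation(idx)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train = table.take(np.sort(np.concatenate(train_idx)))
    test = table.take(np.sort(np.concatenate(test_idx)))
    return train, test


def standardize(train_targets: FeatureTable) -> Standardization:
    """Fit the z-scoring map on target-class training rows."""
    v = train_targets.values
    if v.shape[0] < 2:
        raise DataError("standardization needs at least 2 training rows")
    mean = v.mean(axis=0)
    sd = v.std(axis=0)  # population sd: transformed sd is exactly 1
    if np.any(sd <= 0):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(sd <= 0)]
        raise DataError(f"feature(s) {bad} are constant over training targets")
    return Standardization(mean=mean, sd=sd)


def apply_standardization(table: FeatureTable, st: Standardization) -> FeatureTable:
    return FeatureTable(
        values=st.transform(table.values),
        labels=table.labels,
        pixel_index=table.pixel_index,
        standardization=st,
    )
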