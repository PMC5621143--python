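"""Synthetic multispectral scene generation.

Emulates a 3-band (green / red / NIR) UAV orthomosaic at 0.5 m resolution
containing spatially contiguous target-weed patches in a background of
smooth-textured vegetation.  The two classes are designed to be confusable
in the visible bands and partially separated in the NIR, with the target
class carrying markedly higher local texture — the statistical structure the
one-class classifiers in this package rely on.

The generative model per pixel and band is

    reflectance = mean[class, band]
                  + spread[class, band] * S_class          (smooth field)
                  + amplitude[class] * mean[class, band] * H_band  (texture)

clipped to [0, 1].  ``S_class`` is one Gaussian-smoothed unit-variance field
per class, shared across bands: canopy density and vigour modulate all bands
together, which gives each class a correlated, low-dimensional spectral
structure as in real vegetation.  ``H_band`` is unsmoothed white noise, one
field per band; its multiplicative scaling concentrates texture in the
high-reflectance NIR band, where canopy texture is strongest.

Nodata pixels carry NaN in every band and are flagged in ``nodata_mask``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from ocweed.errors import ConfigurationError, FormatError, InputError

TARGET = 1  #: label code for the target weed (S. marianum)
OTHER = 2  #: label code for other vegetation
NODATA = 0  #: label code for pixels outside the study area

_BAND_NAMES = ("green", "red", "nir")

# Default class spectra: visible bands nearly identical between the classes,
# NIR partially separated (senescent graminaceous background vs vigorous
# thistle canopy); synthetic values, not field measurements.
_DEFAULT_SPECTRA = {
    TARGET: (0.10, 0.09, 0.55),
    OTHER: (0.09, 0.10, 0.42),
}
_DEFAULT_SPREAD = {TARGET: (0.02, 0.02, 0.02), OTHER: (0.02, 0.02, 0.02)}
_DEFAULT_TEXTURE = {TARGET: 0.055, OTHER: 0.010}


def _as_band_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ConfigurationError(f"{name} must be a scalar or a (green, red, nir) triple")
    return tuple(float(v) for v in arr)


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Attributes
    ----------
    width, height:
        Scene dimensions in pixels.
    pixel_size:
        Ground sampling distance in metres (default 0.5 m).
    class_spectra:
        Per-class mean reflectance triple (green, red, NIR), all in [0, 1].
    class_spread:
        Per-class per-band standard deviation of the smooth field.
    texture_amplitude:
        Per-class multiplicative high-frequency noise scale; must be strictly
        larger for the target class than for the background.
    patch_coverage:
        Requested fraction of the scene covered by target patches, in (0, 1).
    patch_scale:
        Gaussian smoothing length (pixels) of the patch-mask field;
        larger values give fewer, larger patches.
    field_scale:
        Smoothing length (pixels) of the within-class smooth fields; kept
        well above the 7-pixel texture window so the background stays smooth
        at the window scale.
    seed:
        Seed for all randomness; identical configs give bit-identical scenes.
    """

    width: int = 256
    height: int = 256
    pixel_size: float = 0.5
    class_spectra: Mapping[int, Sequence[float]] = None
    class_spread: Mapping[int, Sequence[float]] = None
    texture_amplitude: Mapping[int, float] = None
    patch_coverage: float = 0.30
    patch_scale: float = 12.0
    field_scale: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError(
                f"scene dimensions must be positive, got {self.width}x{self.height}"
            )
        if not 0.0 < self.patch_coverage < 1.0:
            raise ConfigurationError("patch_coverage must lie strictly between 0 and 1")
        if self.patch_scale < 1:
            raise ConfigurationError("patch_scale must be >= 1 pixel")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        self.class_spectra = {
            int(c): _as_band_triple(v, f"class_spectra[{c}]")
            for c, v in (self.class_spectra or _DEFAULT_SPECTRA).items()
        }
        self.class_spread = {
            int(c): _as_band_triple(v, f"class_spread[{c}]")
            for c, v in (self.class_spread or _DEFAULT_SPREAD).items()
        }
        self.texture_amplitude = {
            int(c): float(v)
            for c, v in (self.texture_amplitude or _DEFAULT_TEXTURE).items()
        }
        for c, triple in self.class_spectra.items():
            if any(not 0.0 <= v <= 1.0 for v in triple):
                raise ConfigurationError(f"class {c} mean reflectance outside [0, 1]")
        if TARGET in self.texture_amplitude and OTHER in self.texture_amplitude:
            if not self.texture_amplitude[TARGET] > self.texture_amplitude[OTHER]:
                raise ConfigurationError(
                    "texture_amplitude of the target class must exceed the background's"
                )

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_spectra"] = {int(k): list(v) for k, v in self.class_spectra.items()}
        d["class_spread"] = {int(k): list(v) for k, v in self.class_spread.items()}
        d["texture_amplitude"] = {int(k): v for k, v in self.texture_amplitude.items()}
        return d


@dataclasses.dataclass
class LabelRaster:
    """Per-pixel class codes: 0 = nodata, 1 = target weed, 2 = other vegetation."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InputError("label raster must be 2-D")
        if not np.isin(self.labels, (NODATA, TARGET, OTHER)).all():
            bad = sorted(set(np.unique(self.labels)) - {NODATA, TARGET, OTHER})
            raise InputError(f"label raster contains illegal codes {bad}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def target_fraction(self) -> float:
        valid = self.labels != NODATA
        return float((self.labels == TARGET).sum() / valid.sum())


@dataclasses.dataclass
class MultibandScene:
    """Green/red/NIR reflectance grids plus a nodata mask.

    Nodata pixels hold NaN in every band so that no statistic can silently
    absorb them; ``nodata_mask`` is True exactly at those pixels.
    """

    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    nodata_mask: np.ndarray = None
    pixel_size: float = 0.5

    def __post_init__(self):
        self.green = np.asarray(self.green, dtype=np.float32)
        self.red = np.asarray(self.red, dtype=np.float32)
        self.nir = np.asarray(self.nir, dtype=np.float32)
        if not (self.green.shape == self.red.shape == self.nir.shape):
            raise InputError("all three bands must share identical dimensions")
        if self.nodata_mask is None:
            self.nodata_mask = np.isnan(self.green)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.green.shape:
            raise InputError("nodata mask dimensions must match the bands")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    def bands(self) -> np.ndarray:
        """Stack bands as a (3, H, W) array in (green, red, nir) order."""
        return np.stack([self.green, self.red, self.nir])


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent substreams so changing one parameter does not reshuffle
    unrelated noise: mask, per-class smooth fields, per-band texture noise."""
    root = np.random.SeedSequence(seed)
    names = ("mask", "field", "noise")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def generate_patch_mask(config: SceneConfig) -> LabelRaster:
    """Generate contiguous target-weed patches covering ``patch_coverage``.

    A white-noise field is Gaussian-smoothed at ``patch_scale`` and
    thresholded at the empirical quantile that yields the requested coverage,
    so the realised target fraction is exact up to ties and the patches are
    contiguous blobs whose typical size grows with ``patch_scale``.
    """
    rng = _streams(config.seed)["mask"]
    field = rng.standard_normal((config.height, config.width))
    field = ndimage.gaussian_filter(field, sigma=config.patch_scale)
    cut = np.quantile(field, 1.0 - config.patch_coverage)
    labels = np.where(field > cut, TARGET, OTHER)
    return LabelRaster(labels)


def render_scene(mask: LabelRaster, config: SceneConfig) -> MultibandScene:
    """Render reflectance bands for a labelled scene.

    Raises a configuration error if the mask references a class for which the
    config carries no spectra.  Pixels labelled 0 become nodata (NaN).
    """
    if mask.shape != (config.height, config.width):
        raise InputError(
            f"mask shape {mask.shape} does not match config "
            f"{(config.height, config.width)}"
        )
    streams = _streams(config.seed)
    classes = [int(c) for c in np.unique(mask.labels) if c != NODATA]
    for c in classes:
        if c not in config.class_spectra:
            raise ConfigurationError(f"mask references class {c} with no configured spectra")

    shape = mask.shape
    # One smooth unit-variance field per class (consistent order: sorted codes).
    fields = {}
    for c in sorted(config.class_spectra):
        f = streams["field"].standard_normal(shape)
        f = ndimage.gaussian_filter(f, sigma=config.field_scale)
        sd = f.std()
        fields[c] = f / sd if sd > 0 else f
    # One white-noise field per band, shared across classes.
    noise = {b: streams["noise"].standard_normal(shape) for b in _BAND_NAMES}

    bands = {}
    for bi, b in enumerate(_BAND_NAMES):
        out = np.full(shape, np.nan, dtype=np.float64)
        for c in classes:
            sel = mask.labels == c
            mean = config.class_spectra[c][bi]
            spread = config.class_spread.get(c, (0.0, 0.0, 0.0))[bi]
            amp = config.texture_amplitude.get(c, 0.0)
            out[sel] = (
                mean
                + spread * fields[c][sel]
                + amp * mean * noise[b][sel]
            )
        np.clip(out, 0.0, 1.0, out=out)
        out[mask.labels == NODATA] = np.nan
        bands[b] = out.astype(np.float32)

    return MultibandScene(
        green=bands["green"], red=bands["red"], nir=bands["nir"],
        nodata_mask=mask.labels == NODATA, pixel_size=config.pixel_size,
    )


def simulate_scene(config: SceneConfig) -> tuple[MultibandScene, LabelRaster]:
    """Convenience wrapper: mask + rendered scene from one config."""
    mask = generate_patch_mask(config)
    return render_scene(mask, config), mask


# ---------------------------------------------------------------------------
# Raster I/O: multi-band float32 TIFF (band order green, red, NIR) with a
# JSON sidecar carrying pixel size; nodata travels as NaN inside the bands.
# ---------------------------------------------------------------------------

def write_scene(scene: MultibandScene, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, scene.bands(), photometric="minisblack")
    meta = {"pixel_size": scene.pixel_size, "band_order": list(_BAND_NAMES),
            "nodata": "nan"}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_scene(path) -> MultibandScene:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[-1] == 3 and data.shape[0] != 3:
        data = np.moveaxis(data, -1, 0)  # accept interleaved layout
    if data.ndim != 3 or data.shape[0] != 3:
        raise FormatError(
            f"{path}: expected 3 bands (green, red, nir), got shape {data.shape}"
        )
    pixel_size = 0.5
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        pixel_size = float(json.loads(sidecar.read_text()).get("pixel_size", 0.5))
    g, r, n = (band.astype(np.float32) for band in data)
    return MultibandScene(green=g, red=r, nir=n, pixel_size=pixel_size)


def write_labels(raster: LabelRaster, path) -> None:
    tifffile.imwrite(Path(path), raster.labels.astype(np.uint8),
                     photometric="minisblack")


def read_labels(path) -> LabelRaster:
    data = tifffile.imread(Path(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single-band label raster, got shape {data.shape}")
    return LabelRaster(data)
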