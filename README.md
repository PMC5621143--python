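# ocweed — one-class novelty detection for weed-patch mapping

`ocweed` is a Python library for mapping an invasive weed (milk thistle,
*Silybum marianum*) in multispectral UAV orthomosaics using **one-class
(novelty-detection) classification**: the classifier is trained on pixels of
the target weed only and flags everything that deviates from that
description as "other vegetation".  This matters in practice because ground
truth for the target patches is cheap to collect (their outlines are walked
with a GPS), while exhaustively labelling every other species in a pasture
is not.

The package provides

* a **scene simulator** that emulates a 3-band (green/red/NIR, 0.5 m GSD)
  orthomosaic with contiguous, high-texture weed patches in a smooth
  graminaceous background whose visible reflectance overlaps the target's;
* **feature extraction**: per-pixel 4-vectors (green, red, NIR, and texture
  = local variance of NIR in a 7 × 7 moving window), a balanced two-class
  calibration sample (2 × 1434 pixels) and a stratified 70/30 split;
* four **one-class detectors**, each fitted on target-class training rows
  only and thresholded so a configured fraction of training targets is
  accepted:
  * **OC-SVM / SVDD** — the minimal enclosing supersphere in RBF feature
    space, `K(x,z) = exp(−‖x−z‖²/σ²)` with σ = 2.5, found by solving the
    dual `min αᵀKα` over `{Σαᵢ = 1, 0 ≤ αᵢ ≤ C}`, `C = 1/(Nν)`, ν = 0.05;
  * **OC-SOM** — an 8 × 8 Kohonen map; novelty score is the quantization
    error `min_i ‖x − m_i‖²` to the best matching unit;
  * **Autoencoder** — one sigmoidal hidden layer (8 units), linear output,
    scored by squared reconstruction error;
  * **OC-PCA** — the orthonormal principal subspace `W` of the targets,
    scored by the reconstruction distance `d_PCA(z) = ‖z − W Wᵀ z‖²`,
    10% training outlier fraction;
* **accuracy assessment**: 2 × 2 contingency tables with overall, user's
  and producer's accuracy and omission/commission errors;
* a **pipeline + CLI** (`ocweed simulate/train/classify/evaluate/benchmark`)
  that ties the stages together reproducibly (seeded, versioned JSON model
  files).

All detectors share one decision convention: a training-score order
statistic sets the threshold (`sort` the training novelty scores, cut at the
midpoint around `round(fraction·N)`), and the threshold point itself counts
as a target.

## Worked example

```
python examples/train_and_map.py
```

prints

```
calibration: 2868 px sampled, 2008 train / 860 test; detector sees 1004 target rows only
SVDD: 59 support vectors, sigma=2.5, nu=0.05, calibrated R^2=0.8203

OC-SVM held-out 30% (Overall accuracy 97.21%)
Actual             Target px  Other px  User acc %  Prod acc %
S. marianum              406        24       100.0       94.42
Other vegetation           0       430       94.71       100.0

whole-scene map: 65536 px classified, 98.31% agree with the simulation truth
```

The balanced calibration sample (1434 pixels per class) is split 70/30; only
the 1004 *target* training rows reach the detector.  On the held-out 860
pixels the SVDD accepts 94.4% of true weed pixels (producer's accuracy) and
rejects every other-vegetation pixel; ~5% of true targets are lost by
construction, since the radius is calibrated to reject ν = 5% of training
targets.  Other entry points: `examples/simulate_scene.py` (scene
statistics), `examples/accuracy_from_counts.py` (metric arithmetic),
`examples/benchmark_detectors.py` (all four detectors side by side).

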