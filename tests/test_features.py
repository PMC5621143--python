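import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocweed.errors import DataError, InputError, ParameterError
from ocweed.features import (
    FeatureTable, SplitSpec,
    apply_standardization, assemble_features, balanced_sample,
    local_variance, split, standardize,
)
from ocweed.scene_sim import (
    OTHER, TARGET, LabelRaster, SceneConfig,
    generate_patch_mask, render_scene, simulate_scene,
)


def brute_force_local_variance(band: np.ndarray, window: int) -> np.ndarray:
    """Independent oracle: explicit symmetric padding + per-window loop."""
    half = window // 2
    padded = np.pad(band, half, mode="symmetric")
    out = np.empty_like(band, dtype=float)
    for i in range(band.shape[0]):
        for j in range(band.shape[1]):
            w = padded[i:i + window, j:j + window].ravel()
            w = w[~np.isnan(w)]
            out[i, j] = np.var(w) if w.size else np.nan
    return out


class TestLocalVariance:
    def test_constant_band_is_zero(self):
        assert np.allclose(local_variance(np.full((10, 10), 3.7), 7), 0.0)

    def test_binary_window_value(self):
        # a 7x7 window holding 25 ones and 24 zeros has population variance
        # (25/49)*(24/49)
        band = np.zeros((9, 9))
        ones = [(r, c) for r in range(1, 8) for c in range(1, 8)][:25]
        for r, c in ones:
            band[r, c] = 1.0
        expected = (25 / 49) * (24 / 49)
        got = local_variance(band, 7)[4, 4]
        assert got == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.24990, abs=5e-6)

    def test_impulse_window_value(self):
        h = 2.5
        band = np.zeros((15, 15))
        band[7, 7] = h
        expected = h * h * 48 / 49**2
        assert local_variance(band, 7)[7, 7] == pytest.approx(expected, abs=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            local_variance(np.zeros((5, 5)), 4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), window=st.sampled_from([3, 5, 7]))
    def test_matches_brute_force_oracle(self, seed, window):
        band = np.random.default_rng(seed).uniform(0, 1, (20, 20))
        got = local_variance(band, window)
        want = brute_force_local_variance(band, window)
        assert np.allclose(got, want, atol=1e-10)

    def test_nodata_excluded_and_propagated(self):
        rng = np.random.default_rng(3)
        band = rng.uniform(0, 1, (20, 20))
        band[5:9, 5:9] = np.nan
        got = local_variance(band, 5)
        want = brute_force_local_variance(band, 5)
        assert np.allclose(got, want, atol=1e-10, equal_nan=True)
        # a fully-nodata window stays nodata
        band[:] = np.nan
        assert np.isnan(local_variance(band, 5)).all()


class TestAssembleFeatures:
    def test_all_valid_counts(self):
        cfg = SceneConfig(width=3, height=3, seed=1, patch_scale=1)
        scene, _ = simulate_scene(cfg)
        table = assemble_features(scene)
        assert table.values.shape == (9, 4)

    def test_nodata_rows_dropped(self):
        cfg = SceneConfig(width=10, height=10, seed=2)
        mask = generate_patch_mask(cfg)
        labels = mask.labels.copy()
        flat = labels.ravel()
        flat[:5] = 0
        scene = render_scene(LabelRaster(labels), cfg)
        table = assemble_features(scene, LabelRaster(labels))
        assert len(table) == 100 - 5

    def test_texture_column_matches_oracle(self):
        scene, mask = simulate_scene(SceneConfig(width=12, height=12, seed=4))
        table = assemble_features(scene, mask)
        want = brute_force_local_variance(scene.nir.astype(float), 7)
        idx = table.pixel_index
        assert np.allclose(table.values[:, 3], want[idx[:, 0], idx[:, 1]],
                           atol=1e-10)

    def test_raster_scan_order(self):
        scene, _ = simulate_scene(SceneConfig(width=6, height=5, seed=5))
        table = assemble_features(scene)
        flat = table.pixel_index[:, 0] * 6 + table.pixel_index[:, 1]
        assert np.array_equal(flat, np.sort(flat))

    def test_shape_mismatch_rejected(self):
        scene, _ = simulate_scene(SceneConfig(width=8, height=8, seed=6))
        bad = LabelRaster(np.ones((4, 4), dtype=int))
        with pytest.raises(InputError):
            assemble_features(scene, bad)


@pytest.fixture(scope="module")
def labelled_table():
    scene, mask = simulate_scene(SceneConfig(width=128, height=128, seed=13))
    return assemble_features(scene, mask)


class TestBalancedSample:
    def test_published_sample_size(self, labelled_table):
        sample = balanced_sample(labelled_table, 1434, seed=0)
        assert len(sample) == 2868
        assert int((sample.labels == TARGET).sum()) == 1434
        assert int((sample.labels == OTHER).sum()) == 1434

    def test_zero_per_class_is_empty(self, labelled_table):
        assert len(balanced_sample(labelled_table, 0, seed=0)) == 0

    def test_deterministic(self, labelled_table):
        a = balanced_sample(labelled_table, 200, seed=42)
        b = balanced_sample(labelled_table, 200, seed=42)
        assert np.array_equal(a.pixel_index, b.pixel_index)

    def test_insufficient_pixels_reports_counts(self, labelled_table):
        with pytest.raises(DataError, match=r"\d+ pixels"):
            balanced_sample(labelled_table, 10**6, seed=0)


class TestSplit:
    def test_published_split_sizes(self, labelled_table):
        sample = balanced_sample(labelled_table, 1434, seed=0)
        train, test = split(sample, SplitSpec(train_fraction=0.70, seed=0))
        assert len(train) == 2008
        assert len(test) == 860
        assert int((train.labels == TARGET).sum()) == 1004
        assert int((train.labels == OTHER).sum()) == 1004

    def test_partition_and_stratification(self, labelled_table):
        sample = balanced_sample(labelled_table, 500, seed=1)
        train, test = split(sample, SplitSpec(train_fraction=0.63, seed=1))
        assert len(train) + len(test) == len(sample)
        joined = np.vstack([train.pixel_index, test.pixel_index])
        assert np.array_equal(
            np.sort(joined.view([("r", joined.dtype), ("c", joined.dtype)]),
                    axis=0),
            np.sort(sample.pixel_index.view(
                [("r", joined.dtype), ("c", joined.dtype)]), axis=0),
        )
        for code in (TARGET, OTHER):
            n_train = int((train.labels == code).sum())
            assert abs(n_train - 0.63 * 500) <= 1

    def test_tiny_table_keeps_test_nonempty(self):
        table = FeatureTable(values=np.arange(12.0).reshape(3, 4),
                             labels=[1, 1, 1])
        train, test = split(table, SplitSpec(train_fraction=0.999, seed=0))
        assert len(test) >= 1 and len(train) >= 1

    def test_unlabelled_rejected(self):
        table = FeatureTable(values=np.zeros((4, 4)))
        with pytest.raises(InputError):
            split(table, SplitSpec())


class TestStandardize:
    def test_train_targets_become_zero_mean_unit_sd(self, labelled_table):
        targets = labelled_table.class_rows(TARGET)
        st_map = standardize(targets)
        out = apply_standardization(targets, st_map)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-10)
        assert np.allclose(out.values.std(axis=0), 1.0)

    def test_round_trip_identity(self, labelled_table):
        st_map = standardize(labelled_table.class_rows(TARGET))
        out = apply_standardization(labelled_table, st_map)
        assert np.allclose(st_map.inverse(out.values), labelled_table.values,
                           atol=1e-12)

    def test_constant_feature_rejected(self):
        values = np.random.default_rng(0).normal(size=(20, 4))
        values[:, 2] = 5.0
        with pytest.raises(DataError, match="nir"):
            standardize(FeatureTable(values=values))
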