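import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocweed.errors import ConfigurationError, ParameterError, StateError
from ocweed.features import FeatureTable
from ocweed.oc_som import (
    SomConfig, SomModel,
    bmu_distance, calibrate_and_classify_som, calibrate_som, classify_som,
    fraction_threshold, quantization_errors, train_som,
)
from ocweed.scene_sim import OTHER, TARGET


def oracle_threshold(values, fraction):
    """Independent re-implementation: explicit sort + 1-based indexing."""
    s = sorted(float(v) for v in values)
    k = int(np.floor(fraction * len(s) + 0.5))
    return (s[k - 1] + s[k]) / 2.0


class TestFractionThreshold:
    def test_printed_pseudocode_example(self):
        assert fraction_threshold(range(1, 11), 0.8) == 8.5

    def test_99_percent_of_100(self):
        values = np.arange(1.0, 101.0)
        assert fraction_threshold(values, 0.99) == (99 + 100) / 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 1e6), min_size=4, max_size=60),
        fraction=st.floats(0.3, 0.95),
    )
    def test_matches_independent_oracle(self, values, fraction):
        k = int(np.floor(fraction * len(values) + 0.5))
        if not 1 <= k < len(values):
            return
        assert fraction_threshold(values, fraction) == pytest.approx(
            oracle_threshold(values, fraction), rel=1e-12)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ParameterError):
            fraction_threshold([1.0, 2.0], 0.99)  # k = 2 = n
        with pytest.raises(ParameterError):
            fraction_threshold([1.0], 0.5)


def _model_from_codebooks(cb):
    cb = np.asarray(cb, dtype=float)
    return SomModel(codebooks=cb, grid=np.zeros((cb.shape[0], 2)),
                    rows=cb.shape[0], cols=1)


class TestBmu:
    def test_exact_codebook_hit(self):
        cb = np.random.default_rng(0).normal(size=(8, 4))
        model = _model_from_codebooks(cb)
        idx, dist = bmu_distance(model, cb[5])
        assert (idx, dist) == (5, 0.0)

    def test_tie_broken_by_lowest_index(self):
        model = _model_from_codebooks([[0.0, 0, 0, 0], [1.0, 0, 0, 0]])
        idx, _ = bmu_distance(model, np.array([0.5, 0, 0, 0]))
        assert idx == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_matches_exhaustive_scan(self, seed):
        gen = np.random.default_rng(seed)
        cb = gen.normal(size=(12, 4))
        x = gen.normal(size=4)
        model = _model_from_codebooks(cb)
        idx, dist = bmu_distance(model, x)
        d = [float(np.sum((x - m) ** 2)) for m in cb]
        assert idx == int(np.argmin(d))
        assert dist == pytest.approx(min(d), abs=1e-12)
        assert quantization_errors(model, x[None, :])[0] == pytest.approx(
            min(d), rel=1e-10)


class TestTraining:
    def test_single_unit_converges_to_mean(self, rng):
        X = rng.normal(loc=(2.0, 3.0, 4.0, 5.0), scale=0.1, size=(300, 4))
        table = FeatureTable(values=X)
        model = train_som(table, SomConfig(rows=1, cols=1, epochs=40, seed=0))
        rel = np.linalg.norm(model.codebooks[0] - X.mean(axis=0)) \
            / np.linalg.norm(X.mean(axis=0))
        assert rel < 0.01

    def test_two_units_find_two_clusters(self, rng):
        a = rng.normal(loc=0.0, scale=0.1, size=(150, 4))
        b = rng.normal(loc=10.0, scale=0.1, size=(150, 4))
        X = np.vstack([a, b])
        table = FeatureTable(values=X)
        model = train_som(table, SomConfig(rows=2, cols=1, epochs=50,
                                           radius_final=1e-3, seed=1))
        means = np.array([a.mean(axis=0), b.mean(axis=0)])
        separation = np.linalg.norm(means[1] - means[0])
        # match codebooks to cluster means in either order
        order = np.argsort(model.codebooks[:, 0])
        for cb, mu in zip(model.codebooks[order], means):
            assert np.linalg.norm(cb - mu) < 0.05 * separation

    def test_deterministic_given_seed(self, train_targets):
        sub = train_targets.take(np.arange(150))
        cfg = SomConfig(rows=4, cols=4, epochs=5, seed=3)
        m1 = train_som(sub, cfg)
        m2 = train_som(sub, cfg)
        assert np.array_equal(m1.codebooks, m2.codebooks)

    def test_quantization_error_settles(self, train_targets):
        model = train_som(train_targets, SomConfig(epochs=10, seed=0))
        trace = model.qe_trace
        half = trace[len(trace) // 2:]
        # non-increasing over the final half, up to small online jitter
        for a, b in zip(half, half[1:]):
            assert b <= a * 1.05

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            SomConfig(epochs=0)

    def test_small_sample_warns(self):
        table = FeatureTable(values=np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.warns(UserWarning, match="smaller than SOM grid"):
            train_som(table, SomConfig(rows=8, cols=8, epochs=1, seed=0))


@pytest.fixture(scope="module")
def som_model(train_targets):
    model = train_som(train_targets, SomConfig(seed=5))
    return calibrate_som(model, train_targets)


class TestClassification:
    def test_training_rejection_matches_fraction(self, som_model, train_targets):
        codes = classify_som(som_model, train_targets)
        n = len(train_targets)
        rejected = float(np.mean(codes == OTHER))
        assert abs(rejected - (1 - som_model.fraction_targets)) <= 1.0 / n

    def test_accepted_count_is_exact_order_statistic(self, som_model,
                                                     train_targets):
        qe = quantization_errors(som_model, train_targets.values)
        n = qe.size
        k = int(np.floor(som_model.fraction_targets * n + 0.5))
        assert int(np.sum(qe <= som_model.threshold)) == k

    def test_point_at_threshold_is_target(self):
        # novelty needs a strictly larger quantization error: equality stays
        # a target
        model = _model_from_codebooks([[0.0, 0, 0, 0]])
        x = np.array([0.7, 0.1, -0.2, 0.3])
        model.threshold = float(quantization_errors(model, x[None, :])[0])
        assert classify_som(model, FeatureTable(values=x[None, :]))[0] == TARGET
        beyond = x * 1.001
        assert classify_som(model, FeatureTable(values=beyond[None, :]))[0] \
            == OTHER

    def test_distant_cluster_all_novel(self, som_model, rng):
        far = rng.normal(size=(40, 4)) + 50.0
        codes = classify_som(som_model, FeatureTable(values=far))
        assert np.all(codes == OTHER)

    def test_uncalibrated_model_raises(self, train_targets):
        model = train_som(train_targets.take(np.arange(100)),
                          SomConfig(rows=3, cols=3, epochs=2, seed=0))
        with pytest.raises(StateError):
            classify_som(model, train_targets)

    def test_calibrate_and_classify_wrapper(self, train_targets):
        model = train_som(train_targets.take(np.arange(200)),
                          SomConfig(rows=4, cols=4, epochs=3, seed=2))
        sub = train_targets.take(np.arange(200))
        codes = calibrate_and_classify_som(model, sub, sub)
        assert model.threshold is not None
        assert set(np.unique(codes)) <= {TARGET, OTHER}


def test_grid_size_sweep_runs(train_targets):
    """3x3 through 20x20 grids all train and calibrate on the full
    1004-pixel target training set without error."""
    import time
    t0 = time.time()
    for g in range(3, 21):
        cfg = SomConfig(rows=g, cols=g, epochs=2, seed=0)
        model = train_som(train_targets, cfg)
        calibrate_som(model, train_targets)
    assert time.time() - t0 < 60
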