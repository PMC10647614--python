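"""Sample construction, splitting, and the stacked LSTM classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogstage.model import (
    ModelConfig,
    SequenceSampleSet,
    StackedLSTMClassifier,
    make_samples,
    probabilities_to_labels,
    split_counts,
    split_samples,
    standardize_splits,
)


def _matrix(k, labels=None, n_feat=4, sid="A"):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(k, n_feat)),
                      columns=[f"x{i}" for i in range(n_feat)])
    df["subject_id"] = sid
    df["window_index"] = np.arange(k)
    df["start_day"] = np.arange(k) * 3
    df["end_day"] = np.arange(k) * 3 + 9
    df["label"] = labels if labels is not None else ["CH"] * k
    return df


class TestMakeSamples:
    @pytest.mark.parametrize("k,expected_targets", [
        (11, [10]),
        (15, [10, 12, 14]),
        (10, []),
        (5, []),
    ])
    def test_sample_counts_and_targets(self, k, expected_targets):
        s = make_samples(_matrix(k))
        assert list(s.target_windows) == expected_targets
        if len(s):
            assert s.X.shape[1:] == (10, 4)

    def test_counts_match_enumeration(self):
        """Sample count equals brute-force enumeration for k <= 100."""
        for k in range(0, 101):
            got = len(make_samples(_matrix(k)))
            want = len([s for s in range(0, max(k - 10, 0) + 1, 2)
                        if s + 10 <= k - 1])
            assert got == want, k

    def test_inputs_are_consecutive_windows(self):
        m = _matrix(15)
        s = make_samples(m)
        np.testing.assert_allclose(
            s.X[1], m[[f"x{i}" for i in range(4)]].to_numpy()[2:12]
        )


class TestSplitSamples:
    @pytest.mark.parametrize("n,expected", [
        (20, (15, 3, 2)),
        (10, (8, 1, 1)),
        (1, (1, 0, 0)),
        (3, (1, 1, 1)),
        (0, (0, 0, 0)),
    ])
    def test_count_rule(self, n, expected):
        assert split_counts(n) == expected

    @given(n=st.integers(0, 5000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_counts_partition_and_cover_all_sets(self, n):
        tr, va, te = split_counts(n)
        assert tr + va + te == n
        if n >= 3:
            assert tr >= 1 and va >= 1 and te >= 1

    def test_chronological_order_and_leakage_discard(self):
        s = make_samples(_matrix(120))
        tr, va, te = split_samples(s)
        assert tr.target_windows.max() < va.target_windows.min()
        assert va.target_windows.max() < te.target_windows.min()
        # no evaluation sample's input block reaches the train region
        boundary = tr.target_windows.max()
        for part in (va, te):
            assert (part.target_windows - 10 > boundary).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_counts(10, (0.5, 0.2, 0.2))


def _toy_separable(n_per_class=4, n_feat=5, timesteps=10, seed=0):
    """Linearly separable three-class toy sequences."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(3):
        center = np.zeros(n_feat)
        center[cls] = 3.0
        for _ in range(n_per_class):
            X.append(center + 0.1 * rng.standard_normal((timesteps, n_feat)))
            y.append(cls)
    return SequenceSampleSet(
        np.array(X), np.array(y),
        np.array(["s"] * len(y), dtype=object),
        np.arange(len(y)), [f"x{i}" for i in range(n_feat)],
    )


SMALL = dict(layer_units=(16, 8), dropout=0.0, batch_size=4)


class TestClassifier:
    def test_softmax_rows_sum_to_one(self):
        s = _toy_separable()
        model = StackedLSTMClassifier(5, ModelConfig(**SMALL, epochs=1, seed=0))
        model.fit(s)
        probs = model.predict_proba(s.X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_overfits_separable_toy(self):
        """Separable classes, enough epochs: training accuracy reaches 100%."""
        s = _toy_separable()
        config = ModelConfig(**SMALL, epochs=200, learning_rate=0.01, seed=1)
        model = StackedLSTMClassifier(5, config)
        history = model.fit(s)
        assert history["accuracy"].iloc[-1] == 1.0

    def test_training_is_deterministic(self):
        s = _toy_separable()
        hashes = []
        for _ in range(2):
            model = StackedLSTMClassifier(
                5, ModelConfig(layer_units=(16, 8), dropout=0.5, batch_size=4,
                               epochs=5, seed=3)
            )
            model.fit(s)
            hashes.append(model.weights_hash())
        assert hashes[0] == hashes[1]

    def test_gradients_match_finite_differences(self):
        """Analytic BPTT gradients vs central differences on a tiny net."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 4, 3))
        y = np.eye(3)[[0, 1, 2]]
        config = ModelConfig(layer_units=(5, 4), dropout=0.0, dtype="float64",
                             seed=0)
        model = StackedLSTMClassifier(3, config)

        def loss():
            probs, _ = model._forward(X, training=False)
            return -np.mean(np.sum(y * np.log(probs), axis=1))

        probs, caches = model._forward(X, training=False)
        grads = model._backward(X, y, probs, caches)
        eps = 1e-6
        for name in ("Wx0", "Wh1", "b0", "Wd", "bd"):
            W = model.params[name]
            flat_idx = [0, W.size // 2, W.size - 1]
            for fi in flat_idx:
                orig = W.flat[fi]
                W.flat[fi] = orig + eps
                up = loss()
                W.flat[fi] = orig - eps
                down = loss()
                W.flat[fi] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].flat[fi] == pytest.approx(numeric, abs=1e-6), name

    def test_severity_tie_break(self):
        assert probabilities_to_labels([[0.1, 0.2, 0.7]])[0] == "MCI"
        assert probabilities_to_labels([[1 / 3, 1 / 3, 1 / 3]])[0] == "MCI"
        assert probabilities_to_labels([[0.4, 0.4, 0.2]])[0] == "TR"

    def test_prediction_order_preserved(self):
        s = _toy_separable()
        model = StackedLSTMClassifier(5, ModelConfig(**SMALL, epochs=1, seed=0))
        model.fit(s)
        full = model.predict(s.X)
        np.testing.assert_array_equal(full[:4], model.predict(s.X[:4]))

    def test_dimension_mismatch_rejected(self):
        model = StackedLSTMClassifier(5, ModelConfig(**SMALL, epochs=1))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 10, 7)))

    def test_save_load_roundtrip(self, tmp_path):
        s = _toy_separable()
        model = StackedLSTMClassifier(5, ModelConfig(**SMALL, epochs=2, seed=0))
        model.fit(s)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = StackedLSTMClassifier.load(path)
        np.testing.assert_array_equal(
            model.predict_proba(s.X), loaded.predict_proba(s.X)
        )


class TestSignalRecovery:
    """Checks on the shared reference benchmark run (session fixture)."""

    def test_mean_accuracy_beats_chance_by_20_points(self, benchmark_result):
        """Strong injected drift: mean test accuracy across the 5 seeded
        runs exceeds the 3-class chance level by at least 20 points."""
        mean_overall = benchmark_result.scenario_means[2].overall
        assert mean_overall >= 33.3 + 20.0

    def test_permuted_labels_fall_to_chance(self, benchmark_result):
        """Shuffled training targets: accuracy within 10 points of chance,
        guarding against leakage through overlapping samples."""
        from cogstage.benchmark import build_splits, train_and_score

        prepared = benchmark_result.prepared
        tr, va, te = build_splits(prepared, 2)
        accs = []
        for seed in (11, 12, 13):
            rng = np.random.default_rng(seed)
            shuffled = SequenceSampleSet(
                tr.X, rng.permutation(tr.y), tr.subject_ids,
                tr.target_windows, tr.columns,
            )
            rep, _ = train_and_score(shuffled, va, te, seed=seed, epochs=30)
            accs.append(rep.overall)
        assert abs(float(np.mean(accs)) - 33.3) <= 10.0


def test_standardize_uses_train_statistics_only():
    rng = np.random.default_rng(0)
    def part(scale):
        return SequenceSampleSet(
            scale * rng.standard_normal((20, 10, 3)) + scale,
            rng.integers(0, 3, 20),
            np.array(["s"] * 20, dtype=object), np.arange(20), ["a", "b", "c"],
        )
    tr, va, te, (mean, sd) = standardize_splits(part(1.0), part(5.0), part(5.0))
    flat = tr.X.reshape(-1, 3)
    np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-12)
    assert abs(va.X.reshape(-1, 3).mean()) > 0.1  # not re-centered on itself
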