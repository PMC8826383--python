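"""Network building blocks and the read classifier: convolution oracle,
loss identities, branch isolation, training behaviour, fold assignment and
incremental feature selection."""

import numpy as np
import pytest

from methcall.nn.layers import (
    Adam,
    Conv1D,
    LocallyConnected1D,
    bce_loss,
    conv1d_feature_map,
    sigmoid,
)
from methcall.nn.model import (
    ConvSpec,
    ModelSpec,
    ReadClassifier,
    TrainingConfig,
    call_reads,
    train_model,
    windows_to_tensors,
)
from methcall.nn.selection import (
    incremental_feature_selection,
    split_genome_folds,
)


class TestConvolutionOracle:
    def test_hand_evaluated_kernel(self):
        out = conv1d_feature_map([1, 2, 3, 4, 5], [1, 0, -1])
        np.testing.assert_allclose(out, [-2, -2, -2])

    def test_identity_kernel(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_allclose(conv1d_feature_map(x, [1.0]), x)

    def test_kernel_longer_than_input(self):
        with pytest.raises(ValueError):
            conv1d_feature_map([1, 2], [1, 2, 3])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            k = int(rng.integers(1, n + 1))
            x = rng.standard_normal(n)
            kern = rng.standard_normal(k)
            expected = np.array(
                [sum(x[i + j] * kern[j] for j in range(k)) for i in range(n - k + 1)]
            )
            np.testing.assert_allclose(conv1d_feature_map(x, kern), expected, atol=1e-12)

    def test_conv_layer_agrees_with_reference_per_channel(self, rng):
        """The batched same-padded layer reduces to the sliding dot product
        on its valid region for a single in/out channel."""
        layer = Conv1D(1, 1, 3, rng)
        x = rng.standard_normal((1, 10, 1)).astype(np.float32)
        out = layer.forward(x) - layer.params["b"][0]
        ref = conv1d_feature_map(x[0, :, 0], layer.params["W"][:, 0])
        np.testing.assert_allclose(out[0, 1:-1, 0], ref, atol=1e-5)


class TestBceLoss:
    def test_perfect_prediction_loss_vanishes(self):
        assert bce_loss(np.array([1.0]), np.array([1 - 1e-9])) < 1e-6

    def test_half_score_is_ln2(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 2, 50).astype(float)
        yhat = rng.uniform(0.01, 0.99, 50)
        perm = rng.permutation(50)
        assert bce_loss(y, yhat) == pytest.approx(bce_loss(y[perm], yhat[perm]))

    def test_empty_batch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))


class TestLocallyConnected:
    def test_tied_weights_reproduce_plain_convolution(self, rng):
        conv = Conv1D(3, 4, 3, rng)
        lc = LocallyConnected1D(3, 4, 3, l_in=12, rng=rng)
        lc.set_tied_kernel(conv.params["W"], conv.params["b"])
        x = rng.standard_normal((2, 12, 3)).astype(np.float32)
        out_lc = lc.forward(x)
        out_conv = conv.forward(x)[:, 1:-1, :]  # same-padding border trimmed
        np.testing.assert_allclose(out_lc, out_conv, atol=1e-5)

    def test_parameter_count_scales_with_length(self, rng):
        small = LocallyConnected1D(2, 3, 3, l_in=8, rng=rng)
        large = LocallyConnected1D(2, 3, 3, l_in=16, rng=rng)
        assert large.params["W"].size == small.params["W"].size * 14 / 6


class TestReadClassifier:
    def test_scores_in_unit_interval(self, tiny_model_spec, rng):
        m = ReadClassifier(tiny_model_spec, l=13, seed=1)
        Xs = rng.standard_normal((16, 13, 9)).astype(np.float32)
        Xe = rng.standard_normal((16, 13, 9)).astype(np.float32)
        s = m.forward(Xs, Xe)
        assert s.shape == (16,)
        assert np.all((s >= 0) & (s <= 1))

    def test_sequence_only_ignores_error_tensor(self, rng):
        spec = ModelSpec(mode="sequence_only", sequence_conv=ConvSpec(2, 8, 4))
        m = ReadClassifier(spec, l=13, seed=1)
        Xs = rng.standard_normal((8, 13, 9)).astype(np.float32)
        s1 = m.predict(Xs, None)
        s2 = m.predict(Xs, rng.standard_normal((8, 13, 9)).astype(np.float32))
        np.testing.assert_array_equal(s1, s2)

    def test_even_l_rejected(self, tiny_model_spec):
        with pytest.raises(ValueError):
            ReadClassifier(tiny_model_spec, l=16)

    def test_persistence_roundtrip(self, tmp_path, tiny_model_spec, rng):
        m = ReadClassifier(tiny_model_spec, l=13, seed=4)
        m.save(tmp_path / "model", feature_schema=["signal_mean", "quality"])
        m2, schema = ReadClassifier.load(tmp_path / "model")
        assert schema == ["signal_mean", "quality"]
        Xs = rng.standard_normal((5, 13, 9)).astype(np.float32)
        Xe = rng.standard_normal((5, 13, 9)).astype(np.float32)
        np.testing.assert_array_equal(m.predict(Xs, Xe), m2.predict(Xs, Xe))


def _toy_tensors(rng, n, shift=3.0, l=13):
    """Linearly separable toy windows: channel-0 means around the centre
    base shifted for label 1."""
    y = (np.arange(n) % 2).astype(np.float32)
    Xs = rng.standard_normal((n, l, 9)).astype(np.float32)
    Xe = rng.standard_normal((n, l, 9)).astype(np.float32)
    Xs[y == 1, l // 2 - 2 : l // 2 + 3, 0] += shift
    return Xs, Xe, y


class TestTraining:
    def test_learns_separable_data(self, rng):
        spec = ModelSpec(mode="sequence_only", sequence_conv=ConvSpec(2, 16, 4),
                         head_units=32)
        m = ReadClassifier(spec, l=13, seed=0)
        Xs, Xe, y = _toy_tensors(rng, 1200)
        cfg = TrainingConfig(max_epochs=10, batch_size=64, seed=0, learning_rate=0.01)
        train_model(m, (Xs[:1000], None, y[:1000]), (Xs[1000:], None, y[1000:]), cfg)
        scores = m.predict(Xs[1000:], None)
        acc = np.mean((scores >= 0.5) == (y[1000:] == 1))
        assert acc >= 0.95

    def test_zero_learning_rate_freezes_parameters(self, tiny_model_spec, rng):
        m = ReadClassifier(tiny_model_spec, l=13, seed=0)
        before = [{k: v.copy() for k, v in d.items()} for d in m.get_state()]
        Xs, Xe, y = _toy_tensors(rng, 64)
        cfg = TrainingConfig(learning_rate=0.0, max_epochs=1, batch_size=32, seed=0)
        train_model(m, (Xs, Xe, y), (Xs, Xe, y), cfg)
        for d_before, d_after in zip(before, m.get_state()):
            for k in d_before:
                if k.startswith("running_"):
                    continue  # batch-norm running stats update without gradients
                np.testing.assert_array_equal(d_before[k], d_after[k])

    def test_seeded_runs_reproduce_epoch_losses(self, tiny_model_spec, rng):
        Xs, Xe, y = _toy_tensors(rng, 128)
        histories = []
        for _ in range(2):
            m = ReadClassifier(tiny_model_spec, l=13, seed=3)
            cfg = TrainingConfig(max_epochs=2, batch_size=32, seed=3)
            histories.append(train_model(m, (Xs, Xe, y), (Xs, Xe, y), cfg))
        assert histories[0] == histories[1]

    def test_calibration_on_balanced_data(self, rng):
        spec = ModelSpec(mode="sequence_only", sequence_conv=ConvSpec(2, 8, 4),
                         head_units=16)
        m = ReadClassifier(spec, l=13, seed=1)
        Xs, _, y = _toy_tensors(rng, 600, shift=2.0)
        cfg = TrainingConfig(max_epochs=5, batch_size=64, seed=1, learning_rate=0.01)
        train_model(m, (Xs[:500], None, y[:500]), (Xs[500:], None, y[500:]), cfg)
        scores = m.predict(Xs[500:], None)
        assert scores[y[500:] == 1].mean() > scores[y[500:] == 0].mean()

    def test_empty_training_set(self, tiny_model_spec):
        m = ReadClassifier(tiny_model_spec, l=13)
        with pytest.raises(ValueError):
            train_model(m, (None, None, np.array([])), (None, None, np.array([])),
                        TrainingConfig())


class TestCallReads:
    def test_threshold_and_tie_rule(self, small_separable_windows):
        windows, _ = small_separable_windows
        spec = ModelSpec(mode="sequence_only", sequence_conv=ConvSpec(1, 4, 4),
                         head_units=8)
        m = ReadClassifier(spec, l=17, seed=0)
        df = call_reads(m, windows[:100])
        assert set(df.columns) >= {"read_id", "chrom", "strand", "position", "score", "call"}
        np.testing.assert_array_equal(df["call"], (df["score"] >= 0.5).astype(int))
        assert df["call"].mean() == np.mean(df["score"] >= 0.5)


class TestGenomeFolds:
    def test_printed_sections(self):
        assign = split_genome_folds()
        assert assign(1_500_000) == 2
        assert assign(0) == 1
        assert assign(4_699_999) == 5

    def test_partition_property(self, rng):
        assign = split_genome_folds()
        positions = rng.integers(0, 4_700_000, size=500)
        folds = [assign(int(p)) for p in positions]
        assert set(folds) <= {1, 2, 3, 4, 5}

    def test_outside_positions_rejected(self):
        assign = split_genome_folds()
        with pytest.raises(KeyError):
            assign(5_000_000)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            split_genome_folds([(0, 10), (5, 20)])


class TestIncrementalFeatureSelection:
    def test_greedy_trace(self):
        table = {
            ("f1",): 0.8,
            ("f1", "f2"): 0.85,
            ("f1", "f2", "f3"): 0.84,
            ("f1", "f2", "f4"): 0.9,
        }
        selected = incremental_feature_selection(
            ["f1", "f2", "f3", "f4"], lambda s: table[s]
        )
        assert selected == ["f1", "f2", "f4"]

    def test_monotone_oracle_keeps_everything(self):
        selected = incremental_feature_selection(
            ["a", "b", "c"], lambda s: 0.1 * len(s)
        )
        assert selected == ["a", "b", "c"]

    def test_single_candidate(self):
        assert incremental_feature_selection(["only"], lambda s: 0.5) == ["only"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            incremental_feature_selection([], lambda s: 0.0)


def test_sigmoid_range_and_symmetry(rng):
    z = rng.standard_normal(100) * 50
    s = sigmoid(z.astype(np.float32))
    assert np.all((s >= 0) & (s <= 1))
    np.testing.assert_allclose(s + sigmoid(-z.astype(np.float32)), 1.0, atol=1e-6)
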