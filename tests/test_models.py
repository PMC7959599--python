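import numpy as np
import pytest

from promokit import (
    CNNSpec,
    LSTMSpec,
    RFSpec,
    SeqRecord,
    TrainConfig,
    build_cnn,
    build_lstm,
    build_rf,
    encode_dataset,
    fit_vocabulary,
    predict,
    train,
)
from promokit.models import InputContract
from promokit.nn import Conv1D, Dense, Dropout, LSTM, MaxPool1D, Sequential


def n_params(net: Sequential) -> int:
    return sum(p.size for layer in net.layers for p in layer.params)


def make_dataset(rng, n=40, length=30, k=2, labels=None, n_classes=2):
    recs = [
        SeqRecord(
            f"r{i}",
            "".join(rng.choice(list("ACGT"), size=length)),
            label=int(labels[i]) if labels is not None else int(i % n_classes),
        )
        for i in range(n)
    ]
    vocab = fit_vocabulary([r.bases for r in recs], k)
    return encode_dataset(recs, "fbt", k, vocab=vocab), vocab


TINY_CNN = CNNSpec(n_filters_per_layer=4, dense_units=(16, 8, 4), embedding_dim=4)


class TestSpecs:
    def test_paper_defaults(self):
        cnn, lstm, rf, cfg = CNNSpec(), LSTMSpec(), RFSpec(), TrainConfig()
        assert (cnn.n_conv_layers, cnn.filter_width) == (3, 5)
        assert (cnn.pool_size, cnn.pool_stride) == (4, 1)
        assert cnn.dense_units == (1025, 512, 128)
        assert cnn.dropout_rate == 0.20
        assert (lstm.lstm_units, lstm.dense_units, lstm.dropout_rate) == (128, 64, 0.5)
        assert (rf.n_trees, rf.min_samples_split, rf.bootstrap) == (300, 2, False)
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (10, 128, 1e-3)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CNNSpec(dense_units=(128, 512))
        with pytest.raises(ValueError):
            CNNSpec(dropout_rate=1.5)
        with pytest.raises(ValueError):
            RFSpec(n_trees=0)


class TestBuildCNN:
    def test_structural_counts(self):
        net = build_cnn(CNNSpec(), vocab_size=16, n_positions=249, n_classes=2)
        convs = [l for l in net.layers if isinstance(l, Conv1D)]
        pools = [l for l in net.layers if isinstance(l, MaxPool1D)]
        denses = [l for l in net.layers if isinstance(l, Dense)]
        drops = [l for l in net.layers if isinstance(l, Dropout)]
        assert len(convs) == len(pools) == 3
        assert len(denses) == 4  # 3 hidden + 1 output
        assert denses[-1].W.shape[1] == 1
        assert [d.W.shape[1] for d in denses[:3]] == [1025, 512, 128]
        assert all(d.rate == 0.20 for d in drops)

    def test_parameter_count_closed_form(self):
        """Shape arithmetic for embedding_dim=8, 4 filters, 20 positions."""
        spec = CNNSpec(n_filters_per_layer=4, embedding_dim=8)
        net = build_cnn(spec, vocab_size=5, n_positions=20, n_classes=2)
        emb = (5 + 1) * 8
        conv1 = 5 * 8 * 4 + 4
        conv23 = 2 * (5 * 4 * 4 + 4)
        flat = 4 * (20 - 3 * 3)  # each pool removes pool_size-1 positions
        dense = (
            flat * 1025 + 1025 + 1025 * 512 + 512 + 512 * 128 + 128 + 128 + 1
        )
        assert n_params(net) == emb + conv1 + conv23 + dense

    def test_untrained_binary_output_in_unit_interval(self, rng):
        net = build_cnn(TINY_CNN, vocab_size=10, n_positions=29, n_classes=2)
        p = net.predict_proba(rng.integers(0, 11, size=(5, 29)))
        assert ((p >= 0) & (p <= 1)).all()

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(CNNSpec(), vocab_size=4, n_positions=3)

    def test_onehot_front_has_no_embedding(self):
        from promokit.nn import Embedding

        net = build_cnn(TINY_CNN, 16, 29, 2, encoder="onehot")
        assert not any(isinstance(l, Embedding) for l in net.layers)


class TestBuildLSTM:
    def test_structure_and_heads(self, rng):
        net = build_lstm(LSTMSpec(), vocab_size=16, n_positions=20, n_classes=2)
        assert sum(isinstance(l, LSTM) for l in net.layers) == 1
        denses = [l for l in net.layers if isinstance(l, Dense)]
        assert [d.W.shape[1] for d in denses] == [64, 1]

    def test_multiclass_probabilities_sum_to_one(self, rng):
        net = build_lstm(
            LSTMSpec(lstm_units=8, dense_units=4, embedding_dim=3),
            vocab_size=6, n_positions=12, n_classes=3,
        )
        p = net.predict_proba(rng.integers(0, 7, size=(6, 12)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestRandomForest:
    def test_300_trees_after_fit(self, rng):
        data, _ = make_dataset(rng)
        rf = build_rf(RFSpec(), seed=0)
        trained = train(rf, data, None, TrainConfig(seed=0), kind="rf")
        assert len(trained.estimator.estimators_) == 300

    def test_feature_count_matches_positions(self, rng):
        data, _ = make_dataset(rng, length=30, k=2)
        rf = build_rf(RFSpec(n_trees=10), seed=0)
        trained = train(rf, data, None, TrainConfig(), kind="rf")
        assert trained.estimator.n_features_in_ == 29 == data.n_positions

    def test_deterministic_refit(self, rng):
        data, _ = make_dataset(rng, n=30)
        preds = []
        for _ in range(2):
            rf = build_rf(RFSpec(n_trees=20), seed=5)
            trained = train(rf, data, None, TrainConfig(seed=5), kind="rf")
            _, y_hat = predict(trained, data)
            preds.append(y_hat)
        assert (preds[0] == preds[1]).all()

    def test_memorizes_separable_fixture(self):
        # 10 linearly separable samples: token at position 0 decides the class
        X = np.array([[i % 2 + 1] * 5 for i in range(10)])
        y = X[:, 0] - 1
        from promokit.encoding import EncodedDataset

        data = EncodedDataset(
            X=X, y=y, encoder="fbt", k=1, source_length=5,
            vocab_checksum="t", vocab_size=2, ids=[str(i) for i in range(10)],
        )
        rf = build_rf(RFSpec(n_trees=10), seed=0)
        trained = train(rf, data, None, TrainConfig(), kind="rf")
        _, y_hat = predict(trained, data)
        assert (y_hat == y).all()


class TestTrainPredict:
    def test_label_out_of_range_rejected(self, rng):
        data, _ = make_dataset(rng, labels=[0, 1, 2] * 10, n=30)
        net = build_cnn(TINY_CNN, data.vocab_size, data.n_positions, 2)
        with pytest.raises(ValueError, match="labels"):
            train(net, data, None, TrainConfig(patience=None), n_classes=2)

    def test_contract_mismatch_refused(self, rng):
        data, vocab = make_dataset(rng, n=24)
        net = build_cnn(TINY_CNN, data.vocab_size, data.n_positions, 2)
        trained = train(net, data, data, TrainConfig(epochs=1, seed=0))
        other_recs = [
            SeqRecord(f"x{i}", "".join(rng.choice(list("ACGT"), size=30)), label=0)
            for i in range(4)
        ]
        other_vocab = fit_vocabulary([r.bases for r in other_recs], 2)
        other = encode_dataset(other_recs, "fbt", 2, vocab=other_vocab)
        if other.vocab_checksum != data.vocab_checksum:
            with pytest.raises(ValueError, match="contract"):
                predict(trained, other)

    def test_probability_half_labels_positive(self, rng):
        data, _ = make_dataset(rng, n=12)
        net = build_cnn(TINY_CNN, data.vocab_size, data.n_positions, 2)
        for layer in net.layers:
            for p in layer.params:
                p[...] = 0.0  # zero weights -> logit 0 -> probability 0.5
        trained = train(net, data, None, TrainConfig(epochs=0, patience=None))
        proba, y_hat = predict(trained, data)
        assert np.allclose(proba, 0.5)
        assert (y_hat == 1).all()

    def test_multiclass_argmax_tie_toward_smaller_index(self):
        assert np.array([0.2, 0.5, 0.3]).argmax() == 1
        assert np.array([0.4, 0.4, 0.2]).argmax() == 0

    def test_untrained_model_is_chance_level_on_balanced_data(self, rng):
        data, _ = make_dataset(rng, n=200, labels=[0, 1] * 100)
        net = build_cnn(TINY_CNN, data.vocab_size, data.n_positions, 2)
        trained = train(net, data, None, TrainConfig(epochs=0, patience=None))
        _, y_hat = predict(trained, data)
        acc = (y_hat == data.y).mean()
        assert 0.35 <= acc <= 0.65

    def test_training_loss_finite_after_first_epoch(self, rng):
        y = np.array([0, 1] * 32)
        data, _ = make_dataset(rng, n=64, labels=y)
        net = build_cnn(TINY_CNN, data.vocab_size, data.n_positions, 2)
        trained = train(net, data, data, TrainConfig(epochs=1, seed=0))
        assert np.isfinite(trained.history.loss[0])
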