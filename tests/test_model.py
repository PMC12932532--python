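"""Transformer classifier: shape contracts, determinism, order
sensitivity, and learnability on a trivially separable task."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from apneaformer.config import ModelConfig, PosencConfig
from apneaformer.model import (
    ApneaTransformerClassifier,
    build_classifier,
    build_encoder_block,
    predict_seconds,
)


def tiny_clf(**kw):
    params = dict(num_blocks=1, num_heads=1, head_size=8, ff_hidden=16,
                  mlp_units=32, epochs=0, random_state=0, class_weight=None)
    params.update(kw)
    return ApneaTransformerClassifier(**params)


class TestEncoderBlock:
    def test_shape_preserved(self, rng):
        block = build_encoder_block(ModelConfig(num_heads=2, head_size=4),
                                    c_in=3, rng=rng)
        x = rng.normal(size=(2, 15, 3)).astype(np.float32)
        assert block.forward(x).shape == x.shape

    def test_zeroed_ff_sublayer_reduces_to_layernorm(self, rng):
        block = build_encoder_block(ModelConfig(num_heads=2, head_size=4,
                                                dropout=0.0), c_in=3, rng=rng)
        block.ff2.params["W"][...] = 0
        block.ff2.params["b"][...] = 0
        x = rng.normal(size=(1, 12, 3)).astype(np.float32)
        a = block.drop1.forward(block.attn.forward(x))
        h = block.norm1.forward(x + a)
        np.testing.assert_allclose(block.forward(x), block.norm2.forward(h),
                                   atol=1e-6)

    def test_attention_softmax_rows(self, rng):
        block = build_encoder_block(ModelConfig(num_heads=4, head_size=8),
                                    c_in=1, rng=rng)
        block.forward(rng.normal(size=(2, 9, 1)).astype(np.float32))
        w = block.attn.last_attention
        assert w.shape == (2, 4, 9, 9)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)


class TestForwardContracts:
    def test_published_configuration_output_shape(self):
        """Full 6-block, 4-head, head-size-256 model on a 30 s window at
        80 Hz: (batch, 2400, 1) -> (batch, 30) probabilities."""
        net = build_classifier(ModelConfig(), sequence_length=2400)
        x = np.random.default_rng(0).normal(size=(1, 2400, 1)).astype(np.float32)
        p = net.forward_proba(x)
        assert p.shape == (1, 30)
        assert ((p > 0) & (p < 1)).all()

    @pytest.mark.parametrize("fs", [1, 2, 8])
    def test_shape_algebra_any_sampling_rate(self, fs, rng):
        L = 30 * fs
        net = build_classifier(
            ModelConfig(num_blocks=1, num_heads=1, head_size=8, ff_hidden=8,
                        mlp_units=16), sequence_length=L)
        x = rng.normal(size=(3, L, 1)).astype(np.float32)
        assert net.forward_proba(x).shape == (3, 30)

    def test_eval_mode_is_pure_function(self, rng):
        net = build_classifier(
            ModelConfig(num_blocks=2, num_heads=2, head_size=8, dropout=0.1),
            sequence_length=60)
        x = rng.normal(size=(2, 60, 1)).astype(np.float32)
        np.testing.assert_array_equal(net.forward_proba(x), net.forward_proba(x))

    def test_batch_equivariance(self, rng):
        net = build_classifier(
            ModelConfig(num_blocks=1, num_heads=2, head_size=8),
            sequence_length=40)
        x = rng.normal(size=(4, 40, 1)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(net.forward_proba(x)[perm],
                                   net.forward_proba(x[perm]), atol=1e-5)

    def test_sequence_length_mismatch_rejected(self, rng):
        net = build_classifier(ModelConfig(num_blocks=1, num_heads=1,
                                           head_size=4), sequence_length=60)
        with pytest.raises(ValueError):
            net.forward_proba(rng.normal(size=(1, 50, 1)).astype(np.float32))


class TestOrderSensitivity:
    def test_time_pooled_no_pe_model_permutation_invariant(self, rng):
        """Without positional encoding the encoder stack is permutation
        equivariant, so the time-pooled logit ignores sample order."""
        net = build_classifier(
            ModelConfig(num_blocks=1, num_heads=2, head_size=8, dropout=0.0,
                        pool_axis="time",
                        posenc=PosencConfig(strategy="none")),
            sequence_length=24)
        x = rng.normal(size=(1, 24, 1)).astype(np.float32)
        perm = rng.permutation(24)
        np.testing.assert_allclose(net.forward_proba(x),
                                   net.forward_proba(x[:, perm]), atol=1e-4)

    @pytest.mark.parametrize("strategy", ["none", "naive", "autoencoder"])
    def test_reversal_changes_per_second_output(self, strategy, rng):
        net = build_classifier(
            ModelConfig(num_blocks=1, num_heads=2, head_size=8, dropout=0.0,
                        posenc=PosencConfig(strategy=strategy,
                                            ae_filters=(8, 4))),
            sequence_length=60)
        x = rng.normal(size=(1, 60, 1)).astype(np.float32)
        assert not np.allclose(net.forward_proba(x),
                               net.forward_proba(x[:, ::-1]), atol=1e-6)


class TestPredictSeconds:
    @pytest.fixture
    def fitted(self, rng):
        clf = tiny_clf(epochs=1)
        X = rng.normal(size=(8, 30, 1)).astype(np.float32)
        y = (rng.random((8, 30)) < 0.3).astype(np.int8)
        return clf.fit(X, y), X

    def test_threshold_rule(self, fitted):
        clf, X = fitted
        pred, proba = predict_seconds(clf, X, threshold=0.5)
        np.testing.assert_array_equal(pred, (proba >= 0.5).astype(np.int8))
        pred0, _ = predict_seconds(clf, X, threshold=0.0)
        assert pred0.all()

    def test_threshold_monotonicity(self, fitted):
        clf, X = fitted
        counts = [predict_seconds(clf, X, threshold=t)[0].sum()
                  for t in (0.0, 0.25, 0.5, 0.75, 1.01)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_refitted_length_enforced(self, fitted, rng):
        clf, _ = fitted
        with pytest.raises(ValueError):
            clf.predict_proba(rng.normal(size=(1, 40, 1)))


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        clf = tiny_clf()
        params = clf.get_params()
        assert params["head_size"] == 8
        clf.set_params(head_size=16)
        assert clf.head_size == 16

    def test_clone_compatible(self):
        from sklearn.base import clone

        clf = tiny_clf(posenc_strategy="naive")
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    def test_fitted_attributes(self, rng):
        clf = tiny_clf(epochs=1)
        X = rng.normal(size=(4, 30, 1)).astype(np.float32)
        y = (rng.random((4, 30)) < 0.5).astype(np.int8)
        clf.fit(X, y)
        assert clf.sequence_length_ == 30
        assert clf.n_parameters_ > 0
        assert len(clf.history_["loss"]) == 1
        assert clf.network_.summary()[0][0] == "posenc"


def _amplitude_burst_task(n_windows, seconds=30, fs=2, seed=0):
    """Positive seconds carry an injected high-amplitude burst — linearly
    separable per second given positional features."""
    rng = np.random.default_rng(seed)
    L = seconds * fs
    X = 0.1 * rng.normal(size=(n_windows, L, 1)).astype(np.float32)
    y = np.zeros((n_windows, seconds), dtype=np.int8)
    for i in range(n_windows):
        if rng.random() < 0.8:
            start = int(rng.integers(0, seconds - 10))
            length = int(rng.integers(8, 15))
            y[i, start : start + length] = 1
            for s in range(start, min(start + length, seconds)):
                X[i, s * fs : (s + 1) * fs, 0] += 1.0
    return X, y


def test_tiny_model_learns_amplitude_task():
    """A 1-block, 1-head, head-size-8 model reaches held-out per-second
    AUC >= 0.9 on the separable amplitude task within a few epochs."""
    X, y = _amplitude_burst_task(250, seed=3)
    clf = tiny_clf(epochs=10, class_weight="balanced", random_state=1)
    clf.fit(X[:200], y[:200])
    proba = clf.predict_proba(X[200:])
    assert roc_auc_score(y[200:].ravel(), proba.ravel()) >= 0.9
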