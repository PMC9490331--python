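"""Gradient and training-loop verification of the neural layer library.

Every layer's hand-derived backward pass is checked against central finite
differences in float64; the JIT-compiled float32 LSTM kernels are checked
against the pure-numpy reference path.
"""

from __future__ import annotations

import numpy as np
import pytest

from dendrofill import nn

from conftest import numerical_gradient


def _check_layer(layer, x, tol=1e-5):
    """Finite-difference check of dx and all parameter gradients."""
    rng = np.random.default_rng(0)
    y = layer.forward(x, training=True)
    dy = rng.normal(size=y.shape)
    for p in layer.params():
        p.grad[...] = 0.0
    dx = layer.backward(dy)

    def loss():
        return float(np.sum(layer.forward(x, training=True) * dy))

    gx = numerical_gradient(loss, x)
    scale = 1.0 + np.max(np.abs(gx))
    assert np.max(np.abs(gx - dx)) / scale < tol
    for p in layer.params():
        gp = numerical_gradient(loss, p.data)
        scale = 1.0 + np.max(np.abs(gp))
        assert np.max(np.abs(gp - p.grad)) / scale < tol


@pytest.mark.usefixtures("float64_nn")
@pytest.mark.parametrize(
    "make_layer,shape",
    [
        (lambda r: nn.Dense(4, 5, r), (3, 7, 4)),
        (lambda r: nn.LSTM(4, 6, r), (3, 8, 4)),
        (lambda r: nn.LSTM(4, 6, r, return_sequences=False), (3, 8, 4)),
        (lambda r: nn.Conv1D(4, 5, 3, r), (3, 8, 4)),
        (lambda r: nn.Conv1D(4, 5, 3, r, stride=2), (3, 8, 4)),
        (lambda r: nn.Conv1DTranspose(4, 5, 3, r, stride=2), (3, 4, 4)),
        (lambda r: nn.Conv2D(3, 4, (3, 3), r, stride=(2, 2)), (2, 4, 4, 3)),
        (lambda r: nn.Conv2DTranspose(3, 4, (3, 3), r, stride=(2, 2)), (2, 2, 2, 3)),
        (lambda r: nn.BatchNorm(4), (3, 8, 4)),
        (lambda r: nn.ReLU(), (3, 8, 4)),
        (lambda r: nn.Sigmoid(), (3, 8, 4)),
        (lambda r: nn.Tanh(), (3, 8, 4)),
        (lambda r: nn.RepeatVector(5), (3, 4)),
        (lambda r: nn.TakeLast(), (3, 8, 4)),
        (lambda r: nn.GlobalAvgPool1D(), (3, 8, 4)),
        (lambda r: nn.ResidualBlock1D(4, 6, (3, 3, 3), r), (3, 8, 4)),
        (
            lambda r: nn.Bidirectional(
                nn.LSTM(4, 5, r, return_sequences=False),
                nn.LSTM(4, 5, r, return_sequences=False),
            ),
            (2, 6, 4),
        ),
        (
            lambda r: nn.GlobalContextConcat(nn.LSTM(4, 5, r, return_sequences=False)),
            (2, 6, 4),
        ),
        (
            lambda r: nn.Sequential(
                [
                    nn.LSTM(4, 5, r, return_sequences=False),
                    nn.RepeatVector(6),
                    nn.LSTM(5, 5, r),
                    nn.Dense(5, 4, r),
                    nn.Sigmoid(),
                ]
            ),
            (2, 6, 4),
        ),
    ],
    ids=[
        "dense", "lstm_seq", "lstm_last", "conv1d", "conv1d_stride2",
        "conv1d_transpose", "conv2d_stride2", "conv2d_transpose", "batchnorm",
        "relu", "sigmoid", "tanh", "repeat", "take_last", "gap1d",
        "residual_block", "bidirectional", "global_context", "encoder_decoder",
    ],
)
def test_layer_gradients_match_finite_differences(make_layer, shape):
    rng = np.random.default_rng(7)
    layer = make_layer(np.random.default_rng(1))
    x = rng.normal(size=shape)
    _check_layer(layer, x)


@pytest.mark.usefixtures("float64_nn")
def test_batchnorm_inference_gradient():
    """BatchNorm in inference mode backpropagates through frozen statistics."""
    rng = np.random.default_rng(3)
    layer = nn.BatchNorm(4)
    layer.forward(rng.normal(size=(6, 4)), training=True)  # populate stats
    x = rng.normal(size=(3, 4))
    y = layer.forward(x, training=False)
    dy = rng.normal(size=y.shape)
    for p in layer.params():
        p.grad[...] = 0.0
    dx = layer.backward(dy)

    def loss():
        return float(np.sum(layer.forward(x, training=False) * dy))

    gx = numerical_gradient(loss, x)
    assert np.max(np.abs(gx - dx)) < 1e-6


def test_numba_lstm_matches_numpy_reference():
    """The JIT float32 kernels agree with the float64 numpy loop."""
    if not nn._HAS_NUMBA:
        # library falls back to the (already gradient-checked) numpy path
        return
    rng = np.random.default_rng(5)
    x = rng.normal(size=(4, 12, 3))
    l32 = nn.LSTM(3, 6, np.random.default_rng(2))
    old = nn.DEFAULT_DTYPE
    nn.DEFAULT_DTYPE = np.float64
    l64 = nn.LSTM(3, 6, np.random.default_rng(2))
    nn.DEFAULT_DTYPE = old
    y32 = l32.forward(x, training=True)
    nn._HAS_NUMBA = False
    y64 = l64.forward(x, training=True)
    nn._HAS_NUMBA = True
    assert np.max(np.abs(y32.astype(np.float64) - y64)) < 1e-5
    dy = rng.normal(size=y64.shape)
    dx32 = l32.backward(dy.astype(np.float32))
    nn._HAS_NUMBA = False
    dx64 = l64.backward(dy)
    nn._HAS_NUMBA = True
    assert np.max(np.abs(dx32.astype(np.float64) - dx64)) < 1e-4
    for p32, p64 in zip(l32.params(), l64.params()):
        assert np.max(np.abs(p32.grad.astype(np.float64) - p64.grad)) < 1e-3


def test_early_stopper_stops_after_patience_epochs():
    """With patience p and a loss that only worsens after epoch 1, training
    stops at epoch p + 1 and remembers epoch 1 as best."""
    p = 4
    stopper = nn.EarlyStopper(patience=p)
    losses = [1.0] + [1.0 + 0.1 * k for k in range(1, 20)]
    stopped_at = None
    for epoch, loss in enumerate(losses):
        if stopper.update(epoch, loss):
            stopped_at = epoch
            break
    assert stopped_at == p  # zero-based: the (p+1)-th epoch
    assert stopper.best_epoch == 0


def test_fit_restores_best_validation_weights_and_is_seeded():
    """Training history is seed-reproducible and the returned parameters
    correspond to the best validation epoch."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(64, 6)).astype(np.float32)
    W_true = rng.normal(size=(6, 2))
    Y = (X @ W_true).astype(np.float32)
    Xv, Yv = X[:16], Y[:16]

    def build():
        net = nn.Sequential([nn.Dense(6, 8, np.random.default_rng(3)), nn.Tanh(),
                             nn.Dense(8, 2, np.random.default_rng(4))])
        return nn.NeuralNetwork(net, loss="mse", seed=11)

    m1, m2 = build(), build()
    h1 = m1.fit(X, Y, Xv, Yv, batch_size=16, max_epochs=30, patience=30, lr=1e-2)
    h2 = m2.fit(X, Y, Xv, Yv, batch_size=16, max_epochs=30, patience=30, lr=1e-2)
    assert h1 == h2
    best = int(np.argmin(h1["val_loss"]))
    assert m1.evaluate(Xv, Yv) == pytest.approx(h1["val_loss"][best], rel=1e-5)


def test_fit_raises_on_divergence():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(32, 4)).astype(np.float32) * 1e3
    Y = rng.normal(size=(32, 2)).astype(np.float32) * 1e3
    net = nn.NeuralNetwork(
        nn.Sequential([nn.Dense(4, 2, np.random.default_rng(0))]), seed=0
    )
    with pytest.raises(RuntimeError, match="non-finite"):
        net.fit(X, Y * np.inf, X, Y, max_epochs=2, patience=5)


def test_softmax_cross_entropy_gradient():
    rng = np.random.default_rng(2)
    logits = rng.normal(size=(5, 3))
    onehot = np.eye(3)[rng.integers(0, 3, size=5)]
    _, grad = nn.softmax_cross_entropy(logits, onehot)

    def loss():
        return nn.softmax_cross_entropy(logits, onehot)[0]

    g = numerical_gradient(loss, logits)
    assert np.max(np.abs(g - grad)) < 1e-6
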