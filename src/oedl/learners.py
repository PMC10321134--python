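"""Three deep base learners under one fit / predict-probability contract.

* ``dnn`` — a fully connected stack: each neuron is an activation of a
  weighted sum of the previous layer, y = sigma(sum w_i x_i + b), with a
  softmax head.
* ``lstm_rnn`` — one or more LSTM layers followed by a fully connected
  output layer.  Tabular rows enter as a single time step by default
  (sequence length 1, feature-width input); a features-as-timesteps mode
  feeds one feature per step instead.
* ``dbn`` — a deep belief network: greedy layer-wise restricted-Boltzmann
  pretraining (CD-1; Gaussian visible units on the first layer, Bernoulli
  above) followed by supervised backpropagation fine-tuning of the
  unrolled sigmoid network.

All families train with Adam on softmax cross-entropy, mini-batches
shuffled by a seeded generator, so training is bit-deterministic on one
machine.  Architectures are described by a :class:`LearnerSpec`, the
vocabulary the swarm optimizer searches over.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FAMILIES = ("dnn", "lstm_rnn", "dbn")
MAX_NEURONS = 100


@dataclass
class LearnerSpec:
    """Architecture + training hyperparameters for one base learner."""

    family: str = "dnn"
    n_hidden_layers: int = 2
    neurons: tuple[int, ...] = (10, 10)
    lr: float = 1e-4
    batch_size: int = 20
    momentum_beta: float = 0.9
    epochs: int = 1000
    features_as_timesteps: bool = False  # lstm_rnn only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        self.neurons = tuple(int(n) for n in self.neurons)
        if len(self.neurons) != self.n_hidden_layers:
            raise ValueError("neurons length must equal n_hidden_layers")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if any(n < 1 or n > MAX_NEURONS for n in self.neurons):
            raise ValueError(f"neurons must lie in [1, {MAX_NEURONS}]")
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size and epochs must be positive")
        if not (0 <= self.momentum_beta < 1):
            raise ValueError("momentum_beta must lie in [0, 1)")

    def with_epochs(self, epochs: int) -> "LearnerSpec":
        return replace(self, epochs=epochs)


def default_specs(epochs: int = 1000, lr: float = 1e-4) -> dict[str, LearnerSpec]:
    """The pre-optimization starting point: two hidden layers of 10."""
    return {
        fam: LearnerSpec(family=fam, n_hidden_layers=2, neurons=(10, 10), epochs=epochs, lr=lr)
        for fam in FAMILIES
    }


# ----------------------------------------------------------------------
# numerics
# ----------------------------------------------------------------------


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    """Adam with configurable first-moment decay (the momentum term)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------


class _Dense:
    def __init__(self, rng, n_in, n_out, W=None, b=None):
        self.W = W if W is not None else rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = b if b is not None else np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _Activation:
    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x):
        if self.kind == "relu":
            self._mask = x > 0
            return x * self._mask
        self._out = _sigmoid(x)
        return self._out

    def backward(self, dout):
        if self.kind == "relu":
            return dout * self._mask
        return dout * self._out * (1 - self._out)

    def params(self):
        return []

    def grads(self):
        return []


class LSTMCell:
    """One LSTM cell; gate weights stacked as [input, forget, cell, output]."""

    def __init__(self, rng, n_in, n_hidden, Wx=None, Wh=None, b=None):
        s = np.sqrt(1.0 / max(n_in, 1))
        self.n_hidden = n_hidden
        self.Wx = Wx if Wx is not None else rng.normal(0, s, (n_in, 4 * n_hidden))
        self.Wh = Wh if Wh is not None else rng.normal(0, s, (n_hidden, 4 * n_hidden))
        self.b = b if b is not None else np.zeros(4 * n_hidden)

    def gates(self, x_t, h_prev):
        z = x_t @ self.Wx + h_prev @ self.Wh + self.b
        H = self.n_hidden
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        return i, f, g, o


def lstm_forward(cell: LSTMCell, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step: c_t = f*c_prev + i*g, h_t = o * tanh(c_t)."""
    i, f, g, o = cell.gates(np.atleast_2d(x_t), np.atleast_2d(h_prev))
    c_t = f * np.atleast_2d(c_prev) + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class _LSTMLayer:
    """LSTM over a (n, T, d) sequence, returning the final hidden state."""

    def __init__(self, rng, n_in, n_hidden):
        self.cell = LSTMCell(rng, n_in, n_hidden)
        self.n_hidden = n_hidden

    def forward(self, x):  # x: (n, T, d); 2-D input is lifted to one step
        self._lifted = x.ndim == 2
        if self._lifted:
            x = x[:, None, :]
        n, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        self._cache = []
        self._x = x
        self._hs = np.zeros((n, T + 1, H))
        for t in range(T):
            i, f, g, o = self.cell.gates(x[:, t, :], h)
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((i, f, g, o, c, c_new))
            h, c = h_new, c_new
            self._hs[:, t + 1, :] = h
        return h

    def backward(self, dh_last):
        x = self._x
        n, T, d = x.shape
        H = self.n_hidden
        cell = self.cell
        dWx = np.zeros_like(cell.Wx)
        dWh = np.zeros_like(cell.Wh)
        db = np.zeros_like(cell.b)
        dx = np.zeros_like(x)
        dh = dh_last
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, c_new = self._cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            h_prev = self._hs[:, t, :]
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ cell.Wx.T
            dh = dz @ cell.Wh.T
            dc = dc * f
        self.dWx, self.dWh, self.db = dWx, dWh, db
        return dx[:, 0, :] if self._lifted else dx

    def params(self):
        return [self.cell.Wx, self.cell.Wh, self.cell.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]


# ----------------------------------------------------------------------
# restricted Boltzmann machine
# ----------------------------------------------------------------------


@dataclass
class RBMParams:
    """W couples visible to hidden; b, c are visible / hidden biases."""

    W: np.ndarray  # (n_visible, n_hidden)
    b: np.ndarray  # visible bias
    c: np.ndarray  # hidden bias
    gaussian_visible: bool = False

    def __post_init__(self) -> None:
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("RBM shapes inconsistent: W must be (len(b), len(c))")


def rbm_energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy E(v,h) = -b.v - c.h - v.W.h (binary units)."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.size != params.b.size or h.size != params.c.size:
        raise ValueError("v/h shapes do not match RBM")
    return float(-params.b @ v - params.c @ h - v @ params.W @ h)


def rbm_partition(params: RBMParams) -> float:
    """Exact partition function by enumeration over all binary states.

    Only feasible for small machines (<= ~12 total units); used to verify
    that exp(-E)/Z normalizes to a probability distribution.
    """
    nv, nh = params.b.size, params.c.size
    if nv + nh > 16:
        raise ValueError("exhaustive Z only supported for <= 16 total units")
    z = 0.0
    for iv in range(2**nv):
        v = np.array([(iv >> k) & 1 for k in range(nv)], dtype=float)
        for ih in range(2**nh):
            h = np.array([(ih >> k) & 1 for k in range(nh)], dtype=float)
            z += np.exp(-rbm_energy(params, v, h))
    return float(z)


def rbm_prob(params: RBMParams, v: np.ndarray, h: np.ndarray, z: float | None = None) -> float:
    """p(v,h) = exp(-E(v,h)) / Z with Z by exhaustive enumeration."""
    z = rbm_partition(params) if z is None else z
    return float(np.exp(-rbm_energy(params, v, h)) / z)


def rbm_free_energy(params: RBMParams, v: np.ndarray) -> float:
    """F(v) = -b.v - sum_j softplus(c_j + (vW)_j), marginalizing h."""
    v = np.asarray(v, dtype=float)
    x = params.c + v @ params.W
    return float(-params.b @ v - np.sum(np.logaddexp(0.0, x)))


def rbm_cd_step(params: RBMParams, v0: np.ndarray, lr: float, rng: np.random.Generator
                ) -> RBMParams:
    """One CD-1 update on a batch of visible vectors (in place, returned).

    Positive phase uses hidden probabilities given the data; the negative
    phase reconstructs the visible layer from sampled hidden states and
    takes one more hidden inference step.
    """
    v0 = np.atleast_2d(np.asarray(v0, dtype=float))
    ph0 = _sigmoid(params.c + v0 @ params.W)
    h0 = (rng.random(ph0.shape) < ph0).astype(float)
    if params.gaussian_visible:
        v1 = params.b + h0 @ params.W.T  # mean-field real-valued reconstruction
    else:
        pv1 = _sigmoid(params.b + h0 @ params.W.T)
        v1 = (rng.random(pv1.shape) < pv1).astype(float)
    ph1 = _sigmoid(params.c + v1 @ params.W)
    n = v0.shape[0]
    params.W += lr * (v0.T @ ph0 - v1.T @ ph1) / n
    params.b += lr * (v0 - v1).mean(axis=0)
    params.c += lr * (ph0 - ph1).mean(axis=0)
    return params


def _pretrain_dbn(X: np.ndarray, neurons: tuple[int, ...], rng: np.random.Generator,
                  epochs: int = 15, lr: float = 0.01, batch: int = 32) -> list[RBMParams]:
    """Greedy layer-wise CD-1 pretraining; returns one RBM per hidden layer."""
    layers: list[RBMParams] = []
    data = X
    for li, nh in enumerate(neurons):
        nv = data.shape[1]
        params = RBMParams(
            W=rng.normal(0, 0.01, (nv, nh)),
            b=np.zeros(nv),
            c=np.zeros(nh),
            gaussian_visible=(li == 0),
        )
        n = data.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for s in range(0, n, batch):
                rbm_cd_step(params, data[order[s:s + batch]], lr, rng)
        layers.append(params)
        data = _sigmoid(params.c + data @ params.W)  # propagate probabilities up
    return layers


# ----------------------------------------------------------------------
# networks + training
# ----------------------------------------------------------------------


class _Network:
    """A feed-forward composition of layers ending in raw class logits."""

    def __init__(self, layers, reshape=None):
        self.layers = layers
        self.reshape = reshape  # applied to X before the first layer

    def logits(self, X):
        h = X if self.reshape is None else self.reshape(X)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, dlogits):
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def _build_network(spec: LearnerSpec, n_features: int, n_classes: int,
                   rng: np.random.Generator, X: np.ndarray | None = None) -> _Network:
    if spec.family == "dnn":
        layers = []
        n_in = n_features
        for n_out in spec.neurons:
            layers.append(_Dense(rng, n_in, n_out))
            layers.append(_Activation("relu"))
            n_in = n_out
        layers.append(_Dense(rng, n_in, n_classes))
        return _Network(layers)
    if spec.family == "lstm_rnn":
        if spec.features_as_timesteps:
            reshape = lambda X: X[:, :, None]  # one feature per time step
            n_in = 1
        else:
            reshape = lambda X: X[:, None, :]  # single step, feature-wide
            n_in = n_features
        layers = []
        for n_out in spec.neurons:
            layers.append(_LSTMLayer(rng, n_in, n_out))
            n_in = n_out
        layers.append(_Dense(rng, n_in, n_classes))
        # deeper LSTM layers consume the final hidden state as a length-1 sequence
        return _Network(layers, reshape=reshape)
    # dbn: unroll pretrained RBMs into a sigmoid stack + softmax head
    rbms = _pretrain_dbn(X, spec.neurons, rng)
    layers = []
    for rbm in rbms:
        layers.append(_Dense(rng, rbm.W.shape[0], rbm.W.shape[1],
                             W=rbm.W.copy(), b=rbm.c.copy()))
        layers.append(_Activation("sigmoid"))
    layers.append(_Dense(rng, spec.neurons[-1], n_classes))
    return _Network(layers)


@dataclass
class TrainedLearner:
    spec: LearnerSpec
    network: _Network = field(repr=False)
    loss_history: list[float] = field(default_factory=list, repr=False)
    n_classes: int = 3

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return softmax(self.network.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit(spec: LearnerSpec, X: np.ndarray, y: np.ndarray, seed: int = 0,
        n_classes: int = 3) -> TrainedLearner:
    """Train one base learner with Adam on softmax cross-entropy.

    ``y`` holds integer class codes in [0, n_classes).  Mini-batch order
    and every weight initialization flow from ``seed``, so two runs with
    the same inputs produce identical loss histories and parameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or not np.isfinite(X).all():
        raise ValueError("X must be a fully numeric 2-D array without missing values")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError("labels outside class range")
    rng = np.random.default_rng(seed)
    net = _build_network(spec, X.shape[1], n_classes, rng, X=X)
    opt = _Adam(net.params(), spec.lr, spec.momentum_beta)
    onehot = np.eye(n_classes)[y]
    n = X.shape[0]
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, spec.batch_size):
            idx = order[s:s + spec.batch_size]
            logits = net.logits(X[idx])
            probs = softmax(logits)
            loss = -np.mean(np.sum(onehot[idx] * np.log(probs + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            net.backward((probs - onehot[idx]) / len(idx))
            opt.step(net.grads())
        history.append(epoch_loss / n)
    return TrainedLearner(spec, net, history, n_classes)
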