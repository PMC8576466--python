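"""Minimal 1D convolutional / fully connected network in numpy.

Implements exactly what the spectral classifiers need and nothing
more: valid-mode 1D convolution blocks (conv -> ReLU -> max-pool),
dense layers with inverted dropout, softmax cross-entropy, Adam, and
early stopping on a held-out validation split.  All computation is
float32 im2col matrix multiplication; training is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError


@dataclass
class NetworkSpec:
    """Architecture and training schedule of the FCNN/CNN classifiers.

    ``conv_blocks`` is a list of (filters, kernel_width, pool_width);
    an empty list yields a pure fully connected network.  The final
    dense layer is the class layer (probability-normalized) and is
    appended automatically from the number of classes seen at fit time.
    Defaults are sized so a full leave-one-patient-out experiment runs
    in minutes on a single laptop CPU core.
    """

    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(8, 7, 2), (16, 7, 2), (32, 7, 2)])
    dense_layers: list[int] = field(default_factory=lambda: [64, 32])
    dropout_rates: list[float] = field(default_factory=lambda: [0.5, 0.3])
    max_epochs: int = 30
    early_stop_patience: int = 5
    batch_size: int = 128
    learning_rate: float = 2e-3
    validation_fraction: float = 0.1
    #: stop as converged once validation cross-entropy drops below this
    convergence_loss: float = 0.02

    def validate(self, kind: str = "cnn") -> list[str]:
        bad = []
        if kind == "cnn" and not self.conv_blocks:
            bad.append("cnn requires at least one conv block")
        for f, k, p in self.conv_blocks:
            if f < 1 or k < 1 or p < 1:
                bad.append(f"invalid conv block ({f},{k},{p})")
        if any(not 0 <= d < 1 for d in self.dropout_rates):
            bad.append("dropout rates must be in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            bad.append("max_epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            bad.append("learning_rate must be > 0")
        return bad


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Conv1D:
    """Valid-mode convolution via im2col; stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0, scale, size=(c_out, c_in * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def _cols(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, L) -> (N, L_out, C*k)
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.c_in * self.k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._cols(x)
        if train:
            self._x_shape, self._cols_cache = x.shape, cols
        out = cols @ self.W.T + self.b            # (N, L_out, c_out)
        return out.transpose(0, 2, 1)             # (N, c_out, L_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.transpose(0, 2, 1)               # (N, L_out, c_out)
        n, l_out, _ = d.shape
        d2 = d.reshape(n * l_out, -1)
        cols2 = self._cols_cache.reshape(n * l_out, -1)
        self.dW = (d2.T @ cols2).astype(np.float32)
        self.db = d2.sum(axis=0).astype(np.float32)
        dcols = (d2 @ self.W).reshape(n, l_out, self.c_in, self.k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for j in range(self.k):
            dx[:, :, j:j + l_out] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = (self._x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.W.T


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers = layers
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                key = (li, name)
                m, v = self.state.get(key, (np.zeros_like(g), np.zeros_like(g)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p = getattr(layer, name)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    np.float32)


class NeuralNetClassifier:
    """FCNN/CNN spectrum classifier with softmax output.

    ``kind`` selects the architecture family: "cnn" uses the spec's
    conv blocks before the dense head, "fcnn" ignores them.
    """

    def __init__(self, spec: NetworkSpec | None = None, kind: str = "cnn",
                 seed: int = 0):
        self.spec = spec or NetworkSpec()
        bad = self.spec.validate(kind)
        if bad:
            raise ValidationError("; ".join(bad))
        self.kind = kind
        self.seed = seed
        self.classes_: np.ndarray | None = None

    # ---- architecture -------------------------------------------------
    def _build(self, n_features: int, n_classes: int,
               rng: np.random.Generator):
        self._convs: list[_Conv1D] = []
        self._pools: list[int] = []
        length, channels = n_features, 1
        if self.kind == "cnn":
            for f, k, p in self.spec.conv_blocks:
                if length < k:
                    raise ValidationError(
                        f"input length {length} shorter than kernel {k}")
                self._convs.append(_Conv1D(channels, f, k, rng))
                length = length - k + 1
                length = length // p
                if length < 1:
                    raise ValidationError("pooling collapsed the signal")
                self._pools.append(p)
                channels = f
        flat = length * channels if self.kind == "cnn" else n_features
        widths = list(self.spec.dense_layers) + [n_classes]
        self._dense: list[_Dense] = []
        n_in = flat
        for w in widths:
            self._dense.append(_Dense(n_in, w, rng))
            n_in = w

    # ---- forward / backward -------------------------------------------
    def _forward(self, X: np.ndarray, train: bool,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        a = X
        if self.kind == "cnn":
            a = a[:, None, :]                    # (N, 1, L)
            self._relu_masks, self._pool_args = [], []
            for conv, p in zip(self._convs, self._pools):
                z = conv.forward(a, train)
                mask = z > 0
                a = z * mask
                if train:
                    self._relu_masks.append(mask)
                n, c, l = a.shape
                l_p = l // p
                a = a[:, :, :l_p * p].reshape(n, c, l_p, p)
                arg = a.argmax(axis=3)
                if train:
                    self._pool_args.append((arg, a.shape))
                a = a.max(axis=3)
            a = a.reshape(a.shape[0], -1)
        self._dense_masks = []
        for i, layer in enumerate(self._dense):
            z = layer.forward(a, train)
            if i < len(self._dense) - 1:
                mask = z > 0
                a = z * mask
                drop = self.spec.dropout_rates[i] \
                    if i < len(self.spec.dropout_rates) else 0.0
                if train and drop > 0:
                    keep = (rng.random(a.shape) >= drop) / (1.0 - drop)
                    a = a * keep
                    self._dense_masks.append((mask, keep.astype(np.float32)))
                elif train:
                    self._dense_masks.append((mask, None))
            else:
                a = z
        return a

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for i in range(len(self._dense) - 1, -1, -1):
            if i < len(self._dense) - 1:
                mask, keep = self._dense_masks[i]
                if keep is not None:
                    d = d * keep
                d = d * mask
            d = self._dense[i].backward(d)
        if self.kind == "cnn":
            n = d.shape[0]
            shape = self._pool_args[-1][1]
            d = d.reshape(n, shape[1], shape[2])
            for j in range(len(self._convs) - 1, -1, -1):
                arg, (nn_, c, l_p, p) = self._pool_args[j]
                dpool = np.zeros((nn_, c, l_p, p), dtype=np.float32)
                np.put_along_axis(dpool, arg[..., None], d[..., None], axis=3)
                dz = np.zeros(
                    (nn_, c, self._relu_masks[j].shape[2]), dtype=np.float32)
                dz[:, :, :l_p * p] = dpool.reshape(nn_, c, l_p * p)
                dz = dz * self._relu_masks[j]
                d = self._convs[j].backward(dz)
                if j > 0:
                    _, (n2, c2, l2, p2) = self._pool_args[j - 1]
                    d = d.reshape(n2, c2, -1)

    # ---- training ------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y.tolist()), key=str))
        class_index = {c: i for i, c in enumerate(self.classes_.tolist())}
        yi = np.array([class_index[v] for v in y])
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValidationError("training set has a single class")
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], n_classes, rng)
        layers = self._convs + self._dense

        # stratified validation split for early stopping
        val_idx: list[int] = []
        for c in range(n_classes):
            members = np.flatnonzero(yi == c)
            members = members[rng.permutation(members.size)]
            k = max(1, int(round(self.spec.validation_fraction * members.size)))
            val_idx.extend(members[:k].tolist())
        val_mask = np.zeros(X.shape[0], dtype=bool)
        val_mask[val_idx] = True
        if val_mask.all():
            val_mask[:] = False
        Xtr, ytr = X[~val_mask], yi[~val_mask]
        Xval, yval = X[val_mask], yi[val_mask]

        opt = _Adam(layers, self.spec.learning_rate)
        best_loss, best_params, patience = np.inf, None, 0
        for _epoch in range(self.spec.max_epochs):
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                logits = self._forward(Xtr[idx], train=True, rng=rng)
                probs = _softmax(logits)
                d = probs.copy()
                d[np.arange(idx.size), ytr[idx]] -= 1.0
                self._backward((d / idx.size).astype(np.float32))
                opt.step()
            if Xval.shape[0]:
                p = self.predict_proba(Xval)
                loss = -np.mean(np.log(
                    p[np.arange(Xval.shape[0]), yval] + 1e-12))
            else:
                p = self.predict_proba(Xtr)
                loss = -np.mean(np.log(p[np.arange(Xtr.shape[0]), ytr] + 1e-12))
            if loss < best_loss - 1e-5:
                best_loss = loss
                best_params = [(l.W.copy(), l.b.copy()) for l in layers]
                patience = 0
            else:
                patience += 1
                if patience >= self.spec.early_stop_patience:
                    break
            if loss < self.spec.convergence_loss:
                break
        if best_params is not None:
            for layer, (W, b) in zip(layers, best_params):
                layer.W, layer.b = W, b
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, X.shape[0], 256):
            logits = self._forward(X[start:start + 256], train=False)
            out.append(_softmax(logits))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
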