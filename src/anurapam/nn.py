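"""A small, deterministic NumPy CNN for spectrogram-image classification.

Implements exactly the compact architecture the classifier uses: three
valid-padding 3x3 convolution blocks with 32/64/128 filters, each followed
by ReLU and 2x2 max pooling, then flatten, a 512-unit ReLU dense layer and
a K-way softmax trained with cross-entropy and Adam.  Everything is float32,
seeded and single-threaded-reproducible: two runs with the same seed produce
bit-identical parameters and losses.

Convolutions avoid im2col copies: a 3x3 valid convolution is the sum of nine
shifted (N*oh*ow, cin) @ (cin, cout) matmuls, which is memory-light and fast
enough on one CPU for the dataset sizes this package trains at.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv3x3:
    """Valid 3x3 convolution, NHWC layout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * cin))
        self.w = (rng.standard_normal((3, 3, cin, cout)) * std).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, cin = x.shape
        oh, ow = h - 2, w - 2
        out = np.tile(self.b, (n, oh, ow, 1)).astype(DTYPE)
        for dy in range(3):
            for dx in range(3):
                patch = x[:, dy:dy + oh, dx:dx + ow, :].reshape(-1, cin)
                out += (patch @ self.w[dy, dx]).reshape(n, oh, ow, -1)
        if train:
            self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, cin = x.shape
        oh, ow = h - 2, w - 2
        cout = self.w.shape[-1]
        g2 = grad.reshape(-1, cout)
        self.db = grad.sum(axis=(0, 1, 2))
        self.dw = np.empty_like(self.w)
        dx = np.zeros_like(x)
        for dy in range(3):
            for dx_ in range(3):
                patch = x[:, dy:dy + oh, dx_:dx_ + ow, :].reshape(-1, cin)
                self.dw[dy, dx_] = patch.T @ g2
                dx[:, dy:dy + oh, dx_:dx_ + ow, :] += (
                    g2 @ self.w[dy, dx_].T).reshape(n, oh, ow, cin)
        self._x = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2, valid (odd trailing rows/cols dropped)."""

    def __init__(self):
        self._arg = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        win = x[:, : oh * 2, : ow * 2, :].reshape(n, oh, 2, ow, 2, c)
        win = win.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, 4, c)
        arg = win.argmax(axis=3)
        out = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._arg = arg
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        win_grad = np.zeros((n, oh, ow, 4, c), dtype=grad.dtype)
        np.put_along_axis(win_grad, self._arg[:, :, :, None, :],
                          grad[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : oh * 2, : ow * 2, :] = (
            win_grad.reshape(n, oh, ow, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5).reshape(n, oh * 2, ow * 2, c))
        self._arg = None
        return dx

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.w = (rng.standard_normal((nin, nout)) * std).astype(DTYPE)
        self.b = np.zeros(nout, dtype=DTYPE)
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adaptive-moment optimizer with the standard beta/epsilon defaults."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[tuple[str, object]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (name, layer) in enumerate(params):
            p = getattr(layer, name)
            g = getattr(layer, "d" + name)
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class SequentialCNN:
    """The conv32-pool-conv64-pool-conv128-pool-flatten-dense512-softmaxK net."""

    def __init__(self, input_shape: tuple[int, int, int], n_classes: int,
                 conv_filters: tuple[int, ...] = (32, 64, 128),
                 dense_units: int = 512, seed: int = 0):
        h, w, c = input_shape
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0DE]))
        self.input_shape = (h, w, c)
        self.n_classes = int(n_classes)
        self.conv_filters = tuple(conv_filters)
        self.dense_units = int(dense_units)
        self.seed = int(seed)

        layers: list = []
        cin = c
        for cout in conv_filters:
            layers += [Conv3x3(cin, cout, rng), ReLU(), MaxPool2()]
            h, w = (h - 2) // 2, (w - 2) // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for three conv/pool blocks")
            cin = cout
        layers.append(Flatten())
        flat = h * w * cin
        layers += [Dense(flat, dense_units, rng), ReLU(),
                   Dense(dense_units, n_classes, rng)]
        self.layers = layers

    # -- forward / predict --------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            probs.append(softmax(self._forward(x[i:i + batch_size], False)))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- training -----------------------------------------------------------

    def _params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int,
            batch_size: int = 32, learning_rate: float = 1e-3,
            seed: int | None = None, verbose: bool = False) -> dict:
        """Train with softmax cross-entropy and Adam; returns the history.

        Shuffling is seeded (defaults to the build seed), so training is
        reproducible bit-for-bit on the same machine.
        """
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        y = np.asarray(y)
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError("labels inconsistent with the number of classes")
        n = x.shape[0]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed if seed is None else int(seed), 1]))
        opt = Adam(lr=learning_rate)
        history = {"loss": [], "accuracy": []}
        params = self._params()
        for epoch in range(int(epochs)):
            order = rng.permutation(n)
            total_loss = 0.0
            correct = 0
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                xb = x[idx]
                yb = y[idx]
                logits = self._forward(xb, True)
                p = softmax(logits.astype(np.float64))
                eps = 1e-12
                total_loss += -np.log(p[np.arange(len(yb)), yb] + eps).sum()
                correct += int((p.argmax(axis=1) == yb).sum())
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad = (grad / len(yb)).astype(DTYPE)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(params)
            history["loss"].append(total_loss / n)
            history["accuracy"].append(correct / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  "
                      f"loss {history['loss'][-1]:.4f}  "
                      f"acc {history['accuracy'][-1]:.4f}")
        return history

    # -- introspection / persistence ----------------------------------------

    @property
    def n_params(self) -> int:
        return sum(getattr(layer, name).size for name, layer in self._params())

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for name, layer in self._params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self._params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (name, layer), w in zip(params, weights):
            cur = getattr(layer, name)
            if cur.shape != w.shape:
                raise ValueError("weight shape mismatch")
            setattr(layer, name, w.astype(cur.dtype))

    def save(self, path) -> None:
        meta = np.array([*self.input_shape, self.n_classes, self.dense_units,
                         self.seed, *self.conv_filters], dtype=np.int64)
        arrays = {f"p{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, meta=meta, **arrays)

    @classmethod
    def load(cls, path) -> "SequentialCNN":
        data = np.load(path)
        meta = data["meta"]
        h, w, c, k, dense, seed = (int(v) for v in meta[:6])
        filters = tuple(int(v) for v in meta[6:])
        net = cls((h, w, c), k, conv_filters=filters, dense_units=dense,
                  seed=seed)
        net.set_weights([data[f"p{i}"]
                         for i in range(len(net.get_weights()))])
        return net
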