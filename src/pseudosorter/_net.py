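"""Minimal dense-network engine used by the sorter.

Fully connected layers with ReLU hidden activations, manual backprop, and
Adam. Everything runs in float32 NumPy, which keeps training bit-reproducible
under a single integer seed on any CPU.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "softmax", "log_softmax"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Dense:
    """Affine layer y = xW + b with He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        # scale=0 gives a zero-initialized layer (used for classification
        # heads on top of a pretrained encoder, so the first updates do not
        # destroy the pretrained features through huge logits)
        std = np.sqrt(2.0 / n_in) if scale is None else scale
        self.W = (rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
                  if std > 0 else np.zeros((n_in, n_out), dtype=np.float32))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward(train=True)"
        self.gW += self._x.T @ gy
        self.gb += gy.sum(axis=0)
        return gy @ self.W.T

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class MLP:
    """Stack of Dense layers; ReLU between layers, linear output."""

    def __init__(self, dims, rng: np.random.Generator):
        dims = list(dims)
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.dims = dims
        self.layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self._masks: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if train:
            self._masks = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train=train)
            if i < last:
                if train:
                    self._masks.append(h > 0)
                h = np.maximum(h, 0.0)
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        last = len(self.layers) - 1
        for i in range(last, -1, -1):
            gy = self.layers[i].backward(gy)
            if i > 0:
                gy = gy * self._masks[i - 1]
        return gy

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights) -> None:
        it = iter(weights)
        for layer in self.layers:
            layer.W = np.asarray(next(it), dtype=np.float32).copy()
            layer.b = np.asarray(next(it), dtype=np.float32).copy()


class BatchNorm:
    """Per-feature batch normalization (training-mode statistics).

    Used inside the contrastive projection head, which is only ever run in
    training batches; no running statistics are kept. The mean subtraction
    removes the common activation direction that all-ReLU stacks produce,
    which would otherwise start cosine similarities near 1 and invite
    collapse.
    """

    def __init__(self, n_features: int, affine: bool = True,
                 eps: float = 1e-5):
        self.eps = eps
        self.affine = affine
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if train:
            self._xhat, self._istd = xhat, istd
        return self.gamma * xhat + self.beta if self.affine else xhat

    def zero_grad(self) -> None:
        self.ggamma[...] = 0.0
        self.gbeta[...] = 0.0

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        n = gy.shape[0]
        if self.affine:
            self.ggamma += (gy * xhat).sum(axis=0)
            self.gbeta += gy.sum(axis=0)
            gy = gy * self.gamma
        return (istd / n) * (n * gy - gy.sum(axis=0)
                             - xhat * (gy * xhat).sum(axis=0))

    @property
    def params(self):
        if not self.affine:
            return []
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ProjectionHead:
    """Dense -> BN -> ReLU -> Dense -> BN(no affine) contrastive head."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.fc1 = Dense(dim, dim, rng)
        self.bn1 = BatchNorm(dim)
        self.fc2 = Dense(dim, dim, rng)
        self.bn2 = BatchNorm(dim, affine=False)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.bn1.forward(self.fc1.forward(x, train), train)
        if train:
            self._mask = h > 0
        h = np.maximum(h, 0.0)
        return self.bn2.forward(self.fc2.forward(h, train), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.fc2.backward(self.bn2.backward(gy))
        gy = gy * self._mask
        return self.fc1.backward(self.bn1.backward(gy))

    @property
    def params(self):
        return (self.fc1.params + self.bn1.params + self.fc2.params
                + self.bn2.params)

    def zero_grad(self) -> None:
        for mod in (self.fc1, self.bn1, self.fc2, self.bn2):
            mod.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [self.fc1.W.copy(), self.fc1.b.copy(),
                self.bn1.gamma.copy(), self.bn1.beta.copy(),
                self.fc2.W.copy(), self.fc2.b.copy()]

    def set_weights(self, weights) -> None:
        (self.fc1.W, self.fc1.b, self.bn1.gamma, self.bn1.beta,
         self.fc2.W, self.fc2.b) = [
            np.asarray(w, dtype=np.float32).copy() for w in weights]


class Adam:
    """Adam over the (param, grad) slots of one or more modules."""

    def __init__(self, modules, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if not isinstance(modules, (list, tuple)):
            modules = [modules]
        self.modules = list(modules)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in self._slots()]
        self._v = [np.zeros_like(p) for p, _ in self._slots()]

    def _slots(self):
        out = []
        for mod in self.modules:
            out.extend(mod.params)
        return out

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self._slots()):
            m = self._m[i]
            v = self._v[i]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
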