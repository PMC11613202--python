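"""Minimal 1-D convolutional network engine with explicit backpropagation.

Implements exactly the layer set the spectral networks need — same-padded 1-D
convolutions, ReLU, max pooling, fully connected layers, identity-skip
residual blocks — plus AdamW and a reduce-on-plateau learning-rate schedule.
Every layer carries a hand-derived ``backward``; the test suite checks all of
them against central finite differences.

All arithmetic is plain numpy (float32 by default, see ``DTYPE``),
single-threaded and deterministic: the same seed yields bit-identical
training runs on one machine.
"""

from __future__ import annotations

import numpy as np

#: dtype of all parameters and activations.  float32 doubles GEMM throughput
#: (the training loop is BLAS-bound on skinny matrices); set to float64
#: before building a network when checking gradients against finite
#: differences.
DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in weight decay
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1d(Layer):
    """Same-padded 1-D convolution; odd kernel only.

    Operates channels-last, on (N, L, C) inputs, so every tap is one GEMM on
    contiguous memory with no transposition copies — the layout that keeps a
    pure-numpy training loop fast at spectrum-sized inputs.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-convolution")
        self.cin, self.cout, self.k = cin, cout, kernel
        # W[t] is the (cin, cout) matrix of tap t
        self.W = Param(_he_init(rng, (kernel, cin, cout), cin * kernel), name="conv.W")
        self.b = Param(np.zeros(cout), decay=False, name="conv.b")
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, L, C = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        flat = xp.reshape(N * (L + 2 * p), C)
        y = np.tile(self.b.value, (N, L, 1))
        for t in range(self.k):
            full = (flat @ self.W.value[t]).reshape(N, L + 2 * p, self.cout)
            y += full[:, t : t + L, :]
        self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None
        N, L, O = dy.shape
        p = self.k // 2
        dy2 = dy.reshape(N * L, O)
        dxp = np.zeros_like(xp)
        for t in range(self.k):
            xs = xp[:, t : t + L, :]
            self.W.grad[t] += np.einsum("nlc,nlo->co", xs, dy, optimize=True)
            dxp[:, t : t + L, :] += (dy2 @ self.W.value[t].T).reshape(N, L, self.cin)
        self.b.grad += dy2.sum(axis=0)
        return dxp[:, p : p + L, :]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis of (N, L, C)
    inputs; trailing remainder samples are dropped."""

    def __init__(self, size: int = 2):
        self.size = size
        self._idx: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, L, C = x.shape
        s = self.size
        lo = L // s
        if lo < 1:
            raise ValueError("input too short for pooling")
        xw = x[:, : lo * s, :].reshape(N, lo, s, C)
        self._idx = xw.argmax(axis=2)
        self._in_len = L
        return np.take_along_axis(xw, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, lo, C = dy.shape
        s = self.size
        dxw = np.zeros((N, lo, s, C), dtype=dy.dtype)
        np.put_along_axis(dxw, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((N, self._in_len, C), dtype=dy.dtype)
        dx[:, : lo * s, :] = dxw.reshape(N, lo * s, C)
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self,
        nin: int,
        nout: int,
        rng: np.random.Generator,
        bias_init: float = 0.0,
        w_scale: float = 1.0,
    ):
        self.W = Param(w_scale * _he_init(rng, (nout, nin), nin), name="fc.W")
        self.b = Param(np.full(nout, bias_init), decay=False, name="fc.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResidualBlock(Layer):
    """n same-convolutions with an identity skip: y = ReLU(x + convs(x)).

    Channel count is preserved so the skip is a plain addition.
    """

    def __init__(self, channels: int, kernel: int, n_convs: int, rng: np.random.Generator):
        layers: list[Layer] = []
        for i in range(n_convs):
            layers.append(Conv1d(channels, channels, kernel, rng))
            if i < n_convs - 1:
                layers.append(ReLU())
        self.body = Sequential(*layers)
        self.out_relu = ReLU()

    def parameters(self) -> list[Param]:
        return self.body.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.out_relu.forward(x + self.body.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.out_relu.backward(dy)
        return dsum + self.body.backward(dsum)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


class AdamW:
    """AdamW with decoupled weight decay (decay skipped for biases and any
    Param flagged decay=False, e.g. learned log-sigma loss weights)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if p.decay and self.weight_decay > 0:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the epoch loss stops improving.

    ``improved`` means the loss dropped below best - threshold within the
    last ``patience`` epochs.  Training should stop once lr < min_lr.
    """

    def __init__(
        self,
        optimizer: AdamW,
        factor: float = 0.5,
        patience: int = 10,
        threshold: float = 1e-4,
        min_lr: float = 1e-6,
    ):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.threshold:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.opt.lr *= self.factor
                self.stale = 0

    @property
    def done(self) -> bool:
        return self.opt.lr < self.min_lr


# ---------------------------------------------------------------------------
# Shared numerical helpers
# ---------------------------------------------------------------------------


def l2_normalize_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z / ||z||; zero rows stay zero.  Returns (z_hat, norms)."""
    norms = np.linalg.norm(z, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return z / safe[:, None], norms


def l2_normalize_rows_backward(
    dzhat: np.ndarray, z: np.ndarray, zhat: np.ndarray, norms: np.ndarray
) -> np.ndarray:
    """Backward of row-wise l2 normalization: (I - zhat zhat^T)/||z|| dzhat.

    Zero rows receive zero gradient (subgradient choice at the origin).
    """
    safe = np.where(norms > 0, norms, 1.0)
    proj = (dzhat * zhat).sum(axis=1, keepdims=True)
    dz = (dzhat - proj * zhat) / safe[:, None]
    dz[norms == 0] = 0.0
    return dz


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax via the log-sum-exp trick."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
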