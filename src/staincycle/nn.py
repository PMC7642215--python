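"""Minimal CPU neural-network layer library (numpy, manual backprop).

The translation networks and the patch classifier are plain layer stacks, so
instead of a full autodiff graph this module implements layer-wise forward /
backward passes over a :class:`Sequential` container. Every layer keeps a
*stack* of forward caches: a network may be forwarded several times before
gradients are propagated (a CycleGAN generator runs once to translate and once
to reconstruct within a single step), and ``backward`` calls must then arrive
in reverse (LIFO) order of the forwards. Parameter gradients accumulate until
``zero_grad``; the Adam optimizer reads them in place.

Shapes follow the NCHW convention; parameters and activations are float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Layer:
    """Base class: parameter dict, gradient dict, forward-cache stack."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def clear_cache(self) -> None:
        self._cache.clear()

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _init_weight(rng: np.random.Generator, shape, fan_in: int, init: str) -> np.ndarray:
    if init == "gan":        # DCGAN-style init
        w = rng.normal(0.0, 0.02, size=shape)
    elif init == "he":
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    else:
        raise ValueError(f"unknown init {init!r}")
    return w.astype(DTYPE)


class Conv2d(Layer):
    def __init__(self, in_c: int, out_c: int, k: int, s: int = 1, p: int = 0,
                 rng: np.random.Generator | None = None, init: str = "gan") -> None:
        super().__init__()
        self.in_c, self.out_c, self.k, self.s, self.p = in_c, out_c, k, s, p
        rng = rng or np.random.default_rng(0)
        self._register("W", _init_weight(rng, (out_c, in_c, k, k), in_c * k * k, init))
        self._register("b", np.zeros(out_c, dtype=DTYPE))

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_c:
            raise ValueError(f"Conv2d expects {self.in_c} channels, got {c}")
        ho, wo = self.out_shape(h, w)
        xp = _pad2d(x, self.p)
        # im2col: one BLAS matmul instead of k*k small contractions
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                       axis=(2, 3))
        win = win[:, :, ::self.s, ::self.s]              # n, c, ho, wo, k, k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, c * self.k * self.k)
        wmat = self.params["W"].reshape(self.out_c, -1)
        y = cols @ wmat.T + self.params["b"]
        self._cache.append((cols, x.shape, ho, wo))
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(
            n, self.out_c, ho, wo)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache.pop()
        n, c, h, w = xshape
        gyf = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(
            n, ho * wo, self.out_c)
        wmat = self.params["W"].reshape(self.out_c, -1)
        self.grads["W"] += (gyf.reshape(-1, self.out_c).T @
                            cols.reshape(-1, c * self.k * self.k)
                            ).reshape(self.params["W"].shape)
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        gcols = (gyf @ wmat).reshape(n, ho, wo, c, self.k, self.k)
        gcols = gcols.transpose(0, 3, 4, 5, 1, 2)        # n, c, k, k, ho, wo
        hp, wp = h + 2 * self.p, w + 2 * self.p
        gxp = np.zeros((n, c, hp, wp), dtype=gy.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                gxp[:, :, ki:ki + ho * self.s:self.s,
                    kj:kj + wo * self.s:self.s] += gcols[:, :, ki, kj]
        p = self.p
        if p:
            return gxp[:, :, p:p + h, p:p + w]
        return gxp


class ConvTranspose2d(Layer):
    """Transposed convolution; weight layout (in_c, out_c, k, k)."""

    def __init__(self, in_c: int, out_c: int, k: int, s: int = 1, p: int = 0,
                 op: int = 0, rng: np.random.Generator | None = None,
                 init: str = "gan") -> None:
        super().__init__()
        self.in_c, self.out_c, self.k, self.s, self.p, self.op = in_c, out_c, k, s, p, op
        rng = rng or np.random.default_rng(0)
        self._register("W", _init_weight(rng, (in_c, out_c, k, k), in_c * k * k, init))
        self._register("b", np.zeros(out_c, dtype=DTYPE))

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.s - 2 * self.p + self.k + self.op,
                (w - 1) * self.s - 2 * self.p + self.k + self.op)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_c:
            raise ValueError(f"ConvTranspose2d expects {self.in_c} channels, got {c}")
        ho, wo = self.out_shape(h, w)
        hc = (h - 1) * self.s + self.k + self.op
        wc = (w - 1) * self.s + self.k + self.op
        canvas = np.zeros((n, self.out_c, hc, wc), dtype=x.dtype)
        W = self.params["W"]
        for ki in range(self.k):
            for kj in range(self.k):
                canvas[:, :, ki:ki + h * self.s:self.s, kj:kj + w * self.s:self.s] += \
                    np.einsum("nchw,co->nohw", x, W[:, :, ki, kj], optimize=True)
        y = canvas[:, :, self.p:self.p + ho, self.p:self.p + wo]
        y = y + self.params["b"][None, :, None, None]
        self._cache.append((x, ho, wo))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, ho, wo = self._cache.pop()
        n, c, h, w = x.shape
        # Re-embed the output gradient in the uncropped canvas frame.
        gcanvas = _pad2d(gy, self.p)
        W = self.params["W"]
        gx = np.zeros_like(x)
        for ki in range(self.k):
            for kj in range(self.k):
                gs = gcanvas[:, :, ki:ki + h * self.s:self.s, kj:kj + w * self.s:self.s]
                self.grads["W"][:, :, ki, kj] += np.einsum(
                    "nchw,nohw->co", x, gs, optimize=True)
                gx += np.einsum("nohw,co->nchw", gs, W[:, :, ki, kj], optimize=True)
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        return gx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel spatial normalization (no affine parameters)."""

    def __init__(self, num_features: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.num_features = num_features
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache.append((xhat, inv))
        return xhat

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache.pop()
        m1 = gy.mean(axis=(2, 3), keepdims=True)
        m2 = (gy * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (gy - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.maximum(x, 0)
        self._cache.append(x > 0)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._cache.pop()


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos = x > 0
        self._cache.append(pos)
        return np.where(pos, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        pos = self._cache.pop()
        return np.where(pos, gy, self.slope * gy)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.tanh(x)
        self._cache.append(y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y = self._cache.pop()
        return gy * (1.0 - y * y)


class GlobalAvgPool2d(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache.append(x.shape)
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache.pop()
        return np.broadcast_to(gy[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 init: str = "he") -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self._register("W", _init_weight(rng, (out_f, in_f), in_f, init))
        self._register("b", np.zeros(out_f, dtype=DTYPE))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache.append(x)
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._cache.pop()
        self.grads["W"] += gy.T @ x
        self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def clear_cache(self) -> None:
        for layer in self.layers:
            layer.clear_cache()

    def named_parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "named_parameters"):
                out.extend(layer.named_parameters())
            else:
                out.extend((layer, name) for name in layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.named_parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": layer.params[name]
                for i, (layer, name) in enumerate(self.named_parameters())}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, (layer, name) in enumerate(self.named_parameters()):
            arr = state[f"{i}.{name}"]
            if arr.shape != layer.params[name].shape:
                raise ValueError(f"shape mismatch for parameter {i}.{name}")
            layer.params[name] = arr.astype(DTYPE).copy()
            layer.grads[name] = np.zeros_like(layer.params[name])

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


class Adam:
    """Adam over one or more Sequential networks."""

    def __init__(self, nets: list[Sequential], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8) -> None:
        self.nets = nets
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._slots = [(layer, name) for net in nets for layer, name in net.named_parameters()]
        self._m = [np.zeros_like(layer.params[name]) for layer, name in self._slots]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in self._slots]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self._slots):
            g = layer.grads[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for net in self.nets:
            net.zero_grad()


# ---------------------------------------------------------------------------
# Losses. Each returns (scalar loss, gradient w.r.t. the first argument).
# ---------------------------------------------------------------------------

def bce_with_logits(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on raw scores (sigmoid applied internally)."""
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite discriminator scores")
    s = scores.astype(np.float64)
    # stable log(1 + exp(-|s|)) formulation
    loss = np.maximum(s, 0) - s * target + np.log1p(np.exp(-np.abs(s)))
    grad = (expit(s) - target) / s.size
    return float(loss.mean()), grad.astype(DTYPE)


def mse_to(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    d = scores.astype(np.float64) - target
    return float((d * d).mean()), (2.0 * d / d.size).astype(DTYPE)


def l1(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.abs(d).mean()), (np.sign(d) / d.size).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch; labels are integer class indices."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
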