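"""A compact, fully seeded CPU convolutional-network engine.

Implements exactly what the profiling pipeline needs — strided 3×3
convolutions, residual blocks, global average pooling, a linear head,
softmax cross-entropy, Adam, and activation/gradient capture for GradCAM —
with every array operation in NumPy and all randomness drawn from one
Generator, so that training runs are bit-reproducible on a single CPU.

Convolution runs as one im2col copy plus BLAS matrix products, which is
fast at the crop sizes this package works with (≤ ~200 px).
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Residual", "GlobalAvgPool", "Linear", "ConvNet", "Adam",
           "build_model", "softmax", "cross_entropy"]


class Module:
    def parameters(self) -> list[dict]:
        return []

    def clear_cache(self) -> None:
        pass

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Module):
    """k×k convolution, stride s, zero padding p, He-initialized.

    Forward/backward run as one im2col copy plus BLAS matrix products."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [
            {"value": self.W, "grad": self.gW},
            {"value": self.b, "grad": self.gb},
        ]

    def _out_hw(self, H, W):
        k, s, p = self.k, self.stride, self.pad
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x, train=False):
        from numpy.lib.stride_tricks import sliding_window_view

        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        Ho, Wo = self._out_hw(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp_shape = xp.shape
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # N,C,Ho,Wo,k,k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        self._cols = cols
        Wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wmat.T + self.b
        return np.ascontiguousarray(out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2))

    def backward(self, g):
        k, s, p = self.k, self.stride, self.pad
        N, cout, Ho, Wo = g.shape
        C = self._xp_shape[1]
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, cout)
        self.gb += g2.sum(axis=0)
        self.gW += (g2.T @ self._cols).reshape(self.W.shape)
        gcols = g2 @ self.W.reshape(cout, -1)  # N*Ho*Wo, C*k*k
        gwin = gcols.reshape(N, Ho, Wo, C, k, k)
        gxp = np.zeros(self._xp_shape, dtype=g.dtype)
        for dy in range(k):
            for dx in range(k):
                gxp[:, :, dy : dy + Ho * s : s, dx : dx + Wo * s : s] += gwin[
                    :, :, :, :, dy, dx
                ].transpose(0, 3, 1, 2)
        self._cols = None
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp

    def clear_cache(self):
        self._cols = None


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Normalizing with batch statistics keeps the optimization away from the
    uniform-logit saddle and gives the small residual nets the memorization
    capacity their full-scale counterparts have."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [
            {"value": self.gamma, "grad": self.ggamma},
            {"value": self.beta, "grad": self.gbeta},
        ]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv.astype(x.dtype), train)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, inv, train = self._cache
        self.ggamma += (g * xhat).sum(axis=(0, 2, 3))
        self.gbeta += g.sum(axis=(0, 2, 3))
        gxh = g * self.gamma[None, :, None, None]
        if not train:
            return gxh * inv[None, :, None, None]
        n = g.shape[0] * g.shape[2] * g.shape[3]
        sum_g = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / n) * (n * gxh - sum_g - xhat * sum_gx)

    def clear_cache(self):
        self._cache = None

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def clear_cache(self):
        self._mask = None


class Residual(Module):
    """y = relu(x + conv2(relu(conv1(x)))) — identity skip, constant width."""

    def __init__(self, channels, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(channels, dtype=dtype)
        self.relu_out = ReLU()

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())

    def forward(self, x, train=False):
        h = self.conv1.forward(x)
        h = self.relu1.forward(self.bn1.forward(h, train))
        h = self.bn2.forward(self.conv2.forward(h), train)
        return self.relu_out.forward(x + h)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        return g + gh

    def clear_cache(self):
        for m in (self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out):
            m.clear_cache()

    def buffers(self):
        return self.bn1.buffers() + self.bn2.buffers()


class GlobalAvgPool(Module):
    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, g):
        H, W = self._hw
        return np.repeat(np.repeat(g[:, :, None, None], H, axis=2), W, axis=3) / (H * W)


class Linear(Module):
    def __init__(self, din, dout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((dout, din)) * np.sqrt(2.0 / din)).astype(dtype)
        self.b = np.zeros(dout, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [
            {"value": self.W, "grad": self.gW},
            {"value": self.b, "grad": self.gb},
        ]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.gW += g.T @ self._x
        self.gb += g.sum(axis=0)
        return g @ self.W

    def clear_cache(self):
        self._x = None


class ConvNet:
    """Sequential conv net: conv body → GAP → linear head.

    The GAP output is the embedding. `forward(record_layer=i)` captures the
    activation of body module i and `backward(capture_layer=i)` its
    gradient, which is what class-activation mapping needs.
    """

    def __init__(self, body: list[Module], head: Linear, n_classes: int, arch: str = "custom",
                 dtype=np.float32):
        self.dtype = dtype
        self.body = body
        self.pool = GlobalAvgPool()
        self.head = head
        self.n_classes = n_classes
        self.arch = arch
        self.trained = False

    def parameters(self):
        ps = []
        for m in self.body:
            ps += m.parameters()
        return ps + self.head.parameters()

    def zero_grad(self):
        for p in self.parameters():
            p["grad"][...] = 0.0

    def forward(self, x, train: bool = False, record_layer: int | None = None):
        x = np.asarray(x, dtype=self.dtype)
        self._recorded = None
        for i, m in enumerate(self.body):
            x = m.forward(x, train) if isinstance(m, (BatchNorm2d, Residual)) else m.forward(x)
            if record_layer is not None and i == record_layer:
                self._recorded = x
        self._emb = self.pool.forward(x)
        return self.head.forward(self._emb)

    def backward(self, glogits, capture_layer: int | None = None):
        """Backprop from dL/dlogits; optionally return dL/d(activation) at a
        body layer (for GradCAM) alongside accumulating parameter grads."""
        g = self.pool.backward(self.head.backward(glogits))
        captured = None
        for i in range(len(self.body) - 1, -1, -1):
            if capture_layer is not None and i == capture_layer:
                captured = g
            g = self.body[i].backward(g)
        return captured

    def clear_caches(self):
        """Drop forward caches (im2col buffers, masks) kept for backward."""
        for m in self.body:
            m.clear_cache()
        self.head.clear_cache()

    def embed(self, x, batch_size=128) -> np.ndarray:
        """Penultimate (GAP) representation, fixed dimension."""
        outs = []
        for i in range(0, len(x), batch_size):
            self.forward(x[i : i + batch_size])
            outs.append(self._emb.copy())
            self.clear_caches()
        return np.concatenate(outs, axis=0)

    def predict_logits(self, x, batch_size=128) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size]))
            self.clear_caches()
        return np.concatenate(outs, axis=0)

    def predict(self, x, batch_size=256) -> np.ndarray:
        return self.predict_logits(x, batch_size).argmax(axis=1)

    def _buffers(self):
        out = []
        for m in self.body:
            out += m.buffers()
        return out

    def state_dict(self):
        return [p["value"].copy() for p in self.parameters()] + [
            b.copy() for b in self._buffers()
        ]

    def load_state_dict(self, state):
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p["value"][...] = s
        for b, s in zip(self._buffers(), state[len(params) :]):
            b[...] = s

    def clone(self) -> "ConvNet":
        return copy.deepcopy(self)


def build_model(arch: str, in_channels: int, n_classes: int, rng: np.random.Generator,
                dtype=np.float32) -> ConvNet:
    """Model factory.

    "resnet18_small" — narrow residual net (16/32/64 channels, one residual
    block per stage), the desk-scale default for ~55-px crops.
    "resnet50" — the full-scale recipe's architecture family rendered in this
    engine: wider (32/64/128/256) and deeper (two residual blocks per stage).
    """
    if arch == "resnet18_small":
        widths, blocks = (16, 32, 64), 1
    elif arch == "resnet50":
        widths, blocks = (32, 64, 128, 256), 2
    else:
        raise ValueError(f"unknown architecture {arch!r}")
    body: list[Module] = []
    cin = in_channels
    for w in widths:
        body.append(Conv2d(cin, w, stride=2, rng=rng, dtype=dtype))
        body.append(BatchNorm2d(w, dtype=dtype))
        body.append(ReLU())
        for _ in range(blocks):
            body.append(Residual(w, rng=rng, dtype=dtype))
        cin = w
    head = Linear(cin, n_classes, rng=rng, dtype=dtype)
    return ConvNet(body, head, n_classes, arch=arch, dtype=dtype)


class Adam:
    def __init__(self, params: list[dict], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p
    g[np.arange(n), y] -= 1.0
    return float(loss), g / n
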