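"""Minimal convolutional-network engine (numpy, CPU).

Implements exactly what the CDF-regression estimator needs: 3x3
convolutions (stride 1 or 2, zero padding 1), ReLU, dense layers, a
monotone CDF head (softmax increments + running sum), the W1 training loss,
and Adam.  Forward/backward passes are plain numpy in float32, so runs are
bit-reproducible under a fixed seed on a given platform.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np


def _conv_slices(xp: np.ndarray, stride: int, h_out: int, w_out: int):
    """Yield the nine 3x3-tap views of a padded input (B, C, Hp, Wp)."""
    for ki in range(3):
        for kj in range(3):
            yield xp[:, :, ki:ki + stride * h_out:stride,
                     kj:kj + stride * w_out:stride]


class Conv3x3:
    """3x3 convolution, zero padding 1, stride 1 or 2, ReLU fused optional."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = (rng.standard_normal((c_out, c_in, 3, 3))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        s = self.stride
        h_out, w_out = h // s, w // s
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.stack([v.reshape(b, c, -1) for v in
                         _conv_slices(xp, s, h_out, w_out)], axis=2)
        cols = np.ascontiguousarray(cols.reshape(b, c * 9, h_out * w_out))
        # weight layout matches cols layout (channel slow, tap fast)
        wm = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(wm, cols) + self.b[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(b, -1, h_out, w_out)

    def backward(self, grad: np.ndarray):
        x_shape, cols = self._cache
        b, c, h, w = x_shape
        s = self.stride
        h_out, w_out = h // s, w // s
        g = np.ascontiguousarray(grad.reshape(b, -1, h_out * w_out))
        wm = self.w.reshape(self.w.shape[0], -1)
        self.dw = np.tensordot(g, cols, axes=([0, 2], [0, 2])).reshape(self.w.shape)
        self.db = g.sum(axis=(0, 2))
        dcols = np.matmul(wm.T, g)
        dcols = dcols.reshape(b, c, 9, h_out, w_out)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=np.float32)
        k = 0
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s] += dcols[:, :, k]
                k += 1
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    n_params = 0

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm2d:
    """Per-channel batch normalization with learned scale/shift.

    Uses batch statistics while training and exponential running statistics
    for inference; switched by ``train_mode``.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.w = np.ones(c, dtype=np.float32)   # gamma
        self.b = np.zeros(c, dtype=np.float32)  # beta
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.train_mode = True

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x):
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return (self.w[None, :, None, None] * xhat
                + self.b[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dw = (grad * xhat).sum(axis=(0, 2, 3))
        self.db = grad.sum(axis=(0, 2, 3))
        g = self.w[None, :, None, None] * grad
        if self.train_mode:
            gm = g.mean(axis=(0, 2, 3), keepdims=True)
            gx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = (g - gm - xhat * gx) * inv[None, :, None, None]
        else:
            dx = g * inv[None, :, None, None]
        return dx.astype(np.float32)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_out, n_in))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.w


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclasses.dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self, layers_with_grads) -> None:
        self._t += 1
        for layer in layers_with_grads:
            for name, gname in (("w", "dw"), ("b", "db")):
                if not hasattr(layer, gname):
                    continue
                p = getattr(layer, name)
                g = getattr(layer, gname).astype(np.float32)
                # clip per-tensor gradient norm (rare huge batches destabilize
                # the batch-norm statistics early in training)
                norm = float(np.sqrt((g * g).sum()))
                cap = 10.0 * np.sqrt(g.size)
                if norm > cap:
                    g = g * (cap / norm)
                key = id(layer) * 2 + (name == "b")
                if key not in self._state:
                    self._state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._state[key]
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                mhat = m / (1 - self.beta1**self._t)
                vhat = v / (1 - self.beta2**self._t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


class SpeckleNet:
    """Four convolutional stages + fully connected head emitting a CDF.

    Each stage is [Conv3x3(stride 2), BatchNorm, ReLU, Conv3x3, BatchNorm,
    ReLU]; the head is Dense -> ReLU -> Dense -> softmax increments ->
    cumulative sum, so every output is a valid nondecreasing CDF ending at
    1 by construction.
    """

    def __init__(self, channels: tuple[int, ...], hidden: int, n_out: int,
                 input_size: int, seed: int, in_channels: int = 1):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.in_channels = in_channels
        self.stages: list[list] = []
        c_prev = in_channels
        size = input_size
        for c in channels:
            self.stages.append([Conv3x3(c_prev, c, 2, rng), BatchNorm2d(c),
                                ReLU(), Conv3x3(c, c, 1, rng), BatchNorm2d(c),
                                ReLU()])
            c_prev = c
            size //= 2
        self.flat_dim = c_prev * size * size
        self.head = [Dense(self.flat_dim, hidden, rng), ReLU(),
                     Dense(hidden, n_out, rng)]
        self.trainable = [True] * (len(self.stages) + 1)  # stages + head

    # -- bookkeeping ------------------------------------------------------
    def stage_param_counts(self) -> list[int]:
        counts = [sum(l.n_params for l in st if hasattr(l, "n_params"))
                  for st in self.stages]
        counts.append(sum(l.n_params for l in self.head))
        return counts

    def n_params(self) -> int:
        return int(sum(self.stage_param_counts()))

    def _param_layers(self):
        for st in self.stages:
            for l in st:
                if hasattr(l, "w"):
                    yield l
        for l in self.head:
            if hasattr(l, "w"):
                yield l

    def stage_digest(self, index: int) -> str:
        """sha256 of a stage's parameters (index len(stages) = head)."""
        h = hashlib.sha256()
        group = self.stages[index] if index < len(self.stages) else self.head
        for l in group:
            if hasattr(l, "w"):
                h.update(np.ascontiguousarray(l.w).tobytes())
                h.update(np.ascontiguousarray(l.b).tobytes())
            if isinstance(l, BatchNorm2d):
                h.update(np.ascontiguousarray(l.run_mean).tobytes())
                h.update(np.ascontiguousarray(l.run_var).tobytes())
        return h.hexdigest()

    def digests(self) -> list[str]:
        return [self.stage_digest(i) for i in range(len(self.stages) + 1)]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, C, n, n) float32 -> CDF (B, n_out).

        With ``train`` the batch-norm layers of *trainable* stages use (and
        update) batch statistics; frozen stages always run in inference
        mode, so fine-tuning leaves them bitwise untouched.
        """
        h = x.astype(np.float32)
        for flag, st in zip(self.trainable, self.stages):
            for l in st:
                if isinstance(l, BatchNorm2d):
                    l.train_mode = bool(train and flag)
        for st in self.stages:
            for l in st:
                h = l.forward(h)
        h = h.reshape(h.shape[0], -1)
        for l in self.head:
            h = l.forward(h)
        self._q = softmax(h)
        return np.cumsum(self._q, axis=1)

    def backward(self, dcdf: np.ndarray) -> None:
        # through cumsum: dq_j = sum_{k>=j} dcdf_k
        dq = np.flip(np.cumsum(np.flip(dcdf, axis=1), axis=1), axis=1)
        q = self._q
        dz = q * (dq - (q * dq).sum(axis=1, keepdims=True))
        g = dz.astype(np.float32)
        for l in reversed(self.head):
            g = l.backward(g)
        b = g.shape[0]
        size = self.input_size // 2 ** len(self.stages)
        g = g.reshape(b, -1, size, size)
        for st in reversed(self.stages):
            for l in reversed(st):
                g = l.backward(g)

    def trainable_layers(self):
        out = []
        for flag, st in zip(self.trainable, self.stages):
            if flag:
                out.extend(l for l in st if hasattr(l, "w"))
        if self.trainable[-1]:
            out.extend(l for l in self.head if hasattr(l, "w"))
        return out

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self._param_layers()):
            out[f"w{i}"] = l.w
            out[f"b{i}"] = l.b
            if isinstance(l, BatchNorm2d):
                out[f"rm{i}"] = l.run_mean
                out[f"rv{i}"] = l.run_var
        return out

    def load_state_arrays(self, arrays) -> None:
        for i, l in enumerate(self._param_layers()):
            l.w = np.ascontiguousarray(arrays[f"w{i}"], dtype=np.float32)
            l.b = np.ascontiguousarray(arrays[f"b{i}"], dtype=np.float32)
            if isinstance(l, BatchNorm2d):
                l.run_mean = np.ascontiguousarray(arrays[f"rm{i}"], dtype=np.float32)
                l.run_var = np.ascontiguousarray(arrays[f"rv{i}"], dtype=np.float32)


def w1_batch_loss(cdf: np.ndarray, target: np.ndarray,
                  bin_weights: np.ndarray,
                  huber_delta: float = 0.0) -> tuple[float, np.ndarray]:
    """Mean W1 (um) over a batch and its gradient wrt the predicted CDF.

    With ``huber_delta`` > 0 the per-bin absolute error is smoothed below
    ``huber_delta`` (in CDF units), which removes the constant-magnitude
    sign gradients near the optimum; the reported loss still equals W1 for
    errors beyond the smoothing scale.
    """
    diff = cdf - target
    if huber_delta > 0:
        a = np.abs(diff)
        per = np.where(a < huber_delta, a * a / (2 * huber_delta),
                       a - huber_delta / 2)
        loss = float((per @ bin_weights).mean())
        grad = np.clip(diff / huber_delta, -1.0, 1.0) * bin_weights[None, :] \
            / cdf.shape[0]
    else:
        loss = float((np.abs(diff) @ bin_weights).mean())
        grad = np.sign(diff) * bin_weights[None, :] / cdf.shape[0]
    return loss, grad.astype(np.float32)
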