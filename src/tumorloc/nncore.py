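"""Minimal 3D neural-network compute core (NumPy, CPU).

Layers operate on arrays of shape ``(n, c, d, h, w)`` and implement explicit
``forward``/``backward`` passes; networks wire them together by hand.  The
set of primitives is exactly what the two segmentation architectures need:

* ``Conv3d`` — 3x3x3 / 1x1x1 convolution, valid or same padding, realised as
  a sum of per-offset channel matmuls (no im2col buffer);
* ``BatchNorm3d`` / ``GroupNorm3d`` — with the standard simplified backward;
* ``ReLU``, ``Dropout``, ``MaxPool3d(2)``;
* ``LinearResize`` — any separable linear spatial map expressed as one
  interpolation matrix per axis, used for average pooling (kernel 3,
  stride 3, pad 1) and trilinear upsampling; its backward is the exact
  adjoint (transposed matrices);
* softmax cross-entropy with optional per-voxel selection, and Adam with
  the AMSGrad correction and L2 weight decay.

Everything is deterministic given the ``numpy.random.Generator`` handed to
the network; float32 is the default compute dtype (float64 available for
gradient checking).
"""

from __future__ import annotations

import numpy as np

_OFFSETS3 = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


class Layer:
    """Base: stateless unless it owns parameters (``params``/``grads``)."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv3d(Layer):
    def __init__(self, cin: int, cout: int, ksize: int, padding: str | int = 0,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * ksize**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize, ksize))
        self.params = {"w": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.ksize = ksize
        self.pad = ksize // 2 if padding == "same" else int(padding)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.pad:
            p = self.pad
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._x = x
        w, b = self.params["w"], self.params["b"]
        n, c, D, H, W = x.shape
        k = self.ksize
        od, oh, ow = D - k + 1, H - k + 1, W - k + 1
        V = od * oh * ow
        out = np.zeros((n, w.shape[0], V), dtype=x.dtype)
        if k == 1:
            out += np.matmul(w[:, :, 0, 0, 0], x.reshape(n, c, V))
        else:
            for i, j, l in _OFFSETS3:
                xs = np.ascontiguousarray(
                    x[:, :, i:i + od, j:j + oh, l:l + ow]).reshape(n, c, V)
                out += np.matmul(w[:, :, i, j, l], xs)
        out = out.reshape(n, w.shape[0], od, oh, ow)
        out += b[None, :, None, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        w = self.params["w"]
        n, c, D, H, W = x.shape
        k = self.ksize
        od, oh, ow = gout.shape[2:]
        V = od * oh * ow
        gflat = np.ascontiguousarray(gout).reshape(n, -1, V)
        gx = np.zeros_like(x)
        if k == 1:
            xs = x.reshape(n, c, V)
            self.grads["w"][:, :, 0, 0, 0] += np.matmul(
                gflat, xs.transpose(0, 2, 1)).sum(axis=0)
            gx += np.matmul(w[:, :, 0, 0, 0].T, gflat).reshape(x.shape)
        else:
            for i, j, l in _OFFSETS3:
                xs = np.ascontiguousarray(
                    x[:, :, i:i + od, j:j + oh, l:l + ow]).reshape(n, c, V)
                self.grads["w"][:, :, i, j, l] += np.matmul(
                    gflat, xs.transpose(0, 2, 1)).sum(axis=0)
                gx[:, :, i:i + od, j:j + oh, l:l + ow] += np.matmul(
                    w[:, :, i, j, l].T, gflat).reshape(n, c, od, oh, ow)
        self.grads["b"] += gout.sum(axis=(0, 2, 3, 4))
        if self.pad:
            p = self.pad
            gx = gx[:, :, p:-p, p:-p, p:-p]
        return gx


class BatchNorm3d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ax = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * ivstd[None, :, None, None, None]
        self._xhat, self._ivstd, self._train = xhat, ivstd, train
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None, None, None] * xhat + b[None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        ax = (0, 2, 3, 4)
        xhat, ivstd = self._xhat, self._ivstd
        self.grads["gamma"] += (gout * xhat).sum(axis=ax)
        self.grads["beta"] += gout.sum(axis=ax)
        g = self.params["gamma"][None, :, None, None, None]
        dxhat = gout * g
        if not self._train:
            return dxhat * ivstd[None, :, None, None, None]
        N = gout.shape[0] * gout.shape[2] * gout.shape[3] * gout.shape[4]
        s1 = dxhat.sum(axis=ax)[None, :, None, None, None]
        s2 = (dxhat * xhat).sum(axis=ax)[None, :, None, None, None]
        return (ivstd[None, :, None, None, None] / N) * (N * dxhat - s1 - xhat * s2)


class GroupNorm3d(Layer):
    def __init__(self, c: int, n_groups: int = 4, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        if c % n_groups != 0:
            n_groups = 1  # degrade gracefully for tiny widths
        self.g = n_groups
        self.eps = eps
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, D, H, W = x.shape
        xg = x.reshape(n, self.g, c // self.g, D, H, W)
        ax = (2, 3, 4, 5)
        mean = xg.mean(axis=ax, keepdims=True)
        var = xg.var(axis=ax, keepdims=True)
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mean) * ivstd
        self._xhat, self._ivstd, self._shape = xhat, ivstd, x.shape
        y = xhat.reshape(n, c, D, H, W)
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None, None, None] * y + b[None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, D, H, W = self._shape
        xhat, ivstd = self._xhat, self._ivstd
        y = xhat.reshape(n, c, D, H, W)
        self.grads["gamma"] += (gout * y).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += gout.sum(axis=(0, 2, 3, 4))
        g = self.params["gamma"][None, :, None, None, None]
        dxhat = (gout * g).reshape(n, self.g, c // self.g, D, H, W)
        N = (c // self.g) * D * H * W
        ax = (2, 3, 4, 5)
        s1 = dxhat.sum(axis=ax, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=ax, keepdims=True)
        gx = (ivstd / N) * (N * dxhat - s1 - xhat * s2)
        return gx.reshape(n, c, D, H, W)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask.astype(gout.dtype)


class MaxPool3d2(Layer):
    """2x2x2 max pooling; spatial dims must be even.  Tied maxima share the
    gradient (valid subgradient)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, D, H, W = x.shape
        xr = x.reshape(n, c, D // 2, 2, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        m = xr == out[:, :, :, None, :, None, :, None]
        self._m = m / m.sum(axis=(3, 5, 7), keepdims=True)
        self._inshape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout[:, :, :, None, :, None, :, None] * self._m
        return g.reshape(self._inshape).astype(gout.dtype)


def avgpool_matrix(L: int, k: int = 3, s: int = 3, p: int = 1) -> np.ndarray:
    """Interpolation matrix of 1D average pooling, count-include-pad."""
    out = (L + 2 * p - k) // s + 1
    M = np.zeros((out, L))
    for i in range(out):
        for j in range(k):
            idx = s * i - p + j
            if 0 <= idx < L:
                M[i, idx] = 1.0 / k
    return M


def upsample_matrix(L: int, factor: int) -> np.ndarray:
    """Interpolation matrix of 1D linear upsampling (half-pixel centers)."""
    out = L * factor
    M = np.zeros((out, L))
    for i in range(out):
        pos = (i + 0.5) / factor - 0.5
        i0 = int(np.floor(pos))
        w = pos - i0
        i0c = min(max(i0, 0), L - 1)
        i1c = min(max(i0 + 1, 0), L - 1)
        M[i, i0c] += 1.0 - w
        M[i, i1c] += w
    return M


class LinearResize(Layer):
    """Separable linear spatial map: one matrix per spatial axis, applied by
    tensordot; backward applies the transposes (exact adjoint)."""

    def __init__(self, mats: list[np.ndarray], dtype=np.float32):
        super().__init__()
        self.mats = [m.astype(dtype) for m in mats]

    @staticmethod
    def _apply(x: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
        for axis, M in enumerate(mats):
            x = np.moveaxis(np.tensordot(x, M, axes=([2 + axis], [1])), -1, 2 + axis)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self._apply(x, self.mats)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self._apply(gout, [M.T for M in self.mats])


def avgpool3_layer(shape: tuple[int, int, int], dtype=np.float32) -> LinearResize:
    return LinearResize([avgpool_matrix(L) for L in shape], dtype=dtype)


def upsample_layer(shape: tuple[int, int, int], factor: int, dtype=np.float32) -> LinearResize:
    return LinearResize([upsample_matrix(L, factor) for L in shape], dtype=dtype)


def log_softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    return np.exp(log_softmax(logits, axis=axis))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          select: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over (optionally selected) voxels.

    ``logits``: (n, C, *spatial); ``targets``: (n, *spatial) int class index;
    ``select``: optional boolean mask of voxels contributing to the mean.
    Returns (loss, dlogits).
    """
    lsm = log_softmax(logits, axis=1)
    tgt = np.expand_dims(targets, 1)
    nll = -np.take_along_axis(lsm, tgt, axis=1)[:, 0]
    if select is None:
        select = np.ones_like(nll, dtype=bool)
    nsel = int(select.sum())
    if nsel == 0:
        return 0.0, np.zeros_like(logits)
    loss = float(nll[select].sum() / nsel)
    p = np.exp(lsm)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, tgt, 1.0, axis=1)
    d = (p - onehot) * np.expand_dims(select, 1) / nsel
    return loss, d.astype(logits.dtype)


class AdamAMSGrad:
    """Adam with the AMSGrad maximum-of-second-moment correction and a
    classic L2 penalty added to the gradient."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.items = [(lay, name) for lay in layers for name in lay.params]
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(lay.params[n]) for lay, n in self.items]
        self.v = [np.zeros_like(lay.params[n]) for lay, n in self.items]
        self.vhat = [np.zeros_like(lay.params[n]) for lay, n in self.items]
        self.t = 0

    def zero_grad(self) -> None:
        for lay, _ in self.items:
            lay.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for i, (lay, name) in enumerate(self.items):
            g = lay.grads[name] + self.wd * lay.params[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.vhat[i] / (1 - b2**self.t)
            lay.params[name] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def match_channels(x: np.ndarray, cout: int) -> np.ndarray:
    """Adapt the channel axis of an identity shortcut: zero-pad up to
    ``cout`` or truncate down to it."""
    cin = x.shape[1]
    if cin == cout:
        return x
    if cin < cout:
        return np.pad(x, ((0, 0), (0, cout - cin), (0, 0), (0, 0), (0, 0)))
    return x[:, :cout]


def match_channels_adjoint(g: np.ndarray, cin: int) -> np.ndarray:
    """Adjoint of :func:`match_channels` for a shortcut input with ``cin``
    channels (``g`` carries the shortcut-output gradient)."""
    cout = g.shape[1]
    if cin == cout:
        return g
    if cin < cout:
        return g[:, :cin]
    return np.pad(g, ((0, 0), (0, cin - cout), (0, 0), (0, 0), (0, 0)))


def crop_center(x: np.ndarray, margin: int) -> np.ndarray:
    """Crop ``margin`` voxels off each spatial border."""
    if margin == 0:
        return x
    m = margin
    return x[:, :, m:-m, m:-m, m:-m]
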