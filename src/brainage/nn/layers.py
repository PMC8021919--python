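"""Layer primitives with explicit forward/backward passes.

Convolution is implemented by unrolling the k^3 kernel offsets (im2col):
for each offset a strided slice of the padded input is matched against the
corresponding kernel slab, so both directions reduce to dense einsums.  All
layers cache whatever the backward pass needs on ``forward`` and release it
after ``backward``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameter/gradient registries plus the two-pass protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _im2col(xp: np.ndarray, k: int, stride: int, out_sp: tuple[int, int, int]) -> np.ndarray:
    """(N, C, Dp, Hp, Wp) padded input -> (N, C*k^3, Do*Ho*Wo) columns."""
    N, C = xp.shape[:2]
    Do, Ho, Wo = out_sp
    cols = np.empty((N, C, k * k * k, Do * Ho * Wo), dtype=xp.dtype)
    i = 0
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                patch = xp[
                    :,
                    :,
                    kd : kd + stride * Do : stride,
                    kh : kh + stride * Ho : stride,
                    kw : kw + stride * Wo : stride,
                ]
                cols[:, :, i, :] = patch.reshape(N, C, -1)
                i += 1
    return cols.reshape(N, C * k**3, -1)


def _col2im(
    dcols: np.ndarray,
    xp_shape: tuple[int, ...],
    k: int,
    stride: int,
    out_sp: tuple[int, int, int],
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the padded grid."""
    N, C = xp_shape[:2]
    Do, Ho, Wo = out_sp
    dc = dcols.reshape(N, C, k**3, Do, Ho, Wo)
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    i = 0
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                dxp[
                    :,
                    :,
                    kd : kd + stride * Do : stride,
                    kh : kh + stride * Ho : stride,
                    kw : kw + stride * Wo : stride,
                ] += dc[:, :, i]
                i += 1
    return dxp


class Conv3d(Layer):
    """3D convolution, cubic kernel, symmetric zero padding, no bias (BN follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = (kernel - 1) // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        # He initialization for ReLU networks; weight stored flat (Cout, Cin*k^3)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.params = {"w": w}
        self.grads = {"w": np.zeros_like(w)}
        self._cache: tuple | None = None

    def out_shape(self, in_sp: tuple[int, int, int]) -> tuple[int, int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return tuple((d + 2 * p - k) // s + 1 for d in in_sp)  # type: ignore[return-value]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        N = x.shape[0]
        in_sp = x.shape[2:]
        out_sp = self.out_shape(in_sp)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = _im2col(xp, self.kernel, self.stride, out_sp)
        # (Cout, Cin*K) @ (N, Cin*K, L) -> (N, Cout, L), plain batched BLAS
        out = np.matmul(self.params["w"], cols)
        self._cache = (cols, xp.shape, out_sp)
        return out.reshape(N, self.out_channels, *out_sp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, out_sp = self._cache  # type: ignore[misc]
        N = dout.shape[0]
        d2 = dout.reshape(N, self.out_channels, -1)
        self.grads["w"] += np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0)
        dcols = np.matmul(self.params["w"].T, d2)
        dxp = _col2im(dcols, xp_shape, self.kernel, self.stride, out_sp)
        self._cache = None
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W) with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {"gamma": np.zeros(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(inv_std)
        if training:
            self._cache = (xhat, inv_std)
        return self._bc(self.params["gamma"]) * xhat + self._bc(self.params["beta"])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache  # type: ignore[misc]
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self._bc(self.params["gamma"])
        # standard batch-norm backward (training statistics)
        dx = (
            dxhat
            - self._bc(dxhat.mean(axis=axes))
            - xhat * self._bc((dxhat * xhat).mean(axis=axes))
        ) * self._bc(inv_std)
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class GlobalAvgPool3d(Layer):
    """(N, C, D, H, W) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        super().__init__()
        self._sp: tuple[int, int, int] | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._sp = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w = self._sp  # type: ignore[misc]
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            dout[:, :, None, None, None], dout.shape + (d, h, w)
        ) * scale


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        b = np.zeros(out_features)
        self.params = {"w": w, "b": b}
        self.grads = {"w": np.zeros_like(w), "b": np.zeros_like(b)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        dx = dout @ self.params["w"]
        self._x = None
        return dx
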