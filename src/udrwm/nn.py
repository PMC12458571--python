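"""Minimal NumPy layers for 3D convolutional autoencoders.

Convolution is implemented by shift-and-stack im2col: for each of the k^3
kernel offsets the (padded) input is sliced on a regular stride grid, so
both the forward gather and the backward scatter (col2im) are 27 cheap
strided slice operations plus one BLAS matmul.  Transposed convolution is
the exact adjoint of the convolution with the same geometry, which makes
decoder shapes invert encoder shapes by construction (odd sizes included).

All parameters are float64; layers cache what backward needs.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Conv3dGeom",
    "Conv3d",
    "ConvTranspose3d",
    "Dense",
    "ReLU",
    "Adam",
]


class Conv3dGeom:
    """Geometry of one stride-s, pad-p, kernel-k 3D convolution."""

    def __init__(self, in_shape: tuple[int, int, int], kernel: int, stride: int, pad: int):
        self.in_shape = tuple(in_shape)
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self.out_shape = tuple(
            (d + 2 * pad - kernel) // stride + 1 for d in in_shape
        )
        if any(d < 1 for d in self.out_shape):
            raise ValueError(
                f"conv geometry collapses {in_shape} to {self.out_shape} "
                f"(kernel {kernel}, stride {stride}, pad {pad})"
            )
        self.n_out = int(np.prod(self.out_shape))
        self.offsets = list(itertools.product(range(kernel), repeat=3))

    def _padded(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))

    def _slices(self, off: tuple[int, int, int]):
        s = self.stride
        return tuple(
            slice(a, a + s * d, s) for a, d in zip(off, self.out_shape)
        )

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, *in_shape) -> (B, P, C*k^3) patch matrix."""
        B, C = x.shape[:2]
        xp = self._padded(x)
        cols = np.empty((B, C, len(self.offsets), self.n_out), dtype=x.dtype)
        for o, off in enumerate(self.offsets):
            sl = self._slices(off)
            cols[:, :, o, :] = xp[(slice(None), slice(None)) + sl].reshape(B, C, -1)
        return cols.transpose(0, 3, 1, 2).reshape(B, self.n_out, -1)

    def col2im(self, cols: np.ndarray, channels: int) -> np.ndarray:
        """Adjoint of im2col: (B, P, C*k^3) -> (B, C, *in_shape)."""
        B = cols.shape[0]
        p = self.pad
        padded_shape = tuple(d + 2 * p for d in self.in_shape)
        xp = np.zeros((B, channels) + padded_shape, dtype=cols.dtype)
        c4 = cols.reshape(B, self.n_out, channels, len(self.offsets)).transpose(0, 2, 3, 1)
        for o, off in enumerate(self.offsets):
            sl = self._slices(off)
            xp[(slice(None), slice(None)) + sl] += c4[:, :, o, :].reshape(
                (B, channels) + self.out_shape
            )
        if p == 0:
            return xp
        return xp[:, :, p:-p, p:-p, p:-p]


class Layer:
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params().values()))


class Conv3d(Layer):
    def __init__(self, in_ch, out_ch, in_shape, kernel=3, stride=2, pad=1, rng=None):
        self.geom = Conv3dGeom(in_shape, kernel, stride, pad)
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel**3
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        B = x.shape[0]
        cols = self.geom.im2col(x)  # (B, P, Cin*K)
        self._cols = cols
        out = cols @ self.W.T + self.b  # (B, P, Cout)
        return out.transpose(0, 2, 1).reshape((B, self.out_ch) + self.geom.out_shape)

    def backward(self, dout):
        B = dout.shape[0]
        d2 = dout.reshape(B, self.out_ch, -1).transpose(0, 2, 1)  # (B, P, Cout)
        cols = self._cols
        self.dW = np.einsum("bpo,bpk->ok", d2, cols)
        self.db = d2.sum(axis=(0, 1))
        dcols = d2 @ self.W  # (B, P, Cin*K)
        return self.geom.col2im(dcols, self.in_ch)


class ConvTranspose3d(Layer):
    """Adjoint convolution: upsamples ``in_shape`` back to ``out_shape``.

    ``out_shape`` is the spatial shape of the *matching encoder input*, so
    geometry is specified exactly and no output-padding bookkeeping is
    needed.
    """

    def __init__(self, in_ch, out_ch, in_shape, out_shape, kernel=3, stride=2, pad=1, rng=None):
        self.geom = Conv3dGeom(out_shape, kernel, stride, pad)
        if self.geom.out_shape != tuple(in_shape):
            raise ValueError(
                f"transposed conv geometry mismatch: a (k={kernel},s={stride},p={pad}) conv "
                f"maps {tuple(out_shape)} to {self.geom.out_shape}, not {tuple(in_shape)}"
            )
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel**3
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch * kernel**3))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xf: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        B = x.shape[0]
        xf = x.reshape(B, self.in_ch, -1).transpose(0, 2, 1)  # (B, P, Cin)
        self._xf = xf
        cols = xf @ self.W  # (B, P, Cout*K)
        y = self.geom.col2im(cols, self.out_ch)
        return y + self.b[None, :, None, None, None]

    def backward(self, dout):
        B = dout.shape[0]
        patches = self.geom.im2col(dout)  # (B, P, Cout*K)
        self.dW = np.einsum("bpi,bpk->ik", self._xf, patches)
        self.db = dout.sum(axis=(0, 2, 3, 4))
        dxf = patches @ self.W.T  # (B, P, Cin)
        return dxf.transpose(0, 2, 1).reshape((B, self.in_ch) + self.geom.out_shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Adam:
    """Adam over a flat dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
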