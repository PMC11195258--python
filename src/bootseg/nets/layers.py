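"""Minimal dense-prediction building blocks with explicit backpropagation.

Arrays are channel-first without a batch axis: ``(C, y, x)`` in 2D,
``(C, z, y, x)`` in 3D.  Each layer caches what its backward pass needs;
parameter gradients accumulate in ``grads`` until the optimizer consumes
them.  float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv", "ReLU", "Sigmoid", "AvgPool", "Upsample", "Layer"]


class Layer:
    """Base class: parameter-free layers inherit the empty param dicts."""

    #: when False (inference), layers neither cache for backward nor keep
    #: large im2col buffers alive
    training: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv(Layer):
    """Same-padded convolution (stride 1) for 2D or 3D grids."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, ...], rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = tuple(kernel)
        self.dim = len(self.kernel)
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU trunk
        self.params["weight"] = rng.normal(
            0.0, scale, (out_channels, in_channels) + self.kernel
        ).astype(np.float32)
        self.params["bias"] = np.zeros(out_channels, dtype=np.float32)
        self.grads["weight"] = np.zeros_like(self.params["weight"])
        self.grads["bias"] = np.zeros_like(self.params["bias"])
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    #: im2col buffer budget (entries) for chunked inference
    _CHUNK_ENTRIES = 30_000_000

    @staticmethod
    def _im2col(xp: np.ndarray, kernel: tuple[int, ...], spatial) -> np.ndarray:
        c_in = xp.shape[0]
        dim = len(kernel)
        view = np.lib.stride_tricks.sliding_window_view(
            xp, kernel, axis=tuple(range(1, 1 + dim)))
        # (C, *spatial, *kernel) -> (C, *kernel, *spatial) -> (C*K, N);
        # the reshape performs the single necessary copy
        order = (0,) + tuple(range(1 + dim, 1 + 2 * dim)) + tuple(range(1, 1 + dim))
        n = int(np.prod(spatial))
        k = int(np.prod(kernel))
        return view.transpose(order).reshape(c_in * k, n)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.params["weight"]
        c_in = w.shape[1]
        assert x.shape[0] == c_in, f"expected {c_in} input channels, got {x.shape[0]}"
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel]
        spatial = x.shape[1:]
        n = int(np.prod(spatial))
        k = int(np.prod(self.kernel))
        xp = np.pad(x, pads)

        if not self.training and n * c_in * k > self._CHUNK_ENTRIES:
            # inference on large grids: slab along the first spatial axis so
            # the im2col buffer stays bounded; no cache is kept
            out = np.empty((w.shape[0],) + tuple(spatial), dtype=np.float32)
            per_slice = int(np.prod(spatial[1:])) * c_in * k
            slab = max(1, self._CHUNK_ENTRIES // max(per_slice, 1))
            kz = self.kernel[0]
            wmat = w.reshape(w.shape[0], -1)
            for z0 in range(0, spatial[0], slab):
                z1 = min(z0 + slab, spatial[0])
                sub = xp[:, z0:z1 + kz - 1]
                sub_spatial = (z1 - z0,) + tuple(spatial[1:])
                cols = self._im2col(sub, self.kernel, sub_spatial)
                res = wmat @ cols + self.params["bias"][:, None]
                out[:, z0:z1] = res.reshape((w.shape[0],) + sub_spatial)
            self._cols = None
            self._in_shape = x.shape
            return out

        cols = self._im2col(xp, self.kernel, spatial)
        out = w.reshape(w.shape[0], -1) @ cols + self.params["bias"][:, None]
        self._cols = cols if self.training else None
        self._in_shape = x.shape
        return out.reshape((w.shape[0],) + spatial).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.params["weight"]
        o = w.shape[0]
        spatial = dout.shape[1:]
        n = int(np.prod(spatial))
        dflat = dout.reshape(o, n)
        self.grads["weight"] += (dflat @ self._cols.T).reshape(w.shape)
        self.grads["bias"] += dflat.sum(axis=1)

        # input gradient: scatter each kernel tap back onto the padded grid
        c_in = w.shape[1]
        pads = [k // 2 for k in self.kernel]
        padded_shape = (c_in,) + tuple(s + 2 * p for s, p in
                                       zip(self._in_shape[1:], pads))
        dxp = np.zeros(padded_shape, dtype=np.float32)
        k = int(np.prod(self.kernel))
        # (C*K, O) @ (O, N) -> per-tap input gradients
        contrib = (w.reshape(o, c_in * k).T @ dflat).reshape(
            (c_in,) + self.kernel + (n,))
        offsets = np.stack(np.meshgrid(
            *[np.arange(kk) for kk in self.kernel], indexing="ij"),
            axis=-1).reshape(-1, self.dim)
        for ki, off in enumerate(offsets):
            sl = tuple(slice(int(off[d]), int(off[d]) + self._in_shape[1 + d])
                       for d in range(self.dim))
            tap = tuple(int(off[d]) for d in range(self.dim))
            dxp[(slice(None),) + sl] += contrib[(slice(None),) + tap].reshape(
                (c_in,) + self._in_shape[1:])
        core = tuple(slice(p, p + s) for p, s in zip(pads, self._in_shape[1:]))
        return dxp[(slice(None),) + core]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._y * (1.0 - self._y)).astype(np.float32)


class AvgPool(Layer):
    """Average pooling by integer factors; spatial sizes must divide."""

    def __init__(self, factors: tuple[int, ...]) -> None:
        super().__init__()
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        spatial = x.shape[1:]
        for s, f in zip(spatial, self.factors):
            if s % f:
                raise ValueError(
                    f"spatial shape {spatial} not divisible by pool factors {self.factors}")
        shape = [c]
        for s, f in zip(spatial, self.factors):
            shape += [s // f, f]
        xr = x.reshape(shape)
        axes = tuple(range(2, xr.ndim, 2))
        self._in_shape = x.shape
        return xr.mean(axis=axes).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        scale = 1.0 / float(np.prod(self.factors))
        out = dout * scale
        for axis, f in enumerate(self.factors, start=1):
            out = np.repeat(out, f, axis=axis)
        return out.astype(np.float32)


class Upsample(Layer):
    """Nearest-neighbor upsampling by integer factors."""

    def __init__(self, factors: tuple[int, ...]) -> None:
        super().__init__()
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for axis, f in enumerate(self.factors, start=1):
            out = np.repeat(out, f, axis=axis)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = dout.shape[0]
        shape = [c]
        for s, f in zip(dout.shape[1:], self.factors):
            shape += [s // f, f]
        dr = dout.reshape(shape)
        axes = tuple(range(2, dr.ndim, 2))
        return dr.sum(axis=axes).astype(np.float32)
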