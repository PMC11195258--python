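"""Encoder-decoder (U-Net) dense predictors with one sigmoid head per target.

The same implementation serves the three roles of the pipeline: the 2D
image-to-descriptor net, the 3D stacked-descriptor-to-affinity net, and the
3D multi-task raw-to-affinity+descriptor net — only the ModelSpec differs.
Padding is "same"; tiled inference discards an overlap margin at least as
wide as the receptive-field radius so tile seams vanish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import AvgPool, Conv, Layer, ReLU, Sigmoid, Upsample

__all__ = ["ModelSpec", "UNet", "save_checkpoint", "load_checkpoint"]

KERNEL = 3  # per-axis convolution extent


@dataclass
class ModelSpec:
    """Architecture description of a dense predictor.

    ``out_heads`` maps head names to channel counts, e.g. ``[("lsd", 6)]``,
    ``[("affs", 3)]`` or ``[("affs", 3), ("lsd", 10)]`` for the multi-task
    model.  ``downsample_factors`` has one per-axis factor tuple per level;
    3D defaults keep the coarse sectioning axis unpooled at the first level
    (anisotropy-aware).
    """

    dimensionality: int = 3
    in_channels: int = 1
    out_heads: tuple[tuple[str, int], ...] = (("affs", 3),)
    depth: int = 2
    base_features: int = 12
    downsample_factors: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        self.out_heads = tuple((str(n), int(c)) for n, c in self.out_heads)
        if self.downsample_factors is None:
            if self.dimensionality == 2:
                self.downsample_factors = tuple((2, 2) for _ in range(self.depth))
            else:
                self.downsample_factors = tuple(
                    (1, 2, 2) if level == 0 else (2, 2, 2)
                    for level in range(self.depth)
                )
        self.downsample_factors = tuple(tuple(int(f) for f in fs)
                                        for fs in self.downsample_factors)
        if len(self.downsample_factors) != self.depth:
            raise ValueError("need one downsample factor tuple per level")

    @property
    def total_downsample(self) -> tuple[int, ...]:
        total = np.ones(self.dimensionality, dtype=int)
        for fs in self.downsample_factors:
            total *= np.asarray(fs)
        return tuple(int(t) for t in total)

    def to_json(self) -> str:
        return json.dumps({
            "dimensionality": self.dimensionality,
            "in_channels": self.in_channels,
            "out_heads": list(list(h) for h in self.out_heads),
            "depth": self.depth,
            "base_features": self.base_features,
            "downsample_factors": [list(f) for f in self.downsample_factors],
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            dimensionality=d["dimensionality"],
            in_channels=d["in_channels"],
            out_heads=tuple((n, c) for n, c in d["out_heads"]),
            depth=d["depth"],
            base_features=d["base_features"],
            downsample_factors=tuple(tuple(f) for f in d["downsample_factors"]),
        )


def _conv_block(in_ch: int, out_ch: int, dim: int,
                rng: np.random.Generator) -> list[Layer]:
    k = (KERNEL,) * dim
    return [Conv(in_ch, out_ch, k, rng), ReLU(),
            Conv(out_ch, out_ch, k, rng), ReLU()]


class UNet:
    """Same-padded U-Net; forward/backward operate on single patches."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        dim = spec.dimensionality
        feats = [spec.base_features * 2**i for i in range(spec.depth + 1)]

        self.down_blocks: list[list[Layer]] = []
        self.pools: list[AvgPool] = []
        in_ch = spec.in_channels
        for level in range(spec.depth):
            self.down_blocks.append(_conv_block(in_ch, feats[level], dim, rng))
            self.pools.append(AvgPool(spec.downsample_factors[level]))
            in_ch = feats[level]
        self.bottom = _conv_block(in_ch, feats[spec.depth], dim, rng)

        self.ups: list[Upsample] = []
        self.up_blocks: list[list[Layer]] = []
        in_ch = feats[spec.depth]
        for level in reversed(range(spec.depth)):
            self.ups.append(Upsample(spec.downsample_factors[level]))
            self.up_blocks.append(
                _conv_block(in_ch + feats[level], feats[level], dim, rng))
            in_ch = feats[level]

        self.heads: dict[str, list[Layer]] = {}
        for name, channels in spec.out_heads:
            self.heads[name] = [Conv(feats[0], channels, (1,) * dim, rng), Sigmoid()]

    # -- plumbing --------------------------------------------------------
    def _layers(self):
        for i, block in enumerate(self.down_blocks):
            for j, layer in enumerate(block):
                yield f"down{i}_{j}", layer
        for j, layer in enumerate(self.bottom):
            yield f"bottom_{j}", layer
        for i, block in enumerate(self.up_blocks):
            for j, layer in enumerate(block):
                yield f"up{i}_{j}", layer
        for name, block in self.heads.items():
            for j, layer in enumerate(block):
                yield f"head_{name}_{j}", layer

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p for ln, layer in self._layers()
                for pn, p in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": g for ln, layer in self._layers()
                for pn, g in layer.grads.items()}

    def zero_grad(self) -> None:
        for _, layer in self._layers():
            layer.zero_grad()

    def receptive_radius(self) -> tuple[int, ...]:
        """Per-axis half-width of the receptive field (voxels at full scale)."""
        dim = self.spec.dimensionality
        radius = np.zeros(dim, dtype=int)
        scale = np.ones(dim, dtype=int)
        convs_per_block = 2
        half = KERNEL // 2
        for level in range(self.spec.depth):
            radius += convs_per_block * half * scale
            factors = np.asarray(self.spec.downsample_factors[level])
            radius += (factors - 1) * scale  # pooling-window spread
            scale *= factors
        radius += convs_per_block * half * scale  # bottom
        for level in reversed(range(self.spec.depth)):
            scale //= np.asarray(self.spec.downsample_factors[level])
            radius += convs_per_block * half * scale
        return tuple(int(r) for r in radius)

    # -- forward / backward ---------------------------------------------
    @staticmethod
    def _run(block: list[Layer], x: np.ndarray) -> np.ndarray:
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(block: list[Layer], grad: np.ndarray) -> np.ndarray:
        for layer in reversed(block):
            grad = layer.backward(grad)
        return grad

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        spec = self.spec
        if x.shape[0] != spec.in_channels:
            raise ValueError(
                f"expected {spec.in_channels} input channels, got {x.shape[0]}")
        total = spec.total_downsample
        for s, t in zip(x.shape[1:], total):
            if s % t:
                raise ValueError(
                    f"patch shape {x.shape[1:]} must be divisible by {total}")
        skips = []
        for block, pool in zip(self.down_blocks, self.pools):
            x = self._run(block, x)
            skips.append(x)
            x = pool.forward(x)
        x = self._run(self.bottom, x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.up_blocks, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = self._run(block, x)
        return {name: self._run(block, x) for name, block in self.heads.items()}

    def backward(self, head_grads: dict[str, np.ndarray]) -> None:
        grad = None
        for name, block in self.heads.items():
            g = head_grads.get(name)
            if g is None:
                continue
            gb = self._run_back(block, g)
            grad = gb if grad is None else grad + gb
        if grad is None:
            return
        # decoder blocks are stored deepest-first; backward walks them in
        # reverse execution order and collects the skip-connection gradients
        skip_grads = []  # indexed like skips: skip_grads[i] for down_blocks[i]
        for i in reversed(range(len(self.up_blocks))):
            grad = self._run_back(self.up_blocks[i], grad)
            skip_ch = self._skip_channels[i]
            skip_grads.append(grad[:skip_ch])
            grad = self.ups[i].backward(grad[skip_ch:])
        grad = self._run_back(self.bottom, grad)
        for i in reversed(range(len(self.down_blocks))):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self._run_back(self.down_blocks[i], grad)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Persist spec + parameters as a compressed npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(model.parameters())
    np.savez_compressed(path, __spec__=np.frombuffer(
        model.spec.to_json().encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        spec = ModelSpec.from_json(bytes(data["__spec__"]).decode())
        model = UNet(spec)
        params = model.parameters()
        for name, arr in params.items():
            arr[...] = data[name]
    return model
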