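"""Overlap-tiled inference for 2D section stacks and 3D volumes.

Tiles are padded by at least the network's receptive-field radius and the
margins discarded, so tiled and untiled predictions agree on the interior.
Volume borders are reflect-padded.
"""

from __future__ import annotations

import numpy as np

from ..volumes import VolumeGrid
from .unet import UNet

__all__ = ["tiled_predict", "predict_2d_stack", "predict_3d", "normalize_raw"]


def normalize_raw(data: np.ndarray) -> np.ndarray:
    """Promote raw image data to float32 in [0, 1] (scaled by dtype range)."""
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return ((data.astype(np.float32) - info.min) / (info.max - info.min))
    return np.clip(data.astype(np.float32), 0.0, 1.0)


def _pad_reflect(x: np.ndarray, pad_lo, pad_hi) -> np.ndarray:
    """Reflect padding robust to pads exceeding the array extent."""
    out = x
    pad_lo = list(pad_lo)
    pad_hi = list(pad_hi)
    while any(p > 0 for p in pad_lo) or any(p > 0 for p in pad_hi):
        step_lo, step_hi = [], []
        for axis in range(out.ndim):
            limit = max(out.shape[axis] - 1, 1)
            step_lo.append(min(pad_lo[axis], limit))
            step_hi.append(min(pad_hi[axis], limit))
        mode = "reflect" if all(s > 1 for s in out.shape) else "edge"
        out = np.pad(out, list(zip(step_lo, step_hi)), mode=mode)
        pad_lo = [p - s for p, s in zip(pad_lo, step_lo)]
        pad_hi = [p - s for p, s in zip(pad_hi, step_hi)]
    return out


def _set_training(model: UNet, flag: bool) -> None:
    for _, layer in model._layers():
        layer.training = flag  # type: ignore[attr-defined]


def tiled_predict(model: UNet, x: np.ndarray,
                  tile_shape: tuple[int, ...] | None = None,
                  overlap: tuple[int, ...] | None = None) -> dict[str, np.ndarray]:
    """Run the model over a full (C, *spatial) array by overlapping tiles.

    ``tile_shape`` is the full extent of each processed tile (core +
    2 * overlap); ``overlap`` defaults to the receptive-field radius.  With
    ``tile_shape`` None the whole array is processed as one padded tile.
    """
    spec = model.spec
    dim = spec.dimensionality
    spatial = np.asarray(x.shape[1:], dtype=int)
    total = np.asarray(spec.total_downsample, dtype=int)
    _set_training(model, False)
    try:
        return _tiled_predict_impl(model, x, tile_shape, overlap, spec, dim,
                                   spatial, total)
    finally:
        _set_training(model, True)


def _tiled_predict_impl(model, x, tile_shape, overlap, spec, dim, spatial, total):

    rf = np.asarray(model.receptive_radius(), dtype=int)
    rf_aligned = (np.ceil(rf / total) * total).astype(int)

    if tile_shape is None:
        # single tile: reflect-pad by the receptive radius so border voxels
        # see the same (reflected) context as they would in a tiled run
        padded = (np.ceil(spatial / total) * total).astype(int)
        xp = _pad_reflect(x, [0] + list(rf_aligned),
                          [0] + list(rf_aligned + padded - spatial))
        out = model.forward(xp)
        core = (slice(None),) + tuple(
            slice(int(r), int(r + s)) for r, s in zip(rf_aligned, spatial))
        return {k: np.clip(v[core], 0.0, 1.0) for k, v in out.items()}

    tile = np.asarray(tile_shape, dtype=int)
    if overlap is None:
        overlap = rf_aligned
    ov = np.asarray(overlap, dtype=int)
    # overlap and core must stay aligned with the pooling grid, otherwise
    # tiles are downsampled on shifted grids and seams appear
    ov = (np.ceil(ov / total) * total).astype(int)
    core = tile - 2 * ov
    if np.any(core <= 0):
        raise ValueError(f"tile {tile_shape} too small for overlap {tuple(ov)}")
    if np.any(tile % total) or np.any(core % total):
        raise ValueError(
            f"tile shape {tile_shape} and core {tuple(core)} must be divisible "
            f"by {tuple(total)}")

    n_tiles = np.ceil(spatial / core).astype(int)
    pad_hi = n_tiles * core - spatial + ov
    xp = _pad_reflect(x, [0] + list(ov), [0] + list(pad_hi))

    outputs: dict[str, np.ndarray] = {}
    for idx in np.ndindex(*[int(n) for n in n_tiles]):
        start = np.asarray(idx) * core
        sl_in = (slice(None),) + tuple(
            slice(int(s), int(s + t)) for s, t in zip(start, tile))
        pred = model.forward(xp[sl_in])
        keep = (slice(None),) + tuple(slice(int(o), int(o + c)) for o, c in zip(ov, core))
        for name, arr in pred.items():
            if name not in outputs:
                outputs[name] = np.zeros((arr.shape[0],) + tuple(spatial), np.float32)
            stop = np.minimum(start + core, spatial)
            span = stop - start
            dst = (slice(None),) + tuple(slice(int(s), int(e)) for s, e in zip(start, stop))
            src = (slice(None),) + tuple(
                slice(int(o), int(o + sp)) for o, sp in zip(ov, span))
            outputs[name][dst] = arr[src]
    return {k: np.clip(v, 0.0, 1.0) for k, v in outputs.items()}


def predict_2d_stack(model: UNet, volume: VolumeGrid,
                     tile_shape: tuple[int, int] | None = None,
                     overlap: tuple[int, int] | None = None) -> VolumeGrid:
    """Apply a 2D model independently to every section of a volume.

    Returns the per-section predictions of the model's descriptor head
    stacked along z as a descriptor grid.
    """
    if model.spec.dimensionality != 2:
        raise ValueError("predict_2d_stack needs a 2D model")
    data = normalize_raw(volume.data)
    head = model.spec.out_heads[0][0]
    sections = []
    for z in range(data.shape[0]):
        pred = tiled_predict(model, data[z][None], tile_shape, overlap)
        sections.append(pred[head])
    stacked = np.stack(sections, axis=1)  # (C, z, y, x)
    return VolumeGrid(stacked, volume.voxel_size, volume.offset, semantic="descriptor")


def predict_3d(model: UNet, inputs: VolumeGrid,
               tile_shape: tuple[int, int, int] | None = None,
               overlap: tuple[int, int, int] | None = None) -> dict[str, VolumeGrid]:
    """Overlap-tiled 3D inference; returns every head (affs, and lsd if any)."""
    if model.spec.dimensionality != 3:
        raise ValueError("predict_3d needs a 3D model")
    if inputs.data.ndim == 4:
        data = inputs.data.astype(np.float32)
    else:
        data = normalize_raw(inputs.data)[None]
    if data.shape[0] != model.spec.in_channels:
        raise ValueError(
            f"input has {data.shape[0]} channels, model expects "
            f"{model.spec.in_channels}")
    preds = tiled_predict(model, data, tile_shape, overlap)
    out = {}
    for name, arr in preds.items():
        semantic = "affinity" if name == "affs" else "descriptor"
        out[name] = VolumeGrid(arr, inputs.voxel_size, inputs.offset, semantic=semantic)
    return out
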