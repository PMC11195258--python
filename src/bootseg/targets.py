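"""Training targets derived from label volumes.

Three target families:

* **Local shape descriptors (LSDs)** — per-voxel Gaussian-weighted local
  statistics of the containing object: offset to the local center of mass,
  coordinate variances, pairwise coordinate correlations, and local size.
  10 channels in 3D, 6 per-section channels in 2D, all mapped into [0, 1].
* **Direct-neighbor affinities** — per-voxel connectivity to the preceding
  voxel along each axis (1 iff both voxels carry the same positive id).
* **Loss weights** — masks restricting supervision to annotated voxels,
  optionally class-balanced for affinity targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .volumes import LabelVolume, SparseAnnotation, VolumeGrid

__all__ = [
    "AffinityGrid",
    "LossWeightGrid",
    "DEFAULT_3D_NEIGHBORHOOD",
    "compute_lsd",
    "compute_affinities",
    "make_loss_weights",
    "lsd_channel_count",
]

#: direct-neighbor offsets: each channel links voxel p with p + offset
DEFAULT_3D_NEIGHBORHOOD: tuple[tuple[int, int, int], ...] = (
    (-1, 0, 0),
    (0, -1, 0),
    (0, 0, -1),
)

_CORR_EPS = 1e-12


@dataclass
class AffinityGrid:
    """Per-voxel direct-neighbor connectivity with a supervision mask.

    ``data[d]`` is the affinity of every voxel to its partner at
    ``neighborhood[d]``; ``mask[d]`` is false where that partner falls
    outside the volume or (sparse mode) where either endpoint was not
    annotated.
    """

    data: np.ndarray
    neighborhood: tuple[tuple[int, int, int], ...] = DEFAULT_3D_NEIGHBORHOOD
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.neighborhood):
            raise ValueError(
                f"affinity data must be (D, z, y, x) with D = {len(self.neighborhood)}"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("affinity mask shape must match data")
        if self.data.min(initial=0) < 0 or self.data.max(initial=0) > 1:
            raise ValueError("affinity values must lie in [0, 1]")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.data, self.voxel_size, self.offset, semantic="affinity")


@dataclass
class LossWeightGrid:
    """Non-negative per-entry loss weights, shaped like the target they gate."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.size and self.data.min() < 0:
            raise ValueError("loss weights must be non-negative")


def lsd_channel_count(dimensionality: int) -> int:
    """6 channels for per-section 2D descriptors, 10 for full 3D."""
    if dimensionality == 2:
        return 6
    if dimensionality == 3:
        return 10
    raise ValueError(f"dimensionality must be 2 or 3, got {dimensionality}")


def _gauss_kernel(sigma_nm: float, voxel_nm: float) -> np.ndarray:
    """Unnormalized Gaussian samples truncated at 3 sigma (world units)."""
    radius = int(np.ceil(3.0 * sigma_nm / voxel_nm))
    i = np.arange(-radius, radius + 1, dtype=np.float64)
    return np.exp(-((i * voxel_nm) ** 2) / (2.0 * sigma_nm**2))


def _lsd_nd(mask: np.ndarray, sigma: np.ndarray, voxel_size: np.ndarray,
            m_iso: float) -> np.ndarray:
    """Descriptor channels for one object mask (any dimensionality).

    Returns an array of shape ``(C,) + mask.shape`` where C = offsets +
    variances + correlations + size for ``d = mask.ndim`` axes.  Values are
    only meaningful where ``mask`` is true.
    """
    d = mask.ndim
    kernels = [_gauss_kernel(sigma[a], voxel_size[a]) for a in range(d)]

    def blur(arr: np.ndarray) -> np.ndarray:
        out = arr
        for a in range(d):
            out = correlate1d(out, kernels[a], axis=a, mode="constant", cval=0.0)
        return out

    # world coordinates local to the array, centered to curb cancellation
    coords = []
    for a in range(d):
        c = (np.arange(mask.shape[a], dtype=np.float64) - mask.shape[a] / 2.0) * voxel_size[a]
        shape = [1] * d
        shape[a] = -1
        coords.append(c.reshape(shape))

    fmask = mask.astype(np.float64)
    m = blur(fmask)
    m_safe = np.maximum(m, _CORR_EPS)

    means = []
    for a in range(d):
        means.append(blur(fmask * coords[a]) / m_safe)

    cov = {}
    for a in range(d):
        for b in range(a, d):
            q = blur(fmask * coords[a] * coords[b]) / m_safe
            cov[(a, b)] = q - means[a] * means[b]

    channels = []
    for a in range(d):  # mean offsets, [-sigma, sigma] -> [0, 1]
        off = means[a] - coords[a]
        channels.append(np.clip((off + sigma[a]) / (2.0 * sigma[a]), 0.0, 1.0))
    for a in range(d):  # variances, / sigma^2 -> [0, 1]
        channels.append(np.clip(cov[(a, a)] / sigma[a] ** 2, 0.0, 1.0))
    for a in range(d):  # Pearson correlations, [-1, 1] -> [0, 1]
        for b in range(a + 1, d):
            denom = np.sqrt(np.maximum(cov[(a, a)], 0.0) * np.maximum(cov[(b, b)], 0.0))
            rho = np.where(denom > _CORR_EPS, cov[(a, b)] / np.maximum(denom, _CORR_EPS), 0.0)
            channels.append(np.clip((rho + 1.0) / 2.0, 0.0, 1.0))
    channels.append(np.clip(m / m_iso, 0.0, 1.0))  # size
    return np.stack(channels)


def _object_slices(labels: np.ndarray):
    """Per-id bounding-box slices.

    No padding is needed: descriptor outputs and all contributing mass lie
    on same-label voxels, i.e. inside the object's own bounding box.
    """
    from scipy.ndimage import find_objects

    all_ids, inverse = np.unique(labels, return_inverse=True)
    # densify ids so find_objects stays linear in the number of objects
    if all_ids.size and all_ids[0] == 0:
        dense = inverse.reshape(labels.shape)
        ids = all_ids[1:]
    else:
        dense = inverse.reshape(labels.shape) + 1
        ids = all_ids
    slices = find_objects(dense)
    out = []
    for i, old in enumerate(ids):
        sl = slices[i]
        if sl is None:
            continue
        out.append((old, sl))
    return out


def compute_lsd(labels: LabelVolume, sigma: Sequence[float],
                dimensionality: int = 3) -> VolumeGrid:
    """Local shape descriptors of a label volume.

    Parameters
    ----------
    labels
        Instance ids; id 0 is background and maps to the all-zero vector.
    sigma
        Gaussian scale in nm per axis: ``(z, y, x)`` for 3D, ``(y, x)``
        (or ``(z, y, x)``, z ignored) for per-section 2D descriptors.
    dimensionality
        3 for full 3D descriptors (10 channels), 2 for independent
        per-section descriptors (6 channels).

    Notes
    -----
    For a voxel v with label L the Gaussian weight of a same-label voxel u
    is ``w(u) = exp(-sum_a (u_a - v_a)^2 vs_a^2 / (2 sigma_a^2))``,
    truncated at 3 sigma per axis.  Channels (in order): per-axis offset of
    the local center of mass mapped from [-sigma, sigma] to [0, 1];
    per-axis coordinate variance divided by sigma^2; pairwise Pearson
    correlations mapped from [-1, 1] to [0, 1]; local size (mass relative
    to an unbounded same-label region).
    """
    n_channels = lsd_channel_count(dimensionality)
    sig = np.asarray(sigma, dtype=np.float64).ravel()
    if np.any(sig <= 0):
        raise ValueError(f"sigma must be strictly positive, got {sigma}")
    vs = np.asarray(labels.voxel_size, dtype=np.float64)
    out = np.zeros((n_channels,) + labels.spatial_shape, dtype=np.float32)

    if dimensionality == 3:
        if sig.size != 3:
            raise ValueError("3D descriptors need sigma per (z, y, x)")
        m_iso = float(np.prod([_gauss_kernel(sig[a], vs[a]).sum() for a in range(3)]))
        for obj_id, sl in _object_slices(labels.data):
            sub = labels.data[sl] == obj_id
            desc = _lsd_nd(sub, sig, vs, m_iso)
            region = tuple([slice(None)] + list(sl))
            sel = np.broadcast_to(sub, desc.shape)
            out[region] = np.where(sel, desc, out[region]).astype(np.float32)
    else:
        sig2 = sig[-2:] if sig.size == 3 else sig
        if sig2.size != 2:
            raise ValueError("2D descriptors need sigma per (y, x)")
        vs2 = vs[1:]
        m_iso = float(np.prod([_gauss_kernel(sig2[a], vs2[a]).sum() for a in range(2)]))
        for z in range(labels.spatial_shape[0]):
            section = labels.data[z]
            if not section.any():
                continue
            for obj_id, sl in _object_slices(section):
                sub = section[sl] == obj_id
                desc = _lsd_nd(sub, sig2, vs2, m_iso)
                region = tuple([slice(None), z] + list(sl))
                sel = np.broadcast_to(sub, desc.shape)
                out[region] = np.where(sel, desc, out[region]).astype(np.float32)

    return VolumeGrid(out, labels.voxel_size, labels.offset, semantic="descriptor")


def compute_affinities(labels: LabelVolume,
                       neighborhood: Sequence[Sequence[int]] = DEFAULT_3D_NEIGHBORHOOD,
                       annotation: SparseAnnotation | None = None) -> AffinityGrid:
    """Direct-neighbor affinities of a label volume.

    Channel d at voxel p is 1 iff ``labels[p] > 0`` and the partner voxel
    ``p + neighborhood[d]`` is inside the volume with the same id.  Entries
    with an out-of-bounds partner are 0 and masked out; in sparse mode
    (``annotation`` given) entries where either endpoint is unannotated are
    masked out as well.
    """
    offsets = [tuple(int(c) for c in off) for off in neighborhood]
    for off in offsets:
        if all(c == 0 for c in off):
            raise ValueError("neighborhood offsets must be nonzero")
    lab = labels.data
    shape = lab.shape
    D = len(offsets)
    affs = np.zeros((D,) + shape, dtype=np.float32)
    mask = np.zeros((D,) + shape, dtype=bool)
    ann = annotation.labeled_mask if annotation is not None else None

    for d, off in enumerate(offsets):
        src = tuple(slice(max(-o, 0), min(n - o, n)) for o, n in zip(off, shape))
        dst = tuple(slice(max(o, 0), min(n + o, n)) for o, n in zip(off, shape))
        # src indexes voxel p, dst indexes partner p + off
        same = (lab[src] == lab[dst]) & (lab[src] > 0)
        affs[d][src] = same
        valid = np.ones(lab[src].shape, dtype=bool)
        if ann is not None:
            valid &= ann[src] & ann[dst]
        mask[d][src] = valid

    return AffinityGrid(affs, tuple(offsets), mask, labels.voxel_size, labels.offset)


def make_loss_weights(annotation: SparseAnnotation | None,
                      target: VolumeGrid | AffinityGrid,
                      balance: bool = False) -> LossWeightGrid:
    """Per-entry loss weights for a descriptor or affinity target.

    Weights are 0 outside the annotated mask (and on invalid affinity
    entries), 1 inside.  With ``balance`` (affinity targets only) the two
    affinity classes are reweighted inversely to their in-mask frequency,
    normalized so the mean in-mask weight is 1.
    """
    if isinstance(target, AffinityGrid):
        base = target.mask.copy()
        if annotation is not None:
            # mask endpoints: p annotated and partner annotated
            sparse = compute_affinities(
                annotation.labels, target.neighborhood, annotation
            ).mask
            base &= sparse
        weights = base.astype(np.float32)
        if balance and weights.any():
            binary = target.data >= 0.5
            inside = base
            n = float(inside.sum())
            classes = []
            for cls_mask in (binary & inside, (~binary) & inside):
                if cls_mask.any():
                    classes.append(cls_mask)
            k = len(classes)
            for cls_mask in classes:
                freq = float(cls_mask.sum()) / n
                weights[cls_mask] = 1.0 / (freq * k)
        vs, off = target.voxel_size, target.offset
    else:
        if target.data.ndim != 4:
            raise ValueError("descriptor target must have a channel axis")
        if annotation is None:
            per_voxel = np.ones(target.data.shape[1:], dtype=np.float32)
        else:
            if annotation.labeled_mask.shape != target.data.shape[1:]:
                raise ValueError("annotation shape does not match target")
            per_voxel = annotation.labeled_mask.astype(np.float32)
        weights = np.broadcast_to(per_voxel, target.data.shape).copy()
        vs, off = target.voxel_size, target.offset

    return LossWeightGrid(weights, vs, off)
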