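"""Core in-memory containers for volumetric data.

All grids are indexed ``(z, y, x)``, optionally with a leading channel axis
``(c, z, y, x)``.  ``z`` is the sectioning axis.  Geometry is carried
explicitly: ``voxel_size`` is the physical extent of one voxel per axis in
nanometers and ``offset`` is the world coordinate of voxel ``(0, 0, 0)``
(voxel-corner convention, world = offset + index * voxel_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VolumeGrid",
    "LabelVolume",
    "SparseAnnotation",
    "Skeleton",
]

#: semantics that carry a leading channel axis
CHANNEL_SEMANTICS = frozenset({"descriptor", "affinity"})
VALID_SEMANTICS = frozenset({"raw", "descriptor", "affinity", "weight", "labels"})


def _as_triple(v: Sequence[float], name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries (z, y, x), got {v!r}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeGrid:
    """A scalar or multi-channel 3D grid with explicit geometry.

    Parameters
    ----------
    data
        Array of shape ``(z, y, x)`` or ``(c, z, y, x)``.
    voxel_size
        Physical voxel extent per axis in nm, ordered ``(z, y, x)``.
    offset
        World coordinate of voxel ``(0, 0, 0)`` in nm.
    semantic
        One of ``raw``, ``descriptor``, ``affinity``, ``weight``, ``labels``.
        Descriptor and affinity grids carry a channel axis; the others do not.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semantic: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        self.offset = _as_triple(self.offset, "offset")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.semantic not in VALID_SEMANTICS:
            raise ValueError(f"unknown semantic {self.semantic!r}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        want_channels = self.semantic in CHANNEL_SEMANTICS
        ndim = self.data.ndim
        if want_channels and ndim != 4:
            raise ValueError(
                f"semantic {self.semantic!r} requires a (c, z, y, x) array, got ndim={ndim}"
            )
        if not want_channels and ndim != 3:
            raise ValueError(
                f"semantic {self.semantic!r} requires a (z, y, x) array, got ndim={ndim}"
            )
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.isfinite(self.data).all():
                raise ValueError("grid values must be finite")
        if self.semantic in ("descriptor", "affinity"):
            lo, hi = float(self.data.min(initial=0.0)), float(self.data.max(initial=0.0))
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"{self.semantic} values must lie in [0, 1], got range [{lo}, {hi}]"
                )

    # -- convenience -----------------------------------------------------
    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])  # type: ignore[return-value]

    @property
    def num_channels(self) -> int | None:
        return self.data.shape[0] if self.data.ndim == 4 else None

    def world_coordinates(self, index: Sequence[float]) -> np.ndarray:
        """World position (nm) of a voxel index ``(z, y, x)``."""
        return np.asarray(self.offset) + np.asarray(index) * np.asarray(self.voxel_size)


@dataclass
class LabelVolume:
    """Integer instance-ID volume; id 0 is reserved for background."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be (z, y, x), got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {arr.dtype}")
        if np.issubdtype(arr.dtype, np.signedinteger) and arr.size and arr.min() < 0:
            raise ValueError("label ids must be non-negative")
        self.data = arr.astype(np.uint64, copy=False)
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        self.offset = _as_triple(self.offset, "offset")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Distinct positive instance ids present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class SparseAnnotation:
    """Sparse labels plus the mask of voxels the annotator decided on.

    ``labeled_mask`` is true where a decision was made, including explicit
    background; voxels outside it carry zero loss weight downstream.
    """

    labels: LabelVolume
    labeled_mask: np.ndarray

    def __post_init__(self) -> None:
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        if self.labeled_mask.shape != self.labels.data.shape:
            raise ValueError("labeled_mask shape must match labels")
        if np.any((self.labels.data > 0) & ~self.labeled_mask):
            raise ValueError("every positively labeled voxel must be inside labeled_mask")

    @property
    def labeled_fraction(self) -> float:
        return float(self.labeled_mask.mean())


@dataclass
class Skeleton:
    """Center-line graph of one object: nodes in world nm, undirected edges."""

    object_id: int
    nodes: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.object_id <= 0:
            raise ValueError("object_id must be positive")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at node {a}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references a missing node")

    def path_length(self) -> float:
        """Sum of Euclidean edge lengths in world units (nm)."""
        total = 0.0
        for a, b in self.edges:
            pa = np.asarray(self.nodes[a], dtype=float)
            pb = np.asarray(self.nodes[b], dtype=float)
            total += float(np.linalg.norm(pa - pb))
        return total

    def node_ids(self) -> list[int]:
        return list(self.nodes)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map positive ids to consecutive integers starting at 1 (0 stays 0)."""
    out = np.zeros_like(labels, dtype=np.uint64)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for new_id, old_id in enumerate(ids, start=1):
        out[labels == old_id] = new_id
    return out
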