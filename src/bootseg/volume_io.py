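"""Reading and writing volumes and skeletons with explicit geometry metadata.

Supported containers: Zarr (directory store), HDF5, multi-page TIFF for
grids; SWC for skeletons.  Geometry travels as the attributes ``voxel_size``
and ``offset`` (nm, ``(z, y, x)`` order); the grid semantic travels as
``semantic``.  Axis order on disk and in memory is ``(z, y, x)`` with an
optional leading channel axis.
"""

from __future__ import annotations

import json
import logging
import os
import re
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile
import zarr

from .volumes import LabelVolume, Skeleton, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_skeletons",
    "write_skeletons",
    "FormatError",
]

DEFAULT_DATASET_KEY = "volume"


class FormatError(RuntimeError):
    """Raised for unreadable or structurally invalid files."""


def _sniff_format(path: str | Path) -> str:
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".zarr",):
        return "zarr"
    if suffix in (".n5",):
        raise FormatError(
            f"{p}: N5 containers are not supported by this build; "
            "convert to Zarr or HDF5"
        )
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if p.is_dir() and ((p / "zarr.json").exists() or (p / ".zgroup").exists() or (p / ".zarray").exists()):
        return "zarr"
    raise FormatError(f"cannot determine container format of {p}")


def _normalize_axes(data: np.ndarray, path: str | Path) -> np.ndarray:
    if data.ndim == 2:  # single section -> one-section stack
        return data[np.newaxis, ...]
    if data.ndim in (3, 4):
        return data
    raise FormatError(f"{path}: arrays with {data.ndim} axes are not supported")


def _wrap(data: np.ndarray, voxel_size, offset, semantic: str | None,
          path: str | Path) -> VolumeGrid | LabelVolume:
    data = _normalize_axes(np.asarray(data), path)
    if semantic is None:
        if np.issubdtype(data.dtype, np.integer) and data.ndim == 3 and data.dtype != np.uint8:
            semantic = "labels"
        elif data.ndim == 4:
            semantic = "descriptor"
        else:
            semantic = "raw"
    if semantic == "labels":
        return LabelVolume(data=data, voxel_size=voxel_size, offset=offset)
    return VolumeGrid(data=data, voxel_size=voxel_size, offset=offset, semantic=semantic)


def read_volume(path: str | Path, dataset_key: str | None = None,
                voxel_size=None, offset=None) -> VolumeGrid | LabelVolume:
    """Read a grid from Zarr, HDF5 or multi-page TIFF.

    ``voxel_size``/``offset`` override or supply missing metadata (TIFF
    stacks without tags fall back to ``(1, 1, 1)`` / ``(0, 0, 0)`` with a
    logged warning).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = _sniff_format(path)

    if fmt == "zarr":
        key = dataset_key or DEFAULT_DATASET_KEY
        try:
            group = zarr.open_group(str(path), mode="r")
            arr = group[key]
        except Exception as exc:  # zarr raises assorted store/key errors
            try:
                arr = zarr.open_array(str(path), mode="r")
            except Exception:
                raise IOError(f"cannot open zarr dataset {path}[{key}]: {exc}") from exc
        attrs = dict(arr.attrs)
        data = arr[:]
    elif fmt == "hdf5":
        key = dataset_key or DEFAULT_DATASET_KEY
        try:
            with h5py.File(path, "r") as f:
                if key not in f:
                    raise IOError(f"dataset {key!r} not found in {path}")
                ds = f[key]
                attrs = {k: ds.attrs[k] for k in ds.attrs}
                data = ds[:]
        except OSError as exc:
            raise IOError(f"cannot open HDF5 file {path}: {exc}") from exc
    else:  # tiff
        try:
            with tifffile.TiffFile(path) as tif:
                data = tif.asarray()
                meta = tif.shaped_metadata
                attrs = dict(meta[0]) if meta else {}
        except (tifffile.TiffFileError, ValueError) as exc:
            raise IOError(f"cannot read TIFF {path}: {exc}") from exc
        if "voxel_size" not in attrs and voxel_size is None:
            logger.warning("%s: TIFF has no voxel_size metadata; assuming (1, 1, 1)", path)

    vs = voxel_size if voxel_size is not None else attrs.get("voxel_size", (1.0, 1.0, 1.0))
    off = offset if offset is not None else attrs.get("offset", (0.0, 0.0, 0.0))
    semantic = attrs.get("semantic")
    if semantic is not None:
        semantic = str(semantic)
    return _wrap(data, tuple(np.asarray(vs, dtype=float)), tuple(np.asarray(off, dtype=float)),
                 semantic, path)


def write_volume(grid: VolumeGrid | LabelVolume, path: str | Path,
                 dataset_key: str | None = None, overwrite: bool = False) -> None:
    """Persist a grid with its geometry attributes; lossless for labels."""
    path = Path(path)
    semantic = "labels" if isinstance(grid, LabelVolume) else grid.semantic
    attrs = {
        "voxel_size": list(grid.voxel_size),
        "offset": list(grid.offset),
        "semantic": semantic,
    }
    fmt = _sniff_format(path)
    data = grid.data

    if fmt == "zarr":
        key = dataset_key or DEFAULT_DATASET_KEY
        group = zarr.open_group(str(path), mode="a")
        if key in group:
            if not overwrite:
                raise FileExistsError(
                    f"dataset {key!r} already exists in {path}; pass overwrite=True"
                )
            del group[key]
        arr = group.create_array(key, shape=data.shape, dtype=data.dtype)
        arr[:] = data
        arr.attrs.update(attrs)
    elif fmt == "hdf5":
        key = dataset_key or DEFAULT_DATASET_KEY
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "a") as f:
            if key in f:
                if not overwrite:
                    raise FileExistsError(
                        f"dataset {key!r} already exists in {path}; pass overwrite=True"
                    )
                del f[key]
            ds = f.create_dataset(key, data=data)
            for k, v in attrs.items():
                ds.attrs[k] = v
    else:  # tiff
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} already exists; pass overwrite=True")
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, metadata=attrs, photometric="minisblack")


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------

_OBJECT_RE = re.compile(r"#\s*object\s+(\d+)")


def write_skeletons(skeletons: Sequence[Skeleton], path: str | Path) -> None:
    """Write skeletons as concatenated SWC with ``# object <id>`` separators.

    SWC columns: ``id type x y z radius parent``; coordinates in nm; the
    radius column is written as 1.0.  Node numbering is global and each
    non-root node points at a previously written parent.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# SWC skeleton set", "# columns: id type x y z radius parent"]
    next_id = 1
    for sk in skeletons:
        lines.append(f"# object {sk.object_id}")
        # map local -> global ids following a spanning order so every parent
        # precedes its children
        adjacency: dict[int, list[int]] = {n: [] for n in sk.nodes}
        for a, b in sk.edges:
            adjacency[a].append(b)
            adjacency[b].append(a)
        global_id: dict[int, int] = {}
        parent_of: dict[int, int] = {}
        for root in sorted(sk.nodes):
            if root in global_id:
                continue
            stack = [(root, -1)]
            while stack:
                node, parent = stack.pop()
                if node in global_id:
                    continue
                global_id[node] = next_id
                parent_of[node] = parent
                next_id += 1
                for nb in sorted(adjacency[node], reverse=True):
                    if nb not in global_id:
                        stack.append((nb, node))
        # emit in global-id order
        for node in sorted(global_id, key=global_id.get):
            z, y, x = sk.nodes[node]
            parent = parent_of[node]
            pid = global_id[parent] if parent != -1 else -1
            lines.append(
                f"{global_id[node]} 0 {x:.3f} {y:.3f} {z:.3f} 1.0 {pid}"
            )
        # cycle-closing edges cannot be expressed in SWC's tree encoding;
        # record them as comments so round-trips preserve topology
        seen = {tuple(sorted((global_id[n], global_id[p]))) for n, p in parent_of.items()
                if p != -1}
        for a, b in sk.edges:
            key = tuple(sorted((global_id[a], global_id[b])))
            if key not in seen:
                lines.append(f"# edge {key[0]} {key[1]}")
                seen.add(key)
    Path(path).write_text("\n".join(lines) + "\n")


def read_skeletons(path: str | Path) -> list[Skeleton]:
    """Read a concatenated-SWC skeleton file written by :func:`write_skeletons`.

    Plain single-object SWC files (no separator comments) are also accepted
    and yield one skeleton with ``object_id`` 1.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    skeletons: list[Skeleton] = []
    nodes: dict[int, tuple[float, float, float]] = {}
    edges: list[tuple[int, int]] = []
    current_object: int | None = None

    def flush() -> None:
        nonlocal nodes, edges
        if nodes:
            oid = current_object if current_object is not None else 1
            skeletons.append(Skeleton(object_id=oid, nodes=dict(nodes), edges=list(edges)))
        nodes, edges = {}, []

    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _OBJECT_RE.match(line)
            if m:
                flush()
                current_object = int(m.group(1))
                continue
            me = re.match(r"#\s*edge\s+(\d+)\s+(\d+)", line)
            if me:
                a, b = int(me.group(1)), int(me.group(2))
                if a not in nodes or b not in nodes:
                    raise FormatError(f"{path}: extra edge references missing node")
                edges.append((a, b))
            continue
        fields = line.split()
        if len(fields) != 7:
            raise FormatError(f"{path}: malformed SWC line: {line!r}")
        nid = int(fields[0])
        x, y, z = (float(fields[2]), float(fields[3]), float(fields[4]))
        parent = int(fields[6])
        nodes[nid] = (z, y, x)
        if parent != -1:
            if parent not in nodes:
                raise FormatError(f"{path}: node {nid} references missing parent {parent}")
            edges.append((parent, nid))
    flush()
    return skeletons
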