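"""On-the-fly synthetic 3D instance labels and degraded stacked 2D descriptors.

The generator emulates densely packed, space-filling tissue with elongated
neurite-like processes: seed points partition a smoothed random potential
via seeded watershed, then random per-object morphological perturbations
roughen the boundaries.  Simulated per-section descriptor predictions are
derived from the labels and corrupted with noise, inter-section jitter,
blur and section dropout — the failure modes of a 2D network applied
section by section to serial-section data.

All draws are reproducible: a master seed spawns per-draw sub-seeds through
a counter-based splitting rule (`sub_rng`), so any individual draw can be
re-derived in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .targets import (
    AffinityGrid,
    DEFAULT_3D_NEIGHBORHOOD,
    LossWeightGrid,
    compute_affinities,
    compute_lsd,
)
from .volumes import LabelVolume, VolumeGrid

__all__ = [
    "SynthParams",
    "DegradeParams",
    "generate_labels",
    "simulate_stacked_predictions",
    "make_training_pair",
    "render_raw",
    "sub_rng",
]


def sub_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Child generator for draw ``key`` of a master seed (splittable)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


@dataclass
class SynthParams:
    """Parameters of the synthetic instance-label generator.

    ``smoothness`` (nm) sets the correlation length of the noise potential;
    ``elongation`` gives per-axis ranges of anisotropic stretch factors
    (larger along z makes processes run along z); ``gap_thickness`` voxels
    of background shell between objects (0 keeps the partition
    space-filling); ``perturb_iterations`` is a range of random per-object
    dilate/erode rounds that roughen boundaries.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    voxel_size: tuple[float, float, float] = (40.0, 8.0, 8.0)
    num_objects: tuple[int, int] = (20, 30)
    smoothness: float = 100.0
    elongation: tuple[tuple[float, float], ...] = ((0.5, 2.0), (0.5, 2.0), (0.5, 2.0))
    gap_thickness: int = 0
    perturb_iterations: tuple[int, int] = (0, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_objects[0] < 1:
            raise ValueError("num_objects lower bound must be >= 1")
        if any(lo <= 0 or hi <= 0 for lo, hi in self.elongation):
            raise ValueError("elongation factors must be positive")
        if self.gap_thickness < 0:
            raise ValueError("gap_thickness must be >= 0")
        if any(s < 8 for s in self.shape):
            raise ValueError("each axis of shape must be >= 8")


@dataclass
class DegradeParams:
    """Corruption applied to simulated per-section descriptor predictions."""

    noise_sd: float = 0.05
    jitter_max: int = 1
    dropout_prob: float = 0.05
    blur_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.jitter_max < 0 or self.blur_sigma < 0:
            raise ValueError("degradation magnitudes must be >= 0")


def _nearest_label_fill(labels: np.ndarray) -> np.ndarray:
    """Assign background voxels to the nearest labeled voxel."""
    if not (labels == 0).any():
        return labels
    if not (labels > 0).any():
        return labels
    idx = ndimage.distance_transform_edt(labels == 0, return_distances=False,
                                         return_indices=True)
    return labels[tuple(idx)]


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Keep only the largest face-connected component of each object."""
    structure = ndimage.generate_binary_structure(3, 1)
    for obj_id in np.unique(labels):
        if obj_id == 0:
            continue
        mask = labels == obj_id
        cc, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        labels[mask & (cc != keep)] = 0
    return labels


def _generate_once(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    shape = tuple(params.shape)
    vs = np.asarray(params.voxel_size, dtype=float)

    n = int(rng.integers(params.num_objects[0], params.num_objects[1] + 1))
    seeds = np.stack([rng.integers(0, s, size=n) for s in shape], axis=1)

    stretch = np.array([rng.uniform(lo, hi) for lo, hi in params.elongation])

    markers = np.zeros(shape, dtype=np.int32)
    for i, p in enumerate(seeds, start=1):
        markers[tuple(p)] = i

    # potential = distance to the nearest seed under an anisotropically
    # stretched metric (large stretch along an axis -> cheap travel -> basins
    # elongated along it), distorted by smoothed noise so boundaries are
    # irregular rather than planar Voronoi faces
    dist = ndimage.distance_transform_edt(markers == 0, sampling=vs / stretch)
    sigma_vox = params.smoothness * stretch / vs
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    spacing = float(np.prod(np.asarray(shape) * vs / stretch)) ** (1.0 / 3.0) / n ** (1.0 / 3.0)
    potential = dist + 0.6 * spacing * noise
    labels = watershed(potential, markers).astype(np.uint64)

    n_perturb = int(rng.integers(params.perturb_iterations[0],
                                 params.perturb_iterations[1] + 1))
    structure = ndimage.generate_binary_structure(3, 1)
    for _ in range(n_perturb):
        present = np.unique(labels)
        present = present[present > 0]
        if present.size == 0:
            break
        obj_id = int(rng.choice(present))
        mask = labels == obj_id
        if rng.random() < 0.5:
            grown = ndimage.binary_dilation(mask, structure)
            labels[grown & ~mask] = obj_id
        else:
            shrunk = ndimage.binary_erosion(mask, structure)
            if shrunk.any():
                labels[mask & ~shrunk] = 0

    labels = _enforce_connectivity(labels)
    labels = _nearest_label_fill(labels)
    labels = _enforce_connectivity(labels)
    labels = _nearest_label_fill(labels)

    if params.gap_thickness > 0:
        out = np.zeros_like(labels)
        for obj_id in np.unique(labels):
            if obj_id == 0:
                continue
            mask = labels == obj_id
            shrunk = ndimage.binary_erosion(mask, structure,
                                            iterations=params.gap_thickness)
            out[shrunk] = obj_id
        labels = out
    return labels


def generate_labels(params: SynthParams) -> LabelVolume:
    """Random space-filling 3D instance labels (deterministic given seed).

    Seed points partition a noise-distorted distance potential by seeded
    watershed, random per-object dilate/erode rounds roughen boundaries,
    and an optional erosion introduces background shells between objects.
    Degenerate draws (no object surviving) are retried with a new sub-seed
    up to 5 times.
    """
    for attempt in range(5):
        rng = sub_rng(params.seed, 0, attempt)
        labels = _generate_once(params, rng)
        if (labels > 0).any():
            return LabelVolume(labels, params.voxel_size)
    raise RuntimeError("synthetic label generation degenerated 5 times in a row; "
                       "relax gap_thickness or perturb_iterations")


def section_jitter(degrade: DegradeParams, z: int) -> tuple[int, int]:
    """The (y, x) shift applied to section z — re-derivable in isolation."""
    rng = sub_rng(degrade.seed, 1, z)
    j = degrade.jitter_max
    if j == 0:
        return (0, 0)
    return tuple(int(v) for v in rng.integers(-j, j + 1, size=2))


def _shift2d(section: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill (channels untouched)."""
    out = np.zeros_like(section)
    src_y = slice(max(-dy, 0), min(section.shape[-2] - dy, section.shape[-2]))
    src_x = slice(max(-dx, 0), min(section.shape[-1] - dx, section.shape[-1]))
    dst_y = slice(max(dy, 0), max(dy, 0) + (src_y.stop - src_y.start))
    dst_x = slice(max(dx, 0), max(dx, 0) + (src_x.stop - src_x.start))
    out[..., dst_y, dst_x] = section[..., src_y, src_x]
    return out


def simulate_stacked_predictions(labels: LabelVolume, sigma: Sequence[float],
                                 degrade: DegradeParams) -> VolumeGrid:
    """Stacked per-section 2D descriptors with simulated prediction defects.

    Clean per-section descriptors are translated by a random integer (y, x)
    shift, blurred, corrupted with Gaussian noise, clipped to [0, 1]; whole
    sections are zeroed with probability ``dropout_prob``.
    """
    clean = compute_lsd(labels, sigma, dimensionality=2)
    data = clean.data.astype(np.float32, copy=True)
    for z in range(data.shape[1]):
        section = data[:, z]
        dy, dx = section_jitter(degrade, z)
        if (dy, dx) != (0, 0):
            section = _shift2d(section, dy, dx)
        if degrade.blur_sigma > 0:
            section = ndimage.gaussian_filter(
                section, (0.0, degrade.blur_sigma, degrade.blur_sigma))
        rng = sub_rng(degrade.seed, 2, z)
        if degrade.noise_sd > 0:
            section = section + rng.normal(0.0, degrade.noise_sd, section.shape)
        section = np.clip(section, 0.0, 1.0)
        if sub_rng(degrade.seed, 3, z).random() < degrade.dropout_prob:
            section = np.zeros_like(section)
        data[:, z] = section
    return VolumeGrid(data.astype(np.float32), labels.voxel_size, labels.offset,
                      semantic="descriptor")


def make_training_pair(params: SynthParams, sigma: Sequence[float],
                       degrade: DegradeParams
                       ) -> tuple[VolumeGrid, AffinityGrid, LossWeightGrid]:
    """One synthetic (stacked-2D-descriptor input, 3D affinity target) pair.

    Synthetic labels are dense, so the only unsupervised affinity entries
    are those whose partner voxel falls outside the volume.
    """
    labels = generate_labels(params)
    inputs = simulate_stacked_predictions(labels, sigma, degrade)
    target = compute_affinities(labels, DEFAULT_3D_NEIGHBORHOOD)
    weights = LossWeightGrid(target.mask.astype(np.float32),
                             labels.voxel_size, labels.offset)
    return inputs, target, weights


def render_raw(labels: LabelVolume, noise_sd: float = 0.1,
               boundary_darkening: float = 0.5, seed: int = 0) -> VolumeGrid:
    """Render a grayscale image from labels for self-contained demos.

    Per-object constant intensity, darkened membranes at label boundaries,
    plus Gaussian noise — a minimal stand-in for a membrane-stained
    micrograph that gives an image-to-descriptor network something
    learnable.
    """
    rng = sub_rng(seed, 4)
    lab = labels.data
    intensities = {0: 0.35}
    for obj_id in np.unique(lab):
        if obj_id:
            intensities[int(obj_id)] = float(rng.uniform(0.5, 0.9))
    img = np.vectorize(intensities.get, otypes=[np.float32])(lab.astype(np.int64))
    # boundary voxels: any face neighbor with a different id
    boundary = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        diff = lab[tuple(sl_a)] != lab[tuple(sl_b)]
        boundary[tuple(sl_a)] |= diff
        boundary[tuple(sl_b)] |= diff
    img[boundary] *= 1.0 - boundary_darkening
    img = img + rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    return VolumeGrid(np.clip(img, 0.0, 1.0).astype(np.float32),
                      labels.voxel_size, labels.offset, semantic="raw")
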