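"""Training loops for the three network roles.

* :func:`train_sparse_2d` — image sections + sparse annotations, masked
  supervision restricted to annotated voxels.
* :func:`train_3d_from_synthetic` — stacked-descriptor to affinity model
  trained purely on synthetic pairs drawn on the fly (dataset-agnostic).
* :func:`train_3d_mtlsd` — multi-task raw-to-affinity+descriptor model
  trained on (pseudo) ground-truth labels without sparsity masking.

Every stochastic draw consumes a sub-seed split from ``master_seed`` so
runs are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ..synth import DegradeParams, SynthParams, make_training_pair, sub_rng
from ..targets import (
    compute_affinities,
    compute_lsd,
    make_loss_weights,
)
from ..volumes import LabelVolume, SparseAnnotation, VolumeGrid
from .infer import normalize_raw
from .loss import masked_mse, masked_mse_grad
from .optim import Adam
from .unet import ModelSpec, UNet, save_checkpoint

__all__ = [
    "TrainConfig",
    "TrainReport",
    "train_sparse_2d",
    "train_3d_from_synthetic",
    "train_3d_mtlsd",
]

#: 2D in-section neighborhood for per-section affinity targets
NEIGHBORHOOD_2D = ((0, -1, 0), (0, 0, -1))


@dataclass
class TrainConfig:
    """Optimization settings shared by all three training loops."""

    iterations: int = 500
    batch_size: int = 1
    patch_shape: tuple[int, ...] = (64, 64)
    learning_rate: float = 5e-5
    #: "cosine" anneals the rate to a tenth of its start value over the run;
    #: "constant" keeps it fixed
    lr_schedule: str = "cosine"
    augmentations: tuple[str, ...] = ("flips", "transposes")
    intensity_jitter: float = 0.1
    sigma: tuple[float, ...] = (120.0, 120.0, 120.0)
    min_labeled_fraction: float = 0.05
    #: reweight affinity targets inversely to class frequency (boundaries
    #: are a small minority of bonds, plain MSE otherwise ignores them)
    class_balance: bool = True
    checkpoint_every: int = 0
    checkpoint_path: str | None = None
    master_seed: int = 0


@dataclass
class TrainReport:
    """Loss trace and the trained model."""

    losses: list[float] = field(default_factory=list)
    model: UNet | None = None
    checkpoint_path: str | None = None

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["iteration", "loss"])
            for i, loss in enumerate(self.losses):
                writer.writerow([i, loss])


def _set_lr(optimizer: Adam, cfg: TrainConfig, iteration: int) -> None:
    if cfg.lr_schedule == "constant" or cfg.iterations <= 1:
        return
    if cfg.lr_schedule != "cosine":
        raise ValueError(f"unknown lr_schedule {cfg.lr_schedule!r}")
    lr0, lr_end = cfg.learning_rate, 0.1 * cfg.learning_rate
    frac = iteration / (cfg.iterations - 1)
    optimizer.lr = lr_end + 0.5 * (lr0 - lr_end) * (1.0 + np.cos(np.pi * frac))


def _maybe_checkpoint(model: UNet, cfg: TrainConfig, iteration: int) -> str | None:
    if not cfg.checkpoint_path:
        return None
    last = iteration == cfg.iterations - 1
    periodic = cfg.checkpoint_every and (iteration + 1) % cfg.checkpoint_every == 0
    if last or periodic:
        save_checkpoint(model, cfg.checkpoint_path)
        return cfg.checkpoint_path
    return None


def _augment_2d(arrays: list[np.ndarray], cfg: TrainConfig,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Shared random flips/transpose on the trailing (y, x) axes."""
    if "flips" in cfg.augmentations:
        if rng.random() < 0.5:
            arrays = [np.flip(a, axis=-2) for a in arrays]
        if rng.random() < 0.5:
            arrays = [np.flip(a, axis=-1) for a in arrays]
    if "transposes" in cfg.augmentations and arrays[0].shape[-1] == arrays[0].shape[-2]:
        if rng.random() < 0.5:
            arrays = [np.swapaxes(a, -1, -2) for a in arrays]
    return [np.ascontiguousarray(a) for a in arrays]


def _head_targets_2d(section_labels: np.ndarray, section_mask: np.ndarray,
                     heads: Sequence[tuple[str, int]], sigma, voxel_size):
    """Targets and weights for one 2D section, per head name."""
    lv = LabelVolume(section_labels[None].astype(np.uint64), voxel_size)
    ann = SparseAnnotation(lv, section_mask[None])
    out = {}
    for name, _channels in heads:
        if name == "lsd":
            target = compute_lsd(lv, sigma[-2:], dimensionality=2)
            weights = make_loss_weights(ann, target)
            out[name] = (target.data[:, 0], weights.data[:, 0])
        elif name == "affs":
            target = compute_affinities(lv, NEIGHBORHOOD_2D, ann)
            weights = make_loss_weights(ann, target)
            out[name] = (target.data[:, 0], weights.data[:, 0])
        else:
            raise ValueError(f"unknown head {name!r}")
    return out


def _step(model: UNet, optimizer: Adam,
          batch: list[tuple[np.ndarray, dict[str, tuple[np.ndarray, np.ndarray]]]]
          ) -> float:
    """One optimizer step over a batch of (inputs, per-head targets+weights).

    Layer gradients accumulate across the batch samples and are averaged
    before the update.
    """
    total = 0.0
    for inputs, targets_weights in batch:
        preds = model.forward(inputs)
        grads = {}
        for name, (target, weights) in targets_weights.items():
            total += masked_mse(preds[name], target, weights)
            grads[name] = masked_mse_grad(preds[name], target, weights)
        model.backward(grads)
    scale = 1.0 / len(batch)
    optimizer.step({k: g * scale for k, g in model.gradients().items()})
    model.zero_grad()
    return total * scale


def train_sparse_2d(images: VolumeGrid, annotation: SparseAnnotation,
                    spec: ModelSpec, cfg: TrainConfig) -> TrainReport:
    """Train a 2D dense predictor from sparse section annotations.

    Each iteration samples a random in-section patch whose annotated
    fraction is at least ``cfg.min_labeled_fraction``, applies
    augmentations, recomputes targets from the (augmented) labels and
    optimizes the masked weighted MSE.  Unannotated voxels carry zero
    weight and therefore contribute nothing to any update.
    """
    if spec.dimensionality != 2:
        raise ValueError("train_sparse_2d needs a 2D model spec")
    mask = annotation.labeled_mask
    sections = np.flatnonzero(mask.reshape(mask.shape[0], -1).any(axis=1))
    if sections.size == 0:
        raise ValueError("annotation mask is empty on every section")

    raw = normalize_raw(images.data)
    model = UNet(spec, seed=int(sub_rng(cfg.master_seed, 100).integers(2**31)))
    optimizer = Adam(model.parameters(), cfg.learning_rate)
    report = TrainReport(model=model)
    py, px = cfg.patch_shape[-2:]

    def sample(rng: np.random.Generator):
        for _attempt in range(100):
            z = int(rng.choice(sections))
            oy = int(rng.integers(0, max(raw.shape[1] - py, 0) + 1))
            ox = int(rng.integers(0, max(raw.shape[2] - px, 0) + 1))
            m = mask[z, oy:oy + py, ox:ox + px]
            if m.mean() >= cfg.min_labeled_fraction:
                break
        else:
            raise RuntimeError(
                "no patch met the labeled-fraction threshold after 100 draws; "
                "lower cfg.min_labeled_fraction or annotate more area")
        img = raw[z, oy:oy + py, ox:ox + px]
        lab = annotation.labels.data[z, oy:oy + py, ox:ox + px]
        img, lab, m2 = _augment_2d([img, lab.astype(np.int64), m], cfg, rng)
        if cfg.intensity_jitter > 0:
            j = cfg.intensity_jitter
            img = np.clip(img * rng.uniform(1 - j, 1 + j)
                          + rng.uniform(-j, j), 0.0, 1.0).astype(np.float32)
        tw = _head_targets_2d(lab, m2, spec.out_heads, np.asarray(cfg.sigma),
                              images.voxel_size)
        return img[None], tw

    for i in range(cfg.iterations):
        batch = [sample(sub_rng(cfg.master_seed, 101, i, b))
                 for b in range(cfg.batch_size)]
        _set_lr(optimizer, cfg, i)
        loss = _step(model, optimizer, batch)
        report.losses.append(loss)
        report.checkpoint_path = _maybe_checkpoint(model, cfg, i) or report.checkpoint_path
    return report


def train_3d_from_synthetic(spec: ModelSpec, cfg: TrainConfig,
                            synth: SynthParams, degrade: DegradeParams) -> TrainReport:
    """Train the stacked-2D-descriptor to 3D-affinity model on synthetic pairs.

    A fresh synthetic (input, target) pair is drawn each iteration with a
    sub-seed split from ``cfg.master_seed``; the model never sees raw
    images, which keeps it dataset-agnostic.
    """
    if spec.dimensionality != 3:
        raise ValueError("train_3d_from_synthetic needs a 3D model spec")
    model = UNet(spec, seed=int(sub_rng(cfg.master_seed, 200).integers(2**31)))
    optimizer = Adam(model.parameters(), cfg.learning_rate)
    report = TrainReport(model=model)
    def sample(pair_seed: int):
        sp = replace(synth, seed=pair_seed)
        dg = replace(degrade, seed=pair_seed + 1)
        inputs, target, weights = make_training_pair(sp, cfg.sigma, dg)
        if inputs.data.shape[0] != spec.in_channels:
            raise ValueError(
                f"model expects {spec.in_channels} input channels but synthetic "
                f"descriptors have {inputs.data.shape[0]}")
        if cfg.class_balance:
            weights = make_loss_weights(None, target, balance=True)
        return inputs.data, {"affs": (target.data, weights.data)}

    for i in range(cfg.iterations):
        batch = [sample(int(sub_rng(cfg.master_seed, 201, i, b).integers(2**31)))
                 for b in range(cfg.batch_size)]
        _set_lr(optimizer, cfg, i)
        loss = _step(model, optimizer, batch)
        report.losses.append(loss)
        report.checkpoint_path = _maybe_checkpoint(model, cfg, i) or report.checkpoint_path
    return report


def train_3d_mtlsd(raw: VolumeGrid, pseudo_gt: LabelVolume,
                   spec: ModelSpec, cfg: TrainConfig) -> TrainReport:
    """Train the 3D multi-task model on (pseudo) ground-truth labels.

    Two sigmoid heads — direct-neighbor affinities and 3D descriptors —
    are supervised jointly with unit head weights; there is no sparsity
    mask, only out-of-bounds affinity entries are unsupervised.
    """
    if spec.dimensionality != 3:
        raise ValueError("train_3d_mtlsd needs a 3D model spec")
    if raw.data.shape != pseudo_gt.data.shape:
        raise ValueError("raw and pseudo ground truth must be aligned")
    data = normalize_raw(raw.data)
    model = UNet(spec, seed=int(sub_rng(cfg.master_seed, 300).integers(2**31)))
    optimizer = Adam(model.parameters(), cfg.learning_rate)
    report = TrainReport(model=model)
    pz, py, px = cfg.patch_shape[-3:]
    head_names = [n for n, _ in spec.out_heads]

    def sample(rng: np.random.Generator):
        oz = int(rng.integers(0, max(data.shape[0] - pz, 0) + 1))
        oy = int(rng.integers(0, max(data.shape[1] - py, 0) + 1))
        ox = int(rng.integers(0, max(data.shape[2] - px, 0) + 1))
        img = data[oz:oz + pz, oy:oy + py, ox:ox + px]
        lab = pseudo_gt.data[oz:oz + pz, oy:oy + py, ox:ox + px].astype(np.int64)
        img, lab = _augment_2d([img, lab], cfg, rng)
        if "flips" in cfg.augmentations and rng.random() < 0.5:
            img, lab = np.ascontiguousarray(img[::-1]), np.ascontiguousarray(lab[::-1])
        if cfg.intensity_jitter > 0:
            j = cfg.intensity_jitter
            img = np.clip(img * rng.uniform(1 - j, 1 + j)
                          + rng.uniform(-j, j), 0.0, 1.0).astype(np.float32)
        lv = LabelVolume(lab.astype(np.uint64), raw.voxel_size)
        tw = {}
        if "affs" in head_names:
            affs = compute_affinities(lv)
            if cfg.class_balance:
                w = make_loss_weights(None, affs, balance=True).data
            else:
                w = affs.mask.astype(np.float32)
            tw["affs"] = (affs.data, w)
        if "lsd" in head_names:
            lsd = compute_lsd(lv, cfg.sigma, dimensionality=3)
            tw["lsd"] = (lsd.data, np.ones_like(lsd.data))
        return img[None], tw

    for i in range(cfg.iterations):
        batch = [sample(sub_rng(cfg.master_seed, 301, i, b))
                 for b in range(cfg.batch_size)]
        _set_lr(optimizer, cfg, i)
        loss = _step(model, optimizer, batch)
        report.losses.append(loss)
        report.checkpoint_path = _maybe_checkpoint(model, cfg, i) or report.checkpoint_path
    return report
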