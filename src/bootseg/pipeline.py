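"""Bootstrap orchestration.

The full cycle mirrors the two-volume discipline that keeps volume-specific
biases from propagating: sparse 2D annotations on volume 1 train the 2D
net; the 2D->3D path (stacked per-section descriptors -> synthetic-trained
3D affinity net -> post-processing) segments volume 2; that segmentation
becomes pseudo ground truth for a 3D multi-task (affinity + descriptor)
model; the bootstrapped model is finally evaluated back on volume 1.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from . import volume_io
from .evaluate import (
    filter_ground_truth,
    lsd_error_map,
    min_cut_metric,
    skeletonize,
    variation_of_information,
)
from .nets import (
    ModelSpec,
    TrainConfig,
    predict_2d_stack,
    predict_3d,
    train_3d_from_synthetic,
    train_3d_mtlsd,
    train_sparse_2d,
)
from .postproc import agglomerate, build_rag, grid_search, segment, watershed_fragments
from .synth import DegradeParams, SynthParams, generate_labels, render_raw, sub_rng
from .volumes import LabelVolume, SparseAnnotation, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "simulate_sparse_annotation",
    "run_2d3d",
    "run_bootstrap",
    "make_demo_volumes",
    "demo_config",
]


@dataclass
class PipelineConfig:
    """Everything one bootstrap run needs.

    Volumes may be given in memory or as paths (resolved by
    :meth:`from_yaml`).  ``master_seed`` fixes every stochastic stage.
    """

    raw1: VolumeGrid | None = None
    annotation1: SparseAnnotation | None = None
    gt1: LabelVolume | None = None
    raw2: VolumeGrid | None = None

    sigma: tuple[float, float, float] = (120.0, 80.0, 80.0)
    synth: SynthParams = field(default_factory=lambda: SynthParams(
        shape=(16, 32, 32), num_objects=(4, 10)))
    degrade: DegradeParams = field(default_factory=DegradeParams)

    spec2d: ModelSpec = field(default_factory=lambda: ModelSpec(
        dimensionality=2, in_channels=1, out_heads=(("lsd", 6),), depth=2))
    cfg2d: TrainConfig = field(default_factory=lambda: TrainConfig(
        iterations=500, patch_shape=(64, 64), learning_rate=1e-3))
    spec3d: ModelSpec = field(default_factory=lambda: ModelSpec(
        dimensionality=3, in_channels=6, out_heads=(("affs", 3),), depth=2))
    cfg3d: TrainConfig = field(default_factory=lambda: TrainConfig(
        iterations=500, learning_rate=1e-3))
    spec_mtlsd: ModelSpec = field(default_factory=lambda: ModelSpec(
        dimensionality=3, in_channels=1, out_heads=(("affs", 3), ("lsd", 10)), depth=2))
    cfg_mtlsd: TrainConfig = field(default_factory=lambda: TrainConfig(
        iterations=500, patch_shape=(16, 32, 32), learning_rate=1e-3))

    pseudo_thresholds: tuple[float, float] = (0.5, 0.5)
    boundary_thresholds: tuple[float, ...] = (0.3, 0.5, 0.7)
    merge_thresholds: tuple[float, ...] = (0.3, 0.5, 0.7)

    min_gt_size: int = 500
    error_threshold: float = 0.25
    opening_radius: float = 1.0
    evaluate: bool = True
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        # every training stage consumes sub-seeds of the master seed and the
        # descriptor scale is shared so 2D inputs match the 3D net's training
        for name, cfg in (("cfg2d", self.cfg2d), ("cfg3d", self.cfg3d),
                          ("cfg_mtlsd", self.cfg_mtlsd)):
            setattr(self, name, replace(cfg, sigma=tuple(self.sigma)))
        seeds = sub_rng(self.master_seed, 50).integers(2**31, size=3)
        self.cfg2d = replace(self.cfg2d, master_seed=int(seeds[0]))
        self.cfg3d = replace(self.cfg3d, master_seed=int(seeds[1]))
        self.cfg_mtlsd = replace(self.cfg_mtlsd, master_seed=int(seeds[2]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        paths = raw.pop("paths", {})
        for key, loader in (("raw1", "raw"), ("raw2", "raw"), ("gt1", "labels")):
            if key in paths:
                entry = paths[key]
                vol = volume_io.read_volume(entry["path"], entry.get("dataset_key"))
                kwargs[key] = vol
        if "annotation1" in paths:
            entry = paths["annotation1"]
            labels = volume_io.read_volume(entry["path"], entry.get("dataset_key"))
            mask_entry = paths.get("annotation1_mask")
            if mask_entry:
                mask_vol = volume_io.read_volume(mask_entry["path"],
                                                 mask_entry.get("dataset_key"))
                mask = np.asarray(mask_vol.data) > 0
            else:
                mask = labels.data > 0
            kwargs["annotation1"] = SparseAnnotation(labels, mask)
        for key in ("synth",):
            if key in raw:
                kwargs[key] = SynthParams(**raw.pop(key))
        if "degrade" in raw:
            kwargs["degrade"] = DegradeParams(**raw.pop("degrade"))
        for key in ("spec2d", "spec3d", "spec_mtlsd"):
            if key in raw:
                d = raw.pop(key)
                if "out_heads" in d:
                    d["out_heads"] = tuple((n, c) for n, c in d["out_heads"])
                kwargs[key] = ModelSpec(**d)
        for key in ("cfg2d", "cfg3d", "cfg_mtlsd"):
            if key in raw:
                kwargs[key] = TrainConfig(**raw.pop(key))
        for key, value in raw.items():
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)


def _rag_adjacency(labels: LabelVolume) -> dict[int, dict[int, int]]:
    """Contact-face counts between touching instance ids."""
    lab = labels.data
    contacts: dict[int, dict[int, int]] = {}
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        a, b = lab[tuple(sl_a)], lab[tuple(sl_b)]
        touching = (a != b) & (a > 0) & (b > 0)
        pa, pb = a[touching].astype(int), b[touching].astype(int)
        for u, v in zip(pa.tolist(), pb.tolist()):
            contacts.setdefault(u, {})[v] = contacts.setdefault(u, {}).get(v, 0) + 1
            contacts.setdefault(v, {})[u] = contacts.setdefault(v, {}).get(u, 0) + 1
    return contacts


def simulate_sparse_annotation(dense: LabelVolume, mode: str, amount: float,
                               seed: int = 0, collar: int = 2,
                               exclude_ids: Sequence[int] = ()) -> SparseAnnotation:
    """Derive a sparse annotation from dense labels.

    Modes
    -----
    ``single_section_fraction``
        Pick one section and keep a random subset of its instances covering
        about ``amount`` of the section's labeled area (2D annotation).
    ``n_random_objects``
        Keep ``amount`` uniformly chosen whole instances (3D annotation).
    ``n_adjacent_objects``
        Keep one random instance plus its ``amount - 1`` nearest touching
        neighbours (largest contact area first).

    A ``collar``-voxel band around kept instances is marked as annotated
    background so boundary evidence enters the mask; ``exclude_ids``
    supports mutually exclusive draws.
    """
    rng = sub_rng(seed, 7)
    lab = dense.data
    available = [int(i) for i in np.unique(lab) if i > 0 and int(i) not in set(exclude_ids)]
    if not available:
        raise ValueError("no instances available after exclusions")

    sparse = np.zeros_like(lab)
    if mode == "single_section_fraction":
        z = int(rng.integers(0, lab.shape[0]))
        section = lab[z]
        sec_ids = [i for i in np.unique(section) if i > 0 and int(i) not in set(exclude_ids)]
        rng.shuffle(sec_ids)
        labeled_area = int((section > 0).sum())
        target = amount * labeled_area
        covered = 0
        kept = []
        for i in sec_ids:
            if covered >= target:
                break
            kept.append(i)
            covered += int((section == i).sum())
        sparse[z][np.isin(section, kept)] = section[np.isin(section, kept)]
    elif mode in ("n_random_objects", "n_adjacent_objects"):
        n = int(amount)
        if n > len(available):
            raise ValueError(f"requested {n} instances but only "
                             f"{len(available)} are available")
        if mode == "n_random_objects":
            kept = list(rng.choice(available, size=n, replace=False))
        else:
            first = int(rng.choice(available))
            contacts = _rag_adjacency(dense)
            kept = [first]
            frontier = sorted(contacts.get(first, {}).items(),
                              key=lambda kv: (-kv[1], kv[0]))
            for neighbor, _area in frontier:
                if len(kept) >= n:
                    break
                if neighbor in available and neighbor not in kept:
                    kept.append(neighbor)
            # widen through the adjacency graph if direct contacts run out
            while len(kept) < n:
                ring = {}
                for k in kept:
                    for nb, area in contacts.get(k, {}).items():
                        if nb in available and nb not in kept:
                            ring[nb] = ring.get(nb, 0) + area
                if not ring:
                    raise ValueError("adjacency exhausted before reaching n instances")
                kept.append(max(sorted(ring), key=lambda i: ring[i]))
        keep_mask = np.isin(lab, kept)
        sparse[keep_mask] = lab[keep_mask]
    else:
        raise ValueError(f"unknown sparse-annotation mode {mode!r}")

    labeled = sparse > 0
    if collar > 0:
        if mode == "single_section_fraction":
            structure = np.zeros((1, 3, 3), dtype=bool)
            structure[0] = ndimage.generate_binary_structure(2, 1)
        else:
            structure = ndimage.generate_binary_structure(3, 1)
        band = ndimage.binary_dilation(labeled, structure, iterations=collar)
        labeled_mask = band
    else:
        labeled_mask = labeled
    return SparseAnnotation(LabelVolume(sparse, dense.voxel_size, dense.offset),
                            labeled_mask)


def make_demo_volumes(shape=(64, 96, 96), voxel_size=(40.0, 8.0, 8.0),
                      num_objects=(25, 40), seed: int = 0,
                      ) -> tuple[VolumeGrid, LabelVolume, VolumeGrid, LabelVolume]:
    """Two self-contained synthetic volumes (raw rendering + dense labels)."""
    out = []
    for which in (0, 1):
        vol_seed = int(sub_rng(seed, 60, which).integers(2**31))
        labels = generate_labels(SynthParams(shape=tuple(shape),
                                             voxel_size=tuple(voxel_size),
                                             num_objects=tuple(num_objects),
                                             seed=vol_seed))
        raw = render_raw(labels, seed=vol_seed + 1)
        out += [raw, labels]
    return tuple(out)  # type: ignore[return-value]


def demo_config(master_seed: int = 0, shape=(64, 96, 96),
                iterations: int = 500,
                annotation_fraction: float = 0.3) -> PipelineConfig:
    """Configuration of the self-contained synthetic two-volume demo.

    Volume 1 carries a sparse annotation covering about
    ``annotation_fraction`` of the instances of one section; everything
    else follows the pipeline defaults at desk scale.
    """
    raw1, gt1, raw2, _gt2 = make_demo_volumes(shape=shape, seed=master_seed)
    ann = simulate_sparse_annotation(
        gt1, "single_section_fraction", annotation_fraction,
        seed=int(sub_rng(master_seed, 61).integers(2**31)))
    cfg = PipelineConfig(raw1=raw1, annotation1=ann, gt1=gt1, raw2=raw2,
                         master_seed=master_seed)
    cfg.cfg2d = replace(cfg.cfg2d, iterations=iterations)
    cfg.cfg3d = replace(cfg.cfg3d, iterations=iterations)
    cfg.cfg_mtlsd = replace(cfg.cfg_mtlsd, iterations=iterations)
    return cfg


def _persist(config: PipelineConfig, name: str, grid) -> None:
    if config.out_dir is None:
        return
    store = Path(config.out_dir) / "volumes.zarr"
    volume_io.write_volume(grid, store, dataset_key=name, overwrite=True)


def run_2d3d(config: PipelineConfig, source_volume: VolumeGrid,
             model2d, model3d) -> tuple[LabelVolume, dict]:
    """2D->3D inference: stacked per-section descriptors, 3D affinities,
    post-processing at the configured pseudo-ground-truth thresholds."""
    stacked = predict_2d_stack(model2d, source_volume)
    _persist(config, "stacked_lsds", stacked)
    preds = predict_3d(model3d, stacked)
    affs_grid = preds["affs"]
    _persist(config, "affinities_2d3d", affs_grid)
    from .targets import AffinityGrid

    affs = AffinityGrid(affs_grid.data, voxel_size=affs_grid.voxel_size,
                        offset=affs_grid.offset)
    bt, mt = config.pseudo_thresholds
    seg = segment(affs, bt, mt)
    _persist(config, "pseudo_gt", seg)
    info = {"boundary_threshold": bt, "merge_threshold": mt,
            "num_segments": int(len(np.unique(seg.data)) - (1 if (seg.data == 0).any() else 0))}
    if not seg.data.any():
        logger.warning("2D->3D produced an empty segmentation")
    return seg, info


def run_bootstrap(config: PipelineConfig,
                  cached_pseudo_gt: LabelVolume | None = None) -> dict:
    """Full bootstrap cycle; returns a JSON-serializable stage report.

    ``cached_pseudo_gt`` resumes from the pseudo-ground-truth stage: the 2D
    training and 2D->3D segmentation of volume 2 are skipped and the later
    stages — which draw their sub-seeds independently — produce the same
    results they would in a full run.
    """
    if config.raw1 is None or config.raw2 is None or config.annotation1 is None:
        raise ValueError("config must provide raw1, raw2 and annotation1")
    report: dict = {"master_seed": config.master_seed, "stages": {}}
    t_start = time.time()

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    if cached_pseudo_gt is None:
        # (a) sparse 2D training on volume 1
        t = stage("train_2d")
        rep2d = train_sparse_2d(config.raw1, config.annotation1, config.spec2d,
                                config.cfg2d)
        report["stages"]["train_2d"] = {
            "iterations": len(rep2d.losses),
            "final_loss": rep2d.losses[-1] if rep2d.losses else None,
            "seconds": round(time.time() - t, 2)}

        # (b) synthetic-trained 3D net, then 2D->3D segmentation of volume 2
        t = stage("train_3d_synth")
        rep3d = train_3d_from_synthetic(config.spec3d, config.cfg3d,
                                        config.synth, config.degrade)
        report["stages"]["train_3d_synth"] = {
            "iterations": len(rep3d.losses),
            "final_loss": rep3d.losses[-1] if rep3d.losses else None,
            "seconds": round(time.time() - t, 2)}

        t = stage("pseudo_gt")
        pseudo_gt, info = run_2d3d(config, config.raw2, rep2d.model, rep3d.model)
        info["seconds"] = round(time.time() - t, 2)
        report["stages"]["pseudo_gt"] = info
    else:
        pseudo_gt = cached_pseudo_gt
        report["stages"]["pseudo_gt"] = {"cached": True}

    # (c) bootstrap the 3D multi-task model on the pseudo ground truth
    t = stage("train_mtlsd")
    rep_mt = train_3d_mtlsd(config.raw2, pseudo_gt, config.spec_mtlsd,
                            config.cfg_mtlsd)
    report["stages"]["train_mtlsd"] = {
        "iterations": len(rep_mt.losses),
        "final_loss": rep_mt.losses[-1] if rep_mt.losses else None,
        "seconds": round(time.time() - t, 2)}

    # (d) inference + post-processing grid on volume 1
    t = stage("predict_volume1")
    preds1 = predict_3d(rep_mt.model, config.raw1)
    affs1_grid = preds1["affs"]
    _persist(config, "affinities_vol1", affs1_grid)
    from .targets import AffinityGrid

    affs1 = AffinityGrid(affs1_grid.data, voxel_size=affs1_grid.voxel_size,
                         offset=affs1_grid.offset)
    if config.gt1 is not None and config.evaluate:
        rows, best = grid_search(affs1, config.gt1,
                                 config.boundary_thresholds,
                                 config.merge_thresholds, metric="voi_sum")
        bt, mt = best["boundary_threshold"], best["merge_threshold"]
        report["stages"]["grid_search"] = {"rows": rows, "best": best}
    else:
        bt, mt = config.pseudo_thresholds
    seg1 = segment(affs1, bt, mt)
    _persist(config, "segmentation_vol1", seg1)
    report["stages"]["predict_volume1"] = {
        "boundary_threshold": bt, "merge_threshold": mt,
        "num_segments": int(len(np.unique(seg1.data)) - (1 if (seg1.data == 0).any() else 0)),
        "seconds": round(time.time() - t, 2)}

    # (e) evaluation against volume-1 ground truth
    if config.gt1 is not None and config.evaluate:
        t = stage("evaluate")
        gt_f = filter_ground_truth(config.gt1, config.min_gt_size)
        skeletons = skeletonize(gt_f)
        fragments = watershed_fragments(affs1, bt)
        rag = build_rag(fragments, affs1)
        mapping = agglomerate(rag, mt)
        lut = np.zeros(int(fragments.data.max()) + 1, dtype=np.uint64)
        for f, s in mapping.items():
            lut[f] = s
        seg_of_frag = LabelVolume(lut[fragments.data.astype(np.int64)],
                                  config.gt1.voxel_size, config.gt1.offset)
        edits = min_cut_metric(skeletons, seg_of_frag, rag, fragments)
        voi = variation_of_information(seg1, gt_f)
        metrics = {
            "mcm_splits": edits.splits,
            "mcm_merges": edits.merges,
            "mcm_total": edits.total,
            "mcm_per_object": edits.per_object,
            "mcm_per_length_um": edits.per_length,
            "num_gt_objects": edits.num_objects,
            "voi_split": voi.voi_split,
            "voi_merge": voi.voi_merge,
            "voi_sum": voi.sum,
        }
        if "lsd" in preds1:
            emap, emask = lsd_error_map(preds1["lsd"], seg1, config.sigma,
                                        config.error_threshold,
                                        config.opening_radius)
            _persist(config, "lsd_error_map", emap)
            metrics["lsd_error_mean"] = float(emap.data.mean())
            metrics["lsd_error_mask_fraction"] = float(emask.mean())
        metrics["seconds"] = round(time.time() - t, 2)
        report["stages"]["evaluate"] = metrics

    report["total_seconds"] = round(time.time() - t_start, 2)
    if config.out_dir is not None:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        with open(Path(config.out_dir) / "report.json", "w") as f:
            json.dump(report, f, indent=2)
    return report
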