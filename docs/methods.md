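# Methods

## The problem and the approach

Dense 3D instance segmentation of tissue such as brain neuropil normally
requires dense volumetric training annotations, which cost hundreds to
thousands of expert hours. `bootseg` implements a bootstrap that replaces
them with sparse 2D annotations on single sections:

1. **Sparse → dense, 2D.** A 2D network is trained on sparsely annotated
   sections to predict dense per-section *local shape descriptors* (LSDs).
   Supervision is restricted to annotated voxels by a weighted MSE loss
   whose weights vanish outside the annotation mask, so unannotated areas
   are inferred, never penalized.
2. **Stacked 2D → 3D.** The per-section descriptor maps are stacked along
   z and fed to a lightweight 3D network that predicts direct-neighbor
   *affinities* (per-voxel connectivity to the previous voxel along z, y,
   x). This network is trained **only on synthetic data** generated on the
   fly, so it is dataset-agnostic: it never sees raw images.
3. **Post-processing.** Thresholding, distance-transform-seeded watershed,
   a region adjacency graph (RAG) scored by mean face affinity, and
   hierarchical agglomeration turn affinities into an instance
   segmentation.
4. **Bootstrap.** The segmentation of a second volume becomes pseudo
   ground truth — unproofread — for a 3D multi-task model (MTLSD: affinity
   head + auxiliary 10-channel 3D LSD head), which is then evaluated on
   the first volume against its reference labels using variation of
   information (VOI) and a skeleton-based split/merge edit count.

Two volumes are used throughout (train 2D on volume 1, pseudo-GT on volume
2, evaluate the bootstrapped model on volume 1) so volume-specific biases
do not propagate.

## Local shape descriptors

For a voxel v with label L, same-label voxels u in a 3-sigma box are
weighted by `w(u) = exp(-Σ_a (u_a - v_a)² vs_a² / (2 σ_a²))` (world
units; vs = voxel size). The descriptor channels are, in order: per-axis
offset of the local center of mass, mapped from [-σ, σ] to [0, 1];
per-axis coordinate variance divided by σ²; pairwise Pearson correlations
mapped from [-1, 1] to [0, 1]; and local size (Gaussian mass relative to
an unbounded same-label region). 10 channels in 3D (z, y, x axes), 6 per
section in 2D (y, x). Background voxels carry the all-zero vector;
undefined correlations (zero variance) map to the neutral 0.5.

The implementation evaluates these statistics with separable truncated
Gaussian convolutions per object bounding box; a brute-force per-voxel
summation oracle in the test suite pins the result to < 1e-5.

Numerical choices: truncation at 3σ per axis (< 1.2 % of mass); σ given in
nm so anisotropy is handled in world units; coordinates are centered per
bounding box before the moment computation to avoid cancellation.

Default σ = (120, 80, 80) nm at a voxel size of (40, 8, 8) nm — roughly
ten in-plane voxels, the scale of a neurite cross-section.

## Affinities, loss weights, masking

Affinity channel d at voxel p is 1 iff p and its partner p + offset_d
(offsets negative: the partner precedes p per axis) carry the same
positive id. Entries whose partner leaves the volume are 0 and excluded
from every loss (mask false). In sparse mode an entry is supervised only
when both endpoints were annotated.

The loss everywhere is `L = Σ w (p - t)² / max(Σ w, 1e-8)`; multi-head
losses add with unit weights. The gradient with respect to any prediction
with zero weight is exactly zero (asserted by finite differences in the
suite).

**Class balancing.** Boundary bonds are a small minority (~5–10 % of
supervised entries in space-filling volumes). With plain MSE a few hundred
iterations converge to "affinity 1 everywhere" (we measured a final loss
equal to the boundary fraction, and a single output segment). Affinity
training therefore reweights the two classes inversely to their in-batch
frequency, normalized to mean weight 1 (`TrainConfig.class_balance`,
default on). The same option exists in `make_loss_weights` for sparse 2D
affinity targets.

## Synthetic training data

`generate_labels` emulates densely packed neurite-like tissue: N seed
points partition the volume by seeded watershed of a potential field, then
random per-object dilate/erode rounds roughen the boundaries, and an
optional per-object erosion introduces background shells.

The potential is the distance to the nearest seed under an anisotropically
stretched metric plus smoothed noise (correlation length `smoothness`,
default 100 nm; noise amplitude 0.6 of the mean seed spacing). We
initially used pure smoothed noise as the potential, but seeded watershed
of a smooth random field is degenerate in practice — most seeds sit on
slopes and one or two basins swallow the volume (measured: 2 of ~27
objects covering > 99 % of a 64³ draw). The distance-plus-noise potential
keeps sizes balanced while the metric stretch produces elongation: a
stretch range of (0.5, 2) per axis (default) yields mildly anisotropic
processes; stretching z harder produces clearly z-elongated ones (a
statistical test in the suite checks this).

`simulate_stacked_predictions` mimics what a section-wise 2D model emits:
clean per-section 2D LSDs, each section independently translated by an
integer jitter (≤ 1 voxel default), blurred (σ 0.5 voxel), noised
(sd 0.05), clipped, and dropped (zeroed) with probability 0.05. These
corruptions model prediction noise, inter-section registration error and
missing/failed sections. What they do **not** model: systematic,
structured errors of a particular trained 2D net (e.g. consistent
boundary displacement), staining/modality variation, or imaging artifacts
in raw space — the 3D net never sees raw images, by design.

All draws derive from a master seed through counter-based sub-seed
splitting (`sub_rng`), so any individual draw is reproducible in
isolation.

## Networks

Same-padded encoder–decoder U-Nets with two 3×3(×3) convolutions + ReLU
per level, average-pool downsampling (anisotropy-aware: the first 3D level
pools (1, 2, 2)), nearest-neighbor upsampling with skip concatenation, and
one 1×1 sigmoid head per output. Parameters update with Adam. The
implementation is a compact numpy stack with hand-written backpropagation
(im2col convolutions); gradient correctness is pinned by finite-difference
tests, and inference runs in a chunked, cache-free mode so full volumes
fit in memory.

Defaults at desk scale: 2D net depth 2, base 12 features; 3D nets depth 2,
base 12. Optimizer default 5e-5; the desk-scale demo configs use 1e-3
because they train for only a few hundred iterations, with a cosine
schedule annealing to a tenth of the start rate (constant is available).
Gradients can accumulate over a configurable batch of patches per step.
Patch sampling for sparse 2D training rejects patches with < 5 % annotated
voxels. Augmentations: in-plane flips and transposes (targets recomputed
from the transformed labels), intensity jitter on raw inputs only.

Tiled inference pads tiles by the receptive-field radius (computed from
the architecture, including the spread of the pooling windows) rounded up
to the pooling grid, and discards the margins; tiled and untiled outputs
agree to < 1e-4. Volume borders are reflect-padded.

## Post-processing

Foreground mask: a voxel is foreground iff at least one of its touching
bonds exceeds the boundary threshold. (A channel-*mean* indicator was
considered and rejected: with ground-truth affinities a boundary voxel
still has ≥ 5 of 6 bonds at 1, so a mean mask never separates touching
objects and exact recovery is impossible.) Seeds are plateau-merged local
maxima of the anisotropy-aware Euclidean distance transform (footprint
3×9×9 voxels by default — wide in-plane because z is coarse); watershed
floods the negative distance transform inside the mask, additionally
gated by the connected components of the above-threshold bond graph so no
fragment ever spans a bond at or below the threshold — in particular
never a 0-affinity face of ground-truth affinities.

RAG edges carry the mean predicted affinity over the face voxel-pairs
joining two fragments. Agglomeration processes edges in decreasing score
order, merging at or above the merge threshold; the score between
clusters is re-derived from the original face-pair sums (equivalently the
pair-count-weighted mean of constituent edges), so the maximum score never
increases and the segment count is monotone in the threshold. Ties break
on (smaller id, larger id). A brute-force recompute-all implementation
cross-checks agglomeration on small random graphs.

With ground-truth affinities of space-filling synthetic volumes this
pipeline recovers the source labels exactly (VOI ≈ 0, zero edit
operations) at thresholds (0.5, 0.5).

## Evaluation

* `filter_ground_truth`: labels smaller than 500 voxels removed
  ("smaller than" read strictly), then face-connected components relabeled
  consecutively; components that fall under the threshold after splitting
  are removed too, making the operation idempotent.
* `skeletonize`: per-object 3D topological thinning; skeleton voxels
  become nodes at voxel-center world coordinates, 26-adjacencies reduced
  to a minimum spanning tree (shortest-edge preference), terminal branches
  shorter than 10× the minimum voxel size pruned. Objects that thin away
  entirely yield a single node at their most interior voxel.
* Min-cut edit metric: skeleton nodes map to the segment at their voxel
  (background nodes dropped, logged). Split edits per skeleton = connected
  components of the same-segment subgraph, minus one. Merge edits per
  segment hosting k ≥ 2 skeletons = the minimum number of cut operations,
  each removing one minimum unit-capacity edge cut between a
  still-connected skeleton pair in the segment's fragment graph. The
  count is exact (branch-and-bound over pairs and over all minimum cuts)
  up to 12 fragment-graph edges per segment, greedy sequential beyond;
  an exhaustive state-space-search oracle verifies the exact regime.
  Edits are reported in total, per ground-truth object, and per micron of
  skeleton path length.
* VOI: conditional entropies in bits over ground-truth-foreground voxels.
* LSD error map: Euclidean norm across channels of (predicted descriptors
  − descriptors recomputed from the evaluated segmentation); the error
  mask thresholds the norm and applies binary opening with an
  anisotropy-aware ellipsoid so single-voxel boundary disagreements
  vanish while genuine split/merge blobs survive.

## The synthetic demonstration and problem sizes

The self-contained demo builds two 64×96×96 volumes at (40, 8, 8) nm with
25–40 objects each, renders "raw" images as per-object constant intensity
with darkened membranes plus Gaussian noise (σ 0.1), and annotates ~30 %
of the instances of one section of volume 1 (with a 2-voxel annotated-
background collar, since instance labels alone carry no boundary
evidence). Networks train for 500 iterations each — chosen as a desk-scale
budget that one CPU completes in minutes; the 3D training patches are
16×32×32 with 4–10 objects. The rendered images are far easier than real
micrographs (no texture, no staining variation, no registration error),
so passing the end-to-end bounds demonstrates that the plumbing, losses,
masking and post-processing interact correctly — not that the method
reaches publication-grade accuracy on electron micrographs.

## Known limitations

* The numpy networks are desk-scale: minutes per 500 iterations on small
  patches; they are not a route to GPU-scale training.
* The synthetic generator produces convex-ish, non-branching cells;
  branching neurites and organelle-rich interiors are out of scope.
* Merge-edit counting falls back to a greedy (upper-bound) count for
  segments whose fragment graphs exceed 12 edges.
* Post-processing is in-memory; block-wise processing of larger-than-RAM
  volumes is not implemented.
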