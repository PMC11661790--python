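# Methods

This note documents the models, algorithms and numerical choices behind
tomoseg, and what its synthetic phantoms do and do not show about real
cryo-electron tomography data.

## Problem setting

A tomogram is a 3D reconstruction of a vitrified specimen, stored as an MRC
grid with an isotropic voxel size in Angstrom.  Semantic segmentation
assigns each voxel a probability of belonging to a feature of interest
(membrane, carbon support film, ribosome, antibody platform, ...).  tomoseg
covers the downstream chain: sparse 2D annotations → balanced training sets
→ per-feature CNNs → slice-wise whole-volume prediction → conditional
combination of multiple feature predictions → particle coordinates and
surface meshes.

## Annotation and training sets

Annotations are boxes on individual z-slices: a positive box carries a
binary label mask; a negative box shows confusable content and an all-zero
label.  Patches are 64 × 64 pixels by default.  Each patch is normalised to
zero mean and unit variance (statistics in float64; a patch whose standard
deviation is below 1e-9 maps to zeros — the normalisation the network sees
at inference is identical).

Positives are usually scarce, so the set is rebalanced before training:
every positive is copied 10 times and negatives are drawn uniformly **with
replacement** until the negative:positive ratio is 1.3:1 (count rounded
half-up).  Every emitted patch receives a random orientation.  By default
the orientation is one of the 8 dihedral symmetries of the square (4
rotations × optional flip): these are exact for binary labels, avoiding
interpolation artifacts.  An `arbitrary_rotation` flag rotates by a uniform
random angle instead, with bilinear image and nearest-neighbour label
interpolation.  All draws derive from a single integer seed.

## Network architectures and training

The registry ships three compact 2D segmentation networks, all mapping a
(64 × 64 × 1) patch to per-pixel probabilities via a terminal sigmoid:

* `eman2_like` — three 5 × 5 convolutions (1→8→8→1) with ReLU, no
  downsampling; ~2,000 parameters.
* `vgg_small` — stacked 3 × 3 convolutions with two max-pool stages and a
  nearest-neighbour-upsampling decoder; ~8,300 parameters.
* `unet` — a depth-2 U-Net (8/16/32 channels) with skip connections;
  ~29,600 parameters.

Any Python file dropped into a plugins directory that defines `ARCH_NAME`,
`DOWNSAMPLE` and `build(box_size, rng)` is auto-registered, so users can add
architectures without touching the package.

Networks are trained by minimising mean pixel-wise binary cross-entropy
with Adam (learning rate 1e-3, β₁ = 0.9, β₂ = 0.999) for 50 epochs at batch
size 32 by default.  No validation split is applied by default, so every
annotated patch contributes to the fit and the recorded per-epoch loss is
the training loss; with `validation_split > 0` the recorded history holds
validation losses instead.  Weight initialisation (He-normal), shuffling and
augmentation are all seeded, making training reproducible on one device.
A non-finite loss aborts training naming the epoch.

The layers are implemented directly on numpy in channels-last layout;
convolutions are evaluated as sums of spatially shifted BLAS matrix
products, and every layer's backward pass is analytic (verified against
numerical differentiation in the test suite).  This keeps the toolkit free
of heavyweight runtime dependencies while training the small shipped
networks in minutes on one CPU core.

## Whole-volume inference

Volumes are segmented slice by slice.  Each z-slice is covered by box-sized
tiles on a stride grid (final row/column shifted flush with the edge);
tiles are normalised exactly like training patches; overlapping predictions
are blended by uniform averaging (a `crop` mode that keeps only central
tile regions is available).  Slices smaller than the box are reflect-padded
and cropped back.  Output voxels always lie in [0, 1].

## Model interactions and competition

Multi-feature segmentations are refined by two suppression-only mechanisms.

**Interactions** (parent → child, radius R in nm): a binary mask is made by
thresholding the parent's prediction at the interaction threshold
(inclusive ≥), then dilated with a circular kernel of radius
`round(R·10/pixel_size)` pixels (round half-up; radius 0 means no
dilation).  Colocalization multiplies the child by the mask; avoidance by
its complement.  The kernel is a 2D disk applied per slice, matching the
slice-wise segmentation model; a 3D-ball mode is available behind a flag.
For avoidance we complement **after** dilating — suppression covers
everything within R of an above-threshold parent voxel; the two orders
differ at mask borders and the implementation keeps them switchable via the
mask mode.  Dilation by large kernels is evaluated as a thresholded FFT
convolution with the same kernel, which is exact for binary masks and keeps
R = 30 nm interactions fast.

**Competition**: each feature may *emit* and/or *absorb*.  An absorbing
feature's value at a voxel is set to zero when any **other** emitting
feature's value there is strictly higher; exact ties survive.  All
comparisons read the original inputs (simultaneous update), which makes the
operation idempotent and order-free.

A pipeline applies competition first, then interactions in their configured
order (each rule consumes the current state).  The relative order is a
design choice — competition is a symmetric arbitration step, interactions
are directed edits — and the configuration keeps the interaction list
explicitly ordered because interaction chains do not commute in general.

## Particle picking

Six steps convert a prediction volume into coordinates:

1. threshold at a user-chosen level (inclusive);
2. Euclidean distance transform of the binary foreground;
3. watershed of the negated distance transform seeded at its local maxima
   (3 × 3 × 3 maximum filter; each connected plateau of maxima contributes
   one seed at its lowest flat index, so seeding is deterministic);
   foreground connectivity is 26-connected throughout;
4. groups smaller than the minimum volume (nm³, voxel count ×
   (pixel_size/10)³) are discarded;
5. each group is weighted by the sum of prediction values over its voxels;
   groups are then visited in descending weight (ties broken by centroid,
   lexicographically) and a group survives only if its centroid lies at
   least the minimum spacing (nm) from every already-retained centroid —
   a greedy resolution of the pairwise "lower weight is discarded" rule
   that is deterministic for chains of mutually close groups;
6. the unweighted centroid of each surviving group's voxel indices, rounded
   half-up to integers, is reported, sorted by descending weight.

Spacing is measured centroid-to-centroid.  On volumes where every
26-connected component has a unique distance-transform maximum plateau the
grouping provably coincides with connected-component labelling, which the
test suite exploits as an independent oracle.

## Meshes and dust

Isosurfaces are extracted with marching cubes at the chosen level, scaled
to Angstrom by the voxel size and written as Wavefront OBJ (1-based
indices, triangles only).  "Dust" — small false-positive components — is
removed in voxel space: 26-connected components of the thresholded volume
below a minimum volume in nm³ are zeroed, leaving retained components
bit-identical.  Voxel-space filtering (rather than mesh-component
filtering) keeps the dust rule identical to the picking minimum-volume
rule.

## The synthetic phantom

The generator emulates the vesicle-sample scene that motivates the
interaction rules: spherical-shell membranes (outer radius 12–18 nm, 5 nm
thick), an optional carbon-film-like half-space slab with a straight edge,
platform discs (radius 4 nm, 3 nm thick) whose centres sit 22 nm outside
the membrane surface, solid-sphere granules (4–8 nm), cylindrical filaments
(2 nm radius, 30–60 nm long), all painted at unit contrast on a zero
background with additive Gaussian noise (σ = 0.2 by default).  The default
pixel size is 10 Å (1 nm per voxel), typical of binned tomograms.  Objects
are placed by bounded rejection sampling so ground-truth volumes are
pairwise disjoint; placement failure raises an error naming the constraint.

Platform normals are confined near the vesicle equator (axial component
≤ 0.15): the z-slice through a platform then also cuts its host membrane,
the geometry in which slice-wise proximity rules between platform and
membrane are meaningful (and the geometry in which such annotations are
made in practice).  Optional flags add anisotropic z-blur or invert the
contrast; neither is on by default because the method does not depend on
missing-wedge artifacts.

What the phantom does **not** model: CTF and dose effects, missing-wedge
distortion, structured background (crowded cytoplasm), intensity gradients,
or realistic membrane texture.  Passing phantom tests therefore
demonstrates the correctness of the algorithms (grouping, algebra, picking
geometry, training mechanics) — not segmentation accuracy on real
tomograms, which depends on annotation quality and feature contrast.

## Problem sizes used in the validation runs

The shipped validation suite and `scripts/acceptance.py` use: 50 random
≤ 32³ sphere scenes for the watershed/connected-components comparison; a
64 × 96 × 96 volume with 20 planted blobs for recovery; a 48 × 192 × 192
granule phantom yielding ~500 rebalanced patches (22 positive and 10
negative boxes) for the training run — 50 epochs at batch 32 with the
`eman2_like` architecture, evaluated on a held-out 40 × 128 × 128 phantom;
and a 96 × 128 × 128 two-vesicle phantom with six platforms plus 300
injected on-membrane false positives for the interaction chain (avoid
membrane R = 10 nm, then colocalize with membrane R = 30 nm).  These sizes
make the whole validation run complete in a few minutes on one CPU core
while keeping every stage at a scale where brute-force oracles are exact.

## Known limitations

* Training is CPU-bound and single-threaded beyond BLAS; the shipped
  architectures are deliberately small.  Larger networks belong behind the
  plugin interface with an external runtime.
* Anisotropic voxel sizes are read with the x spacing and a warning;
  downstream arithmetic assumes isotropy.
* The STAR dialect is a minimal RELION-style coordinate block without
  optics groups.
* Prediction volumes are written as float32 MRC in [0, 1]; tools expecting
  rescaled integer volumes need a conversion step.
* Adversarial (pix2pix-style) training is out of scope.
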