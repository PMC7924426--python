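# Methods

`symslice` classifies 3D organ scans by reducing each volume to a single
2D image sampled on its plane of best bilateral symmetry, then classifying
that image with a small convolutional network. Because the symmetry plane
is a property of the imaged anatomy rather than of the scanner coordinate
frame, the representative image is stable under changes of patient
orientation (rotation, translation) and imaging direction (axis
permutation) — the property the whole pipeline exists to provide. This
note records the model, the parameters that matter, the numerical choices,
and what the synthetic phantoms do and do not establish.

## Volume reconstruction

A scan arrives as a DICOM series (stacked by ascending `InstanceNumber`),
a NIfTI file, or an `.npz` array container. Because in-plane pixel spacing
(`ps_x`, `ps_y`) generally differs from the slice spacing (`st`), the
voxel lattice is resampled to an isotropic grid before any geometry is
computed. The resampled array size is

    [n_x,  round(n_y · ps_y / ps_x),  round(n_z · st / ps_x)]

with spacing `ps_x` on every axis, cubic interpolation, and edge-clamped
boundary handling. Non-integer sizes round half away from zero with a
floor of one. Both the y and the z extent are normalized by `ps_x`; when
`ps_x ≠ ps_y` this is applied literally rather than symmetrized. Physical
extent is preserved to within one output voxel per axis.

## Segmentation

The organ is isolated with two-threshold global Otsu: the pair
`(t_low, t_high)` maximizing the between-class variance of the three-class
partition of a 256-bin global histogram, searched exhaustively over all
bin pairs (ties resolved to the lexicographically smallest pair). Voxels
with intensity in the closed band `[t_low, t_high]` form the organ mask;
discarding the outer classes also removes artifacts at the extremes of the
intensity spectrum and bright non-anatomical structures (bone shells,
scanner table). The mask is converted to a point cloud of voxel
coordinates. Otsu runs on the resampled volume, since its output feeds the
point cloud directly.

Two pragmatic refinements feed the symmetry stage:

- **Largest connected component.** Partial-volume voxels at the edges of
  bright excluded structures fall inside the band as thin shells detached
  from the organ; only the largest connected in-band component is treated
  as the organ. Without this, shell voxels perturb the cloud's centroid
  and moment statistics differently at different orientations.
- **Sub-voxel boundary.** The cloud handed to the registration is the set
  of marching-cubes iso-surface vertices of a lightly smoothed
  (σ = 1 voxel) copy of the volume at the two band thresholds, restricted
  to within one voxel of the organ component. A binary voxel surface
  carries a ≈0.5-voxel staircase mismatch floor which, on an organ a few
  dozen voxels across, hides tilts of several degrees; iso-surface
  vertices resolve the boundary to a fraction of a voxel. Thresholds,
  cloud statistics, and the extracted slice all use the unsmoothed data.

## Symmetry-plane estimation

The estimator uses the classical reflection-registration construction:
reflect the cloud about a starting plane `(H₀, b₀)`, rigidly register the
reflection back onto the original with point-to-point ICP (nearest
neighbours via a k-d tree; closed-form Kabsch update with determinant
correction), and form the composite map `S(x) = Mx + c` with `M = R·H₀`
and `c = R·b₀ + t`. For a true symmetry `M` has eigenvalues {−1, +1, +1}:
the eigenvector at −1 is the plane normal and the offset is
`d = (n·c)/2`. ICP defaults: 50 iterations, stop when the relative RMS
change drops below 1e−4, clouds subsampled to at most 5000 points with a
fixed seed.

ICP is local and, for smooth nearly-convex shells, its cost surface has a
flat valley: most correspondences are satisfied by a whole neighbourhood
of planes, and only a small fraction of points (interior cavities,
asymmetric outline) carry the tilt information. The estimator therefore
wraps the core construction in a global-then-local search:

1. **Seeding.** Starting normals are the cloud's three principal axes,
   the bisectors of any axis pair whose variances are within 15% of each
   other (when two variances tie, the eigenvectors rotate freely in their
   subspace and can start the search 45° from the truth), and the best
   directions of a coarse 96-direction Fibonacci-hemisphere sweep of the
   symmetry score below.
2. **Refinement.** Each seed runs the reflect–register–re-estimate cycle
   up to three times; a true symmetry plane is a fixed point of this map.
3. **Selection.** Candidates are ranked by the mean nearest-neighbour
   distance, in the 90th–99th percentile band, between the cloud and its
   reflection about the candidate plane. The tail band is what makes the
   score discriminative — the mean is diluted by trivially-matching
   points, while the extreme tail is noise — and the same objective is
   used everywhere a plane must be compared.
4. **Polish.** The best two candidates are refined by Nelder–Mead over
   two tilt parameters and the offset on that objective, with a coarse
   simplex (≈8° tilt steps) followed by a fine one (≈3°), and the better
   final score wins.

The slice axes span the `+1` eigenspace of `M`, i.e. the plane itself.
For a near-exact reflection that eigenspace is numerically degenerate (a
complex pair with arbitrary phase), so the in-plane basis is fixed by the
data instead: `axis_u` is the principal axis of the solid organ cloud
projected onto the plane, `axis_v` its in-plane complement, and the sign
of each is chosen so the third moment (skewness) of the cloud projections
is positive, falling back to a fixed component-sign rule only when the
skewness is indistinguishable from zero. The normal is then rebuilt as
`n = u × v` (right-handed) with the offset's sign following it. Every
choice depends on the imaged content alone, which makes the frame — and
hence the extracted image — equivariant under rigid motions and axis
permutations of the data. Frame axes are computed from the dense solid
cloud even though registration runs on the boundary, because
volume-weighted moments are markedly more stable than surface ones.

The reported `residual_rms` is the winning candidate's final ICP
correspondence RMS in voxel units; genuinely symmetric shapes give values
near the discretization floor.

## Representative-image extraction

The raster lies on the estimated plane. Its origin is the orthogonal
projection of a reference point onto the plane — by default the midpoint
of the volume-box corner projections, and in the pipeline the segmented
cloud's centroid, which makes the image follow the imaged content rather
than the scanner box. The window is square with side equal to the
volume's longest grid edge, so the physical step per pixel
(side / 223 for a 224-pixel raster) is identical for a volume and any
rotated, translated, or axis-permuted copy of it. (Bounding the raster by
the corner projections themselves, the obvious alternative, rescales the
image by up to ~14% as the plane tilts within ±15° and destroys pixelwise
comparability.) Sampling is nearest-neighbour with zero fill outside the
volume, so every in-volume pixel equals some voxel's value exactly.
Finally the image is padded to square if needed, linearly rescaled from
its own [min, max] to [0, 255] (a constant image maps to zeros), rounded,
and resized to 224 × 224 with bilinear interpolation. Per-image rescaling
makes the pipeline modality-agnostic; intensity calibration across scans
is deliberately not assumed.

## Orientation perturbations and datasets

Patient-orientation changes are modelled by random rigid motions of the
isotropic volume: one angle per axis uniform in ±15°, composed x→y→z
about the volume center, plus one offset per axis uniform in ±5 voxels,
resampled with linear interpolation and zero fill. Imaging-direction
changes are modelled by one of the five non-identity axis permutations
(pure index permutation, no interpolation). Both operations require an
isotropic volume — a voxel-space rotation of an anisotropic lattice would
shear the anatomy.

`build_datasets` performs a stratified 70/30 split (per class,
`round(f·n)` to training), derives rigidly-transformed and axis-swapped
copies of the test set 1:1, and builds an augmented training set from a
copy of the training items, half rigidly perturbed and half axis-swapped.
All randomness derives from one seed; the perturbation parameters of
every derived item are recorded.

## Synthetic phantoms

The generator emulates the study conditions without any external data:
four classes (head, thorax, breast, abdomen) with class-distinctive
geometry, built mirror-symmetric about a known sagittal plane on an
anisotropic grid (default 56×56×24 voxels at 0.8×0.8×2.4 mm). Intensities
occupy three tiers — background ≈5, soft tissue ≈108–128, bright
structures and artifacts ≥205 — separated by wide gaps so the
two-threshold band isolates the soft tissue. Bright structures (skull-like
rim, vertebral column, internal markers, a scanner-table slab present in
every class) are excluded by the band and leave crisp class-distinctive
holes in the cloud while remaining visible in the slice. A Gaussian
point-spread function of (0.7, 0.7, 1.0) voxels band-limits the geometry;
the axial width matches the slice spacing, as in clinical reconstructions,
which keeps the coarsely sampled z direction free of aliasing. Mirrored
noise specks at the intensity extremes exercise the band's artifact
rejection and are confined to the background.

Three design constraints matter and were each arrived at the hard way:

- Bodies are egg-shaped (unequal y/z semi-axes) with an off-center
  on-plane marker, so the sagittal plane is the *unique* mirror symmetry;
  a plain ellipsoid has three.
- All tissue keeps ≥3 mm clearance from the volume boundary under the
  worst ±15°/±5-voxel perturbation, and ≥3 mm from the table slab, so
  that content is never clipped and partial-volume shells never bridge
  components differently at different orientations.
- `asymmetry_jitter` (default 0.5 voxel) displaces the members of
  mirrored structure pairs, mostly along the mirror normal; in-plane
  jitter is applied at quarter strength because a differential in-plane
  displacement of a pair tilts the true best-fit plane by roughly
  displacement/separation, which would invalidate the nominal plane as
  ground truth long before the jitter reached a voxel.

With jitter and noise at zero the voxel lattice is mirror-symmetric
exactly. What phantom results do **not** establish: robustness to
anatomy-scale asymmetries (tumors, resections), to intensity
non-uniformity (bias fields), to multi-modal intensity statistics, or to
organs truncated by the field of view.

## Classifier

The network has exactly 20 layers: an image input, four blocks of
(3×3 convolution, batch normalization, ReLU, 2×2 max pooling with stride
2) with 8, 16, 32, 64 filters, one fully connected layer, softmax, and a
classification output. A 224×224×1 input reaches the dense layer as
14×14×64. It is implemented directly in numpy (im2col convolutions via
stride tricks, float32 arithmetic) with He initialization from a fixed
seed, and trained with SGD + momentum 0.9 on the cross-entropy at
learning rate 0.01 for 30 epochs, batch size 32. The rate is set for
reliable convergence at the package's default problem size (~10²
training images, so only ~10² parameter updates); at that budget 1e−3
visibly underfits. Everything is configurable. Inputs are scaled to
[0, 1]; prediction returns per-class softmax probabilities and reports
confidence as the maximum probability ×100%.

An alternative conventional backend computes HOG descriptors
(9 orientations, 16×16 cells, 2×2 blocks) and fits an RBF-kernel SVM
(one-vs-one) with its regularization chosen by stratified five-fold
cross-validation.

Evaluation uses the confusion matrix: accuracy = trace/total (micro), and
sensitivity, specificity, precision, F-measure, and G-mean computed per
class one-vs-rest and then macro-averaged. Macro F is the mean of
per-class F values, not the F of the macro precision/recall pair. Classes
with a vanishing denominator contribute 0 and are flagged with a warning
rather than producing NaN.

## Scales, budgets, and known limitations

The default experiment trains on 80 phantom representative images
(20 per class) and evaluates 40 held-out phantoms under the three
orientation conditions; a full run (extraction of 200 images plus
training) takes on the order of ten minutes on one CPU core. The phantom
grid size is chosen so a single extraction takes about 1.5 s; clinical
archives operate far from this point — hundreds of 512³ volumes — and
desk-scale phantoms make the symmetry problem *harder*, not easier: tilt
identifiability scales with organ radius in voxels, which is why the
estimator needs the sub-voxel boundary and the tail-band objective at
this scale.

Known limitations: the plane search assumes a single dominant mirror
symmetry; point-to-point ICP is used (point-to-plane was not explored);
the slice's in-plane skewness sign rule can still flip for content that
is almost perfectly symmetric along an in-plane axis (the classifier is
robust to this only insofar as flipped images remain class-typical);
DICOM handling covers single-frame series ordered by `InstanceNumber`
only, with no `ImageOrientationPatient` world coordinates.
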