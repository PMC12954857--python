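# Methods

This note records the scientific conventions, modeling choices and known
limitations behind `tomodenoise`. It is written for a reader who wants to
know exactly what the synthetic benchmark measures and where its edges are.

## Geometry and coordinate conventions

Arrays are indexed `(z, y, x)`. Z is the beam direction at zero tilt; the
tilt axis is Y; a projection at tilt θ is the line integral of the volume
rotated by −θ about Y. Coordinates are 0-based voxel indices everywhere
inside the package; conversion to external 1-based conventions happens only
at file boundaries. MRC files are written mode 2 (32-bit float) with the
standard X-fastest axis order, which maps directly onto a C-ordered
`(nz, ny, nx)` array.

## The measurement model

The simulator realizes the standard linear model of tomography: noisy
projections `y = A x + ε`, where `A` is the parallel-beam projection
operator over a limited tilt range and `ε` is per-pixel noise. Two noise
models are provided: i.i.d. additive Gaussian, and a Poisson–Gaussian
compound in which intensities are mapped through a positive affine ramp
`rate(v) = 0.1 + 0.9 (v − min)/(max − min)`, Poisson counts with a
per-pixel dose budget are drawn and mapped back, and Gaussian read noise is
added. The affine ramp is needed because projection intensities are not
count-valued; its range [0.1, 1] keeps all rates strictly positive.

**Projection** is rotate-then-sum with trilinear interpolation (not ray
casting): simple, adequate at desk scale, and mass-conserving to within 1%
across the tilt range for a fully contained object (asserted by test). At
exactly 0° no interpolation occurs and the projection equals the direct
Z-sum.

**Filtered back-projection** applies a Ram-Lak ramp `|ν|` (cycles/pixel)
along the detector X axis per projection and back-projects with linear
interpolation. The sum is scaled by the mean angular spacing Δθ in radians —
the discrete quadrature weight of the inverse Radon transform — so a
full-angular-range reconstruction approximates the object in its own
density units (a 64³ unit-density sphere reconstructs to ≈0.99 at center).
The operator is linear in the projections by construction. Band limitation
(the Gaussian roll-off filter with defaults 0.42 / 0.03 cycles per pixel)
is a separate post-filter, not folded into FBP, keeping reconstruction and
band limitation independently testable.

**Missing wedge.** With tilts confined to [−60°, 60°], the set of central
sections leaves all Fourier directions within 30° of k_z unmeasured. The
wedge mask marks exactly this region: a voxel passes iff the folded line
angle of its (k_x, k_z) projection lies in the tilt interval; the mask is
constant along k_y (single-axis geometry) and explicitly symmetrized under
*modular* negation because on even grids the Nyquist plane is its own
conjugate partner with a sign-flipped folded angle. The analytic zero
fraction for ±60° is 2·30°/180° = 1/3 of directions — equivalently 1/3 of
Fourier voxels *within the Nyquist sphere*; over the whole cubic grid the
expected fraction is tan(30°)/2 ≈ 0.289 because corner voxels weight
directions unevenly. Tests use the sphere-restricted count.

A ±60° FBP reconstruction of a centered sphere puts ≈2.8% of its Fourier
energy into the unmeasured wedge (versus ≈34% for a full-range
reconstruction of the same object — the isotropic share of the wedge
region). The residual few percent is interpolation leakage inherent to the
rotate-then-sum projector and linear back-projection; a slice-insertion
simulator would reduce it further but was not needed at this scale. The
reconstruction also shows the expected Z-elongation: the half-maximum
extent of the sphere along Z exceeds that along X.

## Training-pair generation

**T2T** splits an acquired (noisy) tilt series by index parity — half A
takes index 0 — mimicking even/odd tilt splitting. **F2F** simulates the
movie-frame route explicitly: each tilt is realized as `frames_per_tilt`
independent sub-exposure frames carrying `dose/frames` each and per-frame
Gaussian sigma `σ√frames`, so the average of all frames reproduces
full-exposure statistics while each half-average carries √2 more noise than
the full exposure — the halves-have-more-noise property holds by
construction rather than by assumption. The mean of the two halves *is* the
full-dose realization.

**N2N pairs** are random subvolume corners from the two
half-reconstructions, emitted in both mapping directions (a→b and b→a) so
the learned mapping is symmetric, with optional augmentation by one of
{0°, 90°, 180°, 270°} about the tilt axis (exact `rot90` permutations, no
interpolation). Augmentation defaults to on for L2 training.

**Wedge-corrupted pairs** (`scheme="ddw"`) additionally draw a uniform
random 3D rotation per pair, rotate both subvolumes, corrupt the input with
an artificial wedge in canonical orientation, and attach the acquisition
wedge rotated by the same rotation as the pair's loss mask — the loss is
evaluated only where the target carries measured information. This is a
deliberately compact rendition of the wedge-corruption training idea;
fidelity to any specific published implementation is not claimed. Combining
the FSC loss with a loss mask is supported but flagged experimental: a
masked frequency-space loss turns denoising into a partial inpainting
problem and is known to be harder to optimize.

## Losses

L2 (mean squared error) is the default; L1 is provided. The FSC loss is

    L = 1 − [ Σ_q w_q FSC_q ] / [ Σ_q w_q ],   FSC_q = Re Σ_{k∈q} F_p conj(F_t) / sqrt(Σ|F_p|² Σ|F_t|²)

with trapezoid quadrature weights over an inclusive shell range. Choices
worth stating:

- **DC excluded by default** (`q_lo = 1`): DC correlation is a statement
  about mean brightness, not structure. Configurable.
- **Trapezoid weights**: the scalar score is an integral over shells;
  trapezoid is the natural discrete quadrature and is documented as this
  package's choice.
- **Dead shells** (zero denominator, e.g. fully inside a hard wedge mask)
  get zero quadrature weight rather than a defined-zero correlation, so
  they contribute no spurious gradient.
- The loss is bounded in [0, 2], zero iff per-shell correlation is perfect,
  symmetric in its arguments, and invariant to positive rescaling of either
  argument (unlike L2) — all asserted by tests.
- The gradient is analytic (Wirtinger calculus through the FFT) and matches
  central finite differences to better than 1% at randomly probed voxels.

## Network backbones

Both models are implemented in numpy with hand-written backward passes and
He-style seeded initialization; evaluation is deterministic.

- **U-Net**: `depth` = number of 2× down-samplings (default 3, i.e. four
  resolution scales), 64 base channels doubling per scale, two 3³ convs +
  ReLU per scale, max-pool down, transposed-conv up, skip concatenation, no
  normalization layers. ≈22.4M trainable parameters at the default — the
  "tens of millions" regime of a standard three-stage 3D U-Net. Input sides
  must be divisible by 2^depth.
- **MS-D**: `depth` dilated 3³ conv layers (default 10) of `width` channels
  (default 1), dilations cycling 1…10, dense connections from the input and
  every earlier layer into each later layer, final 1³ linear projection —
  1507 parameters at the default, four orders of magnitude below the U-Net.
  Parameter count follows the closed form Σ_i 27·c_i·w + w with c_i the
  accumulated channel count, verified against brute-force enumeration.

Computation is float32 by default (`ModelConfig.dtype`), which roughly
halves the memory traffic of the convolution inner loops; float64 is used
in tests that compare analytic gradients against finite differences.

Training uses Adam (β = 0.9/0.999, ε = 1e-8) with mini-batch gradient
averaging. Epoch shuffles derive from `(seed, epoch)` and the optimizer
moments travel in the returned history state, so a run resumed from a
checkpoint continues bit-for-bit. A non-finite loss aborts with the
offending batch named.

**Tiled inference** covers the volume with overlapping tiles blended by a
separable raised-cosine window ramping across the overlap margins (floored
at 1e-6 so edge voxels keep support); accumulated weights are normalized to
unity per voxel, so an identity model reproduces its input exactly,
regardless of tiling.

## Evaluation stack

- **SNR**: paired signal/background cubic regions; per pair the signal
  amplitude is the mean difference and the noise power the background
  variance; the estimate is `10·log10(mean(s²)/mean(σ²))` dB. The
  ratio-of-means aggregation (not mean-of-ratios) and the per-pair (not
  pooled) background variance are this package's documented reading of the
  protocol. On the analytic construction (offset 10, unit noise) the
  estimator recovers 20 dB within 0.5 dB at 100 region pairs, and its error
  shrinks with region count.
- **Matching**: greedy, score-descending (ties lexicographic by (z, y, x)),
  each found particle taking its nearest unmatched truth within the
  tolerance (inclusive); deterministic and O(n²) with an explicit distance
  matrix — appropriate for desk-scale lists. Greedy is the field's standard
  for picking evaluation; global optimal assignment is deliberately not
  attempted.
- **PR-AUC**: thresholds sweep the distinct found scores descending; at
  each, matching is recomputed on the retained subset; the area is a
  trapezoid over recall after prepending the zero-recall boundary point. At
  equal recall only the best precision is kept, so trailing false positives
  that add no recall cannot erode the area of a perfect ranking. Precision
  at zero predictions is defined as 1. PR-AUC is invariant to strictly
  monotone score transforms.
- **F1 vs Z-score**: scores standardized against a caller-supplied score
  population (typically all map voxels), F1 evaluated on a uniform Z grid
  spanning the found scores; affine-invariant by construction.
- **Template matching**: masked zero-mean NCC via FFT cross-correlations
  with local mean/variance correction; scores clipped to [−1, 1] only to
  absorb float error (the clamp magnitude is recorded). The score percentile
  for peak extraction is computed over valid voxels only — border voxels
  never hold full-template scores and would bias the threshold. Peak
  positions are voxel-resolution local maxima (no subvoxel refinement), so
  distance metrics inherit ±0.5-voxel quantization. Defaults: 99.5th
  percentile, minimum separation of a template radius.

## The synthetic benchmark: what it does and does not show

The standard study (`experiments.simulate_split_study`) is a 64³ phantom of
12 non-overlapping unit-density spheres of radius 5, projected over −60°…
+60° in 3° steps (41 tilts), with Gaussian noise at 30% of the clean
projection standard deviation, T2T-split and FBP-reconstructed. Problem
sizes (200 pairs of 32³ subvolumes, ≤10 epochs, an 8-layer width-1 MS-D)
were chosen so a full train/denoise/evaluate cycle completes in about a
minute on one CPU core while still showing a clear Noise2Noise effect: the
denoised volume's voxel-MSE against the hidden phantom drops below the
noisy reconstruction's in the large majority of seeds.

What the synthetic data does **not** emulate: contrast transfer functions,
dose weighting and radiation damage, sample drift and alignment error,
structured cellular background, or the spatial correlation of real
detector noise. Passing tests therefore demonstrate the correctness of the
operators and the reality of the Noise2Noise mechanism under the stated
model — not performance on experimental tomograms. Quantities that depend
on real data (absolute SNR values of cellular tomograms, subtomogram-
averaging resolutions, PR-AUC of template matching against curated ground
truth) are out of scope here; the package provides the instruments, not
those numbers.

The loss-comparison harness trains the same backbone under L2 and FSC
losses on identical data and seeds and reports per-shell FSC-to-truth
curves for both. It deliberately asserts nothing about which loss wins at
which frequency: that outcome is data-dependent, and the harness exists to
surface it, not to judge it.

## Numerical details and edge cases

- FSC shells have width one Fourier voxel by default (1/n cycles/voxel);
  a voxel at radius r belongs to shell ⌊r/width⌋ with exact boundaries
  assigned to the lower shell; voxels beyond 0.5 cycles/voxel (cube
  corners) are excluded. Shell centers are reported as lower edges from 0.
- Threshold resolution interpolates linearly between adjacent shells; a
  curve that never crosses returns the Nyquist resolution (2× voxel size)
  with a flag rather than an error.
- Volume rotations fill from-outside voxels with the volume mean (not
  zero) to avoid dark-corner bias in training losses; rotations that are
  exact signed axis permutations take an exact permutation path.
- `apply_wedge` verifies that the imaginary residue after filtering is
  below 1e-5 of the data range (it must be, for a Hermitian mask) and then
  discards it.
- All stochastic operations take explicit integer seeds and are
  reproducible bit-for-bit on a fixed platform; nothing reads global RNG
  state.

## Known limitations

- The projector/back-projector pair leaves a few percent of Fourier energy
  inside the nominally unmeasured wedge (interpolation sidelobes); studies
  needing a mathematically exact wedge null should impose the wedge mask
  explicitly.
- No CTF, no dose weighting, no motion: the simulator models geometry and
  noise, not the full image-formation physics.
- Orientation search in template matching is not implemented (the
  synthetic targets are spheres); the `orientations` parameter is reserved.
- The U-Net at its default width is practical for inference and parameter
  accounting but slow to *train* in pure numpy; the MS-D network is the
  intended training workhorse at desk scale.
- MRC I/O supports modes 0, 1, 2 and 6 with the standard axis mapping
  (mapc,mapr,maps = 1,2,3); exotic axis orders are rejected rather than
  permuted.
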