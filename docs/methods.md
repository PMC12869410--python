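# Methods

## Density model

A structure is represented as a mixture of N isotropic 3D Gaussians.
Working coordinates are box fractions in [−0.5, 0.5] (+x right, +y up,
+z toward the viewer); widths are box-fraction standard deviations.
The neutral (consensus) mixture is seeded from an atomic model or toy
point cloud by weighted k-means: centers are centroids, amplitudes are
proportional to cluster mass and normalized to mean 1 (so decoder
amplitude gates are comparable across datasets), and all widths start
at `width0` (default 0.02 box ≈ 2.8 Å in the default 140 Å box).
Anisotropic Gaussians are out of scope.

Centers may range to ±0.6 so decoded motion cannot push a valid mixture
out of its own container invariants.

## Image formation

Projection is analytic in Fourier space.  After rotating centers into
the lab frame (r_lab = R r_model) and dropping z, each Gaussian
contributes

    a · 2πσ² · exp(−2π²σ²|k|²) · exp(−2πi k·(c_xy + s)),

with k in cycles/box and phases referenced to the box center; the
`fourier_to_image` pair makes this exactly consistent with rfft2 of
real-space images.  The CTF uses the underfocus-positive convention
CTF(k) = −(√(1−A²) sin χ + A cos χ)·exp(−B k²/4) with the standard
defocus/Cs phase polynomial χ; the same function serves the simulator
and the training loss, so the conventions cannot drift apart.
Astigmatism is not modelled (defocus U = V).

## Loss

Negative mean Fourier-ring correlation over integer-radius rings up to
`max_freq` (default box/3 cycles/box; motion experiments use 0.42·box —
see below).  Rings are weighted uniformly; an all-zero ring contributes
zero.  The loss is invariant to any per-ring positive rescaling of
either argument, which makes it robust to the CTF envelope and to
global scale, at the cost of being blind to global amplitude drift (the
per-Gaussian *relative* amplitudes still matter).  A per-ring SNR
weighting would be a natural refinement and is deliberately not
implemented; uniform weighting keeps the objective assumption-free.

## Networks

* **Encoder** (deliberately plain, shared by both decoders): particle
  Fourier coefficients below `enc_cutoff` (default box/4 cycles/box),
  phase-flipped by the sign of that particle's CTF, real/imaginary
  concatenated, per-particle standardized → 3×256 MLP → d-dim latent
  (default d = 4; the desk-scale compositional recipes use d = 8 to
  give the 8 independent binary factors room).
* **Point Transformer decoder**: point hierarchy of k-means centroids
  (64/256/N by default; the last level is the neutral centers), kNN
  tables with k_attn = 16 including self, and 3-NN inverse-distance
  interpolation tables, all precomputed once.  Per level: vector
  self-attention with a two-layer position-encoding MLP θ on fixed
  relative positions, channel-wise softmax over neighbors after the
  two-layer γ MLP, residual connection; transition-up between levels
  with a linear channel projection; residual branches (32 channels,
  linear) from the intermediate levels straight to the full point set;
  concatenation → pointwise affine head → 5 channels per Gaussian.
  Channel widths default to 256/128/64 per level; the desk-scale
  configs use 64/48/32 with levels 16/64/N, a size at which the full
  training loop runs in minutes on one CPU while preserving every
  architectural element.  The head is zero-initialized, so an untrained
  decoder is exactly the identity: the training trajectory starts at
  the consensus structure.
* **Output activations** (bounded so early training cannot explode):
  Δcenter = 0.1·tanh(·) box units; amplitude gate = 2·sigmoid(·)
  (neutral at 1, floor 0 = segment absent); width factor =
  exp(0.5·tanh(·)).  Scales are configurable.
* **MLP baseline**: latent → 3×256 MLP → N×5 head with the identical
  output activations, so decoder comparisons isolate the architecture.

All networks run on the package's numpy reverse-mode autodiff engine
(`ptgmm.autodiff`); fused primitives with hand-written adjoints cover
the two hot paths (neighbor gathers, the batched Gaussian projection)
and are finite-difference-checked in the test suite.

## Training

Adam (lr 1e-3 default, cosine decay), batch 32–64, single seed driving
weight init and shuffling; training is bit-reproducible on one CPU.
Two refinements exist for experiments whose heterogeneity class is
known:

* `channels` = "amplitude" | "position" restricts the loss to one
  delta channel, holding the others neutral.  Motion experiments train
  position-only: with free amplitude channels, per-particle density
  redistribution can masquerade as motion and contaminates the
  recovered displacements.
* `motion_l2` adds a small L2 penalty on Δcenter (default 0 in
  general, 0.7 in the motion recipe) to suppress sub-resolution jitter
  of static regions that the band-limited loss cannot see.

Motion experiments also raise the loss cutoff to 0.42·box cycles/box,
since Å-scale rigid shifts live near the resolution limit, and use a
finer atom splat (3 Å) so signal survives at those frequencies.

## Synthetic data

The toy structure is a large central core blob plus K−1 compact blobs
on a spherical shell (golden-spiral placement, pairwise centroid
separation ≥ 3 blob radii enforced), standing in for a segmented large
complex; default 140 Å box.

* **Compositional**: each non-core segment independently present with
  probability 1−p per particle (default p = 0.5).  With 9 segments the
  state space is 2⁸ = 256; at 12,800 particles the probability of any
  state being unobserved is below 10⁻¹⁸.
* **Conformational**: chosen segments rigidly rotated about fixed axes
  by independent Uniform(−range/2, +range/2) angles.  Axes are hinged
  at each segment's core-facing edge (a domain tilts about its
  attachment point, so displacement grows with distance from the
  hinge); the default 47° range calibrates the default 4-segment
  recipe's mean per-particle atomic RMSD to ≈ 2.2 Å, the magnitude
  regime of real domain-tilting datasets.

Rendering: per-atom Gaussian splat (default σ = 4.5 Å compositional /
3 Å motion) projected analytically, CTF with defocus ~ Uniform(1, 2) µm
at 300 kV, white Gaussian noise scaled so signal-variance /
noise-variance equals the requested SNR (default 0.1; the desk-scale
training recipes use 1–8).  Orientations come from a scrambled-Halton
low-discrepancy sequence on the rotation group ("evenly distributed"
rather than i.i.d.), and are supplied to the model as known poses.

What the simulator does **not** emulate: colored/structured noise, ice
gradients, beam-induced motion, detector MTF, pose errors, non-rigid
intra-segment flexibility.  Passing tests on these data show the
method's machinery is correct and that it resolves the stated
heterogeneity classes under known poses and white noise; they do not
demonstrate robustness to pose error or realistic noise spectra.

## Interpretability workflow

Per-Gaussian feature rows are the amplitude gate (or |Δcenter|) across
a ≤ 2,000-particle subsample, z-scored per row (zero-variance rows are
left at zero).  UMAP (15 neighbors, min_dist 0.1, seeded **random**
init — the default spectral initialization is not run-to-run
reproducible on the disconnected neighbor graphs these matrices
produce, and seeded reproducibility is part of this module's contract)
embeds the rows in 2D; DBSCAN clusters them with eps chosen at the knee
of the 4-NN distance curve (fixed-quantile fallback).  Regions are
matched to true segments by majority label with coverage: a segment
counts as separated when the regions whose majority label is that
segment jointly contain > 50 % of its Gaussians — a segment split into
pure sub-clusters is still separated; two segments merged into one
cluster are not.

Region-focused particle embedding restricts the feature vector to one
region's Gaussians before UMAP + k-means; class ids are relabelled by
descending class size for stability.  Class-difference volumes render
the mean decoded mixture of each class on a voxel grid and subtract;
direct particle backprojection is intentionally not the default path.

## Evaluation

* **Amplitude accuracy**: a Gaussian is called present when its gate
  ≥ 0.5 (the gate is 1 at neutral, so 0.5 is the natural midpoint);
  accuracy pools all (particle, Gaussian) pairs of toggleable segments
  (core Gaussians have constant truth and are excluded by default;
  both pooling modes are available).
* **Motion RMSD**: each atom inherits the Δcenter of its nearest
  Gaussian (Å); RMSD per particle over all atoms; the zero-motion
  baseline equals the true movement magnitude.  Nearest-single-Gaussian
  transfer is the default; its discretization floor depends on the
  Gaussian density (at 224 Gaussians on the single-region toy the
  oracle floor is ≈ 0.1× baseline).

## Problem sizes

The bundled desk-scale recipes are sized for minutes on a single CPU
core, the package's reference execution environment: the compositional
benchmark uses 2,000 particles, a 48-pixel box, 256 Gaussians, a
16/64/256 hierarchy with 64/48/32 channels, and 10 epochs; the
single-region motion benchmark uses 600 particles, 224 Gaussians, 32
epochs.  The full-size architecture (1,024 Gaussians, 64/256/1024,
256/128/64 channels) is exercised structurally in the tests and is the
configuration the larger published-scale experiments would use; at that
scale training takes hours and is not part of the default suite.

## Numerical notes

* float32 throughout the networks; float64 in geometry/metrics.
* k-means uses 10 restarts with a fixed seed; ties broken by lowest
  inertia (scikit-learn semantics).
* Nearest-atom assignment breaks exact ties toward the lowest atom
  index.
* Interpolation weights guard coincident points (weight → 1 exactly).
* The FRC denominator is exact with a zero-ring guard in the metric
  path; the differentiable training path adds ε = 1e-8 for gradient
  stability.
* All stochastic steps (simulation, init, shuffling, embedding,
  clustering) derive from explicit integer seeds; reruns are
  bit-identical on one CPU.

## Known limitations

* Poses are inputs; no pose refinement.
* Isotropic single-σ Gaussians; no anisotropy, no astigmatism.
* Uniform FRC ring weights (no SNR weighting).
* The amplitude-vs-motion degeneracy is resolved by channel
  restriction only when the heterogeneity class is declared; "all"
  mode can mix the two explanations on continuous-motion data.
* UMAP/DBSCAN hyperparameters are defaults with a data-driven eps;
  heavily fragmented regions are handled by the coverage-based
  matching, but pathological feature matrices can still over-merge.
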