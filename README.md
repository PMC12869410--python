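# ptgmm

Structural-heterogeneity analysis for cryo-EM particle images with a
Gaussian-mixture density model and a **Point Transformer decoder**.

A protein map is represented as a mixture of N isotropic 3D Gaussians
(centers **c**ᵢ, amplitudes aᵢ, widths σᵢ).  An encoder–decoder pair is
trained unsupervised against the particle images: the encoder maps each
(CTF-phase-flipped, band-limited) particle to a low-dimensional latent
conformation code **z**, and the decoder maps **z** to per-Gaussian
deltas (Δ**c**ᵢ, Δaᵢ, Δσᵢ) of the consensus ("neutral") mixture.  The
training loss is the negative Fourier-ring correlation between the
CTF-modulated analytic projection of the decoded per-particle mixture
and the observed particle:

    L = − mean over rings r of  Re⟨P_r, O_r⟩ / (‖P_r‖ ‖O_r‖)

The decoder is the interesting part: an **upsampling Point Transformer**
over a precomputed k-means hierarchy of the neutral mixture
(64 → 256 → N points by default).  Each level runs vector self-attention
over k-nearest neighbors with a learned relative-position encoding,

    yᵢ = Σ_{j∈N(i)} softmax_j( γ(φ(xᵢ) − ψ(xⱼ) + δᵢⱼ) ) ⊙ (α(xⱼ) + δᵢⱼ),
    δᵢⱼ = θ(pᵢ − pⱼ),

followed by inverse-distance transition-up between levels; the first two
levels also feed residual branches straight to the full point set.  A
plain MLP decoder with identical output channels is kept as the
comparison baseline.

Because every Gaussian has an amplitude and a position per particle, the
decoder output is directly interpretable.  The package includes the
divide-and-conquer workflow built on that: embed all Gaussians by their
output profiles across particles (UMAP), cluster into regions of
correlated dynamics (DBSCAN), then re-embed the *particles* using only
one region's outputs and classify (k-means) — isolating one structural
degree of freedom at a time — and render class-difference volumes.

Simulators for the two canonical heterogeneity classes are first-class
citizens: **compositional** (segments independently present/absent per
particle, ribosome-assembly style) and **conformational** (rigid domains
tilting about hinge axes by uniform random angles, transporter style),
rendered as CTF-modulated noisy projections with quasi-evenly
distributed known orientations, with full ground truth for scoring.

## Worked example

Simulate a 9-segment toy complex in which each of the 8 peripheral
segments is independently absent in half the particles (so the ensemble
spans 2⁸ = 256 compositional states), train the Point Transformer
model, and score it against the ground truth:

```python
from ptgmm.workflows import run_compositional_experiment

res = run_compositional_experiment(seed=1, epochs=10, batch_size=32)
print("states:", res["n_states"])
print("accuracy:", round(res["accuracy"], 4))
print("regions recovered:", res["n_regions_recovered"])
```

On one CPU this takes about six minutes and prints

```
states: 256
accuracy: 0.9338
regions recovered: 8
```

meaning: the simulated set realized all 256 compositional states; after
unsupervised training, thresholding the per-Gaussian amplitude gate at
0.5 calls presence/absence of the corresponding segment correctly for
93.4 % of (particle, Gaussian) pairs; and UMAP + DBSCAN on the
per-Gaussian amplitude profiles separates all 8 independently toggled
segments without manual intervention.

The same pipeline is available from a shell:

```
ptgmm simulate-comp --n-segments 9 --n-particles 2000 --seed 1 --out-dir run/
ptgmm train   --stack run/particles.mrcs --star run/particles.star \
              --structure run/structure.tsv --epochs 10 --seed 1 --out run/model.npz
ptgmm infer   --checkpoint run/model.npz --stack run/particles.mrcs \
              --star run/particles.star --out run/outputs.npz
ptgmm evaluate --outputs run/outputs.npz --checkpoint run/model.npz \
              --structure run/structure.tsv --ground-truth run/ground_truth.tsv \
              --out run/metrics.json
ptgmm segment-gmm --outputs run/outputs.npz --seed 1 --out run/regions.tsv
ptgmm focus   --outputs run/outputs.npz --regions run/regions.tsv --region 1 \
              --k 2 --seed 1 --out run/classes.tsv
ptgmm diffmap --outputs run/outputs.npz --classes run/classes.tsv \
              --checkpoint run/model.npz --out run/diff.mrc
```

Every command takes `--seed` and writes a provenance JSON; re-running a
command with the same seed reproduces its outputs bit-identically on
one CPU.

## File formats and conventions (normative)

* **Images**: MRC2014 mode-2 stacks (`.mrcs`), little-endian.
* **Metadata**: STAR table with RELION-style columns; orientations are
  intrinsic ZYZ Euler angles (rot, tilt, psi) in degrees, mapping model
  coordinates into the lab frame whose +z axis is the projection
  direction.
* **Fourier layout**: rfft2 half-plane, DC at (0, 0), frequencies in
  cycles/box, phases referenced to the box center.
* **CTF**: underfocus positive, CTF(k) = −(√(1−A²) sin χ + A cos χ)·env,
  shared bit-for-bit between the simulator and the training loss.
* **Coordinates**: box-normalized model coordinates in [−0.5, 0.5],
  +x right, +y up, +z toward the viewer.

See `docs/methods.md` for the model, training procedure, simulation
conditions and their limitations.

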