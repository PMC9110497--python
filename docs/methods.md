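# Methods

## Problem and model

Surgical smoke removal is cast as unpaired translation between a clear
domain X and a hazy domain Y.  Two residual generators are learned jointly —
G : X→Y and F : Y→X — against two patch discriminators, with the combined
objective

    L = L_GAN + λ_cyc·L_cyc + α·L_IC + β·L_DC,   λ_cyc = 10, α = 3, β = 0.05.

The adversarial terms use the least-squares form (mean squared deviation of
the patch-score grid from 1 for real targets, 0 for fakes); the log-form
objective is available separately for analysis.  L_cyc is the symmetric L1
reconstruction penalty.  The two smoke-specific terms are evaluated **only on
generator outputs** and therefore steer only the generator update: although
they are bookkept alongside the discriminators' domains, a term that never
sees a real image has no discriminator gradient, so applying them in the
generator step is the only reading that does anything.

### Inter-channel term

For a pixel P in unit range, Ψ(P) = |P_R−P_G| + |P_G−P_B| + |P_B−P_R| ∈
[0,2]; dense gray smoke collapses Ψ toward 0.  The per-image mean is
normalised by 2 into [0,1] (the normalisation constant is the package's
choice; it keeps the term on the cycle loss's scale before α = 3 is
applied) and passed through a boundary map with pivot 1: generated clear
frames are penalised by |v−1| (pushing chroma up), generated hazy frames by
1−|v−1| (pushing toward grayness).

### Dark-channel term

The dark channel is the k×k patchwise minimum over space and channels,
window clamped at the border (clamping avoids the artificial dark frame
that zero padding would create).  Aggregation is a rank-based trimmed mean
with 1% per tail: bright speculars and dead-dark pixels are discarded
without biasing the bulk.  Patch size defaults: 15 for full-resolution
evaluation (the dehazing-literature standard), 7 inside the training loss
where crops are small and locality keeps the gradient cheap.  Both ends are
configurable.

Soft-matting refinement solves (L + ε·E)t = ε·t_raw with L the matting
Laplacian of the colour image (3×3 windows, window regulariser 1e-4), data
weight ε = 1e-4, by conjugate gradients to relative residual 1e-6.
Constants lie in L's null space, so constant maps are exact fixed points and
large ε returns the raw map.  Refinement is off inside gradient steps (a
sparse solve per batch is disproportionate) and on for reported dark
channels and the fog proxy.

The loss keeps the dark-channel penalty on G(x) — the generated *hazy*
image — as well as on F(y); a config switch (`dc_include_hazy_term`) allows
ablating it, since penalising the dark channel of an image that is supposed
to contain smoke is a defensible thing to question.

## Networks and optimisation

Generator: reflect-padded 7×7 stem → two stride-2 3×3 convolutions → n
residual blocks (two reflect-padded 3×3 convolutions each) → two
nearest-upsample + 3×3 convolutions → 7×7 tanh head; instance normalisation
without learnable affine; weights ~ N(0, 0.02).  Nearest-upsample + conv
replaces transposed convolution: it is checkerboard-free and has a simple
exact adjoint.  Defaults (9 blocks, base width 64) give 11,378,179
parameters.  Discriminator: n stride-2 4×4 convolutions then two stride-1
4×4 convolutions to a 1-channel patch-score grid; the default 3-layer spec
has a 70×70 receptive field and maps 256×256 → 30×30 scores.

Everything runs on a purpose-built numpy reverse-mode autograd engine
(`desmoke.nn`): convolution via im2col/GEMM, argmin-routed gradients for the
channel/patch minima and the trimmed mean, instance-norm and reflection-pad
adjoints.  Every op is finite-difference checked in the test suite.

Optimisation: Adam (0.5, 0.999), lr 0.002 constant for the first 50 epochs
then linearly to 0 over the next 50 (lr(e) = lr0·(100−e)/50 for e ≥ 50 —
continuous at the boundary, exactly 0 after the final epoch), batch 4,
random 256×256 crops, a 50-image history pool per discriminator.  The lr is
an order of magnitude above the common backbone default; it is implemented
as specified and overridable.  One step = one joint G/F update followed by
one update per discriminator (half-weighted real/fake least squares against
pooled fakes).

## Synthetic data

The simulator emulates the study conditions rather than any particular
recording.  Clear frames are procedural phantoms: multi-octave value noise
mapped into a reddish tissue gamut with correlated channels, specular spots
and a corner vignette — giving trimmed-mean dark channels below 0.2 and
inter-channel discrepancies well above smoke level.  Smoke follows the
atmospheric scattering model I = J·t + A·(1−t) with near-white A =
(0.96, 0.96, 0.98) and t = exp(−density·n(x)), n a smooth log-normal field
of unit mean so −mean(log t) equals the requested density.  Grade densities
are light 0.3, medium 0.8, heavy 1.8 (chosen once for clear separation of
the grade means; recorded in every manifest).  Partial smoke masks t to a
quantile region of a smooth field, so the covered area equals the requested
fraction exactly with contour-shaped boundaries.  Hazy frames are built from
*different* phantoms than the clear domain, preserving the unpaired
assumption.

What the simulator does **not** reproduce: instrument and tissue geometry,
motion blur, interlaced video artefacts, colour calibration of real
endoscopes, temporally coherent smoke.  Passing tests therefore demonstrate
the mechanics and the relative behaviour of the losses, not clinical-grade
desmoking.

## Metrics

* **REA**: visible edges are luminance-gradient pixels (3×3 Sobel, Rec. 601
  luminance) exceeding 5% of the local mean luminance (11×11 window);
  REA = (n_restored − n_original)/n_original.  An edgeless original is a
  distinct error (undefined ratio).
* **JNBM**: 64×64 blocks are edge blocks when >0.2% of pixels are edge
  pixels (|horizontal Sobel| > 10% of full scale); per edge pixel the edge
  width is the span between the neighbouring luminance extrema along its
  row; widths are pooled as (Σ|w/w_JNB|^3.6)^(1/3.6) within and across
  blocks with w_JNB = 5 for block contrast ≤ 50 (8-bit) else 3; the score is
  (number of edge blocks)/(pooled distortion).  An image with no edge blocks
  returns 0 with a warning so batch evaluation never aborts.
* **Fog proxy**: trimmed mean of the matting-refined dark channel.  The
  published fog-density evaluator requires a corpus-trained natural-scene-
  statistics model, which is out of scope; the proxy tracks the same
  physical signal (scattered light lifting all channels) and is labelled
  `fog_proxy` in every output so it can never be mistaken for the published
  score.

## Desk-scale experiment

The shipped experiment (`desmoke.experiments`) uses 80 images per domain at
64×64, 10 epochs (5 constant + 5 decay), generator base width 8 with 2
residual blocks, and a 2-layer discriminator — its 34-pixel receptive field
fits a 64×64 frame, which the default 70-pixel field does not.  The full
objective (α = 3, β = 0.05) and a baseline (α = β = 0) are trained on
identical data, initialisation and batch order; the claim tested is
relative: the full model's hazy→clear mapping should lower the trimmed-mean
dark channel of held-out hazy frames below both the inputs and the
baseline's outputs.

## Numerical choices and degenerate inputs

* All loss formulas operate on [0,1] images; networks map [−1,1] internally
  and remap at their boundary (the inter-channel boundary map needs the
  unit scale).
* float32 throughout the engine; reference (numpy/float64) routes exist for
  every loss and are tested for parity at 1e-5.
* Rank ties in minima and trimming resolve by first occurrence (numpy
  argsort/argmin order); gradients route to the selected element only.
* Inputs not divisible by the generator's downsampling factor are
  reflect-padded and cropped back, logged.
* Images with no visible edges: REA raises (undefined), JNBM returns 0 with
  a warning.

## Limitations

* The engine is CPU-only and single-threaded BLAS-bound; full-scale
  (256×256, 100-epoch) training is out of reach — the desk-scale profile is
  the supported regime.
* Absolute metric values on synthetic phantoms are not comparable to values
  reported on real surgical data; only orderings and deltas are meaningful
  here.
* The fog proxy saturates for images whose dark channel is already near 1
  and is blind to smoke that darkens rather than brightens (not a property
  of the scattering model used).
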