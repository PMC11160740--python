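# Methods

`cryofield` reconstructs an ensemble of 3D density maps ab initio from
cryo-EM particle images (or cryo-ET subtilt images), estimating per-particle
poses and conformational embeddings jointly with the map.  This note records
the model, the numerical conventions, the synthetic study design, and the
design decisions taken where more than one reasonable choice existed.

## Image formation model

A particle image is modeled as

    I_i = C_i * P_{φ_i} V(z_i) + η_i

with CTF `C_i`, orthographic projection `P_φ` at pose φ = (R, t) ∈
SO(3) × R², conformation-conditional volume `V(z)`, and white Gaussian
noise η.  All computation is carried out in Hartley space, where the model
becomes

    H(I_i) = Ĉ_i ⊙ T_{t_i} S_{R_i} V̂(z_i) + η̂_i ,

`S_R` sampling the rotated central plane of V̂ (Fourier slice theorem) and
`T_t` the real-valued Hartley translation operator

    (T_t H)(k) = cos(2π t·k) H(k) + sin(2π t·k) H(−k).

Conventions:

* The discrete Hartley transform is unitary (`H = Re F − Im F` with the
  orthonormal centered DFT), hence an involution.  Under this normalization
  the slice theorem carries a factor √D, which is applied in the
  observation/loss pipeline so that the slicing operator itself remains a
  pure central-plane lookup.
* Frequency lattices are centered with coordinates in cycles/pixel,
  [−0.5, 0.5).  The −k partner of a lattice point is its index negation
  mod D (the periodic extension of the grid); the Nyquist row/column are
  their own partners.  Consequently `T_t` is an exact isometry on the open
  sub-Nyquist disk and exact everywhere for integer shifts; fractional
  shifts perturb only the self-paired Nyquist lines, which the training
  loss excludes (residuals are restricted to |k| < D/2, corners and the
  Nyquist ring left out).
* Rotations act on frequency coordinates as k ↦ R·k; translations by t
  move image content by +t pixels.  The viewing direction of a pose is
  R·ẑ (third column), which is invariant under the in-plane spin
  R ↦ R·Rz(ψ) — the invariance the out-of-plane/in-plane error
  decomposition relies on.
* Gridded Hartley volumes are sliced by cubic B-spline interpolation with a
  cached prefilter.  Plain trilinear lookup leaves ~10 % relative L2 error
  against the real-space projection oracle at D = 32 (Hartley volumes of
  compact bodies are sharply peaked near DC); cubic interpolation brings
  the slice-theorem discrepancy to ~1.3 %, of which roughly half is the
  projection oracle's own resampling error.

## CTF and tomography weighting

The paper-silent CTF functional form follows the CTFFIND convention,

    C(k) = −(√(1−w²) sin γ + w cos γ),
    γ = π λ Δz(α)|k|² − (π/2) Cs λ³ |k|⁴ + φ_shift,

with astigmatic defocus Δz(α) and an optional B-factor envelope
exp(−B|k|²/4).  At k = 0 the value is −w.

Subtilt images multiply the CTF by cos(tilt angle) (sample-thickness SNR
loss) and by the cumulative-dose attenuation exp(−d / 2N_e(k)) with the
standard critical-exposure curve N_e(k) = 0.245 k^−1.665 + 2.81 (k in Å⁻¹,
dose in e⁻/Å²).

## Volume representation

V̂_θ(z, ·) is a coordinate MLP: the frequency k ∈ [−0.5, 0.5]³ is expanded
in 64 Gaussian Fourier features (B ∈ R^{64×3}, entries N(0, 0.5²), fixed
after initialization), concatenated with the latent z ∈ R^d (d = 8 by
default) and passed through three width-256 residual blocks
(y = ReLU(x + W_b ReLU(W_a x))) and a final linear map to one scalar.
Weights use the uniform ±1/√fan_in initialization.

Two implementation decisions matter:

* **Feature bandwidth.** The base frequencies are interpreted relative to
  the Fourier lattice of the data: queries are scaled by D/4 before the
  sinusoid, giving an effective bandwidth of 0.125 cycles per lattice
  cell.  Without the scale (phases < 1 rad across the whole domain) the
  basis cannot represent a D = 32 Hartley volume at all; with a full
  0.5 cycles/cell the field oscillates near the Nyquist rate of the
  rasterized copy used by the pose search, and interpolated slices diverge
  from direct evaluation.  0.125 cycles/cell is the measured compromise
  (volume-fit MSE ratio ≈ 190×, slice consistency ≈ 6 %, sub-degree
  planted-pose recovery through the rasterized path).
* **Gradients** for θ, z, the frequency coordinates (for pose gradients)
  and the in-plane shift are all derived by hand and verified against
  finite differences in the test-suite; the whole network runs in float32
  numpy.

Latents are per-particle rows of a table, drawn from N(0, 0.1²) at
initialization and optimized directly (autodecoder); there is no image
encoder.

## Pose estimation

**Hierarchical search.** The base grid is the Hopf-fibration product of the
nside-4 nested HEALPix sphere grid (192 pixels) with 24 in-plane angles at
15° spacing — 4,608 rotations — times 49 shifts on a 7×7 grid over
[−10, 10] px.  The top 8 rotations are refined five times; each round
scores the 8 children of every kept node (4 HEALPix sub-pixels × 2 spin
half-steps) with the translation grid halved and recentered on the
incumbent shift.  Ties break on (error, node id), making the search
bitwise deterministic.  Images are band-limited at a cutoff ramping
linearly from k_min = 6 to k_max = 16 cycles per image length over the
search phase.

The exhaustive base stage is scored on polar rings (integer radii × 24
angles, quadrature weights matching the lattice density): the 24 spins of
one viewing direction are index-rolls of a single ring sampling, so only
192 planes are interpolated per image, ~25× fewer points than naive
lattice scoring.  Kept nodes are re-scored on the lattice metric so the
base stage and refinement rounds are commensurable; refinement rounds use
the exact masked lattice with cubic interpolation.  When the source is the
neural field, the in-band ball (radius cutoff + 3) is rasterized once per
particle and sliced by interpolation; `reprojection_error` as a public
operation always evaluates exactly.

**Gradient refinement.** After the search phase, poses become free
parameters: rotations via the two-row (6-parameter) representation
orthonormalized by Gram-Schmidt — initialized exactly at the grid solution
— and translations as raw pixel shifts, optimized by Adam together with θ
and z.

## Training schedule

Defaults follow the standard three-phase recipe: pretrain θ for 10,000
image visits with poses drawn once uniformly over SO(3) (translations 0)
and latents frozen (Adam lr 1e-4, batch 32); grid search per batch of 8
with θ (1e-4) and z (1e-2) updates until max(2N, 5×10⁵) visits; then pose
SGD (lr 1e-3, batch 256).  The tilt variant ties subtilts to one particle
pose during search (first 11 tilts), resamples latents from N(0, 0.1²)
per epoch for the first 50,000 particle visits, processes max(2N, 1.5×10⁵)
particles in the search phase, and relaxes to independent subtilt poses in
SGD (lr 1e-5, batch 32).

A single global intensity gain between decoder output and observed images
is fitted by closed-form least squares once at the end of pretrain and
frozen.  (Refitting it every batch lets the decoder scale and the gain
drift in opposite directions — numerically legal, scientifically useless.)

Two additional regimes are first-class:

* **Fixed-pose mode** (`train_spa(..., poses=(R, t))`): the search phase
  keeps the given poses and optimizes only the decoder and latents — the
  standard heterogeneous-training regime when consensus poses are known;
  the SGD phase still refines poses by gradient.
* **Entanglement guard** (`z_delay_images`): for the first part of the
  search phase every particle shares a single zero latent, so the
  conformation space cannot absorb pose errors.  At full scale the sheer
  particle count prevents this degeneracy; at small N the autodecoder can
  otherwise memorize each image in its latent and fit the data with
  arbitrary poses.  (The tilt-series schedule has the analogous built-in
  guard: latents are resampled per epoch early in the search phase.)

**Scaled study design.**  The reference schedules assume ~10⁵–10⁶ image
visits.  The package's own tests and the built-in synthetic studies run at
D = 32 with hundreds of images; for these the phase lengths are shortened,
the field learning rate raised (the number of optimizer steps, not the
number of images, is what the dynamics need), k_max is set proportionally
to the smaller box (8 at D = 32, matching the reference quarter-band), and
the loss sum may be stochastically subsampled over band coordinates
(`freq_subsample`) — an unbiased minibatch over the frequency sum that
roughly triples throughput.  All such settings are explicit `TrainConfig`
fields; the defaults remain the reference values.

## Synthetic data

Ground-truth volumes are Gaussian-mixture phantoms: a fixed, asymmetric
ten-blob body (several length scales inside a radius-0.28 box ball) whose
broadband, asymmetric power spectrum makes projection orientations
identifiable; heterogeneity variants remove a four-blob peripheral
subcomplex (two-state compositional pair) or rotate a three-blob
sub-component about a fixed axis (continuous 1D motion, 50 states at
0.03 rad by default).  Phantoms have closed-form Hartley transforms, used
as oracles in tests.

Single-particle datasets use uniform SO(3) rotations, centered images
(optional uniform shifts), log-normal defocus (median 1.0 µm, σ_log 0.3,
300 kV, Cs 2.7 mm, w 0.07) and additive white Gaussian noise of std 0.5 by
default.  Tilt series use the dose-symmetric scheme (0, +3°, −3°, …) about
the y axis with per-subtilt cos(tilt) and dose weighting.  Every dataset
is bitwise reproducible from its seed.

What the generator does *not* emulate: structural realism of any specific
complex, detector physics (DQE/MTF), ice gradients, per-micrograph noise
correlation, or particle-picking artifacts.  Passing tests therefore
demonstrate the correctness of the estimators on data exactly following
the generative model, not performance on real micrographs.

## Evaluation

* **FSC** with one-pixel shells, DC included, threshold crossings by
  linear interpolation; the per-image variant averages FSC between each
  particle's decoded map and its ground-truth map.
* **Rotation accuracy**: global alignment by scanning the candidate set
  {rᵢ⁻¹Rᵢ} of the first ≤100 particles for the minimizer of the mean
  Frobenius distance, then decomposition into out-of-plane (angle between
  viewing directions) and in-plane (wrapped ZYZ spin difference, with a
  quaternion fallback within 0.1° of the Euler-chart pole).  Because
  projections cannot distinguish a structure from its mirror image, an
  ab initio run lands on either hand; `align_rotations(..., allow_flip=True)`
  also tries the mirrored reference and is what end-to-end evaluations use.
* **Translation accuracy**: the unknown 3D origin shift u* is solved by
  linear least squares from Tᵢ − tᵢ ≈ P rᵢ u (P the 2×3 projector);
  corrected translations tᵢ + P rᵢ u* then minimize the residual, so the
  correction can only reduce the MSE.
* **Quaternion loss** L(q, q′) = 1 − (q·q′)², double-cover invariant.

## Known limitations

* CPU-only: the decoder is a float32 numpy MLP; problem sizes beyond
  D ≈ 64 / 10⁴ images are impractical.
* The ab initio pose bootstrap (random-pose pretrain → grid search) is the
  method's hardest regime at small problem sizes.  With the decoder
  initialized at the true map, the alternating loop is verifiably stable
  (poses snap to sub-degree accuracy and keep improving), and the
  conformation machinery separates states given poses; but from the
  rotational-average initialization the joint dynamics need visit counts
  of the order the reference schedules prescribe (~10⁵) and particle
  counts well above desk scale to break symmetry.  Desk-scale ab initio
  runs on a few hundred particles typically stall in the blurred-average
  optimum; the end-to-end desk study reports this honestly rather than
  masking it.
* Fractional shifts at the Nyquist lines are inherently ambiguous on an
  even grid (excluded from the loss).
* The tilt-series path assumes a single global tilt axis and a rigid
  scheme during search; per-subtilt relaxation happens only in SGD.
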