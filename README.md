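# cryofield

Ab initio heterogeneous reconstruction for cryo-EM single-particle and
cryo-ET subtilt data: one tool that jointly estimates, from particle images
alone, (i) a conformation-conditional 3D density map, (ii) per-particle
poses, and (iii) per-particle conformational embeddings.

It is aimed at structural biologists and methods developers who want a
transparent, dependency-light (numpy/scipy) reference implementation of the
neural-field approach to heterogeneous reconstruction — every transform,
gradient and search step is ordinary, inspectable array code — together
with a synthetic-data generator that makes the whole pipeline testable
without any downloads.

## The model

An image is a random realization of the forward model

    I_i = C_i * P_{φ_i} V(z_i) + η_i ,

with CTF `C_i`, orthographic projection `P_φ` at pose φ = (R, t) ∈
SO(3) × R², and white Gaussian noise η.  The conformational ensemble
V(z) is a coordinate network (64 Gaussian Fourier features → 3 residual
layers of width 256 → scalar) that maps a latent z ∈ R^d and a frequency
k ∈ [−0.5, 0.5]³ to a Hartley coefficient of the map.  Everything is
optimized by minimizing the Hartley-space reconstruction error

    L(θ, {φ_i}, {z_i}) = Σ_i ‖ H(I_i) − Ĉ_i ⊙ T_{t_i} S_{R_i} V̂_θ(z_i) ‖² ,

where `S_R` slices the rotated central plane (Fourier slice theorem) and
`T_t` is the Hartley translation operator.  Poses are estimated in two
stages: exhaustive hierarchical search over a Hopf-fibration grid of
SO(3) × R² (4,608 rotations × 49 shifts at the base level, five top-8
refinement rounds, band-limit ramping from k = 6 to 16 cycles/image),
then stochastic gradient refinement.  Latents are per-particle variables
optimized directly (autodecoder).  Tilt series use the same machinery with
subtilts tied to one particle pose through the known dose-symmetric tilt
scheme, cos(tilt) and cumulative-dose CTF weighting.

See `docs/methods.md` for conventions, defaults and the scaled study
design.

## Worked example

Simulate a two-state synthetic dataset, train, and analyze the latent
space (a deliberately tiny demo schedule; real runs use the defaults):

```sh
$ cryofield simulate --preset spa-2cluster --n 16 --boxsize 32 \
      --noise-std 0.1 --seed 3 --outdir sim
{"preset": "spa-2cluster", "n_images": 16, "D": 32, "pixel_size": 15.08,
 "noise_std": 0.1, "seed": 3}

$ cryofield train --particles sim/particles.mrcs --ctf sim/particles.star \
      --outdir run --dim 4 --seed 0 \
      --pretrain-images 128 --hps-images 32 --sgd-images 32
{"images_processed": 192, "gain": 0.06641936568818911}

$ cryofield analyze --run run --kmeans 2 --boxsize 32 --seed 0
{"k": 2, "cluster_sizes": [7, 9],
 "explained_variance_ratio": [0.3942305974302194, 0.2783068068215893],
 "maps": ["run/analysis/map_000.mrc", "run/analysis/map_001.mrc"]}
```

`simulate` writes the particle stack (MRCS + STAR) plus full ground truth
(poses, state labels, per-state maps).  `train` reports how many image
visits were processed and the fitted global intensity gain between the
decoder and the data; it writes checkpoints, a `poses.star` table, the
latent array and a consensus map.  `analyze` clusters the latents
(cluster sizes shown), reports the PCA variance spectrum, and decodes one
map per cluster centroid.  Comparing the two ground-truth state maps:

```sh
$ cryofield fsc sim/state_000.mrc sim/state_001.mrc
{"pixel_size": 15.08, "resolution_0.5": 16.0, "resolution_0.143": 16.0}
```

— the states share most of their mass, so their FSC never drops below 0.5
within the band (crossings are reported in shells; 16 = Nyquist at D = 32).

`eval-poses` compares two pose tables (global alignment, out-of-plane /
in-plane split, optimal 3D origin shift), and `train-tilt` runs the
subtomogram-averaging variant.

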