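# Methods

## Model overview

The package implements an ideal-observer analysis of glint-based binaural
localization for CF echolocation. Its moving parts:

1. **Hypothesis space** (`glintloc.directions`). Candidate target
   directions form a deterministic Fibonacci-spiral grid on the frontal
   hemisphere: the forward direction-cosine is stratified uniformly on
   (0, 1) (equal-area by Archimedes' projection) and successive points
   advance by the golden angle. The grid is exact in count, deterministic,
   and its nearest-neighbour spacing has a coefficient of variation ≈0.01
   (the quality gate is <0.25). All spatial outputs use the Lambert
   azimuthal equal-area projection centred on the midline, so solid angle
   maps to planar area.

2. **Directivity and pinna motion** (`glintloc.ahrtf`). The emission and
   ear patterns are circular Gaussian lobes in off-axis angle,
   −3(ψ/ψ_hp)² dB with ψ_hp half the half-power beamwidth, optionally with
   a raised side lobe (two lobes combine by maximum). Pinna movement is a
   rigid rotation of the ear pattern along a linear arc, by default from
   (−15°, −15°) to (+15°, +15°) in (azimuth, elevation) for the right ear
   and mirrored for the left, so the ears sweep elevation in anti-phase.
   The emission pattern does not move. Measured or externally simulated
   directivity grids load from CSV and are interpolated linearly on the
   Lambert plane with nearest-node fallback.

3. **Templates and glint sampling** (`glintloc.templates`). The expected
   level at stroke position j toward direction θ is emission gain plus
   rotated-ear gain; each direction's 2×N_pos matrix is shifted to zero
   mean so that the echo-strength nuisance parameter carries all absolute
   level. One full ear stroke spans one call duration. Glint times are
   t₀ + i/f with phase t₀ ~ U(0, 0.5/f) (or, in random mode, the same
   number of times drawn uniformly over the call), and templates are
   sampled at those times by linear interpolation in dB between stroke
   positions.

4. **Noise** (`glintloc.noise`). The 2k-sample level vector has
   covariance σ² on the diagonal, ρσ² between simultaneous left/right
   samples, zero elsewhere; system noise acts as a detection floor via an
   elementwise maximum.

5. **Inference** (`glintloc.inference`). Gaussian log likelihood about
   the floor-censored mean, uniform discrete marginalization over echo
   strength, Bayes over directions, Shannon entropy in bits with
   0·log 0 = 0. All aggregation is in log space (log-sum-exp). Mean
   entropy per (direction, flutter, strength) cell is a Monte-Carlo
   average over measurement realizations.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| grid size | 500 (full runs 3252) | number of candidate directions |
| call duration | 50 ms | CF call length; one ear stroke spans it |
| flutter rates | 20–200 Hz | wingbeat rates; k = f·D glints per call |
| σ (low / mid / high) | 1.5 / 3.0 / 6.0 dB | per-sample level SD for the dominant-glint, intermediate and whole-echo channels |
| ρ (left/right) | 0.9 | correlation of simultaneous binaural samples |
| detection floor | 0 dB | censoring level; makes A an SNR |
| echo strengths A | 0–70 dB, 10 dB steps (desk scale) | nuisance grid; also the evaluated true strengths |
| realizations | 20 | Monte-Carlo draws per cell |
| N_pos | 100 | stroke positions per template |
| beamwidths | 60° emission and ears | half-power widths of the synthetic lobes |
| ear boresights | ±20° azimuth, +10° elevation | binaural disparity source |
| pinna arc | ±15° azimuth and elevation | rigid-rotation sweep |

The three σ levels model, respectively, the amplitude stability of
dominant glints, an intermediate channel, and a frequency channel driven
by the whole echo. The exact numerical values are package choices within
the qualitative three-level design; they are fully configurable, and every
comparative experiment takes its σ values from the configuration.

## What the synthetic generator does and does not emulate

The Gaussian-lobe patterns reproduce the gross features that drive the
analysis — a smooth single main lobe at ~75 kHz, peak normalization,
binaural disparity from offset boresights, smooth low-frequency template
modulation under the pinna sweep. They do **not** reproduce the fine
structure of a real head's directionality: multi-lobed interference
patterns, frequency-dependent notches, or left/right asymmetries beyond
mirroring. Consequently, quantities that depend on the fine structure of
the real templates — the exact 90%-performance crossover rates, the
absolute central entropy at a given flutter rate, the exact channel
crossover — are *not* expected to match published values for any
particular species; the package reports its own values for whatever
directivity it is given. Qualitative orderings (entropy decreasing in
flutter rate and echo strength, robustness of the low-noise channel to
sampling, the central low-entropy region expanding with strength, the
high-noise centre/periphery contrast flip) are preserved at desk scale
and are what the test suite asserts.

Two synthetic-template behaviours deserve explicit mention:

* **Channel comparison.** With iid noise across stroke positions, channel
  information scales like (samples per ear)/σ². At the defaults
  (N_pos = 100, σ = 1.5 vs 6.0 dB) the whole-echo channel carries
  100/36 ≈ 2.8 effective units against 3/2.25 ≈ 1.3 for the 60 Hz sampled
  channel, so the sampled channel only overtakes it above ~130 Hz. A
  dominant-glint advantage down to 60 Hz requires either a larger σ ratio
  or temporally correlated whole-echo noise (fewer effective samples);
  both are configurable, neither is the default.
* **Random glint spacing.** Uniformly random sample times can cluster and
  leave parts of the stroke unsampled; at 100 Hz this costs ≈0.1 bit
  relative to regular spacing on the default templates (the modes agree
  at 200 Hz). The effect is systematic, not Monte-Carlo noise.

## Numerical choices

* **Likelihood under censoring**: the floor enters as a censored *mean*
  inside an ordinary Gaussian density (not a Tobit-style censored
  likelihood); this matches the model's definition of the expected value
  and keeps the density proper.
* **Marginalization**: discrete uniform average over the strength grid,
  computed by log-sum-exp; the grid defaults to the same strengths the
  experiment evaluates.
* **Vectorized evaluation**: per realization, all (direction, strength)
  hypothesis means are whitened once through the Cholesky factor of Σ and
  all measurements scored by a single matrix product; the per-measurement
  path and the batched path agree to 1e-8 bits and both are under test.
* **Zero-noise limit**: σ = 0 degenerates to exact matching (entropy =
  log₂ of the number of exactly matching directions), computed with
  direct residuals to avoid cancellation.
* **Underflow**: if every direction's marginal likelihood underflows to
  zero, the posterior falls back to uniform with a logged warning.
* **Tie-breaks and degenerate inputs**: single-point grids and
  single-position trajectories are handled as their natural limits
  (on-axis direction; stationary ear at the arc midpoint); a call shorter
  than half a flutter period still yields one glint.
* **Seeding**: every random stream derives from the root seed through a
  `SeedSequence` keyed by (purpose, mode, flutter rate, realization), so
  any cell of a large run is reproducible in isolation and whole runs are
  bit-identical given (config, seed). Within one realization the glint
  phase is shared across directions and strengths (phases remain
  independent across realizations, so cell means are unbiased); noise
  draws are per cell.

## Scale of the shipped experiments

Desk-scale defaults (500-direction grid, 8 echo strengths, 20
realizations) run each experiment in one to a few minutes on one CPU;
property checks use 300 directions and 10 realizations, which preserve
every qualitative ordering above. The full 3252-direction grid sits
behind the `--full` flag and changes resolution, not conclusions.

## Known limitations

* Glints enter only as sample times; the glint waveform (Doppler spectrum
  of the wingbeat) is not modelled.
* Pinna deformation beyond rigid rotation is neglected, as is head
  movement during the call; FM call components are out of scope.
* The unsampled (whole-echo) channel assumes noise independent across
  stroke positions; temporal correlation would reduce its effective
  sample count and is not implemented.
* The posterior is reported only through its entropy; point estimates and
  angular error metrics are deliberately out of scope.
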