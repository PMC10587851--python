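# Methods

## The testing problem

Standard automated perimetry estimates a light-sensitivity threshold (in dB
of stimulus attenuation) at each of the 52 non-blind-spot locations of the
24-2 grid by presenting stimuli and recording seen/not-seen responses. ZEST
(zippy estimation by sequential testing) treats each location's threshold as
a random variable with a discrete prior over 0..40 dB, updates it after
every presentation with a fixed-shape likelihood, presents the posterior
mean, and stops at a posterior SD of 1.5 dB or 10 presentations. The
package simulates this procedure, its structurally seeded variant (S-ZEST),
and spatially enhanced versions of both, against a configurable simulated
observer, and measures accuracy (pointwise MAE, mean-sensitivity absolute
error) and speed (presentation counts) over synthetic cohorts.

## The engine

* **Likelihood.** P(seen | threshold = x) = 0.03 + 0.94·Φ((x − s)/1 dB) for
  stimulus s; the complement for "not seen". The asymptotes encode
  irreducible response error and keep every update bounded away from zero.
* **Update.** posterior ∝ prior × L^w. The tested location uses w = 1.
  Neighbour updates use w < 1 via *power* scaling (log-likelihood scaling),
  so updates compose additively in w; a linear flattening
  w·L + (1 − w) is available behind `neighbor_update="linear"`. Power
  scaling was chosen as the standard fractional-evidence semantics.
* **Stimulus choice.** Posterior mean rounded half-up to integer dB,
  clamped to [0, 40] (perimeter hardware convention).
* **Termination.** Posterior SD ≤ 1.5 dB, checked after each update of the
  *tested* location only, or 10 presentations. Neighbour updates never
  trigger termination, so every location receives at least one presentation
  and a never-tested location cannot finish.
* **Order.** Non-terminated locations are tested in uniformly random order
  from the test-level seeded generator; runs are bit-reproducible given
  (seed, inputs).
* **Numerical floor.** If an unnormalised posterior sums below 1e-300 it is
  re-floored at 1e-12 per point and renormalised with a logged warning; in
  practice the prior floor (below) prevents this.

## Priors

* **Agnostic (ZEST).** Per location, a 4:1 mixture of a "normal" component
  (Gaussian, SD 2 dB, centred on an eccentricity-dependent normative mean:
  33 dB on the innermost ring, −0.7 dB per 6° of additional eccentricity)
  and an "abnormal" component (half-Gaussian at 0 dB with SD 8 dB mixed 1:1
  with a uniform over 0..25 dB). Both components are synthetic stand-ins —
  normative perimetric databases are proprietary — and are fully
  overridable; the 4:1 ratio is configurable.
* **Structural (S-ZEST).** Empirical conditionals P(observed | rounded
  predicted), built from paired records with *both eyes of the test subject
  excluded* (leave-one-subject-out). Rounding is half-away-from-zero. Each
  bin histogram is convolved with a discrete Gaussian kernel (SD 1 dB,
  configurable; 0 disables) and floored at 1e-4 per domain point before
  renormalisation: raw bins are sparse at extreme predictions, and a
  zero-mass point could never be recovered by updating. Bins with fewer
  than `min_count` (10) records defer to the nearest populated bin, else to
  the pooled fallback. Records are pooled across locations (one conditional
  table), with per-location tables possible by filtering records.
* **Regularisation vs recovery.** Parameter-recovery checks (bin SD ≈
  injected noise SD) are computed on unregularised bins (smoothing 0, floor
  0), because both regularisers add known spread: the floor alone
  contributes ≈ 0.4% uniform mass over the whole domain, inflating
  off-centre bin SDs by up to ~17% of a 2-dB conditional SD.

## Spatial enhancement

Nearest neighbours (4-connectivity, pairs exactly 6° apart; "queen"
8-connectivity available) are connected, never across the horizontal
midline, reflecting the anatomical raphe. A response at one location also
updates its non-terminated neighbours with the scaled likelihood, weight
0.2 for the agnostic strategy. For the structural strategy, edges whose
predicted sensitivities differ by more than 3 dB (strict) are disconnected
first — preserving predicted scotoma edges — and the surviving edges carry
weight 0.4. Rook connectivity is a choice, not a given: the connectivity
convention of the originating spatial-ZEST literature is not fully
specified, so it is exposed as configuration.

## Simulated observer

P(seen) = FP + (1 − FP − FN)·(1 − Φ((s − t)/SD(t))) with guess rate FP and
lapse rate FN. Presets: reliable (5%/5%), high-FP (20%/5%), high-FN
(5%/20%). SD(t) = min(cap, exp(A·t + B)) with A = −0.081, B = 3.27 and
cap 6 dB — the exponential variability model for mixed healthy/glaucoma
observers; variability rises steeply as sensitivity falls. A `gardiner`
preset raises the cap to 10 dB to approximate a segmented-linear
variability model for thresholds above 0 dB; its slope coefficients reuse
the defaults and are marked stand-ins.

**Global visit effect (GVE).** One Gaussian offset δ ~ N(0, σ²) per test
shifts the latent true field (clamped to [0, 40]) at every location,
producing positively correlated errors within a test. Without it, the
variability of global indices such as mean sensitivity is severely
understated. The offset is applied to the latent field rather than to
responses as the simplest generator of correlated errors of the right
kind. `estimate_gve_sigma` recovers σ from a test-retest series as the SD
across tests of the per-test mean deviation from the median field; it
includes a small upward bias of Var(pointwise noise)/52 from averaging 52
noisy locations.

## Synthetic cohorts

Each eye starts from the normative field and subtracts an archetypal defect
(superior/inferior arcuate band, nasal step, altitudinal, diffuse) scaled
by a severity in [0, 1] (max depth 30 dB), plus 1 dB Gaussian roughness;
masks never cross the midline except `diffuse`. Defaults, chosen once:
25 subjects × 2 eyes; severity Beta(1.5, 4) rescaled to [0.05, 0.8] (most
eyes mildly/moderately damaged, matching a stable-glaucoma MD range
qualitatively — the generator reports the realised mean deviation
distribution); 10 predicted fields per eye (emulating one OCT scan per
visit) with independent per-location N(0, 2 dB) prediction noise, zero
bias; per-visit offset SD 1 dB. One predicted field is drawn uniformly at
random per simulated test, mirroring clinical re-use of whichever scan is
at hand.

What the generator does **not** emulate: spatially correlated prediction
errors (real structure-function models err coherently along nerve-fibre
bundles), eye-specific GVE heterogeneity, floor effects in structural
imaging at advanced damage, learning/fatigue. Passing comparisons on this
cohort therefore demonstrate that the machinery reproduces the *direction*
of the published strategy orderings under its stated noise model, not the
published magnitudes, which depend on a private clinical cohort and a real
deep-learning predictor. In particular, the synthetic structural priors
are sharper than real ones, so S-ZEST's speed advantage here is larger
than would be observed clinically.

## Evaluation

Per eye and configuration: MAE (mean over locations and simulations of
|estimate − truth|), mean signed error, MS-AE (mean |MS_est − MS_true|),
and mean total presentations. Cohort tables report the between-eye SD of
per-eye means (the convention under which cohort SDs are meaningful in
simulation studies) and also the pooled single-measurement SD. Mixed-model
significance testing is deliberately out of scope; the per-eye long-format
CSV supports it externally.

## Problem sizes and determinism

Default experiment sizes: 50 eyes, 200 simulations/eye for the four-way
reliable comparison; 50/eye for the unreliability signatures; 100/eye for
the GVE contrast; 2,000 repetitions per threshold for recovery; 10,000
draws per calibration point. Sizes are the package's own defaults for a
single-CPU run; all scale linearly. Every random quantity flows from one
top-level seed through `numpy` `SeedSequence` spawn keys of
(CRC32(eye_id), simulation index), so any subset of the experiment
reproduces the full run's numbers exactly, and identical streams are used
across strategy configurations for paired comparisons.

## Known limitations

* The 24-2 grid only (the data-driven `Grid` type makes other patterns
  mechanical to add, but none are shipped or tested).
* Global indices beyond MS (MD, PSD, VFI) require normative databases and
  are out of scope.
* No growth patterns or variance-prioritised seeding; locations are tested
  in random order.
* The GVE is a single additive Gaussian per test — no location-varying
  weights or skew.
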