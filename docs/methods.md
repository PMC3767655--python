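# Methods

## The scientific question

When actomyosin contractility is relaxed (e.g., by the ROCK inhibitor
Y-27632), focal adhesions (FAs) disassemble, and different adhesome
proteins leave the adhesion at characteristically different rates.  Two
independent measurements describe this process:

1. **Molecular kinetics (FRAP).** Bleaching a diffraction-limited spot on an
   FA and fitting the recovery with a diffusion–exchange model yields the
   apparent pseudo-first-order binding rate k_on and the unbinding rate
   k_off of the tagged protein.
2. **Structural kinetics (time-lapse imaging).** Segmenting and tracking
   individual FAs through a 2-h movie yields survival and normalized
   intensity-decay curves, whose single-exponential time constant τ
   measures how fast the protein's FA pool disappears.

The bridge between the two is the disassembly statistic

    K_dis = k_off − k_on        (units 1/min)

When rebinding is progressively blocked during disassembly, the bound pool
decays approximately mono-exponentially, y(t) = exp(−K_dis·t), reaching 1/e
(≈37%) of its initial value at t = 1/K_dis.  A positive K_dis means net
disassembly, K_dis ≈ 0 a stable state, and negative K_dis net assembly.
The package's central experiment is the closure test: predict the
disassembly curve from FRAP-derived rates, measure it independently from
the movie, and compare.

## The FRAP forward model

`frap_model.simulate_recovery` integrates a radially symmetric two-species
reaction–diffusion system on 0 ≤ r ≤ R_dom:

* free species f(r,t): diffuses with D_C everywhere; on the FA footprint
  (r ≤ r_FA) it is consumed at k_on·f and produced at k_off·b;
* bound species b(r,t): exists on r ≤ r_FA, diffuses with D_M (default 0,
  constrained < 0.01 µm²/s), with ∂b/∂t = k_on·f − k_off·b + D_M∇²b.

Pre-bleach the system is at exchange steady state (b/f = k_on/k_off on the
FA), with the free amplitude scaled by the cytoplasmic pool N_C.  Note that
a consistent steady state ties the pool ratio to the rate ratio,
N_FA/N_C = k_on/k_off; the fixed pools therefore enter the fit through this
ratio and through the amplitude scaling rather than as two independent
degrees of freedom.  The bleach is instantaneous (the pulse is ~10 ms,
orders of magnitude below recovery times) and multiplies both species by
exp(−K_bleach·exp(−2r²/w²)), where w is the e⁻² radius of the Gaussian
spot.  The observable is the beam-weighted fluorescence
F(t) = ∬(f+b)·exp(−2r²/w²)dA, normalized to 1 pre-bleach.

The reported spot size 0.77 µm is read as the e⁻² **diameter**, giving
w = 0.385 µm — consistent with a 63×/1.4 NA diffraction-limited spot.  The
FA footprint default r_FA = 0.56 µm (a 1 µm² disc) is a configuration
choice; FA size for FRAP is not otherwise constrained.

### Numerics

Conservative finite-volume discretization on cell centers r_i = (i+½)Δr
with Δr = w/20 (a grid coarser than w/10 is rejected); fluxes vanish at
r = 0 and at the reflecting outer boundary R_dom = 10 µm ≥ 10w.  The two
species are interleaved so the operator is banded (bandwidth 2) and each
Crank–Nicolson step is a banded solve.  Because the fast diffusive
transient (τ_D = w²/4D_C ≈ 30 ms) and the slow exchange phase (1/k_off,
minutes) differ by four orders of magnitude, the time step starts at
τ_D/50 and grows geometrically by 15% per step, capped at 1/60 of the
horizon; the readout is interpolated to requested times with a monotone
cubic (PCHIP).  Verified properties: mass conservation to <0.1% after the
bleach, <1% sup-norm agreement with the closed-form Gaussian-spot
pure-diffusion series when binding is off, and an effective recovery rate
within 10% of k_off in the reaction-dominant limit (D_C large, 90% bound).

### Fitting protocol

* `fit_diffusion`: short-timescale curves (≤3 s post-bleach) are fit with
  the closed-form pure-diffusion series over (D, K_bleach); exchange is
  negligible on this window.  Physiological D_C is 1–1.5 µm²/s.
* `fit_exchange`: with D_C, N_FA, N_C fixed, (k_on, k_off, K_bleach) are
  free.  The SSR surface of diffusion–exchange fits is multi-modal, so the
  fit evaluates a 4×4 log grid of rate starts over [1e-4, 1e-1] s⁻¹ and
  polishes the three best with a bounded trust-region least-squares in
  log-rate space; ties within 0.1% SSR break toward smaller k_off.  A rate
  landing at the search boundary sets a warning flag.  Mobile fraction
  R_f and half-time T_1/2 are read off the fitted noiseless curve
  (plateau = mean of the last 10% of samples).

Normalization divides each trace by its pre-bleach mean (gain cancels; the
fit is invariant to intensity units) and averages traces synchronized at
the bleach point, emulating the 20–30-curve averaging protocol.

## The synthetic data generator

The generator is the study-conditions oracle: it emulates the statistical
structure the analysis assumes, with known ground truth.

* **FRAP traces**: the noiseless forward solution plus i.i.d. additive
  Gaussian noise on the normalized scale (default 2% — typical for
  single-spot confocal FRAP), 25 traces per average.
* **Movies**: 41 frames at 3-min intervals (2 h), drug at frame 5;
  256×256 px at 0.16 µm/px; an elliptical cell with cytoplasmic background
  (100 photons) over a camera offset (10 photons).  Adhesions are
  anisotropic 2-D Gaussian blobs (σ = axis/2.355, i.e., axes are FWHMs):
  a hard ellipse would not reproduce the diffraction-blurred TIRF
  appearance, and Gaussian pairs remain watershed-separable.  Major axes
  1.2–2.8 µm, minor 0.4–0.8 µm, peaks 500–900 photons (≥5× background).
  Blob centroids are static (FA sliding is out of scope) and at least 2 µm
  apart — adhesions are disjoint structures.
* **Decay**: before the drug every blob is constant; after it the
  amplitude is multiplied by exp(−(t−t_drug)/τ).  Default group τ presets
  are the midpoints of the observed ranges: fast 7.5, mid 16, slow
  26.5 min.  Central adhesions (normalized boundary distance > 0.35) use
  τ/central_speedup with central_speedup = 1.5 by default (the observed
  regime is 1.3–2×).  Death is declared when the decay factor crosses 5%
  of the pre-drug peak — an exponential never reaches zero, so a finite
  ground-truth lifespan needs a threshold; 5% is at the sensitivity limit
  of the segmentation at default SNR, and the blob is removed from the
  render at that frame (death = complete disassembly).
* **Nuisance processes**: global photobleaching multiplies all
  fluorescence by exp(−t/τ_bleach), default τ_bleach = 300 min — mild, so
  the correction is exercised without dominating the kinetics.  Poisson
  shot noise acts on total photons, then Gaussian read noise (SD
  2 photons).  Post-drug birth of new (drug-resistant, central) adhesions
  is a Poisson process with default rate 0, so recovery tests are clean.

What the generator does **not** emulate: optical PSF beyond the Gaussian
blob, FA sliding/fission/fusion, spatially varying background, detector
gain nonlinearity, or the biological spread of τ within a protein group.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the model's assumptions, not robustness to every property of
real TIRF data.

## Image analysis

* **Background**: white top-hat with a 2 µm disc (larger than any FA minor
  axis), removing smooth cytoplasmic background while preserving blob
  peaks within ~10% on ramps.
* **Detection**: Gaussian smoothing (σ = 1 px), threshold at
  median + 6·1.4826·MAD of the background-subtracted frame — robust
  statistics rather than Otsu, because FA-sparse frames are not bimodal.
  The threshold is floored at 2% of the frame's 99.9th percentile so a
  near-noiseless frame (degenerate MAD) does not admit arbitrarily faint
  artifacts.  Regions whose centroid falls within 3 px of the cell
  boundary are discarded when a cell mask is supplied: adhesions are
  intracellular, and the top-hat leaves residues along the curved mask
  edge.
* **Splitting**: marker-controlled watershed on the inverted smoothed
  image, seeded by local maxima at ≥0.5 µm separation; regions below
  0.2 µm² are dropped.
* **Photometry**: per-region total intensity is measured over the label
  expanded by 4 px (≈ one minor-axis FWHM, without overlap between
  neighbors), minus the frame's residual-floor median.  Summing only
  above-threshold pixels would clip the blob skirt and bias decay
  constants low by ~10–15%; the expanded aperture makes the measure
  proportional to the true blob integral.  Records carry 30+ geometric
  and intensity features (µm units via the pixel size; 0-based (row, col)
  coordinates; the primary centroid is intensity-weighted).
* **Bleach correction**: reference = mean over cytoplasm excluding FA
  pixels, factors = reference[0]/reference[t].  Excluding FA pixels
  matters: a whole-cell reference would "correct away" genuine FA
  disassembly.
* **Ratio imaging**: per-pixel log(a/max(b, floor)) inside the FA mask,
  with floored pixels flagged.

## Tracking and kinetics

Greedy nearest-neighbor linking gated at 1 µm with a 1-frame gap
tolerance; adhesions are near-stationary at 3-min sampling, so global
assignment would buy nothing and greedy is fully deterministic
(ties: smaller distance, then smaller label).  Death = missing more than
max_gap consecutive frames; tracks reaching the last frame are flagged
censored.  Peripheral vs central uses the normalized distance transform of
the cell mask with a 0.25 band — the band is a configurable stand-in for
an anatomical lamella boundary the data cannot provide.

The survival curve counts the drug-time cohort still alive at each offset;
the intensity curve normalizes each track at drug time and averages with
dead tracks contributing 0 (dropping them would bias the decay shallow).
Single-exponential fits fix the amplitude to 1 (curves are normalized at
drug time by construction); a free-amplitude variant exists for curves
that are not.  τ is initialized by log-linear regression on values >0.05.
Comparison of predicted exp(−K_dis·t) and measured curves uses the
[0, 60] min window (>2 time constants of the slowest group), RMS on the
measured grid, and the implied-rate ratio; with several proteins the
Kendall concordance of rate rankings is reported.  All kinetic outputs at
this layer are per minute; FRAP-layer 1/s values are converted explicitly.

## Problem sizes and determinism

Default runs use 20 adhesions per movie (12 peripheral, 8 central), 3
movies (one per τ group), 25 FRAP traces per averaged curve, and 20
Monte-Carlo fits for the rate-recovery estimate — sizes at which every
statistic is stable yet a full run finishes in minutes on one CPU.  All
generators are pure functions of (config, seed); a run seed fans out to
per-stage child seeds via `numpy.random.SeedSequence`, and segmentation,
tracking and fitting contain no randomness at all.

## Known limitations

* The exchange fit assumes a single binding class; proteins with two
  kinetically distinct pools would need a triple-state model (out of
  scope).
* The predicted curve ignores diffusion during disassembly, so against
  data where diffusion contributes, predicted rates run systematically
  fast; no correction factor is applied.
* The apparent k_on is treated as constant during disassembly; in reality
  the available-site count decays, so exp(−K_dis·t) is a first
  approximation.
* Survival curves from a homogeneous group with a deterministic death
  threshold are step-like; real lifespan spread requires per-adhesion τ
  variability the generator does not include by default.
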