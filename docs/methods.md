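# Methods

`specklesize` estimates powder particle size distributions (PSDs) from the
autocorrelation of backscattered laser speckle. This note records the model,
the conventions and numerical choices behind the implementation, what the
synthetic-data generator does and does not emulate, and the known limits.

## Forward model

A coherent beam of wavelength λ = 532 nm illuminates a dense monolayer of
particles through an intensity mask |m(x)|²; a Fourier lens (focal length f)
images the far field onto a camera. Lag coordinates are reported as the
normalized displacement u = u′/(λf), in cycles/mm.

The ensemble-averaged, zero-lag-normalized intensity autocorrelation
factorizes as

    ⟨A(u)⟩ = |M(u)|²_norm · | ∫ r² Jinc(κ r |u|) p(r) dr |²
                            ---------------------------------
                            | ∫ r² p(r) dr |²

where |M(u)|² is the power spectral density (PSD) of the pupil transmission
|m(x)|², p(r) the particle *diameter* density, and Jinc(x) = 2J₁(x)/x. The
pupil PSD is the sidelobe skeleton (it is all the autocorrelation would be
for vanishing size dispersion at u → 0); the size term modulates sidelobe
heights and decays with particle size.

**Jinc scale.** With u in cycles per length and r the particle diameter, the
Fourier transform of a uniform disk fixes κ = π exactly (the van
Cittert–Zernike kernel for a circular patch). The constant is exposed on
`OpticalConfig.jinc_scale` and is pinned operationally: the simulator's
ensemble autocorrelation reproduces the model only with κ = π (see below).

**Sensitivity.** S(u, r) = ∂⟨A(u)⟩/∂p(r) is implemented as the exact Gateaux
derivative of the expression above. Because ⟨A⟩ contains the *squared* size
integral, the derivative carries a leading factor 2 on the usual bracket
form; the implementation is validated against central finite differences to
1e-4 relative and satisfies ∫ S(u,r) p(r) dr = 0 identically (the model is
invariant under rescaling of p). Sensitivity falls with decreasing r — the
small-particle end is the ill-posed end of the inversion.

## Pupils and the energy-partition conventions

Masks are binary (3D-printable opaque/clear), composed from mm-scale
primitives (rectangles, disks, annular sectors) inside a 5 mm clear
aperture with a last-wins rule; boundary cells carry exact area coverage so
open areas and PSD energies are grid-accurate. The canonical pupil grid is
512 × 512 cells of 24 µm; PSDs are computed with 2× zero padding, giving a
spectral pitch of 1/24.576 mm⁻¹ that subdivides the canonical lag pitch
exactly (no interpolation between model and measurement).

**Zero-order lobe.** The main lobe is the steepest-ascent (watershed) basin
of the central PSD peak. Because the innermost diffraction ring is not
separable from the main lobe at camera resolution, the reported zero-order
fraction optionally absorbs the basins adjacent to the central one
(`absorb_first_ring`). For the clear 5 mm disk this reproduces the classic
encircled-energy values: 83.8% within the first Airy null (watershed basin),
91.1% with the first ring absorbed, leaving 8.9% of sidelobe energy beyond
the zero order. Sidelobe *orders* on cross-sections are counted with the
same convention (the first ring belongs to the zero order), which makes the
clear-pupil 2nd-order landmark the third Airy ring, ≈ 0.0015 after size
modulation by a 106–180 µm powder.

**Effective region.** Lag pixels whose peak-normalized PSD exceeds 0.023
form the effective region; this threshold marks where engineered sidelobes
stay above single-frame background fluctuation, and it generates the
digital filter applied to autocorrelations before inversion. For the clear
pupil nothing but the main lobe exceeds 0.023 — the quantitative statement
of why clear-pupil sizing needs frame averaging. Clear-pupil estimators
therefore use a lower filter threshold (default 8e-4, passing the first few
Airy rings).

**Engineered mask.** The paper-accurate mask geometry is not available, so
the package ships a synthetic stand-in
(`data/engineered_mask_synthetic.yaml`): crossed opaque bar gratings in the
5 mm disk (x period 1.4 mm at open duty 0.399; y period 1.8 mm at duty
0.835). It was designed numerically to the published instrument targets —
open area ≈ 1/3 (achieved 0.326), eight dominant sidelobes with different
x/y peak radii, and a 2nd-order x sidelobe of 0.055 for a 106–180 µm powder.
Its zero-order (ring-absorbed) fraction is 33.0% and its effective-sidelobe
fraction 40.1%; a published partition of 35.05% / 62.9% would require ~94%
of all sidelobe energy to sit above the 0.023 threshold, which is out of
reach for bar-grating geometries — the shipped mask is honest about this
gap, and the lobe report always prints the convention it used.

## Speckle simulator (synthetic-data generator)

One frame is generated as follows.

1. **Surface.** Disks with iid diameters from the target distribution are
   packed by random sequential adsorption at coverage 0.45 into a square
   region covering the beam. The diameter population is drawn up front and
   each disk retries positions until it fits, so the packed diameter law
   equals the target law exactly (plain RSA acceptance-biases against large
   disks; we measured Kolmogorov–Smirnov distance 0.13 at coverage 0.45).
   A top-up draw compensates sampling fluctuations in total area.
2. **Exit field.** Each particle's top facet is rough far below the grid
   scale, so every illuminated sample inside a particle carries an
   independent uniform phase ("δ-correlated facets"); gaps are opaque. Each
   facet is filled with the beam intensity at the particle *center*: the
   beam structure is mm-scale and diffraction-blurred by the time it
   reaches the powder, so a particle samples the local beam level rather
   than imprinting sharp mask edges across its facet. (A per-particle
   *constant* phase does not reproduce the model: it yields a smooth
   spectral-overlap modulation without the Jinc structure. The δ-correlated
   facet model is what makes the coherent part of the source-plane Fourier
   transform average to the r² Jinc kernel.)
3. **Camera.** The intensity is |DFT|² of the exit field; one camera pixel
   equals 1/(grid extent) = 1/12.288 mm⁻¹ of normalized displacement. The
   grid density adapts to the powder (≥ 6 samples across the smallest
   particle; 512–2048 grids over a fixed 12.288 mm field). Optional Poisson
   shot noise, Gaussian read noise and 16-bit quantization.

Fully developed speckle (contrast ≈ 1) emerges by construction. The
simulator is the package's instrument stand-in: per configuration, the
frame autocorrelation equals the van Cittert–Zernike prediction
|FT(source intensity)|² to ~3e-4, and the ensemble autocorrelation
converges to the forward model with one caveat:

**Finite-particle-number floor.** A 5 mm beam holds only ~150 particles of
250–300 µm (~550 of 106–180 µm). The variance of the source-plane Fourier
transform over packings adds a positive bias to ensemble sidelobes of order

    floor(u) ≈ (1/N_p) · [∫|m|⁴ / (∫|m|²)²]·A_beam · E[d̂²(u)]/E[d̂(0)]² · S(q)

with d̂ the disk spectrum and S(q) ≤ 1 the packing structure factor at the
(low) sidelobe frequencies. This is real physics, not a simulator artifact;
the forward model is its N_p → ∞ limit. Consistency is therefore asserted
as: deviation from the model bounded by the analytic Poisson envelope
(S = 1) plus three Monte-Carlo standard errors. At 500 frames of a 106–180
µm powder the maximum deviation over the effective region is ~2e-3 on a
unit-normalized map.

The generator emulates: dense monolayers, sieve-interval and calibrated
(truncated-Gaussian) diameter laws, masked-beam illumination, Fourier-plane
detection, shot/read noise. It does not emulate: 3-D stacking and multiple
scattering, wet-powder optics (liquid films), motion blur, non-spherical
particles, or mask-to-powder diffraction. Passing closed-loop tests
therefore demonstrates the inversion under the stated surface model, not
under all real-powder conditions.

## Autocorrelation estimation

Frame autocorrelations are mean-subtracted circular autocorrelations via
the correlation theorem, normalized to unit zero lag (per frame, *then*
averaged — the alternative order differs at O(1/N) and is not used), with
lag (0,0) at the array center; no apodization, since speckle fills the
frame uniformly. Background fluctuation is the standard deviation in a
square annulus between caller-declared inner/outer half-widths (defaults
20–28 lag pixels, outside the engineered effective region); it follows the
1/√N averaging law to within fit slope −0.5 ± 0.05 when the annulus is
free of static structure (on the clear pupil; the synthetic engineered
mask parks weak high-order grating harmonics there, which floor σ at
large N). One reference behavior does *not* reproduce in the monolayer
surface model: fluctuations are expected to be stronger for finer
powders, but the model inverts the ordering — a 5 mm beam holds ~4× fewer
425–500 µm particles than 106–180 µm ones, and the configuration-noise
component (∝ 1/√N_particles) dominates the background.

## Estimator

A four-stage CNN with a fully connected head maps the filtered 64 × 64
autocorrelation to a 96-bin cumulative distribution on a log-spaced
50–1000 µm diameter grid. The printed parameter budgets are binding: stage
1 holds 4,284 parameters (budget 4,200 ± 10%) and the network 643,732
(625k ± 10%). Each stage is conv3×3(stride 2)–BN–ReLU–conv3×3–BN–ReLU with
channels (21, 40, 64, 96); the head is 1536→256→96. The output head emits
softmax increments whose running sum is the CDF — monotone in [0, 1] by
construction, never clipped — and the L1 loss on CDF bins, weighted by bin
widths, is exactly the 1-Wasserstein distance in µm (training smooths the
kink below 0.02 CDF units, Huber-style, for optimization only).

The default input is the filtered 2-D map itself (no radial reduction:
the pupil's deliberate x/y asymmetry disambiguates spatial frequencies);
configurable alternatives divide by the pupil PSD on the lag grid, which
isolates the size-modulation quotient but amplifies weak-pixel noise.

Training follows the physics-informed recipe, with every calibration
computed at run time from the simulator:

1. **Noise calibration.** A short simulator run yields the single-frame
   noise model — background fluctuation σ_bg, signal-proportional
   fraction α (per-pixel std ≈ √(σ_bg² + (α A(u))²); speckle
   autocorrelation estimates fluctuate in proportion to their local
   value), a library of measured zero-mean single-frame ACF residual
   fields, and the finite-density floor factor (the least-squares scale
   of the analytic Poisson floor against the measured ensemble-mean
   deviation, typically 0.35–0.4 — the packing structure factor
   suppresses the Poisson value).
2. **Pretraining.** All stages train on synthetic forward-model maps with
   the calibrated per-item density floor added and measured residual
   fields injected as noise (scaled by 1/√N for N-frame-average models;
   parametric heteroscedastic noise is the fallback when no residual
   library is supplied). Adam with a 2-epoch warmup and cosine decay to
   5% of the base rate; base rate 1e-3 (higher rates intermittently
   collapse the softmax head to a constant predictor).
3. **Fine-tuning.** Stages 2–4 and the head are frozen and only stage 1
   adapts on autocorrelations of simulated frames (the domain-transfer
   step); frozen stages are bitwise unchanged, including batch-norm
   statistics, which run in inference mode during fine-tuning.

All seeds are explicit; runs are bit-reproducible on a given platform.
The training population mirrors sieve-calibration practice: uniform
intervals with ratios up to 1.9, truncated Gaussians (modes 90–650 µm,
spreads 15–90 µm), and 15% bimodal mixtures.

Shipped defaults are sized for CPU training in minutes (thousands of
items, tens of epochs) rather than the full 9000-item pretraining the
procedure supports. At that scale the held-out benchmark in the
acceptance suite measures a median W1 in the high 20s to high 30s of µm
for the single-frame engineered model (run-to-run training variance is
substantial) — above the 20 µm goal the suite asserts, which presumes a
larger optimization budget — and single-frame closed-loop estimates on
simulated frames scatter by several tens of µm. On this synthetic panel
the engineered single-frame model and the clear-pupil 200-frame model
land within each other's run-to-run spread (the clear model's noise at
N = 200 is minuscule in simulation, unlike on a real instrument, though
it retains a characteristic blind spot: fine powders, whose modulation
barely touches the low-frequency Airy rings). A reference behavior that
places the single engineered frame strictly ahead of 200 clear frames is
therefore not reproduced under these idealized noise conditions; the
acceptance suite states it and reports the measured outcome.

One more training-data lesson is recorded here because it is easy to get
wrong: injecting *measured* single-frame residual fields from a
calibration powder into the synthetic maps emulates that powder's
measurement noise beautifully but does not transfer across sizes — the
residuals carry the calibration powder's own signal-proportional
fluctuations, which masquerade as size information on other powders. The
shipped pipeline therefore trains benchmark models with the parametric
heteroscedastic model (which scales the signal term by each item's own
map) and reserves residual injection for models that are subsequently
fine-tuned on instrument frames.

## Monitoring mode

`run_timelapse` performs one single-shot estimate per frame (no ensemble
averaging), sorts records by timestamp, tolerates unreadable frames, and
smooths the density-peak trace with a moving median (default window 5
frames). Per-frame latency is logged but never asserted.

## Numerical conventions

- Diameter grid: 96 log-spaced nodes on [50, 1000] µm; integrals use
  trapezoid node weights; the CDF is the running weighted sum, making
  density ↔ CDF conversion an exact inverse pair.
- Sieve fractions default to uniform densities on [low, high] µm;
  monodisperse distributions concentrate mass at the nearest grid node.
- Jinc uses a Taylor series below 1e-4 for the removable singularity.
- Degenerate inputs raise: empty distributions, opaque pupils, constant
  images, unfiltered estimator inputs, mismatched grids.

## Known limitations

- The engineered mask is a synthetic stand-in; its effective-sidelobe
  fraction (40%) undershoots the published 62.9% (see above).
- Single-frame accuracy is noise-limited at the calibrated fluctuation
  level; the weak-sensitivity large-size end (≳400 µm) dominates the error
  budget.
- The finite-particle floor bounds how exactly ensemble autocorrelations
  can match the asymptotic forward model at a 5 mm beam.
- Monolayer surface model only; quantitative transfer to real 3-D powder
  beds relies on the first-stage fine-tuning step with instrument data.
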