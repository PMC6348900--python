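# Methods

This note documents the models, conventions and numerical choices behind
`shgtensor`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Coordinate and angle conventions

Images are row-major with the origin at the top-left; x runs rightward
(columns), y downward (rows). Angles are measured counterclockwise from +x
*as displayed* and are axial: every orientation is reduced modulo 180°.
Axial statistics (means, dispersions) are computed on doubled angles, the
standard device for orientation data.

## Structure-tensor analysis

Gradients are Gaussian derivatives at scale `sigma_gradient_um` (default
1 µm); the tensor products are smoothed with a Gaussian window
`sigma_window_um` (default 4 µm, roughly the fiber-bundle scale). All
convolutions use reflect padding. Per pixel, the orientation is the
eigenvector direction of the smallest eigenvalue (structure direction,
perpendicular to the dominant gradient) and the coherence is
(λ1−λ2)/(λ1+λ2).

**DoI.** The degree of isotropy is operationalized as the tensor coherence
per pixel, and the reported DoI of a map as its arithmetic mean over valid
pixels. This is consistent with a [0, 1] range, with 0 for isotropic
texture, and with reporting the mean across a map. Pixels whose tensor
trace falls below 1e−6 × the image maximum trace are masked (coherence is
0/0 there), as is a border margin of ⌈3·sigma_window/pixel⌉ pixels, so
boundary padding never enters statistics.

A practical note on the measurement floor: even a perfectly isotropic
texture measures a small positive mean coherence, because a finite window
contains finitely many independent gradient directions. With the default
scales the floor is ≈ 0.15–0.19 for sub-resolution speckle, comfortably
below the 0.20 nonorganized boundary; textures whose grain approaches the
window scale measure higher. DoI values are therefore comparable only at
fixed scales.

**PO histogram.** Orientations of valid pixels are binned at 1° over
[0°, 180°); by default each vote is weighted by the pixel's coherence, so
structureless pixels barely contribute (configurable off). The histogram is
displayed normalized to max = 1.

**Peak detection.** The histogram is circular with period 180°. Candidates
are local maxima of a lightly smoothed copy (circular Gaussian, sigma 3°)
with prominence ≥ 0.2 × the maximum. Two further rules matter in practice:

* *Enrichment gate.* A preferential orientation is a direction enriched
  over the uniform baseline, so a candidate must reach ≥ 2 × the histogram
  mean. A von Mises mode with concentration ≥ 2 sits ≥ 3 × above the
  uniform level, while the bin noise of a flat histogram built from
  spatially correlated pixels stays ≤ ~1.3 ×; the gate therefore reports
  "absence of PO" on disorganized texture without suppressing real modes.
* *Position refinement.* The peak angle is the axial circular mean of the
  baseline-subtracted histogram mass within the minimum-separation window
  of the mode. Wavy fibers have a bimodal local-tangent distribution
  (lobes straddle the family mean), so a window covering both lobes
  estimates the family mean far less noisily than the raw mode.

Surviving peaks are thinned greedily by height to a minimum circular
separation of 20°. Note that the min-arc separation of two axial directions
is at most 90°, so the measured separation of two nominally orthogonal
families is 90° minus the magnitude of the estimation jitter; with the
bundled crosshatch phantom this measures 89.6 ± 0.3°.

**Structural dispersion.** SD is the sample standard deviation of the
*probability-normalized* bin heights. On sum-normalized heights the
statistic is a proper peakedness functional — it increases monotonically as
the orientation distribution sharpens — whereas on max-normalized heights
it would fall again once a mode narrows to a few bins. On a single-bin
spike both normalizations coincide. SD therefore rises with alignment and
with DoI, which the concentration-ladder test verifies (Spearman ρ = 1
across κ ∈ {0, 1, 2, 4, 8, ∞}).

**Classification.** nonorganized if mean DoI < 0.20 *or* no PO exists;
highly aligned above 0.70; partially aligned between. The boundaries are
the conventional DoI class limits for stromal collagen.

## Synthetic SHG generator

The generator renders what the analysis consumes: bright collagen-like
bands on a dark background, with controllable ground truth.

* **Fibers** are anti-aliased ridges with a Gaussian cross-section
  (`fiber_width_um`, default σ = 1.5 µm) along straight center-lines
  displaced sinusoidally (waviness amplitude/period). Per-fiber angles are
  drawn from an axial von Mises distribution about the family mean with
  concentration κ: κ = 0 is isotropic, κ = ∞ perfectly parallel. Default
  spacing (4–6 µm) is kept above the ridge FWHM; closer packing washes the
  family out into a contrast-free sheet.
* **Lamellar envelopes.** Each family's amplitude is modulated by a smooth
  log-normal random field (correlation length 30 µm, log-sd 0.8). This
  emulates lamellar domains — where two interwoven families coexist, each
  dominates in patches — and is also necessary numerically: without it two
  superimposed orthogonal families of near-uniform contrast degenerate
  into a winner-take-all orientation field.
* **Disorder mix.** A fraction of the signal can be replaced by isotropic
  sub-resolution speckle (grain 0.5 µm), emulating stroma whose bundles are
  not resolvable; this is the knob that moves measured DoI through the
  0.16–0.95 range and is used for depth-graded disorganization.
* **Isotropic texture** (`gen_isotropic`) is band-limited Gaussian noise —
  a rotation-invariant construction — with 0.5 µm grain, representing
  disorganized stroma imaged at the diffraction limit.
* **Depth stacks** scale plane k by exp(−attenuation · k · spacing) and
  rotate family means by k · rotation_per_plane. **Frames** add Gaussian
  read noise or Poisson photon noise; the pipeline acquires 3 frames per
  depth and averages them, and planes are spaced 20 µm with the depth
  origin at the first plane whose total intensity exceeds 10% of the stack
  maximum — the usual "first location where SHG signal appears" convention,
  operationalized with a threshold robust to dark-plane noise.
* The default pixel pitch is 210/512 ≈ 0.41 µm so a 512×512 field spans
  210×210 µm².

Everything is driven by `numpy.random.Generator` seeded through
`SeedSequence`; a fixed seed fixes every pixel.

What the generator does **not** emulate: SHG radiometry (phase matching,
forward/backward ratios), 3-D fiber geometry, keratocytes, or optical
sectioning cross-talk. Passing tests show the *measurement chain* is
correct on textures with known truth, not that any biological effect size
is reproduced.

## Group statistics

* **KS on PO histograms.** Pseudo-samples of N = 1000 points per histogram
  are rebuilt by replicating bin centers proportionally to bin heights
  (largest-remainder allocation), then compared with the two-sample KS
  test (asymptotic p). The p-value is calibrated exactly when a histogram
  encodes ~N independent orientation draws; image-derived histograms have
  spatially correlated pixels, so for them p is a comparative index — the
  same caveat applies to any histogram-level KS. The calibration test
  therefore draws histograms from independent axial von Mises samples,
  where the machinery reduces to genuine two-sample KS (type-I error
  within [0.01, 0.10] at α = 0.05 over 200 replicates).
* **Depth profiles.** Per-plane total intensities are normalized to the
  profile maximum and resampled by linear interpolation onto 20 equal
  fractional-depth steps so corneas of different thickness can be
  averaged. Groups are compared with a Welch t-test across specimens on
  each specimen's depth-averaged normalized intensity. Specimens are the
  independent units; testing between the two per-depth group-mean
  sequences instead would be degenerate under the null (both sequences
  share the depth-decay trend, which dominates their within-sequence
  variance and drives the rejection rate to zero), so the specimen-level
  test was chosen to keep type-I error calibrated while retaining high
  power for attenuation contrasts (0.004 vs 0.008 µm⁻¹ at n = 6 per group
  is detected in > 80% of replicates). The per-depth mean curves and the
  mean relative change over depth are reported alongside.
* **DoI by location.** Plane-level mean DoI values are pooled across
  specimens and layers within each stromal third (thirds of each
  specimen's thickness, half-open intervals with the last closed), and
  compared per third with Welch t-tests. An unpaired design is the
  default; no multiple-testing correction is applied, matching common
  practice in this literature. α = 0.05 throughout.

## Emulation scenarios

Scenario parameters encode the qualitative phenomenology of the two
species archetypes and were fixed as scenario definitions:

* **rabbit_cxl_emulation** — one fiber family per specimen (random base
  angle), κ ≈ 2 (control) with disorder mix graded 0.50 → 0.95 from
  anterior to posterior, so the posterior third measures DoI < 0.2 with no
  PO; treated corneas use κ ≈ 3, mix 0.35 → 0.70, brightness × 1.17 and
  lower attenuation (0.0045 vs 0.0060 µm⁻¹). Result pattern: treated mean
  DoI above control in every third, treated profile above control.
* **chicken_cxl_emulation** — two orthogonal families (κ ≈ 32, spacing
  5 µm, 10°/plane lamellar rotation); controls have equal densities
  (secondary 0.45 in the posterior third, where one PO fades); treated
  corneas have a 0.15-density residual secondary family plus disorder mix
  0.35, calibrated once so the treated mean DoI matches control — the
  archetype is "one PO is maintained, overall organization unchanged".
  Result pattern: no significant DoI difference in any third; anterior/mid
  PO count drops 2 → 1.

Specimen-level variability (log-normal jitter on κ and attenuation, ~8–10%)
makes the group tests honest rather than degenerate. The default cohort is
6 + 6 specimens, 12 planes of 512×512; the end-to-end test suite runs the
same scenarios at 4 + 4 specimens, 9 planes of 256×256, sizes chosen so the
full suite completes in a few minutes while every qualitative conclusion is
unchanged; the statistical simulations use 64×64 planes (depth profiles
depend on totals, not resolution).

## Numerical details and edge cases

* Constant images have no gradient energy anywhere: the valid mask is
  empty and downstream operations raise rather than return NaN.
* Coherence is clipped to [0, 1]; orientation of a zero tensor is
  meaningless but masked.
* Identical inputs to a two-sample test short-circuit to statistic 0,
  p = 1 (Welch is 0/0 there).
* Histogram pseudo-sampling uses largest-remainder rounding so each
  histogram contributes exactly N points.
* Peak thinning is greedy by height; ties are resolved by detection order.
* All TIFF I/O is float32 multi-page with a JSON sidecar carrying pixel
  size, plane spacing, depths and labels; 8/16-bit input is promoted to
  float on read.

## Known limitations

* DoI depends on the analysis scales; cross-study comparisons require
  identical `sigma_gradient`/`sigma_window`.
* The KS p-value on image-derived histograms is anti-conservative
  (correlated pixels); use it comparatively.
* The generator's ground truth assigns one orientation per pixel (the
  locally dominant fiber); at crossings the true tangent is ambiguous by
  construction.
* Peak angles of dispersed families carry ~1° sampling jitter per family
  even for a perfect detector; separations of nominally orthogonal
  families therefore read slightly below 90°.
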