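# Methods

This note documents the models, numerical choices and known limitations of
strawspec, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Absorbance and replicate averaging

Diffuse-reflectance absorbance is `A(λ) = −log₁₀((S−D)/(W−D))` with sample
counts S, white-reference counts W and dark counts D, log base 10 (the
standard AU convention). Replicate measurement points on one fruit are
averaged **as absorbances**, not as raw intensities; for the count levels of
real instruments the difference is far below measurement noise, and
averaging absorbances matches the usual multi-point protocol. Non-positive
net intensities (S−D ≤ 0 or W−D ≤ 0) raise a domain error naming the
offending wavelength — clipping would silently bias every downstream
statistic.

Pigment-solution absorbance is computed as `A = −log₁₀(I₀/I_t)` with the
reference I₀ in the numerator. This yields *negative* values for absorbing
samples; the conventional definition is `−log₁₀(I_t/I₀)`. The sign
convention is kept deliberately (it matches how the quantity is defined for
the pigment standards this package models) and is flagged in the docstring
rather than silently corrected. Band *positions* are unaffected.

## Second-derivative preprocessing

A Savitzky–Golay filter with window 15, polynomial order 2 and derivative
order 2 is the sole preprocessing step. Order 2 is the minimal order
supporting a second derivative and the common chemometrics choice; both
window and order are configurable. The derivative is computed in index
units (per sample-point²) by default; on a uniform grid this differs from
per-nm² scaling only by the constant step², which the linear calibration
absorbs. A `per_nm` option is provided.

Edge points where the full window does not fit are **dropped** — the grid
shrinks by (window−1)/2 = 7 points per side — rather than padded: padded
edges are fabricated data that would leak into the calibration.

Two exact properties are tested: the filter annihilates constants and
linear tilts (its baseline-correction purpose) and reproduces the second
derivative of quadratics exactly. For sinusoids the filter follows the
−ω² law with an attenuation that grows with frequency: below 2% error for a
period of 100 grid points at window 15, about 4% at a period of 60. That
attenuation is the filter's true frequency response, not an implementation
artifact, and a test documents it.

## PLS1 / NIPALS and factor selection

NIPALS was chosen over SIMPLS or kernel PLS because the per-factor deflation
is explicit, which makes the leave-one-out PRESS loop and the coefficient
reconstruction transparent. X and y are mean-centered but **not**
variance-scaled: for derivative spectra the per-channel amplitude carries
information. For a univariate response the inner loop converges after one
pass; the iteration cap (500) and tolerance (1e-12) only matter for
degenerate inputs. The coefficient vector `b = W(PᵀW)⁻¹q` reproduces the
factor-by-factor score recursion to machine precision (tested), and at full
rank the predictions coincide with ordinary least squares (tested against a
direct solve, and against an independent PLSR implementation at every factor
count).

Leave-one-out PRESS refits every fold from scratch — one NIPALS
decomposition per fold at h_max factors, reading off the coefficient vector
at each smaller h — with no shortcut update formulas: correctness over speed
at desk scale (n ≤ ~330, p ≤ 240; the full suite runs in seconds).

Factor selection follows the Haaland–Thomas rule: with h* the PRESS
minimizer (smallest h on ties), select the smallest h ≤ h* whose ratio
PRESS(h)/PRESS(h*) does not exceed the upper critical value of an F
distribution with (n, n) degrees of freedom at probability α = 0.25. The
α default is the level recommended in the classical treatment of this rule;
PRESS(h*) = 0 short-circuits to h*. The dataset split is a uniform random
permutation at a 7:3 ratio under a user seed (unstratified by default; a
per-variety stratified option serves mixed-variety datasets).

## Validation metrics

RMSE is `sqrt(mean((ŷ−y)²))`. R² is `1 − Σ(y−ŷ)²/Σ(y−ȳ)²` and may be
negative for models worse than the mean predictor, which genuinely occurs in
cross-pigment transfer. RPD uses the n−1 sample SD of the test responses
(ddof exposed as an option). Slope and offset regress **predicted on
measured** (`ŷ ~ a·y + b`); bias is `mean(ŷ−y)` and satisfies |bias| ≤ RMSE.
A prediction R² exceeding the calibration R² by more than 0.15 attaches a
logged diagnostic note (it usually signals a lucky split), never an error.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the optics of real fruit tissue.

* **Constituents and bands.** Absorbance is a Beer–Lambert-style additive
  mixture of Gaussian bands: anthocyanin (505 nm plus a variety-shifted
  secondary at 550/560 nm), chlorophyll (673 nm), sugar (838, 952, 970,
  1168, 1187, 1459 nm) and water (976, 1075, 1416 nm), on a per-sample
  smooth baseline (offset + slope + curvature). Visible pigment bands are
  narrow (10–15 nm SD), NIR overtones broad (25–40 nm SD) so that
  second-derivative peaks resolve at the default window of 15 points. Band
  amplitudes are not fitted to any real fruit spectrum; they are set so the
  pipeline's qualitative findings are reproducible.
* **Variety profiles.** White fruit: SSC ~ N(10.04, 1.29²) % Brix, low
  anthocyanin, more chlorophyll, no pigment–ripeness correlation. Red
  fruit: SSC ~ N(8.13, 1.18²), high anthocyanin with correlation 0.8 to the
  sugar signal (pigment accumulates as the fruit sweetens). SSC draws are
  resampled (not clipped) at zero to preserve the normal shape.
* **Reference mismatch.** The refractometer reference reads whole-fruit
  juice while the spectra see the measured equator points; the generator
  separates the two with `reference_error_sd` = 0.35 % Brix. This is the
  error floor that dominates real fruit calibrations and puts the synthetic
  in-domain accuracy at a realistic R²p ≈ 0.9 / RPD ≈ 3 instead of the
  implausible near-perfect recovery a noiseless linear mixture would give.
* **Pigment-linked scattering gain.** The constituent bands are scaled by
  `g(λ) = 1 + 1.5 · anthocyanin · exp(−(λ−500 nm)/200 nm)`. Pigmented
  tissue absorbs and scatters visible photons differently, changing the
  effective optical path and hence the apparent depth of *every* band in the
  visible — this is what makes a visible-range calibration trained on one
  skin color misread the other. A pure additive mixture cannot express that
  failure: pigment bands are spectrally disjoint from sugar bands, so a
  white-trained model would simply ignore the pigment channels and transfer
  fine. The gain decays to nothing in the NIR, where pigments are
  transparent; the NIR instrument preset (`nir_sim_config`) carries
  `scatter_strength = 0` outright rather than an arbitrary residual tail.
* **Instrument noise.** I.i.d. Gaussian absorbance noise of SD 0.002 AU is
  added independently to each of 4 simulated replicate points before
  averaging, mirroring the four-point equator protocol.
* **Detector model (noise survey).** Mean counts = source·exposure; a
  single readout has variance read_noise² + shot_factor·counts; the reported
  intensity is the average of `integrations` readouts, simulated directly as
  a normal with the averaged SD. Dark frames carry read noise only. A
  configuration whose net intensity would go non-positive with probability
  above ~1e-6 per draw is rejected, protecting the log in the apparent-
  absorbance formula.

**What passing tests show — and don't.** The simulation-level results
(in-domain R²p ≥ 0.8 and RPD ≥ 2 at n = 180/150, factor selection in [3,5]
on 3-latent data, the visible-range transfer collapse with NIR retention)
demonstrate that the pipeline correctly extracts, selects and validates the
structure the generator puts in. They do not validate the generator against
real strawberry optics: multiplicative scatter beyond the single gain term,
temperature effects, nonlinear detector response and the true band shapes of
fruit tissue are all absent, so absolute numbers on real fruit will differ.

## Noise-level statistic

Apparent absorbance of repeat t against the first repeat t₀ is
`A(λ,t) = −log₁₀((W(λ,t)−D(λ,t))/(W(λ,t₀)−D(λ,t₀)))`; 20 repeats give 19
apparent spectra. After the second derivative, the per-wavelength SD over
the apparent spectra uses the N−1 denominator with N the number of apparent
spectra (19), and NL is the mean SD over the wavelengths inside the window —
834–872 nm (20 grid points at 2 nm) for the visible instrument, 1435–1552 nm
for the NIR instrument. Window selection intersects the nm interval with
the derivative-trimmed grid, and the point count is reported alongside NL so
the bookkeeping stays visible. NL is invariant to a common gain on all net
intensities (the gain cancels in the ratio), is exactly linear in an
injected absorbance perturbation, and for i.i.d. absorbance noise of SD s
equals s·‖c‖₂ with c the SG derivative coefficients — all three laws are
tested. Absolute NL values are detector-specific and are not comparable
across instruments.

## Problem sizes and determinism

Default study sizes follow the emulated experiment: 180 white and 150 red
fruit, 7:3 split, h_max = 12, 20 white-plate repeats per acquisition
condition; the Monte-Carlo noise-law checks use 100 repeats over 3 seeds per
condition. Every random quantity flows from named integer seeds through
`numpy.random.default_rng` / `SeedSequence`, so datasets, splits, fits and
summary tables are bit-for-bit reproducible; re-running any experiment
configuration reproduces its tables exactly (tested).

## Known limitations

* PLS1 only — a single response; no multi-response PLS2, variable selection,
  interval PLS or orthogonal signal correction.
* No spectral interpolation between grids: transfer requires identical
  wavelength grids by design, so cross-instrument transfer is out of scope.
* The F-rule's (n, n) degrees of freedom treat the LOO predictions as n
  independent errors, the classical approximation.
* The generator's scattering physics is a one-parameter gain, not radiative
  transfer; pigment chemistry is reduced to band positions and amplitudes.
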