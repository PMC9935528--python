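# Methods

## Scope and model

`gloriaqc` implements the curation computations for hyperspectral in situ
remote sensing reflectance datasets distributed in the GLORIA multi-file
CSV layout: reflectance assembly from radiometric components, a procedural
quality-control flag suite, per-spectrum shape metrics, visual-color and
optical-water-type summaries, and water-type-stratified outlier screening
of co-located water-quality measurements. A synthetic generator produces
datasets with known ground truth so every stage is testable without the
archive.

The central quantity is remote sensing reflectance

    R_rs(λ) = L_w(λ) / E_s(λ)        [sr⁻¹]

with L_w the water-leaving radiance just above the surface and E_s the
above-water downwelling irradiance, both on a 1 nm grid over 350–900 nm.
When L_w is not measured directly, the above-water assembly

    R_rs(λ) = (L_t(λ) − ρ·L_sky(λ)) / E_s(λ)

removes surface-reflected sky light from the tilted-view radiance L_t with
a surface reflectance factor ρ (default 0.028, the conventional flat-sea
value near 40° viewing; configurable). This assembly is a convenience for
working with component tables; the QC flags operate on R_rs directly.
Wind-speed- or geometry-dependent ρ models and in-water extrapolation of
L_u(0⁻) are out of scope.

## The flag suite

Flags are tri-state: 1 (issue present), 0 (test passed), NA (the spectrum
does not include the wavelength range the test needs, or a degeneracy such
as zero variance makes it undeterminable). All thresholds are strict
inequalities. Unless noted, tests run on the spectrum standardized to zero
mean and unit sample (n−1) standard deviation over its full non-missing
extent — standardization is global, not per window, so windowed statistics
refer to one common scale.

| Flag | Test |
|---|---|
| Noisy_red | degree-4 polynomial fit over 750–900 nm; RMSE > 0.2 |
| Noisy_blue | degree-4 fit over 350–400 nm; RMSE > 0.15 |
| Baseline_shift | see below; raw sr⁻¹ units |
| Oxygen_signal | oxygen A-band peak height > 0.1 |
| Negative_uv_slope | line fit over 350–420 nm; slope < −0.005 nm⁻¹ |
| QWIP_fail | \|QWIP score\| > 0.2 |
| Suspect | external expert judgment; accepted as input, never computed |
| Flagged | 1 iff any component (incl. Suspect) is 1 |

RMSE uses n (number of fitted points) in the denominator — the plain
root-mean-square of residuals, not a degrees-of-freedom-corrected
estimate. Polynomial fits map the window onto [−1, 1] internally
(numpy `Polynomial.fit`) so the degree-4 system stays well conditioned at
900 nm; coefficients are reported in raw wavelength.

**Baseline shift** works on raw reflectance because its slope threshold
(−8.75×10⁻⁷ sr⁻¹ nm⁻¹) carries physical units; it is deliberately not
scale-invariant. Shifted-up: min(R_rs)/median(R_rs) > 0.6 with a positive
median. Shifted-down: at least 20 negative values anywhere, together with
(a) raw 765–900 nm slope below the threshold and >50 % negative values in
that window, or (b) >70 % negative values in 765–900 nm, or (c) at least
20 negative values within 350–450 nm. The 20-negative gate counts over
whatever spectral extent exists; the up-shift median uses the full
non-missing spectrum, and a non-positive median makes that branch
undeterminable.

**Oxygen peak height**: standardize; anchor a straight baseline at
(750 nm, median of 745–755 nm) and (780 nm, median of 775–785 nm) — the
anchor abscissae are the window midpoints, the symmetric choice; report
the maximum absolute deviation from this baseline within 759–766 nm (a
window that brackets the O₂ A-band at 762 nm while staying clear of the
anchors; configurable). Sign-agnostic: calibration artifacts can imprint
as either a local peak or a dip.

**Coverage rule**: a flag is NA unless *every* integer wavelength of its
window(s) is present and non-missing. A spectrum spanning 400–750 nm (a
legitimate sub-range in these collections) therefore gets NA for
Noisy_red, Noisy_blue, Oxygen_signal and Negative_uv_slope, and 0/1 only
for tests whose windows it covers. Partial-window computation was rejected
because it silently changes what the statistic measures.

## Shape metrics

* **AVW** (apparent visible wavelength): Σ R_rs / Σ (R_rs/λ), discrete
  sums over 400–700 nm inclusive — the reflectance-weighted harmonic mean
  wavelength. Lies in [400, 700] for nonnegative spectra; undefined when
  the weighted sum is non-positive.
* **NDI**: (R_rs(665) − R_rs(492)) / (R_rs(665) + R_rs(492)), bands read
  at the integer grid wavelengths.
* **QWIP score**: NDI − P(AVW), where P is the published 4th-order
  quality-water-index polynomial (coefficients transcribed from Dierssen
  et al. 2022 and stored as named constants in `metrics.py`). Scores near
  zero indicate shapes on the central tendency of natural waters.
* All four metrics (including oxygen peak height) are invariant to
  positive scaling of the spectrum.

**Chromaticity** integrates R_rs against the CIE 1931 2° color-matching
functions over 400–700 nm. The packaged CMF table is the standard 5 nm
tabulation (380–780 nm) interpolated linearly to 1 nm. Each tristimulus
channel is normalized by its own CMF sum over the integration window
(equal-energy normalization), so a spectrally flat spectrum maps exactly
to the equal-energy white point (1/3, 1/3); with a single common
normalization constant the truncation of the CMF support to 400–700 nm
would displace the flat-spectrum locus by ~1 %. Hue angle is measured at
the white point. Only chromaticity coordinates are produced — no color
rendering.

**Optical water types** are assigned by nearest centroid under the
spectral angle on area-normalized spectra (Euclidean optional), with ties
broken to the lowest class id. Centroids are user-supplied: published
typologies differ in both centroids and membership rules, so the
classifier is a pluggable mechanism, not an attempt to reproduce any
specific class census.

## Water-quality screening

Chl a, TSS, a_CDOM(440) and Secchi depth are near log-normal within an
optical water type, so the screen works on log10 of positive values by
default (raw mode available). Within each (water type, variable) group the
mean and sample SD are estimated and values with |z| > k (default 3) are
flagged for reevaluation. Groups with fewer than two usable values or zero
spread yield NA. Non-positive values cannot enter the log transform and
are reported separately as data errors. The screen is advisory and never
mutates or removes records.

A structural point that matters for interpreting k: with a single extreme
value in a group of n, the achievable z is bounded by (n−1)/√n because the
extreme value inflates the group SD it is judged against. A k = 3 screen
can therefore only ever fire in groups of at least 12, regardless of how
extreme the value is.

## Synthetic data

Base spectra are strictly positive sums of a broad Gaussian peak
(450–620 nm, width 70–100 nm, magnitude 0.002–0.03 sr⁻¹), an optional
smaller secondary feature (540–700 nm), and a flat floor, damped by a
smooth logistic NIR falloff centered at 720 nm — shapes spanning clear,
turbid and eutrophic waters. Narrower peak widths are excluded from the
defaults because narrow spectra genuinely leave the QWIP envelope; they
are not "clean" spectra. Every candidate is verified against the full flag
suite with half-threshold margins (and |QWIP| ≤ 0.12) and redrawn on
failure, so the clean false-positive rate is zero by construction.

Artifacts are sized decisively — outside a ±50 % exclusion band around
each QC threshold — so the expected flag outcome is provable rather than
implementation-sensitive; ambiguous amplitudes are rejected at
construction. Two deviations from the generic ±50 % rule:

* the up-shift threshold is a ratio bounded above by 1, so its band is
  ±25 % (flag-1 plants target a min/median ratio of 0.8);
* the negative offset supports only decisive flag-1 sizing (≥1.5× the
  765–900 nm maximum); there is no amplitude at which a negative offset
  provably avoids every down-shift branch across base shapes.

Artifact mechanics, in raw units derived from the base spectrum's SD so
that standardized sizes come out as requested: random-sign noise in the
blue window (350–400 nm) or a red band (786–900 nm — deliberately past
the 785 nm oxygen anchor, because noise inside 759–766 nm would drive the
oxygen metric, itself a high-frequency detector, and make that label
ambiguous); a sub-nm-to-few-nm Gaussian bump at 762 nm; a linear UV ramp
anchored at zero at 420 nm that steers the fitted standardized slope to
the requested value; additive offsets. A strong positive offset flattens
the spectral shape (NDI → 0, AVW → 536 nm) and the QWIP score approaches
−P(536) ≈ +0.36, so its ground truth expects QWIP_fail = 1 alongside
Baseline_shift = 1 — the two tests agree that such a spectrum is wrong.

Every injected spectrum is re-checked against the flag suite at generation
time; if a side effect of the particular base shape contradicts the
constructed labels (e.g. noise tipping a borderline NIR slope), the base
is resampled. Ground truth is thus construction-defined and verified, and
the end-to-end agreement test exercises the full pipeline including file
round trips.

Water-quality values are drawn log-normally per water type with centers
chosen to mimic optically distinct water classes (e.g. Chl a medians of
~25 mg m⁻³ for algal-dominated vs ~0.5 mg m⁻³ for clear waters, σ ≈ 0.3
decades). One 4σ outlier per (water type, variable) is planted in groups
of ≥30 members, at mean + 4·SD of the *other* members on the log10 scale;
that makes the post-plant z a deterministic function of group size
(≥3.16 for n ≥ 30), so recovery at k = 3 is guaranteed rather than
probabilistic. Smaller groups receive no plant — see the z-bound above.

Determinism: all randomness flows from one `numpy` generator seeded by the
config (default seed 20230216); identical configs give byte-identical
outputs.

What the generator does *not* emulate: radiative-transfer realism,
instrument spectral response functions, correlated noise, bidirectional
effects, or the covariance between spectra and water-quality values.
Passing the synthetic recovery tests demonstrates that the flag logic,
thresholds, NA semantics and file plumbing are correct — not that the
thresholds are well calibrated for any particular instrument's data.

## Problem sizes and numerical choices

The synthetic recovery study uses 500 spectra (the default acceptance
scale) with a mixed artifact cycle in which roughly 40 % of spectra carry
an artifact; generation plus QC runs in a few seconds. Windows are
inclusive on both bounds on the integer grid. No extrapolation is
performed anywhere: resampling outside a spectrum's native range yields
missing values, which propagate to NA flags. Numeric CSV output uses up to
10 significant digits, making write→read round trips lossless at
float32-source precision. Ties in optical water type assignment break to
the lowest class id; equality at a QC threshold is a pass (strict
inequalities throughout).

## Known limitations

* Reproducing the per-flag counts of the published archive requires a
  local copy of the distribution (`data/gloria/`); exact equality also
  depends on under-specified choices in the original curation code (the
  standardization extent, the width of the 762 nm search window) that are
  recorded here as explicit parameters.
* The Suspect flag is expert judgment and is only ever passed through.
* The 3C-model reconstruction used for uncertainty analysis in the
  archive's provenance is an external algorithm and out of scope.
* The QWIP polynomial is trusted as published; no refit is attempted.
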