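# Methods

## Targets

Leaf water status is described by two gravimetric variables: equivalent
water thickness, EWT = (FW − DW)/A in g cm⁻², and fuel moisture content,
FMC = (FW − DW)/FW. FMC is carried internally as a fraction in (0, 1) and
multiplied by 100 only at I/O boundaries; mixing percent means with
fractional spreads, as field tables sometimes do, is a formatting ambiguity
the fraction convention removes. Validation enforces FW > DW > 0 and A > 0.

## Adaptive spectral absorption indices

An absorption feature is the triple (λ₁, λ_m, λ₂): left shoulder, peak,
right shoulder. The peak is the reflectance minimum of the feature and the
shoulders are the flanking maxima; the chord from (λ₁, ρ₁) to (λ₂, ρ₂) is
the nonabsorption baseline. Writing d = (λ₂ − λ_m)/(λ₂ − λ₁), the baseline
evaluated at the peak wavelength is exactly d·ρ₁ + (1 − d)·ρ₂ — this
identity (tested to 1e-12) is why the SAI can be written

SAI = (d·ρ₁ + (1 − d)·ρ₂)/ρ_m ,

a baseline-to-peak ratio, i.e. a relative absorption depth. SAI = 1 means
no absorption; deeper absorption raises SAI. The ratio is invariant under
multiplicative scaling of the spectrum (illumination level), which the
tests assert to 1e-12.

### Feature location

Windows (inclusive, nm): SAI_970 → [915, 1085], SAI_1200 → [1085, 1265],
SAI_1660 → [1630, 1690]. Shoulders are searched only near the window edges,
with ~25 % margins: left shoulder in [915, 940] / [1085, 1110] /
[1630, 1645], right shoulder in [1060, 1085] / [1240, 1265] / [1675, 1690].
The peak is the minimum over the open interval between the located
shoulders. All ranges are configurable (YAML config / constructor
arguments).

Numerical conventions:

* **Tie-break**: argmax/argmin ties resolve to the smallest wavelength —
  deterministic and independent of evaluation order.
* **Smoothing**: a Savitzky–Golay filter (15 nm window, quadratic) is
  applied *only to locate* the extrema; the reflectances entering the SAI
  are read from the raw spectrum at the located wavelengths. Location is
  noise-sensitive; values should stay faithful to measurement. Disable
  with `smooth=False` / `--no-smooth`.
* **Degenerate windows**: if the interior minimum lands adjacent to a
  shoulder there is no true dip; the feature is flagged invalid and the SAI
  is reported missing (downstream regressions drop the sample for that
  index, with a logged count). A perfectly flat window is the well-defined
  no-absorption case and evaluates to SAI = 1 exactly.

## Classical indices

Ten fixed-band indices are computed as comparators: WI = ρ900/ρ970,
SRWI = ρ858/ρ1240, NDWI_1240, RDI, RATIO_975, RATIO_1200, DWI, MSI, NDII
and GVMI (formulas in `leafwater/indices.py`). Band means are unweighted
arithmetic means over integer wavelengths, inclusive at both ends, exact on
the 1-nm grid. The DWI baseline is the two-point line through (850, ρ850)
and (1080, ρ1080) evaluated at 970 and 1200 nm. The RDI minimum is searched
over [1120, 1150]; the literature is inconsistent between 1150 and 1250 as
the upper end, and the range is config-overridable. Note RDI can be
slightly negative on spectra with measurement noise but no absorption in
its search range; it is only guaranteed non-negative when a genuine dip is
present.

## Spectra handling

Input CSVs (wide or long layout) are validated, optionally percent-rescaled
(auto-detected when max > 1.5, logged), linearly resampled to the integer
1-nm grid spanning the input range (no extrapolation; idempotent on 1-nm
input), and replicate readings per leaf are averaged pointwise (the mean
is computed with exactly rounded summation, so it is bit-identical under
replicate reordering). Missing interior wavelengths are bridged by linear
interpolation only for gaps ≤ 5 nm; wider gaps are an error, since
interpolating across them could invent or erase a feature. Reflectance
outside [0, 1] warns; outside [−0.05, 1.2] is rejected.

## Cross-validated evaluation

Folds: a seeded random permutation dealt round-robin into k = 10 folds
(sizes differ by at most one; n = 292 gives eight folds of 29 and two of
30). No stratification by species by default; a stratified option exists.
Forms: linear, quadratic and exponential y = a·e^{bx}; the exponential is
fitted by nonlinear least squares initialised from the log-linear solution.

R²cv is the squared Pearson correlation between pooled out-of-fold
predictions and observations. The alternative 1 − SSE/SST definition is
available (`r2_variant="sse"`); the two differ when the out-of-fold
predictions are biased, and the correlation form was chosen as the default
because it matches the common usage of a "cross-validated coefficient of
determination" for index calibrations. rRMSEcv = RMSEcv / mean(observed),
with RMSE over the same pooled out-of-fold pairs; tests recompute it
independently from the per-fold prediction table.

Significance gate: the ranking report marks an index "n.s." when the
overall F-test of its best-form full-data regression has p ≥ 0.05. For
linear/quadratic this is the OLS regression F-test (statsmodels); for the
exponential form the F statistic is built from the nonlinear fit's R² with
1 model degree of freedom. Reported equations round coefficients to 3
decimals; machine outputs keep full precision.

The prediction-similarity analysis reports the squared correlation between
two indices' out-of-fold prediction vectors under a shared fold plan. Its
null level is not zero: prediction vectors have roughly k effective degrees
of freedom, so for unrelated indices the similarity is O(1/(k−1)).

## Synthetic data generator

Spectra are generated on the 350–2500 nm grid as

ρ(λ) = C(λ) · (1 − Σ_k D_k · exp(−(λ − μ_k)²/(2σ_k²))) + ε(λ),

clipped to (0.001, 1). The continuum C rises sigmoidally 0.05 → 0.48
across the 700–760 nm red edge (logistic, midpoint 730 nm, scale 8 nm) and
declines linearly by 10⁻⁴ per nm beyond 1300 nm. Water dips sit at
μ = 970, 1200, 1450, 1950 nm with depths proportional to EWT — at the
reference EWT of 0.010 g cm⁻² they are 0.06, 0.12, 0.55, 0.75, capped at
0.95 — and the dry-matter dip at 1660 nm has depth 0.08·(1 − FMC)/0.40.
Per-leaf heterogeneity enters as independent Normal(0, jitter) shifts of
each dip centre (default σ = 5 nm) plus i.i.d. Normal(0, 0.002) reflectance
noise.

Widths (σ, nm): 970 → 35, 1200 → 12, 1450 → 60, 1950 → 90, 1660 → 12. The
narrow 1200 nm width is a deliberate design choice, representing the sharp
core of that absorption feature: with Gaussian dips on a smooth continuum,
a 40-nm fixed band *mean* is second-order insensitive to small centre
shifts, so a broad dip would make the fixed-band RATIO_1200 effectively a
matched filter that no adaptive index can beat. A narrow core shifted by a
few nm loses part of its mass from the fixed band to first order, while the
per-leaf peak search tracks it — the heterogeneity mechanism adaptive
indices exist for, and the regime in which the generator exercises it.

The default study design is three species — VJ (n=46, EWT 0.006–0.010
g cm⁻², FMC 57.4–67.2 %), VL (n=66, 0.006–0.013, 62.6–77.5 %), VX (n=180,
0.008–0.016, 45.16–82.72 %) — with EWT/FMC drawn uniformly per species.
Gravimetric metadata is back-solved (A ~ U[10, 40] cm², FW = EWT·A/FMC,
DW = FW − EWT·A) so the EWT/FMC formulas recover the drawn truths to
1e-12. Everything is deterministic given the seed.

What the generator does *not* emulate: radiative-transfer realism
(no leaf-structure scattering model), visible-region pigments, asymmetric
or non-Gaussian feature shapes, instrument artefacts (detector joins,
water-vapour noise bands), or correlated noise. Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under controlled
heterogeneity, not field-data accuracy; absolute R²cv values on synthetic
data are cleaner (higher) than typical field results.

## Problem sizes

Tests and the acceptance script use the full default study (n = 292
spectra, 2151 wavelengths each); the whole suite runs in a few seconds and
the acceptance script in under half a minute on one CPU.

## Known limitations

* Shoulder search margins are a design choice (the feature windows
  themselves do not dictate them); pathological spectra whose true
  shoulders fall outside the margins get biased baselines. The margins are
  config-exposed.
* The exponential form can be ill-conditioned when the index range is far
  from zero; the log-linear initialisation handles the usual index ranges
  (≈ 0.8–1.3) but extreme inputs may fail with a clear error.
* Per-species fits use the full data (no nested CV); the species analysis
  is about slope transferability, not out-of-sample accuracy.
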