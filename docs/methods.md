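# Methods

This note documents the models, defaults and design choices behind
`meatspec`: what the synthetic spectra emulate, how each dimension-reduction
method and calibration model is defined, and which numerical conventions fix
the package's exact outputs.

## Synthetic data

### Composition sampler

Each sample's composition closes a mass balance,
`protein + fat + moisture + residual = 100 %`, where the residual is the
non-water/protein/fat remainder (ash, glycogen, minerals).

* **Protein** — truncated normal, mean 19.72 %, CV 6.61 % (SD ≈ 1.30),
  range [14.85, 23.02] %.
* **Fat** — truncated lognormal on [0.55, 16.13] %. The lognormal (μ, σ) are
  calibrated by nested root finding so that the *truncated* distribution has
  mean 3.55 % and CV 88.42 %; matching the untruncated moments and then
  truncating would lose ≈ 20 CV points to the upper cut and the generated
  tables would not show the dispersion they are meant to emulate. The
  resulting σ ≈ 1.05 gives the strong right skew typical of intermuscular
  fat across mixed cuts.
* **Residual** — truncated normal, mean 1.70 % (the value that closes the
  balance at the component means), SD 0.15.
* **Moisture** — the closure remainder, clipped at the top of
  [64.94, 78.70] % with the residual absorbing the clip. Low-side clipping
  can never occur because each sample's fat draw is additionally bounded
  above by `100 − protein − residual − 64.94`; without that bound a large
  fat draw would force a negative residual and push the three reported
  components above 100 %. The per-sample bound binds for ≈ 1–2 % of samples
  and adds a small extra truncation bias to fat, accepted and noted here.

At the degenerate zero-dispersion configuration every sample is exactly
(19.72, 3.55, 75.03). At n = 1000 the sample means of all three components
fall within two standard errors of the configured means.

### Forward optical model

Ideal absorbance is a Beer–Lambert mixture of Gaussian bands over a smooth
baseline:

```
A_i(λ) = baseline(λ) + Σ_b strength_b · conc_i(comp_b) · exp(−(λ−c_b)²/2w_b²)
R_i    = 10^(−A_i)
obs_i  = add_i + mult_i · R_i + ε,   mult_i ~ N(1, 0.07), add_i ~ N(0, 0.012),
                                     ε ~ N(0, noise_sd) per channel
```

Default bands (center nm / σ nm / absorbance per % of component):

| component | bands |
|---|---|
| moisture (O–H overtones) | 760/22/0.0016, 980/28/0.0042, 1450/42/0.011 |
| fat (C–H overtones) | 960/24/0.0045, 1180/32/0.016, 1210/26/0.014 |
| protein (N–H overtones) | 910/28/0.006, 1080/32/0.011, 1450/50/0.004 |
| pigment (myoglobin/oxymyoglobin) | 415/12/0.30, 540/11/0.13, 580/11/0.12 |

The pigment "concentration" is a latent mean-1 lognormal factor (σ = 0.18)
drawn independently of the three targets, so the visible-region troughs at
415/540/580 nm are realistic but carry no composition information by
construction. The mean spectrum of a default dataset shows troughs within a
few nm of 415, 540, 580, 760 and 980 nm in region 1, and the per-wavelength
correlation of scatter-corrected reflectance with fat is opposite in sign to
that with moisture wherever moisture absorption carries signal — both
consequences of the band layout plus the compositional fat/moisture
trade-off, not of any fitted parameter.

Instrument grids: region 1 spans 400–1050 nm with exactly 1130 points
(≈ 0.5757 nm spacing) — the point count is primary because all decimation
arithmetic depends on it; region 2 spans 900–1700 nm with 125 points
(≈ 6.452 nm spacing, both endpoints on the grid, slightly wider than the
nominal 6.25 nm an instrument datasheet would quote for this range).

**Channel noise (`noise_sd = 0.004` reflectance units)** sets where
decimation starts to hurt: white noise averages out over many channels but
not over few, so prediction quality is flat down to ~100 retained channels
and collapses near 10. This knee — stability until the sampling interval
reaches a few nm, then sharp deterioration — is the behaviour real
meat-spectroscopy decimation studies report, and 0.4 % channel noise places
it there. The per-sample affine scatter magnitudes (7 % multiplicative,
0.012 additive) are set large enough that SNV/MSC visibly help, as they do
on real diffuse-reflectance spectra of intact tissue.

Everything is deterministic under a single integer seed; the composition
table and the two regions use child seeds spawned from it. Observed
reflectance is floored at 1e−6 so logarithms and ratios stay defined.

### What the generator does *not* emulate

No Kubelka–Munk/radiative-transfer physics, no instrument line-shape or
wavelength-registration error, no temperature-dependent band shifts, no
carcass/cut stratification (samples are one mixed population). Passing tests
on this generator show the *pipeline* behaves correctly under a realistic
correlation/scatter/noise structure; they do not certify prediction
accuracies on real meat, where model mismatch (nonlinearity, band shifts)
dominates and correlations around 0.7–0.9 rather than 0.99 are typical.

## Pretreatments

* **SNV** — per-spectrum standardization with the n−1 standard deviation
  denominator (a documented convention; it fixes exact test values and
  nothing downstream).
* **MSC** — per-spectrum OLS against a reference spectrum, corrected as
  (x − a)/b. The reference is the **calibration-set mean**; prediction
  spectra are always corrected against that stored reference, never their
  own mean, so no prediction-set statistic leaks into the features. A
  fitted |b| < 1e−8 raises an error naming the sample.
* **Savitzky–Golay** — scipy's `savgol_filter` with `mode="interp"`:
  interior points get the standard least-squares kernel; each edge point is
  the edge-window polynomial evaluated in place, so the grid never shrinks.
  Defaults: window 11 / order 2 in region 1 (≈ 6 nm) and window 5 / order 2
  in region 2 (≈ 26 nm) — wide enough to smooth, narrower than any band.

Pretreatments are fitted on the calibration set and applied to both sets,
and always precede dimension reduction.

## Dimension reduction

* **Correlation thresholding** uses |r| ≥ t (boundary ties included — a
  measure-zero choice documented for reproducibility). Profiles are computed
  on the calibration set only, after MSC, so scatter does not masquerade as
  chemical correlation. Constant columns get an undefined marker and are
  excluded from thresholding.
* **Stepwise regression** is bidirectional partial-F selection with
  α_enter = 0.05, α_remove = 0.10, at most 30 entry steps. Candidates whose
  residual (after projection onto the current design) falls below 1e−8 of
  their column norm are skipped, so perfectly collinear duplicates can never
  both enter. Selection stops early once the fit is numerically perfect.
* **Decimation** keeps grid indices k−1, 2k−1, …, i.e. exactly ⌊p/k⌋
  points — this indexing (rather than 0, k, …, which keeps ⌈p/k⌉) reproduces
  the canonical reduced-set sizes for both grids (565/376/282/113/94/56 from
  1130; 62/41/…/5 from 125). Default factor lists:
  region 1 {1, 2, 3, 4, 10, 12, 20, 30, …, 100 step 10}, region 2 {1…24}.
* **JFPT** detects extrema on the **calibration mean spectrum** (per-sample
  detection would give ragged feature matrices), optionally after S-G
  pre-smoothing (on by default in the harness). Candidates are
  first-difference sign changes; those with prominence below
  `2 × median |Δmean|` (scale-adaptive default) are discarded; alternation
  is enforced by keeping the more extreme of any same-kind run. Features are
  R(peak) − R(trough) for each adjacent pair — offsets added to a whole
  spectrum cancel exactly. Jump count = extrema count − 1.

## Calibration models

* **PLSR** is PLS1 (each target modelled separately) via NIPALS with
  mean-centering only — spectra share a physical scale, so unit-variance
  scaling is not applied. At full rank the coefficients coincide with OLS
  (tested to 1e−6). Component collapse (requesting more components than the
  centred rank supports) raises an error reporting the achievable count.
* **Latent-variable count**: 5-fold cross-validation (shuffled, seeded),
  maximum 15 components, one-standard-error rule — the smallest count whose
  CV RMSE is within one SE of the minimum. On pure noise this selects 1; on
  a noiseless rank-2 response it selects 2.
* **MLR** is OLS with intercept; rank deficiency is detected by pivoted QR
  and reported with the offending columns.
* **SEC/SEP** are plain RMSE without a degrees-of-freedom or
  latent-variable correction (some chemometrics texts subtract LV + 1 from
  the denominator; the plain convention is documented here so the numbers
  are unambiguous). R_C/R_P are Pearson correlations of predicted vs
  measured; a constant side is reported as r = 0.
* **Split**: Kennard–Stone at a 3:1 ratio on the region-1 raw spectra
  (deterministic; seeds with the two mutually farthest samples, then
  repeatedly adds the max–min-distance sample, ties to the lowest index;
  ⌊0.75 n⌋ calibration samples). One split is computed per dataset and
  shared by every model cell, so method comparisons are paired. A seeded
  random split is available as an alternative.

## Study harness

Four experiments mirror the comparison designs:

1. full-spectrum PLSR: 2 regions × 3 targets × 4 pretreatments = 24 cells;
2. correlation-threshold PLSR: thresholds {0.3, 0.4, 0.5} in region 1 and
   {0.1, 0.2, 0.3} in region 2 (the coarse region's correlations are
   weaker) = 18 cells;
3. SWR-MLR and JFPT-MLR on raw spectra: 12 cells;
4. decimation sweep for fat: metrics vs factor k per region and
   pretreatment.

Failed cells (e.g. an empty selection at a high threshold) are recorded with
an error marker, never dropped. The report marks the best cell per
region × target by highest R_P with lower SEP as tie-break. All harness
output is reproducible byte-for-byte from (seed, config).

## Acceptance conditions

The acceptance suite and `scripts/acceptance.py` run at the default study
conditions: n = 150, the default bands, noise and scatter above, and a
fixed seed. Under these conditions full-spectrum PLSR reaches R_P ≥ 0.9
for moisture and protein and ≥ 0.85 for fat (best pretreatment arm);
decimation keeping ≥ 100 channels moves the best-arm fat R_P by < 0.05,
while ≤ 13 channels degrades it far below the sweep optimum. The exact
margin of the mild-decimation check varies a few hundredths across seeds
(CV-chosen component counts are discrete); the check is defined at the
seeded default conditions. The planted-truth selection check uses a
variant generator — the only moisture band at 980 nm, visible pigment bands
as distractors, scatter retained but channel noise off — under which
stepwise selection must place a wavelength within 15 nm of 980. With
channel noise *and* scatter both zero that check would be ill-posed: every
channel with any moisture sensitivity is then a near-perfect linear
correlate, and the selection legitimately prefers the faintest (most
linear) channel over the band centre.

## Known limitations

* The generator's linearity means PLSR/MLR can approach R ≈ 0.99 at the
  default noise; real-tissue nonlinearity is not represented, so absolute
  accuracies are optimistic even though method *orderings* and the
  decimation knee are meaningful.
* Stepwise selection inherits the usual instability of greedy F-tests on
  collinear spectra: selected wavelength lists vary across seeds even when
  predictive performance does not.
* `choose_n_latent`'s one-SE rule is deliberately conservative; with very
  small calibration sets it can under-fit (more so below ~50 samples).
* Region 2's grid uses 6.452 nm spacing to honour both endpoints and the
  125-point count; selections are serialized in physical nm, so this
  convention does not leak into downstream artifacts.
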