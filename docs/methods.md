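# Methods

This note documents the models and procedures implemented in `nirleaf`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data generator does and does not emulate.

## Calibration model

### Preprocessing

Each leaf is scanned several times on the same spot; scans are averaged
per `(sample, state)` after splice correction. Splice correction removes
the artificial steps a multi-detector spectroradiometer leaves at its
detector boundaries: for each boundary, the entire later segment is
shifted by a constant so that the first value after the boundary equals
the last value before it, with the first segment as the anchor and
corrections composing left to right. This additive form is the simplest
correction that leaves every within-segment difference — and hence every
band shape — untouched. The boundary wavelengths default to 1000 and
1800 nm, the conventional VNIR/SWIR-1/SWIR-2 detector limits of a
three-detector field instrument; they are configurable because
instruments differ. Corrected values that leave the admissible range are
clipped into (1e−6, 1] (count logged) so that downstream logarithmic /
absorbance transforms remain defined.

### Kennard–Stone split

Calibration and validation sets come from the Kennard–Stone algorithm:
seed with the two samples at maximum Euclidean distance, then repeatedly
add the sample whose minimum distance to the selected set is largest,
until `round(fraction × n)` (round-half-up; default fraction 0.5) samples
are selected. Distances are computed on the full preprocessed spectrum —
after splice correction and replicate averaging, before any region
subsetting — so that one split is shared by all candidate region sets and
their validation scores are comparable. No autoscaling is applied before
the distance computation: reflectance shares units across wavelengths.
Ties (equal distances) are broken toward the smaller original row index,
making the split fully deterministic; all randomness in the workflow
lives in the region search.

### PLS1 core

The regression engine is single-response partial least squares (PLS1),
with components extracted sequentially NIPALS-style. With one response
the weight update has a closed form, `w ∝ X'y`, so no inner iteration is
needed and the fit is exactly reproducible. Predictors and response are
mean-centered with training means; unit-variance scaling is available
behind a flag but off by default, again because reflectance shares units.
Extraction stops early (with a logged note) if the residual covariance or
score norm falls below a relative tolerance of 1e−10, e.g. on rank-
deficient predictor blocks. The regression vector for k components is
`B_k = W_k (P_k' W_k)^{-1} q_k`, which also gives cheap truncated
predictions for every k from one fit — used for component selection.

The component count is chosen to minimize validation RMSEP, with ties
toward fewer components; the ceiling is 10 (a conventional chemometrics
default), further capped by `min(n_cal − 1, p)`. Validation-based
selection was chosen over cross-validation because the workflow already
maintains a dedicated validation set and reuses it to rank region
candidates.

### Randomized region search

Informative NIR bands occupy narrow wavelength windows; restricting the
predictor block to a union of windows often beats the full spectrum. The
search is randomized rather than exhaustive: each iteration draws a
window count uniformly in 1..8, then that many windows with width uniform
in [20, 250] nm and uniform on-grid start, merging overlaps. The width
cap matters: with unbounded widths the union of up to eight windows
almost always merges into one near-full-span interval and the search
degenerates; 250 nm keeps candidate unions genuinely partial while still
covering multi-band features. The minimum width of 20 nm keeps windows
wider than the instrument's effective resolution.

Every run evaluates the full spectrum as iteration 0, so the reported
winner (lowest validation RMSEP; ties broken by higher R², then earlier
iteration) can never be worse than the full-spectrum baseline. With
`n_iterations = 0` the baseline model itself is returned. The default of
200 iterations saturates on the synthetic designs (the winning RMSEP
stops improving well before 200 draws at 240 samples).

### Response transform

Leaf N under a factorial fertilization design is right-skewed; the
calibration models `ln(leaf N)` and back-transforms predictions with
`exp`. Model selection and the reported metrics operate on the
transformed scale, so an RMSEP for leaf N is in ln-units. Leaf P is
modelled untransformed. Both transforms are explicit, serialized with the
model, and validated (the log transform refuses non-positive responses,
naming the offending sample).

### Outlier screen

A univariate F test on calibration residuals: `F_i = e_i² / s²_(−i)`,
where `s²_(−i)` is the mean squared residual with sample i deleted,
compared against the 99.9th percentile of F(1, n−2). The deletion
variance makes a single gross outlier unable to mask itself by inflating
the pooled variance. Flagged samples are reported but *not* removed by
default — removal is an operator decision, modelled as an explicit
confirmation step (`confirm_removal` / `--remove-outliers`); confirming
removal refits the winning configuration (component count re-chosen)
without the removed samples. With all residuals zero, nothing is flagged
(the 0/0 ratio is defined as 0). The screen runs once, on the winning
model's calibration residuals, after the region search: running it per
candidate would let the search trade outliers against regions and make
candidates incomparable.

### Metrics

`R² = 1 − SS_res/SS_tot` (coefficient of determination of predictions
against observations) and `RMSEP = sqrt(mean((obs − pred)²))`, both on
the validation set and on the transformed scale. R² in the spectroscopy
literature sometimes means squared Pearson correlation instead; that
variant is reported alongside (`r_pearson_squared`) but never used for
selection. With constant observations R² is undefined and an error is
raised.

## Group statistics

The conservation and storage experiments compare predicted leaf N across
groups and sources:

* **Kruskal–Wallis** from its rank definition: mid-ranks over the pooled
  sample, `H = 12/(N(N+1)) Σ n_i (R̄_i − (N+1)/2)²`, divided by the tie
  correction `1 − Σ(t³−t)/(N³−N)`; p-values from the χ² approximation
  with k−1 degrees of freedom regardless of group size (the designs here
  have small groups; a seeded Monte-Carlo permutation p-value is
  available via `exact=True` for n ≤ 10 per group). The all-tied
  degenerate case is guarded to H = 0, p = 1.
* **Dunn's post-hoc test**:
  `z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
  two-sided normal p-values, Holm-adjusted across all unordered pairs by
  default ("none" available); the adjustment is recorded in the output.
  Dunn is only invoked when the preceding Kruskal–Wallis is significant
  at α = 0.05.
* **Pearson correlation** from its product-moment definition, with an
  explicit error on constant input.

The four-source comparison (fresh / dried / treated predictions,
laboratory values) treats the four measurements of the same specimens as
independent groups. That ignores the pairing, but it is replicated as the
analysis it mirrors specifies it, not "fixed".

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions under which the workflow is validated.

### Traits

Leaf traits respond to fertilization through a saturating curve
`trait = a + b·F/(K + F)` with species-specific parameters (leaf N
baselines 1.1–1.3 % dry mass, gains 2.2–2.6, half-saturation 55–65
kg ha⁻¹ yr⁻¹; leaf P baselines 1.4–1.6 mg g⁻¹ with smaller relative
gains), times lognormal individual variation (sd 0.10 ln-units for N,
0.12 for P). The resulting ln(leaf N) distribution over the 4×4 factorial
is roughly symmetric — which is what motivates the log transform.
Wet-lab reference values are ground truth times independent lognormal
assay noise (sd 0.10 ln-units for both traits, representing combustion /
digestion error plus the mismatch between the scanned leaf spot and the
milled tissue fraction actually assayed). Because assay noise is
independent of the spectra, calibration R² is bounded below 1 even with
noiseless spectra, as in real data.

### Spectra

A Beer–Lambert-style forward model: absorbance is a smooth baseline plus
Gaussian bands whose depths scale with a driver value — leaf N bands at
1510, 2054 and 2180 nm (conventional protein/N–H assignments), weaker
leaf P bands at 1680 and 2380 nm, O–H water bands at 1450 and 1940 nm
(driver ≈ 6 for fresh leaves, 0.5 for dried, with per-leaf lognormal
variation), and two broad constant bands shaping the dry-matter baseline.
Reflectance is `10^(−A)` with per-scan multiplicative scatter (random
slope and offset, sd 0.02), additive noise (sd 0.006 per point), and
random detector-boundary steps (sd 0.003) that the splice correction then
removes.

Noise levels and band amplitudes were calibrated once so that the
dried-leaf N calibration attains validation R² ≈ 0.7 (RMSEP ≈ 0.17–0.18
ln-units) and leaf P ≈ 0.5 at the full design size — the quality regime a
greenhouse NIRS calibration of these traits realistically reaches — and
frozen. The P signal is deliberately weaker than N (about half the
absorbance signal-to-noise), reflecting the lower content and weaker
spectral expression of P in leaf tissue.

### Experiment designs

* **Fertilization**: 3 species × 16 N×P level combinations × 5
  individuals = 240 plants, each with paired fresh and dried spectra, 3
  replicate scans per state, and a wet-lab reference table.
* **Conservation treatments**: 40 field specimens of one species; six
  treated groups of 5 (freezing, drying, pesticide and their
  combinations) plus 10 untreated controls — seven groups in total.
  Treated-state spectra are the measured dried-state scans plus a smooth
  per-leaf perturbation (offset, slope and one random broad bump, sd
  0.008 reflectance) standing in for surface change and probe placement;
  the chemical treatment effect is zero by default, encoding the null
  hypothesis the experiment tests. An effect-size knob shifts leaf N in
  one designated group for power studies.
* **Storage re-scan**: 50 dried specimens (the source study does not
  state its count; 50 is a realistic herbarium subset) scanned in two
  sessions with unchanged chemistry. The session scanned by a different
  operator (t0 by default) additionally gets a per-specimen path-length
  distortion, `R → R^γ` with `γ` lognormal (sd 0.15): physically a
  probe-contact/pressure change that rescales apparent band depths. A
  distortion of this multiplicative form was chosen over an additive
  affine one because band-depth rescaling is what actually biases
  predictions; additive offsets are largely orthogonal to the regression
  vector and would leave session correlations implausibly high.

### What the generator does not emulate

Real leaf spectra contain many more constituents (cellulose, lignin,
pigments), wavelength-correlated noise, and species-specific surface
effects (trichomes, cuticle gloss) that are not modelled; the generator's
interferences are water content, smooth scatter and white noise. Passing
tests therefore show that the workflow recovers traits under a faithful
but simplified optical model with realistic noise magnitudes — not that
any particular R² will be reached on a given instrument or flora.

## Pipeline and reproducibility

`run_all` executes the three experiments under one master seed, split
into per-stage seeds via `numpy.random.SeedSequence(master).generate_state`
(each reduced mod 2³¹). Experiment 1 fits the four calibrations (leaf N
with log transform and leaf P untransformed, each on fresh and dried
spectra); its dried-leaf N model is the *reference calibration model*
applied, unchanged, to the conservation and storage datasets — mirroring
the workflow in which one greenhouse calibration serves all downstream
herbarium predictions. All artifacts (model JSONs at full double
precision, iteration logs, prediction CSVs, reports) are written
deterministically: two runs with the same master seed are byte-identical.

Problem sizes in the test suite and acceptance script are the full
designs above (240 / 40 / 50 specimens); repeated-replicate studies (e.g.
the 500-replicate type-I-error check) use one scan per leaf instead of
three, which leaves the tested statistic's null distribution unchanged.

## Known limitations

* The additive splice correction assumes the detector step is constant
  across the segment; instruments with multiplicative inter-detector
  mismatch would need a ratio-based correction.
* The region search optimizes validation RMSEP directly, so the reported
  validation metrics of the *winning* model are mildly optimistic
  (selection bias); an untouched third set would be needed for fully
  unbiased error estimates.
* PLS1 only: traits are calibrated independently; no PLS2, kernel or
  sparse variants.
* The Kruskal–Wallis χ² approximation is used at small group sizes by
  default (matching the analysis it replicates); the permutation option
  exists but is not the default.
* Predictions carry no uncertainty intervals.
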