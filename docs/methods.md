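# Methods

This note documents the models, numerical choices and limitations behind
`teaspec`, in the spirit of a model-documentation page: what each component
assumes, which knobs matter, and what the synthetic study does and does not
establish about real data.

## The synthetic study

### What it emulates

A three-step tea-processing line — fresh-leaf spreading (FLS), steaming
fixation (SF), hot-air drying (HD) — sampled as 30 batches × 3 replicates
per step (270 samples), each measured as a 951-channel VNIR reflectance
spectrum over 400–1000 nm (uniform grid, endpoints inclusive, ≈ 0.63 nm
spacing) with a wet-chemistry TFAA reference value.

Spectra follow a Beer–Lambert-style attenuation model

```
r(λ) = albedo · exp(−Σ_k c_k · profile_k(λ))  + nuisance terms
```

with three unit-normalized Gaussian-band absorption profiles:

* **analyte** — bands at 947 nm (O–H first overtone) and 1000 nm (N–H
  stretch); its coefficient is `analyte_absorptivity × TFAA`, so the
  spectrum responds linearly in absorbance (and, for small coefficients,
  near-linearly in reflectance) to the property of interest;
* **pigment** — a broad Soret-like blue band (430 nm, σ = 40 nm), a weak
  green shoulder (530 nm, amplitude 0.08) and the chlorophyll red band
  (670 nm, σ = 45 nm). Together these carve the two reflectance peaks seen
  in leaf material, in the 500–600 nm and 750–950 nm windows;
* **water/background** — the 970 nm water overtone with a minor 760 nm
  feature; it deliberately overlaps the analyte's 947 nm band so that
  wavelength selectors have genuine interference to disentangle.

Nuisance terms are applied per sample: polynomial baseline drift (degree 2,
coefficient sd 0.004), multiplicative scatter (slope sd 0.03), additive
offset (sd 0.005), iid channel noise (sd 0.002), and compositional jitter
of the pigment/water coefficients (sd 0.10 / 0.04 around means 2.2 / 0.5).
Reflectance is clipped into (0, 1] and clip events are counted in the
provenance record (a handful per 256k values at the defaults). TFAA is
drawn per step from N(4.0, 0.5²), N(3.8, 0.5²), N(4.0, 0.5²) — levels
similar across steps with a slight dip at the middle step, floored at
0.05 %.

The within-step spread and the nuisance magnitudes are not published for
studies of this kind; the defaults were chosen once so that a well-pretreated
full-spectrum PLSR lands in the "highly credible" RPD regime reported for
such calibrations, and are exposed in `SimulationParams` rather than
claimed as properties of any real data.

`SimulationParams.noiseless()` switches every stochastic term off, making
spectra a deterministic function of TFAA — the configuration used by
exactness tests. (The compositional jitter is part of "noiseless off" even
though it is conceptually composition, not noise: determinism in TFAA is
the property the tests rely on.)

### Planted ground truth

Channels where the analyte profile reaches ≥ 50 % of its maximum are
recorded as `planted_band_indices` (116 of 951 at the defaults, spanning
≈ 927–1000 nm). In the noiseless configuration, an OLS fit of TFAA on the
planted-band reflectances attains R² = 1 to ≈ 1e-9: reflectance is
exponential in TFAA, but the planted bands carry many distinct
absorptivities, and their span captures the exponential's curvature far
beyond the linear term. The test asserts R² > 1 − 1e-6 rather than literal
equality for this reason.

For selector benchmarking at a controlled size, `make_planted_benchmark`
generates smooth correlated random spectra (Gaussian-filtered white noise
plus an independent component) with exactly `n_planted` informative bands
and `y` an exact linear function of them.

### What passing tests do not show

The generator has no spatial texture, no moisture kinetics across steps, no
instrument drift between sessions, and interferent variation far simpler
than real leaf matrices. Absolute performance numbers (R² ≈ 0.98–0.99 for
the headline pipeline) therefore exceed what the same pipeline achieves on
real processing-line spectra; the tests establish correctness and relative
behavior of the methods, not field-level accuracy.

## Reference chemistry

The ninhydrin assay standard curve is an OLS line of analyte mass `C0`
(mg) on absorbance at 570 nm. TFAA as % dry mass is

```
TFAA% = 1e-3 · C0 · V1 / (M · m · V2) · 100
```

with V1 the total test-solution volume (mL), V2 the aliquot used (mL), M
the specimen mass (g) and m the dry-matter content. `m` is entered as a
percentage and applied as a fraction (m/100): the fractional reading is the
one that produces the expected ≈ 4 % TFAA at protocol values (0.25 g
sample, 1 mL volumes, ~95 % dry matter). V1 is an explicit input, never
hard-coded, because extraction and post-reagent volumes differ (1.0 vs
2.0 mL) and protocols vary in which one they report.

## Pretreatments

All four transforms are fit-on-calibration / apply-anywhere: MSC stores the
calibration-mean reference spectrum, CT the per-band calibration means; SG
and D1 are parameterless filters. Defaults: SG window 11 / order 2, D1
window 7 / order 2 (common chemometric practice; both exposed). D1 is a
Savitzky–Golay derivative scaled by the channel spacing (units per nm)
rather than simple differencing, for noise robustness; it is applied
standalone, not to pre-smoothed spectra. Edge channels use polynomial
extrapolation of the terminal windows. Chains of length one are the
default study design; arbitrary chains are supported, with each step fitted
on the output of the previous one.

Which eight edge channels to drop in the 951 → 943 refinement is a
convention; the default is a symmetric 4 + 4 trim, since sensor noise
concentrates at both grid ends, and is overridable.

## SPXY splitting

The additive form of the joint distance is used (normalized spectral
distance plus normalized response distance), with the two normalizers being
the dataset maxima. Selection is greedy max-min seeded with the maximum
distance pair; all ties break toward the lowest original row index, making
the split fully deterministic and permutation-covariant. Train size is
⌈fraction · n⌉ (203/67 at 3:1 on 270 samples). The comprehensive-process
split runs SPXY within each step and unions the parts, so every step
contributes proportionally. Distances are computed on raw trimmed spectra,
once per process model, before any pretreatment comparison — so model
differences reflect methods, not splits.

## Wavelength selection

**CARS.** N = 65 Monte-Carlo iterations by default, 80 % row sampling,
PLS components capped at 10 inside the selector. The retention ratio
follows the exponential schedule r_i = e^{−k(i−1)} with r_1 = 1 and
r_N = 2/p. Each iteration keeps the top ⌈r_i·p⌉ bands by absolute PLS
coefficient, then applies adaptive reweighted sampling (weighted draw with
replacement; a band survives if drawn at least once), and records the
5-fold RMSECV of the retained set (best over 1..10 latent variables). The
iteration with minimum RMSECV wins; the retained count never increases and
is floored at 2. The classic "decrease-then-increase" RMSECV shape is
data-dependent and not asserted; what is asserted is that the trace minimum
is no worse than the full-band model on the same folds.

**VISSA.** Inclusion weights start at 0.5. Each iteration draws a weighted
binary sampling matrix (column j has exactly round(w_j·n_submodels) ones,
shuffled per column), scores sub-models by k-fold RMSECV, and replaces
w_j with band j's frequency among the best 5 % of sub-models. Iterations
are accepted only while the best RMSECV improves; the final set is
{j : w_j ≥ 0.999}, falling back to w_j > 0.5 with a warning if no weight
saturates. Sub-model ties break by sub-model index. Defaults
(1000 sub-models, 50 iterations) follow typical model-population-analysis
practice; desk-scale runs in the tests and the acceptance script use
100–200 sub-models, which is sufficient at ≤ 150 bands.

Selector CV uses 5 folds (selector-level) while final-model CV uses 10
(model-level); the two are independent knobs. Both selectors are
deterministic given their seed. On correlated spectra a selector may
occasionally prefer a highly correlated neighbour of a planted band; this
is method behavior, not an implementation defect, and is why recovery
criteria are stated as recall/precision aggregates over seeds rather than
exact set equality.

The percentage column of the selection summary is
100·count/total rounded to one decimal — 67 of 943 is 7.1 %, 41 of 943 is
4.3 % (and 32 of 943 is 3.4 %; published roundings of such tables are not
always arithmetic truths, so the summary recomputes rather than echoes).

## Regression

**PLSR** is PLS1 (NIPALS with X/y deflation), which for a univariate
response yields the same predictions as SIMPLS; the implementation is
validated against scikit-learn's `PLSRegression` to 1e-8 and against OLS at
full rank. The coefficient path for 1..A components comes from one
decomposition, which is what keeps the selector loops (thousands of CV
fits) cheap. Latent-variable count is chosen by seeded 10-fold CV
(contiguous folds after a shuffle), argmin RMSECV, smallest count on ties;
component requests beyond the effective rank truncate with a warning.

**LS-SVR** solves the (n+1)×(n+1) KKT system
`[[0, 1ᵀ],[1, K + I/C]]·[b; α] = [0; y]` with RBF kernel
K_ij = exp(−γ‖x_i−x_j‖²); a linear-kernel mode exists as an OLS-equivalent
oracle for testing. X is centered (the PLSR treatment) before kernel
evaluation. Near-singular systems receive a 1e-12 ridge jitter with a
warning. Hyperparameters come from an exhaustive grid search under 10-fold
RMSECV over libSVM-style grids γ ∈ 2^{−15..3}, C ∈ 2^{−5..15} (log₂ step
2); ties prefer smaller C then smaller γ. The grid is searched per
pretreatment-selector combination.

CV folds are derived from the run seed and shared within a run, so
differences between report rows reflect methods rather than fold draws.

## Evaluation

R² = 1 − SSE/SST and RMSE are the standard forms. RPD is
SD(y_test; n−1)/RMSEP — the standard chemometrics definition; a literal
deviation-ratio variant (`rpd_printed`) is kept for comparison because the
two appear interchangeably (and sometimes garbled) in the applied
literature. Credibility classes: RPD < 1.4 unreliable, 1.4–2.0 credible
(boundaries inclusive), > 2.0 highly credible. For mean-unbiased
predictions the identity RPD² · (1 − R²) · n/(n−1) = 1 links the three
metrics and is used as a cross-check in tests. Report tables flag the best
row per process type by prediction R², ties by RPD; the "ST" step label
is normalized to "SF". CSVs are written with a fixed float format so
identical runs are byte-identical.

## Mapping

Pixel order is fixed: trim → pretreat (with calibration-fitted parameters,
including the calibration MSC reference — a per-image reference would
desynchronize pixel and tabular predictions) → subset to selected bands →
predict. Background is masked by thresholding mean reflectance over
750–950 nm (default 0.15, below which only the dark filler falls). Color
scale defaults to the 2nd–98th percentile of foreground values for
robustness to outlier pixels. Rendering goes through a pure-array path
(PIL) so output bytes are deterministic.

## Orchestration and determinism

`run_matrix` derives every stage seed from the run seed and the stage's
label path (CRC-mixed, < 2³¹), so adding or removing combinations does not
perturb the seeds of others. Provenance sidecars carry the full config echo
and a config hash; reruns with identical config + seed are byte-identical.
Desk-scale problem sizes used by the test suite and the acceptance script
(e.g. 36-sample × 151-channel matrices for the determinism check, 100–200
VISSA sub-models, 100-band selector benchmarks) are the package's choice of
a size that exercises every code path while keeping a full run in the
seconds-to-minutes range.

## Known limitations

* The generator's nuisance structure is far simpler than real leaf
  spectra; absolute metrics on synthetic data overstate field performance.
* PLS1 only (univariate y); no multi-response PLS2.
* No SNV/detrending/OSC pretreatments, no SPA/UVE/GA selectors — out of
  scope by design.
* ENVI support is a pinned dialect (BSQ float32 write, BSQ/BIL read,
  wavelength list required); compressed or BIP variants are rejected.
* LS-SVR solves a dense n×n system; fine for hundreds of samples, not for
  tens of thousands.
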