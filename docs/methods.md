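# Methods

This note documents the models, conventions and numerical choices behind
`plasmanmr`, in the order data flows through the package.

## Spectrum simulation

Spectra are simulated directly in the frequency domain. Every component
(small-molecule metabolite, macromolecule envelope, internal standard)
is a sum of Lorentzian lines; a line of full width at half maximum `w`
Hz at chemical shift `c` contributes a unit-area profile
`(w/2f)/π / ((δ−c)² + (w/2f)²)` on the ppm axis, with `f` the
spectrometer frequency (default 500.13 MHz). Line intensities scale
linearly with concentration (mM) and relative multiplet areas stand in
for proton counts. No free-induction decay, phasing or apodization is
modelled: the package's subject matter begins at the processed
frequency-domain spectrum.

Three observation models emulate the acquisition strategies being
compared:

- **Ultrafiltered NOESY** — macromolecules are removed physically;
  small molecules pass unattenuated.
- **CPMG** (T2 relaxation editing) — every component is attenuated by
  `exp(−L·τ/T2)` with `L` loop count (default 300) and `τ` echo spacing
  (default 1 ms); macromolecule envelopes are additionally multiplied by
  a *residual fraction* (default 0.25). The default macromolecule
  T2 = 0.3 s leaves ~9% of the envelope in CPMG spectra, making CPMG
  suppression deliberately imperfect relative to diffusion editing, as
  observed experimentally. The residual fraction is a configuration
  parameter, not a physical claim.
- **LED** (diffusion editing) — attenuation follows a reduced
  Stejskal–Tanner form `exp(−c·f²·D)` with gradient fraction `f`
  (defaults 0.02 and 0.70), relative diffusion coefficient `D` (1 for a
  fast small molecule) and one instrument constant `c`. The default
  `c = 10` was calibrated so a `D = 1` metabolite loses ≥99% of its
  signal at 70% gradient while keeping ≥99.6% at 2%; both bounds cannot
  be pushed to 99%/99.9% simultaneously under this functional form, so
  the 2%-gradient loss (≤0.4%) was accepted as the slack. Macromolecule
  `D` defaults to 0.002, giving ~1% leakage into the LED difference.

True diffusion coefficients and T2 values for plasma components are not
part of the package's sources; the defaults are plausible placeholders
chosen for the attenuation contrasts above and are exposed on every
component spec.

Noise is iid Gaussian per point (default sd 1.0 intensity unit, giving
the maleate singlet a signal-to-noise ratio of ~140); an optional
intensity-proportional term supports heteroscedastic scenarios.
Replicate concentration variability is log-normal, parameterized by a
CV so that the mean equals the design concentration exactly. One master
seed feeds `numpy.random.SeedSequence` substreams per sample, so cohorts
are bit-reproducible and adding an observation model does not perturb
another sample's draw.

The shipped plasma library covers 16 metabolites at typical plasma
concentrations with canonical shifts, three macromolecule envelopes
(lipoprotein, glycoprotein, broad albumin background), maleic acid
(0.43 mM singlet at 6.0 ppm, linewidth insensitive to filtration) and
TSP (1 Hz filtered, 11 Hz unfiltered — the protein-binding broadening
the maleate standard avoids). The replicate-cohort default applies
2-fold changes to five metabolites between the two groups at 10%
replicate CV. The standard-addition design spikes nine amino-acid/
metabolite stocks (e.g. 5.54 mM glycine) at dilutions 1×, 3×, 5×, 10×
and a water blank into QC plasma, three replicates each (15 samples);
the plasma-phase increment is stock/dilution/5 per the 100 µL → 500 µL
volumetric ratio.

### What the simulator does not emulate

J-coupling evolution and second-order multiplet distortion; pH-dependent
chemical-shift drift (shifts are fixed, which is why no alignment step
exists downstream); realistic lipoprotein subclass profiles; water and
urea exchange artifacts; receiver/phase instabilities. Passing tests
therefore demonstrate the correctness of the *processing chain* under a
controlled observation model, not performance on patient plasma.

## Spectral processing

**Diffusion-edit subtraction** is pointwise: low-gradient minus
high-gradient on an identical axis, with method tags and gradient
ordering validated.

**Underground removal** (the broad-envelope filter applied to LED
differences) estimates the baseline as a rolling *median* over the
filter width (default 20 Hz) and subtracts it. A rolling-minimum
estimator was evaluated first and rejected: on white noise the minimum
is biased low by ~3.5 noise sd, which inflates every integral after
subtraction (the maleate reference absorbs the offset and all
quantification slopes dropped to ~0.85). The median is unbiased on
noise, removes features much broader than the window, preserves
features much narrower, and is idempotent within tolerance. Its known
artifact: clusters of narrow lines whose *span* approaches the window
(the 2.99–3.05 ppm lysine/creatine/creatinine region) are partially
clipped, which is why quantification does not run through this filter
(below).

**Noise estimation** uses 1.4826 × median absolute deviation over a
signal-free region (default: above 10 ppm), robust to stray peaks.
Signal-to-noise for method comparison uses the maleate peak at 6 ppm
against the 8.50–9.99 ppm window. Peak width at half height uses
linearly interpolated half-maximum crossings relative to the local
minimum in the search window. Axis referencing shifts rigidly to put
the glucose doublet at 5.22 ppm; the reference point of a doublet is
the midpoint of its two component maxima.

## Spectral reduction

**Bucketing**: contiguous half-open 0.02 ppm bins over 0–10 ppm; the
value is the plain sum of point intensities (no per-bucket scaling), so
bucket sums conserve point sums exactly. Eleven fixed regions
(macromolecule envelopes, water, glucose/urea, 1-methylhistidine,
acetate) are excluded by bucket center, closed endpoints.

**Peak picking** replaces a wavelet detector with an explicitly
contract-tested local-maximum picker. The signal is first
baseline-corrected by a rolling median over 20 Hz — the implicit
baseline insensitivity of wavelets — then candidate maxima must exceed
`snr_min` (default 3) times the noise sd in both height and topographic
prominence, and must be at least 0.5 Hz wide at half prominence (the
analogue of a wavelet's minimum scale; single-gridpoint noise spikes
fail this). Positions are refined by 3-point parabolic interpolation;
areas are trapezoidal over ±2 FWHM. Without the baseline correction and
width gate, noise ripples riding on residual macromolecule envelopes
flood the peak table (hundreds of false features per spectrum) and
chain into spurious cross-sample groups.

**Grouping** is single-linkage clustering on chemical shift with the
dendrogram cut at 0.0075 ppm (half the bucket width; in one dimension
this reduces to splitting sorted positions at gaps). Within a group a
sample keeps only its peak nearest the group median; displaced
duplicates return to the pool and are re-grouped. **Filling** integrates
each spectrum over the consensus position ± consensus width where a
sample has no picked member; integrals below `snr_min · noise sd ·
interval width` are recorded as missing (non-detects), feeding the
presence filter.

## Feature-table conditioning

The chain runs in a fixed order — presence filter → maleate scaling →
PQN → KNN imputation → glog — and each table records its history;
applying a stage after a later one raises. Re-running the same stage is
allowed (idempotence checks).

- **Presence filter**: keep a feature iff observed in ≥80% of samples
  within *at least one* group. The governing phrase is grammatically
  ambiguous ("either group"); the class-wise reading is the default
  because a feature informative for one group only is exactly what a
  discriminant analysis needs, and the stricter both-groups rule is
  exposed as `rule="all"`.
- **Maleate scaling**: each sample divided by its internal-standard
  feature (nearest feature to 6.0 ppm); errors name the offending
  sample.
- **PQN** is defined as the *fixpoint* of the median-quotient map: the
  reference is the feature-wise median spectrum ignoring non-detects,
  each sample is divided by the median of its observed quotients, and
  the map is re-applied until every per-pass factor is 1 within 1e-12
  (typically < 200 passes). A single pass is not idempotent —
  re-running it changes factors by percents — whereas the fixpoint
  definition makes normalization-of-normalized-data exactly neutral.
  Noise-dominated tables (zero-mean bucket noise) can settle into a
  small limit cycle instead of a fixpoint; this is detected and reported
  with the accumulated factors.
- **KNN imputation** treats *features* as neighbors: distance is the
  root-mean-square difference over co-observed samples (scaling by the
  co-observed count keeps sparsity from shrinking distances), the
  imputed cell is the inverse-distance-weighted mean of the k = 10
  nearest features' values in that sample, zero-distance neighbors share
  uniform weight, and a feature's own observed mean is the fallback when
  fewer than k neighbors are observed.
- **glog** `g(x) = ln(x + √(x² + λ))` with λ calibrated on the
  technical-replicate group: λ* minimizes the spread (sd/mean across
  features) of per-feature replicate variances of the transformed
  values — a variance-stabilization surrogate for the reference
  maximum-likelihood fit, validated against an exhaustive grid oracle.
  The search is a 60-point log grid over `[1e-12, 1e12]·median²`
  followed by golden-section refinement; an all-constant replicate
  block returns the lower bound with a warning. For x < 0 the transform
  is evaluated as `λ/(√(x²+λ) − x)` to avoid catastrophic cancellation.

## Multivariate analysis

PCA is SVD on mean-centered data. PLS-DA is NIPALS PLS1 on
mean-centered X against a centered ±1 class coding (the two-column dummy
coding is equivalent for two classes); no variance scaling by default,
matching the mean-centering-only convention, with unit-variance scaling
available. The continuous decision score is the *centered* regression
prediction, so the threshold sits at the training midpoint: a fully
uninformative (constant) X scores exactly 0 for any fold balance, and
an exact 0 falls to the class coded −1 (documented tie rule).

Component count is chosen by leave-one-out misclassification count,
smallest count winning ties, capped at `min(10, n−2)`. Model quality
uses double (nested leave-one-out) cross-validation: the inner
selection is repeated on every outer training set before the held-out
sample is classified; feature filtering happens once before CV,
matching the described processing sequence. VIP scores follow the
standard formula (ΣVIP² = feature count); the importance threshold
defaults to the conventional 1.0. Signatures from two methods are
compared by greedy nearest-position matching of important features
within 0.005 ppm.

## Quantification validation

Standard-addition concentrations are measured from the plain LED
difference (no underground filter — the subtraction already cancels
macromolecules, and a 20 Hz baseline filter clips the crowded
2.99–3.05 ppm cluster) by joint linear least-squares deconvolution: the
known Lorentzian multiplet profiles of all nine analytes plus the
maleate singlet are fitted simultaneously and concentrations are read
off relative to the maleate coefficient, so the absolute intensity
scale drops out. This mirrors the role of deconvolution software in the
wet protocol; naive window integration (±4 FWHM per line) remains
available and is what the peak-mode feature tables use.

Linearity regresses measured concentration (response) on known added
amount (predictor) by OLS — the standard-addition convention, which
also makes "prediction error = RSE / mean measured concentration"
dimensionally natural. LOD = 3.3·SE(intercept)/slope; LOQ = 3.3·LOD,
exactly. Recovery is ratio-of-means ×100 per spike level (a
difference-based variant is exposed); the synthetic reference assay
reports the true total concentration with configurable proportional
bias (default 0) and 2% log-normal noise, while the NMR side sees only
the protein-unbound fraction — the default library binds 40% of
creatinine and 10% of glycine, reproducing the depressed recoveries
protein binding causes in practice. Bland–Altman differences are
NMR − reference, so positive bias means NMR reads high; limits of
agreement use ±1.96 sd. Repeatability RSD is 100·sd/mean per peak over
QC runs (inter-batch: 45 batches × 1 QC with a multiplicative batch
factor; intra-batch: 19 QCs in one batch), summarized by the median and
the fraction below the 30% cutoff.

## Problem sizes and runtime

Default grids use 32,768 points over −0.5 to 10.8 ppm (0.17 Hz/point,
~6 points across a 1 Hz line); width-estimator tests use 65,536 points.
The shipped comparison runs 18 samples × 4 observation models and
completes, end to end, in well under a minute on one CPU; the
quantification suite (15 + 45 + 19 spectra) in a few seconds.

## Known limitations

- Bucket-mode tables on ultrafiltered spectra are dominated by
  zero-mean noise buckets; PQN becomes unstable (limit cycle) and the
  replicate-calibrated glog maps sign-flipping noise to extreme values,
  so bucket-mode models can classify near chance while peak-mode models
  are perfect — a faithful, if stark, rendition of why peak picking is
  preferred over binning.
- The underground filter's cluster-clipping means peak areas from
  underground-removed spectra are not quantitative in crowded regions;
  classification is unaffected (the distortion is consistent across
  samples) but absolute work should use the deconvolution path.
- The λ objective is a surrogate; it agrees with its grid oracle within
  an order of magnitude but is not the reference maximum-likelihood
  estimate.
- Greedy VIP matching is order-dependent only through distance sorting;
  ties at identical distances resolve by position order.
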