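# plasmanmr

Untargeted plasma ¹H-NMR metabolomics, end to end: a simulator for
plasma spectra under three macromolecule-suppression strategies, the
diffusion-editing processing chain, two spectral-reduction modes, a
feature-conditioning pipeline, PLS-DA classification under double
cross-validation, and a quantification-validation suite.

## The problem

Plasma is full of proteins and lipoproteins whose broad NMR signals
bury the sharp resonances of small polar metabolites. Large cohort
studies usually suppress macromolecules with the CPMG (T2-relaxation
editing) experiment, but residual envelopes distort baselines and
statistics. Physically removing macromolecules by ultrafiltration (UF)
is the gold standard but too laborious at scale. A third route is
diffusion editing: record an LED (longitudinal eddy-current delay)
experiment at low (2%) and high (70%) gradient strength and subtract —
small molecules diffuse fast and vanish at high gradient, so the
difference spectrum retains them while the slow-diffusing macromolecule
envelope cancels.

`plasmanmr` implements this comparison as a reproducible pipeline with
known ground truth. The simulator renders Lorentzian-line spectra under
the three observation models (UF-NOESY passes metabolites only; CPMG
attenuates by `exp(−L·τ/T2)` with a residual macromolecule fraction;
LED attenuates by the reduced Stejskal–Tanner factor `exp(−c·f²·D)`),
and the analysis chain mirrors the untargeted protocol: LED
subtraction, 20 Hz underground (broad-envelope) removal, bucketing
(0.02 ppm, 0–10 ppm, 11 excluded regions) or peak
picking/grouping/filling, then presence filtering (80% rule), scaling
to the maleic-acid internal standard, probabilistic quotient
normalization, KNN imputation, and a generalized log transform with λ
calibrated on technical replicates. Classification is two-class PLS-DA
(NIPALS, mean-centered) with the number of latent variables selected by
leave-one-out CV inside every fold of an outer leave-one-out loop
(double cross-validation); per-feature importance uses VIP scores
(ΣVIP² = number of features). Quantification performance is assessed by
standard addition (linearity; LOD = 3.3·SE(intercept)/slope, LOQ =
3.3·LOD), recovery against a reference assay, Bland–Altman agreement,
and inter-/intra-batch repeatability RSD.

`docs/methods.md` documents every model, default and numerical choice.

## Worked example

Simulate the two-group replicate cohort (9 PA + 9 PPGL aliquots,
2-fold changes on five metabolites, 10% replicate CV), run all three
acquisition methods through the peak-mode pipeline, and compare
signatures:

```python
from plasmanmr.pipeline import RunConfig, run_method_comparison

report = run_method_comparison(RunConfig(seed=1))
for method in ("uf", "cpmg", "led"):
    r = report["methods"][method]["peaks"]
    print(method, r["misclassifications"], r["selected_components"],
          r["n_important"])
print(report["overlaps"]["peaks"])
```

prints

```
uf 0 1 7
cpmg 0 1 7
led 0 1 8
{'cpmg': {'shared': 7, 'a_only': 0, 'b_only': 0},
 'led': {'shared': 7, 'a_only': 1, 'b_only': 0}}
```

— every method separates the groups without a single double-CV
misclassification in peak mode, one latent variable suffices (group
separation dominates the variance), and the LED signature shares all
seven of the UF gold-standard's important features. The quantification
suite:

```python
from plasmanmr.pipeline import RunConfig, run_quant_suite

rep = run_quant_suite(RunConfig(seed=1))
lin = rep.linearity["phenylalanine"]
print(f"slope {lin.slope:.3f}  adj-R2 {lin.r2_adj:.4f}  "
      f"LOD {rep.lod['phenylalanine']*1000:.1f} uM")
print(f"inter-batch median RSD "
      f"{rep.repeatability['inter_batch']['median_rsd']:.1f}%")
```

prints

```
slope 0.999  adj-R2 0.9998  LOD 6.0 uM
inter-batch median RSD 5.8%
```

— the 15-sample standard-addition series recovers a unit slope for an
unbound, well-resolved metabolite with a low-micromolar detection
limit, and QC peaks repeat with a median RSD well below the 30%
acceptability cutoff. Metabolites with a simulated protein-bound
fraction (creatinine: 40%) show correspondingly depressed recovery and
a negative Bland–Altman bias against the reference assay, which sees
the total concentration.

A `plasmanmr` command-line interface wraps the same workflows:
`plasmanmr simulate cohort|standard-addition|repeatability`,
`plasmanmr run-comparison`, `plasmanmr run-quant`,
`plasmanmr export-config`.

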