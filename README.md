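# pris — compartmentalized CT radiomics and a prognostic–predictive survival signature

`pris` implements an end-to-end radiomic analysis of CT tumor imaging for
survival modeling and treatment-benefit assessment, built for the
low-risk (AJCC 8th stage I–II) HPV-associated oropharyngeal carcinoma
setting: patients for whom the open clinical question is whether adding
chemotherapy to radiotherapy is worth its toxicity.

The pipeline:

1. **Imaging** — reads CT volumes and binary tumor masks (NIfTI; DICOM
   series read-only), cleans dead pixels with a 9×9 in-slice averaging
   filter, and resamples to an isotropic 1 mm grid.
2. **Compartments** — per axial slice, dilates the tumor mask in 2D by
   `round(15 / pixel size)` pixels and partitions the 0–15 mm peritumoral
   band into three 5-mm rings by Euclidean distance to the tumor; air
   pixels (< −900 HU) are excluded from the rings.
3. **Texture features** — per-pixel 2D maps from five families: 25 Laws
   kernels (outer products of L5/E5/S5/W5/R5), 48 Gabor magnitude
   responses (6 wavelengths × 8 orientations), 13 Haralick descriptors of
   a windowed gray-level co-occurrence matrix, 13 CoLlAGe descriptors
   (co-occurrence statistics of the dominant gradient-orientation image),
   and 13 gray-level intensity maps (intratumoral only). Pooling pixel
   responses per compartment and taking mean/median/std/skewness/kurtosis
   yields the (4 × 99 + 13) × 5 = **2045-entry feature vector**.
4. **Signature (pRiS)** — LASSO-Cox over a 100-value penalty path down to
   1 % of the data-driven maximum; 10-fold cross-validated
   partial-likelihood deviance nominates the penalty, then the signature
   is locked to exactly 7 nonzero coefficients. The score is
   `pRiS = Σ βᵢ · zᵢ` over the selected standardized features, and
   patients are dichotomized at the training median or at the cutoff
   minimizing the two-group log-rank p over all admissible splits
   (the "X-tile" rule).
5. **Evaluation** — Kaplan–Meier/log-rank, Cox hazard ratios (Efron
   ties), Harrell's C, IPCW time-dependent AUC; an integrated
   radiomic+clinical nomogram with Hosmer–Lemeshow calibration and
   decision-curve analysis (`net benefit = TP/N − (FP/N)·pt/(1−pt)`);
   and the chemotherapy-benefit battery: chemo-vs-radiation hazard
   ratios within each risk group, risk-group comparisons within each
   arm, the treatment×group interaction test, and AJCC-stage subgroups.

Because the source cohorts are not redistributable, the package ships a
first-class synthetic module: CT phantoms with textured tumors, distinct
peritumoral texture, air pockets and dead pixels; and simulated cohorts
with proportional-hazards Weibull survival carrying a planted
treatment-by-risk interaction. Every stage is tested against analytic or
brute-force oracles on these synthetics.

## Worked example

`examples/02_fit_signature.py` simulates 300 patients with 50 features,
two of which (`f000`, `f001`) carry true prognostic signal, and fits the
signature:

```
selected 7 features at penalty 0.0604:
  f000: +0.876  <- planted
  f001: +0.804  <- planted
  f009: +0.002
  f011: +0.003
  f013: +0.056
  f020: +0.061
  f027: -0.024

training C-index: 0.801
median cutoff: -0.111
min-log-rank-p (X-tile) cutoff: +0.462
```

Both planted features dominate the signature; the five others enter with
near-zero weights, and the C-index ≈ 0.8 reflects the strong planted
effects. `examples/03_chemo_benefit.py` runs the stratified benefit
analysis on a cohort where chemotherapy helps only high-risk patients:

```
high-risk chemo vs radiation: HR 0.23 (0.16-0.33), log-rank p 8.95e-18
low -risk chemo vs radiation: HR 1.03 (0.72-1.49), log-rank p 0.863
treatment x risk-group interaction p: 2.2e-09
```

exactly the planted pattern: a protective hazard ratio confined to the
high-risk stratum with a confidence interval straddling 1 in the
low-risk stratum. The other examples cover phantom generation and
feature extraction (`01`), nomogram calibration and decision curves
(`04`), and the full simulate→extract→fit→evaluate pipeline (`05`).

A thin CLI mirrors the library:
`pris simulate|ingest|extract|fit|evaluate|run-all --help`.

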