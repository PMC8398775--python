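# chiralspec

Multi-platform chemometric quantification of the **enantiomeric excess
(EE%) of L-DOPA in solid racemic/enantiopure mixtures** from mid-infrared
(MIR) and near-infrared (NIR) spectra.

In the crystalline state, the racemic compound and the pure enantiomer of a
chiral drug form distinct phases with (slightly) different vibrational
spectra, so the enantiomeric excess of a solid mixture can be calibrated
directly from IR measurements — a fast, solvent-free alternative to chiral
chromatography or polarimetry. The catch is that the two pure-component
spectra are nearly collinear, the response must be pulled out of thousands
of correlated channels, and two instrumental platforms (MIR transmittance
on KBr pellets, NIR diffuse reflectance) see the samples differently. This
package implements, as a tested reusable pipeline, the chemometric workflow
for that problem. It is aimed at chemometricians and pharma analytical
scientists who want a transparent reference implementation of the
multi-block machinery rather than a black box.

## What is inside

For a mixture of `m_rac` grams of racemate and `m_L` grams of pure
L-enantiomer, the response is

    EE% = 100 · (L − D) / (L + D) = 100 · m_L / (m_rac + m_L)

A 33-sample composition table spanning EE% = 0…100 is embedded
(`chiralspec.design`). The original spectra are not publicly deposited, so
a synthetic two-block generator (`chiralspec.simulate`) emulates the data
structure: Gaussian-band pure-component spectra per crystal form
(10–15% band contrast in MIR, ≤ 2% in NIR), Beer–Lambert mixing, then
multiplicative scatter, additive offset, polynomial baseline, a
sample-varying humidity band and white measurement noise, converted to
transmittance/reflectance via `10^(−A)`.

The analysis chain:

* **Preprocessing** (`chiralspec.preprocess`) — pseudo-absorbance
  `A = log10(1/R)` (or `log10(1/T)`), replicate averaging, MIR truncation
  at 3541 cm⁻¹, and the six pretreatment variants built from SNV,
  Savitzky–Golay derivatives (19-point window; 1st derivative/2nd-order
  polynomial, 2nd derivative/3rd-order polynomial) and mean centering.
* **Multi-platform split** (`chiralspec.split`) — per-block PCA on
  mean-centered data, concatenation of the first 5 score columns of each
  block, `T_conc = [T_MIR  T_NIR]`, then Snee's **Duplex** algorithm on
  `T_conc` (23 training / 10 test samples).
* **PLS1** (`chiralspec.pls`) — NIPALS: each component maximizes
  cov(t, y) with t = Xw; with weights mapped back through
  `R = W (PᵀW)⁻¹` the model is `ŷ = T q = X R q = X b`. Complexity by
  8-fold venetian-blind cross-validation (RMSECV), figures of merit
  (RMSEP, bias, R²), **VIP** scores
  `VIP_j = sqrt(p · Σ_f SSY_f (w_jf/‖w_f‖)² / Σ_f SSY_f)` and
  strictly-greater-than-1 variable selection.
* **Multi-block strategies** (`chiralspec.multiblock`) —
  **mid-level fusion** (PLS on concatenated block-model scores);
  **SO-PLS** (`ŷ = X b + Z_orth c`, the second block orthogonalized
  against the first block's scores, complexity from a Måge grid of up to
  12 LVs per block); **SO-CovSel** (same sequential-orthogonalized scheme
  with CovSel variable selection and least squares instead of latent
  variables).
* **Pipeline + CLI** (`chiralspec.pipeline`, `chiralspec` console script) —
  the whole study end-to-end, deterministic under one seed.

## Worked example

```bash
chiralspec run-all --seed 0 --out results
```

simulates both blocks, runs the six-pretreatment ladder on each, refits the
per-block winners on their VIP-selected variables, and fuses the blocks
three ways. The consolidated table (`results/models.csv`) ends with:

```
                  model  variables  complexity  rmsecv   rmsep  bias_p   r2_p
        MIR / SNV (+MC)       3142           2   17.01   15.81    6.11  0.757
        NIR / SNV (+MC)       3112           7    8.18    6.39    2.01  0.960
MIR / SNV (+MC) + VIP>1        753           4    6.86   13.33    5.68  0.827
NIR / SNV (+MC) + VIP>1        935           6    3.10    3.65    0.35  0.987
       Mid-level fusion         10          10    0.08   13.50    5.77  0.823
      SO-PLS (NIR->MIR)       1688           6    3.10    3.65    0.35  0.987
   SO-CovSel (NIR->MIR)          7           7   15.11   12.32    3.46  0.853
```

Reading this: RMSECV/RMSEP are root-mean-square errors (in EE percentage
points, on a 0–100 scale) in cross-validation and on the 10 held-out test
samples; bias is the mean signed test error and R²ₚ the test coefficient of
determination. On these synthetic conditions the NIR block calibrates EE%
far better than the noisier MIR block (test RMSEP 6.4 vs 15.8), VIP
reduction sharpens the NIR model to RMSEP 3.7 (R²ₚ 0.99), and the
sequential multi-block model matches the best single-block result — here
the Måge grid selects (6, 0) components, i.e. the MIR block adds nothing
beyond the NIR information at this seed, and the order-swapped model agrees
to within a few percent. `results/summary.json` records the split, the
VIP counts, the chosen component pairs and the SO-CovSel picks;
`results/predictions/*.csv` holds predicted-vs-measured tables per model.

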