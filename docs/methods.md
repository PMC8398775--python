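# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions and the design choices behind `chiralspec`, in enough detail to
reproduce or audit any stage.

## Response and mixture design

The response is the enantiomeric excess of the L form in a solid mixture of
racemic and enantiopure L material. With `m_rac` grams of racemate
(contributing equal L and D) and `m_L` grams of pure L,

    L = m_rac/2 + m_L,   D = m_rac/2,
    EE% = 100 (L − D)/(L + D) = 100 m_L/(m_rac + m_L).

Both components are the same compound, so the mass ratio equals the mole
ratio and no molar-mass correction applies. The embedded 33-row design
spans EE% 0–100 with total masses near 0.6 g. The table stores the nominal
2-decimal EE% column verbatim, but all regression uses the full-precision
mass-derived value: the nominal column is a rounded view, and one row
("Dopa 045") is internally inconsistent — its masses give 44.91 while the
nominal column reads 44.99. That row is flagged in
`design.KNOWN_EE_DISCREPANCIES`; validation enforces ±0.01 agreement on
the other 32 rows and the documented deviation on that one.

## Synthetic spectra generator

The generator emulates the statistical structure of two-platform solid-state
IR measurements of such mixtures; the original spectra are not available, so
every downstream stage is exercised on this forward model.

**Pure-component spectra.** Sums of Gaussian bands on the instrument grids
(MIR 400–4000 cm⁻¹, 1 cm⁻¹ spacing, 3601 points; NIR 4000–10000 cm⁻¹,
6000/3111 cm⁻¹ spacing, 3112 points — the spacing consistent with that
point count). MIR band widths 12–80 cm⁻¹ plus a broad (380 cm⁻¹) shared
OH envelope; NIR widths 50–600 cm⁻¹. Crystal-form contrast:

* MIR: the NH-stretch triplet (3370/3206/3070 cm⁻¹) is ~10–12% stronger in
  the racemic form; the aliphatic CH bands (2845–3000 cm⁻¹) ~10% stronger
  in pure L; the fingerprint region mixes shared and contrasting bands
  (NH deformation/C=O 1560–1650 cm⁻¹, phenolic CO ~1120 cm⁻¹, aromatic CH
  out-of-plane 810–830 cm⁻¹).
* NIR: combination/overtone bands (4500–5020, 5290, 5950 cm⁻¹) with
  contrast capped at 2% of the tallest band — the two forms are nearly
  collinear.

The contrast magnitudes are emulation parameters chosen once to reproduce
the qualitative picture (strong, visible MIR contrast; almost overlapping
NIR traces); they are not measured quantities.

**Forward model.** Per sample and replicate the ideal absorbance is the
Beer–Lambert convex combination `a = f_L·pure_L + f_rac·racemic` with the
design mass fractions, followed in order by: multiplicative scatter
`exp(N(0, 0.05))`; additive offset `N(0, 0.01)` AU; a random degree-2
polynomial baseline with coefficient sd 0.01 AU on a [−1, 1] axis; a broad
water band (centered 2900 cm⁻¹/width 300 in MIR, 5150 cm⁻¹/width 120 in
NIR) with per-sample amplitude `humidity_sd·|N(1, humidity_sd)|`,
humidity_sd = 0.2 — the amplitude is a property of the specimen, shared by
its replicates; and i.i.d. per-point noise. Intensities are
`10^(−a)` clipped into (1e−6, 1], tagged transmittance (MIR) or
reflectance (NIR).

**Default noise and replicates.** NIR: noise sd 0.0026 AU (SNR ≈ 200 at
its tallest ~0.52 AU band), 3 replicates. MIR: noise sd 0.040 AU, 2
replicates. The deliberately higher MIR noise, together with the water band
sitting on top of the informative 2200–3500 cm⁻¹ region, makes the MIR
channel the weaker platform — the structure the analysis is meant to face:
NIR carries most of the recoverable EE signal despite its tiny contrast,
MIR contributes a noisier, humidity-confounded view. These defaults were
fixed once, when the generator was designed, and define the package's study
conditions.

**Randomness.** One integer seed is expanded with `SeedSequence` spawn keys
into independent streams per (block, sample) — the humidity amplitude — and
per (block, sample, replicate) — all other artifacts. Spectra therefore do
not depend on generation order, and the same seed reproduces blocks bit for
bit.

**What the generator does not emulate:** FT instrument physics
(interferograms, apodization), KBr pellet scattering physics,
wavelength-dependent noise, band-shape asymmetry, temperature effects, or
any nonlinearity of detector response. Passing recovery tests on this
generator shows the pipeline inverts its own forward model under realistic
artifact levels; it does not certify performance on real measurements.

## Preprocessing

Fixed order: intensity → absorbance (`A = log10(1/I)`, base 10 fixed as the
contract; any base is a column rescale absorbed by PLS) → replicate
averaging (arithmetic mean in absorbance space; log and mean do not
commute, so the order matters and is pinned by a regression test) → MIR
truncation at 3541 cm⁻¹ (keeps the 3142 low-wavenumber points; the high
end is baseline) → the pretreatment ladder. The six variants are raw,
1st derivative, 2nd derivative, SNV, SNV + 1st, SNV + 2nd, each followed by
mean centering. Conventions:

* SNV divides by the n−1 row standard deviation (fixed for
  bit-reproducibility; the choice is absorbed downstream).
* Savitzky–Golay: 19-point window, polynomial order 2 (1st derivative) or
  3 (2nd), derivative per index step; edges use the boundary-anchored
  window polynomial evaluated off-center (`scipy.signal.savgol_filter`,
  `mode="interp"`), keeping the column count unchanged.
* Mean centering is never baked into stored matrices: models re-center
  inside every cross-validation fold from the training portion only.
  SNV and the derivatives are row-wise, hence partition-safe.

## Train/test split

A Duplex split on one block ignores the other platform's variability, so
the partition runs on the row-concatenated PCA scores: each averaged block
is mean-centered, the first 5 principal components extracted (SVD, sign
fixed by making the largest-magnitude loading positive), the 33×5 score
matrices concatenated to 33×10, and Snee's Duplex applied with a 10-sample
test set. Duplex here: the globally farthest pair seeds training, the
farthest remaining pair seeds the test set, then points alternate
training/test by the maximin rule (candidate maximizing its minimum
Euclidean distance to the growing set), test assignments stopping at the
requested size, leftovers to training. Pointwise alternation after the
seed pairs and lowest-index tie-breaking are this package's conventions
(fixed by tests against a brute-force reference); distances are unweighted
Euclidean on the score columns. Both extremes of the dominant score
direction land in training by construction, so the test set never demands
extrapolation.

## PLS1, model selection, VIP

NIPALS PLS1 on centered data: per component, weight `w ∝ Xᵀy` (unit norm),
score `t = Xw`, X-loading `p = Xᵀt/tᵀt`, y-loading `q = yᵀt/tᵀt`, deflation
`X ← X − tpᵀ`. The deflated-space weights are mapped to the undeflated
predictors by `R = W(PᵀW)⁻¹` so that `T = X_c R` and `b = Rq`; score-route
and coefficient-route predictions agree to 1e−8 by contract. `PᵀW` is
upper triangular, so truncating R and q reproduces every nested sub-model
exactly — cross-validation fits once per fold at the maximal feasible
component count and reads off all candidate complexities.

Cross-validation: 8 folds, assignment by sorting samples on the response
and dealing round-robin ("venetian blinds" over the sorted order) —
deterministic and spreads the EE range across folds. Centering is
recomputed per fold. The chosen complexity is the smallest count attaining
the minimum RMSECV. Single-block search ceiling: 15 components. If a fold's
training data runs out of rank the fit truncates and deeper counts reuse
the deepest model.

VIP uses the classical deflated-space weights:
`VIP_j = sqrt(p Σ_f SSY_f (w_jf/‖w_f‖)² / Σ_f SSY_f)` with
`SSY_f = q_f² t_fᵀt_f`; mean squared VIP is 1 by identity. Selection keeps
columns with VIP strictly greater than 1; the per-block winner model is
refit on the reduced variables with a fresh complexity search.

## Multi-block strategies

**Mid-level fusion.** The per-block VIP-reduced models' training scores are
concatenated column-wise and modeled by PLS with CV-chosen complexity; test
spectra are projected through the trained block models to produce test
scores. Note the known optimism of this scheme: the block scores are
computed from models trained on the full training set, so the inner CV of
the fusion model under-estimates error and tends to pick generous
complexity. This is the procedure as practiced; the external test set gives
the honest number.

**SO-PLS.** Step 1: PLS(X, y) with lvX components. Step 2: Z is
orthogonalized against the X-scores, `Z_orth = Z_c − T(TᵀT)⁻¹TᵀZ_c`,
implemented as a least-squares solve, never an explicit inverse; the
residual projection must satisfy `max|TᵀZ_orth| ≤ 1e−8‖Z‖`. Step 3:
PLS(Z_orth, y-residuals) with lvZ components. Step 4: `ŷ = Xb + Z_orth c`.
Prediction for new samples reuses the training-time regression of Z on the
X-scores (new X-scores via the first block's R weights), so only the raw
preprocessed blocks are needed. lvZ = 0 reduces exactly to single-block
PLS; lvX = 0 skips the first block. A second block with no variation
orthogonal to the first block's scores (numerically, ‖Z_orth‖ ≤
1e−10‖Z_c‖) is rejected rather than fitted to roundoff noise.

Complexity is chosen on the full (lvX, lvZ) grid up to 12 per block by the
same fold scheme (the diagnostic exported as a Måge plot: RMSECV vs total
components, labeled by the pair). Cells with 0 components are the
fold-train-mean null predictor, making the grid total. Ties go to the
smallest total count, then the smallest first-block count. Both block
orders are always fitted and reported; the contract is comparable
performance (the package asserts ≤ 20% relative RMSEP difference on its
default seeded data), not equality.

**CovSel / SO-CovSel.** CovSel selects, at each step, the column with
maximal squared covariance `(x_jᵀy)²` with the current deflated data, then
deflates both X and y by projecting onto the orthogonal complement of the
selected column (so a selected column can never be selected twice). The
both-X-and-y deflation follows the established CovSel formulation; the
identifiable-toy recovery test pins it down. SO-CovSel mirrors SO-PLS with
CovSel + ordinary least squares in place of PLS: select nX columns from X,
fit, orthogonalize Z against the selected columns' span, select nZ columns
from Z_orth against the residuals, fit, add. The (nX, nZ) pair comes from
the same cross-validated grid search (default ceiling 6 per block) and tie
rule.

## Pipeline

`run_study` executes: simulate (or load) → absorbance → replicate
averaging → MIR cut → 12-model pretreatment ladder (6 × 2 blocks, CV on
the 23 training samples only) → per-block winner by minimum RMSECV →
test-set evaluation → VIP reduction and refit → mid-level fusion → SO-PLS
(NIR as first block by default, order check always emitted) → SO-CovSel.
Problem sizes per run: 33 samples (23/10 split), 3142 + 3112 predictors,
8 folds, LV ceilings 15 (single block) and 12 (per SO-PLS block), CovSel
ceiling 6 per block; a full run takes a few seconds on one CPU. Everything
is deterministic given the seed, and a frozen split (JSON) can be reused
across runs. A leakage audit in the test suite perturbs the test-sample
spectra under a frozen split and verifies every training-time artifact
(RMSECV values, chosen complexities, VIP selections, component pairs,
selected variables, training predictions) is bit-identical.

## Known limitations

* With a single shared latent response, the structural gain of fusing a
  strong and a weak block is small; the sequential model's advantage over
  the best single block is a stochastic property that can invert by ~1% at
  unlucky seeds when the Måge grid picks a marginal second-block component.
  The packaged seeded checks use the default seed 0.
* The pretreatment winner on synthetic data need not match what real
  measurements would select; the report records the winner rather than
  hard-coding one.
* Mid-level fusion inherits the score-leakage optimism described above.
* The simulator's band positions are fixed; calibration transfer,
  wavelength drift and nonlinear detector effects are out of scope.
* The test-set size is fixed at 10 of the 33 samples throughout (a
  `RunConfig` option).
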