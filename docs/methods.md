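# Methods

## Problem

Secondary-structure estimation from protein infrared spectra works on the
amide I / amide II region, 1720–1480 cm⁻¹. The implicit assumption that all
absorbance there is backbone amide is wrong by roughly 20% on average: side
chains of Asn, Gln, Asp, Glu, Arg, Lys, Tyr and His absorb throughout the
window, and their contribution varies from protein to protein with amino-acid
composition. `protir` models that contribution, subtracts it, extracts pure
component spectra from a protein set, and measures whether the subtraction
improves chemometric structure prediction.

## Side-chain band model

Each vibrational mode is a pseudo-Voigt band in the *linear-combination*
form,

    A(ν) = I · [ f_G · exp(−ln2 · (2(ν−ν₀)/w)²) + (1−f_G) / (1 + (2(ν−ν₀)/w)²) ]

with position ν₀ (cm⁻¹), FWHM w (cm⁻¹, shared by both components), peak
intensity I and Gaussian fraction f_G ∈ [0,1]. The linear form is the
standard choice in protein IR curve fitting and matches a four-parameter
band description; the closed-form area is
`f_G·I·(w/2)·√(π/ln2) + (1−f_G)·I·πw/2`.

Intensities are treated as *peak heights* on a per-mole-fraction scale.
Absolute units cancel downstream: the correction step re-expresses the
model on the unit-area scale of the measured spectrum (below).

Ionizable residues carry two band lists (`neutral`, `ionized`, either may
be empty) and a pKa. The deprotonated fraction is Henderson–Hasselbalch,
`f = 1/(1+10^(pKa−pH))`; for acids `f` weights the ionized (carboxylate)
state, for bases (Arg, Lys, His, flagged `is_base`) the charged state
carries `1−f`. Default pKa values: Asp 4.0, Glu 4.4, His 6.0, Tyr 10.0,
Lys 10.5, Arg 12.5. The sample pH defaults to 7.0. All of this is
overridable from a CSV band table that round-trips losslessly.

### Built-in band table

The shipped library covers the 8 residues that dominate the window.
Positions follow the values observed in protein spectra where the two
differ from the free-amino-acid literature:

| residue | state | bands (ν₀ / w / I) |
|---|---|---|
| Arg | ionized | 1673/40/420, 1633/40/300, 1522/30/100 |
| Asp | neutral / ionized | 1729/30/280 · 1570/44/380 |
| Glu | neutral / ionized | 1712/30/220 · **1570**/44/470 (free amino acid: 1559) |
| Asn | — | 1677/30/310, 1612/30/160 |
| Gln | — | 1672/30/360, 1610/30/220 |
| Lys | ionized | 1640/45/130, 1526/45/100 |
| Tyr | neutral / ionized | **1514**/10/430 (free: 1518), 1602/15/160 · 1602/20/160, 1498/20/650 |
| His | neutral / ionized | 1594/30/70 · 1631/30/90 |

Widths default to 30 cm⁻¹ where the source literature is silent, 44 cm⁻¹
for the broad ν_as(COO⁻) modes, and ~10 cm⁻¹ for the very narrow tyrosine
ring mode; Gaussian fraction defaults to 0.5. `default_library(revised=False)`
restores the free-amino-acid Glu/Tyr positions, and
`apply_revised_positions` maps any library to the in-protein positions
(idempotently). The 12 residues with negligible window absorbance are
skipped with a logged notice rather than an error.

## Preprocessing

Exactly three operations, in order: (1) subtract the chord through the
absorbances at the grid points nearest 1720 and 1480 cm⁻¹ and window the
spectrum (idempotent; anchors end at zero); (2) scale to unit trapezoidal
area over the window; (3, diagnostics only) Savitzky–Golay second
derivative, default 9-point window, polyorder 3, which turns narrow bands
into sharp negative lobes — this is how the tyrosine ring position
(1514 vs 1518 cm⁻¹) is read directly off protein spectra. Grid spacing is
always taken from the data. Sets of spectra are linearly interpolated onto
the first spectrum's grid before stacking (the choice is arbitrary and
recorded; any common grid works).

## Concentrations

DSSP output files supply per-residue classes H, E, G, I, T, B, S and blank
(reported as d−); contents are percent of residues, and
`dOthers = 100 − dH − dE` by definition (it deliberately ignores the minor
class labels). Amino-acid composition comes from the one-letter sequence,
with `X` excluded from the denominator by default. The concentration
matrix **C** holds dH, dE, dOthers and the residue contents, all on the
percent scale — extraction is linear, so any fixed unit convention only
rescales the extracted components (here: per percentage point). An
alternative assignment scheme that splits core from peripheral helix and
strand (XTLSSTR-style) is supported as an externally computed table only.

## Pure components

With **A** (wavenumbers × proteins) and **C** (proteins × components), the
pure spectra **S** solve `min ‖A − S·Cᵀ‖_F`, i.e. ordinary least squares
per wavenumber. No intercept (spectra are baseline-corrected and
normalized first) and no non-negativity by default — artefacts in the
extracted components are informative; an NNLS variant sits behind a flag.
A tolerance-based rank test raises before solving, naming the collinear
columns via the smallest singular vectors; the condition number of C and
the residual matrix are reported. By default only dH/dE/dOthers plus the
seven strongest residue absorbers (Asp, Glu, Tyr, Gln, Asn, Arg, Lys)
form C — His is in the band library but its window contribution is minor.

## Side-chain subtraction

Measured spectra are unit-area; the band model is molar-scale. The bridge
is one constant, the per-residue amide window area ε_amide. The model
total area per residue is `T = ε_amide + Σ_r f_r·a_r(pH)` with `f_r` the
mole fraction and `a_r` the residue's integrated library band area over
the window (computed on a 0.5 cm⁻¹ quadrature grid). The side-chain
spectrum divided by `T` is on the unit-area scale and is subtracted; the
subtracted share of the total absorbance is `Σ f_r a_r / T`. ε_amide is
calibrated once so that this share is 0.20 for a reference mean
composition (a fixed average soluble-protein table with, e.g., Arg 4.3%
and Asp+Glu 11.3%), matching the accepted literature figure of ~20%
side-chain absorbance in this region; it is a single explicit, tunable
number. A share above 0.5 (configurable) raises, flagging implausible
inputs. Proteins are ranked by side-chain burden
`Σ_r f_r·a_r` — the same quantity without the normalization.

Two consequences worth knowing:

* On synthetic spectra built from the same library the subtraction is
  exact up to quadrature (~1e−8 on unit-area spectra), because the
  calibration constant is the algebraic inverse of the generator's scale.
* Correcting a convex mixture of two spectra with the mixed composition
  matches the mixture of corrections only to first order in the share
  difference: the denominator `T` depends on composition. The deviation is
  bounded by the share gap times the side-chain amplitude.
* A mis-placed band leaves a bipolar residual against the true amide
  part — subtracting Glu ν_as(COO⁻) at the free-amino-acid 1559 cm⁻¹ from
  data whose band sits at 1570 cm⁻¹ produces a clear negative lobe in the
  1535–1575 region. This is the package's reproduction of the rationale
  for the revised position. The *absolute* corrected spectrum does not go
  negative under the additive forward model, because the amide background
  in that region is an order of magnitude larger than the misplacement
  residual; the published observation of negative absolute values on real
  spectra presumably reflects environment-driven intensity/shape variation
  the four-parameter model does not carry.

## Chemometrics

Three regression families map a predictor block (absorbances per
wavenumber, or the 20 amino-acid fractions) to a structure content:

* **ASLR** — ascending stepwise linear regression. Greedy forward
  selection of single features into an OLS model; the step criterion is
  the leave-one-out RMSE of the augmented model (computed via the hat
  matrix), ties break to the lower feature index, selection stops at
  `max_terms` (default 5, the size of the printed helix-from-composition
  model) or when no candidate improves.
* **PLS** — single-response SIMPLS, mean-centered, no autoscaling
  (predictions are then invariant to feature scaling only if the data are
  centered consistently; this convention is fixed and tested against
  scikit-learn's PLS). The number of latent variables is the first LOO
  RMSECV minimum within 2% of the global minimum, favouring fewer LVs.
* **LS-SVM** — least-squares support-vector regression in the Suykens
  formulation: RBF kernel `exp(−‖x−x′‖²/2σ²)`, one saddle linear system
  `[[0,1ᵀ],[1,K+I/γ]]·[b;α]=[0;y]`. Hyperparameters come from a grid
  (γ ∈ 10^{−1..4}, σ ∈ median-heuristic × {0.25,0.5,1,2,4}) minimizing the
  closed-form LOO residual `α_i/(M⁻¹)_{ii}` — verified against explicit
  refits.

Validation: leave-one-out RMSECV, with the *entire* fitting — including
feature, LV and hyperparameter selection — repeated inside each fold
(`selection="nested"`, the default; `"global"` performs selection once and
is provided because the original procedure may not have nested it, and
for speed at scale). The Kennard–Stone split selects one third of the
proteins by classic max–min distance on standardized structure-content
vectors (spectral-space selection is a flag), trains on the rest and
reports RMSEKS with the *test-set* reference standard deviation — which
generally exceeds the whole-set one, by construction of the max–min rule.
`ζ = STDDEV_REF/RMSE` (sample stddev, ddof = 1) is the headline figure:
ζ ≈ 1 means no better than guessing the mean; a degenerate RMSE of zero is
reported as ζ = 99 (capped). `evaluate_all` crosses structure classes ×
methods × {raw, corrected} × {LOO, KS} into one long-format report whose
stored ζ values are recomputable from their parts.

## Synthetic study generator

What it emulates: a 92-protein reference set.

* **Structure contents**: Dirichlet over (helix, sheet, others) with mean
  (0.30, 0.20, 0.50); the concentration parameter is set in closed form so
  the helix-content standard deviation across proteins is 18.3% — the
  reference spread of the motivating calibration set. Non-helix/sheet mass
  is reported in the unassigned class; minor classes stay at zero (a flag
  can spread a small share).
* **Compositions**: logistic-normal. Latent
  `z_r = log(m_r) + c_r·s̃ + σ·ε` with mean fractions from the reference
  composition table, σ = 0.5 (giving realistic protein-to-protein spread,
  e.g. Arg ranging from ~0 to ~14%), standardized structure content s̃ and
  `c_r = σ·r/√(1−r²)` so the latent correlation with the structure class
  equals the target r. Defaults plant the classic propensities
  (Leu +0.45 and Ala +0.30 with helix, Pro −0.40, Val +0.40 and Ile +0.30
  with sheet, Gly +0.30 with coil), emulating the 0.4–0.5 co-linearity
  observed in real sets; the softmax attenuates small-mean residues, so
  empirical r is checked within ±0.15. Setting the map empty gives
  structure-independent side chains.
* **Spectra**: content-weighted unit-area structure bases (helix amide I
  1656 narrow + amide II 1544; sheet 1634 + 1690 shoulder + 1536; others
  1654 broad + 1536) plus the library side-chain spectrum scaled so the
  *mean* composition contributes a 20% window share (individual proteins
  vary with their burden), plus linear baseline drift (2% of max) and
  Gaussian noise (0.5% of max), then standard preprocessing. Grid:
  4 cm⁻¹ steps over 1448–1752 so the window anchors fall on grid points.

With noise, drift and normalization off, the generated matrix equals
S·C *exactly* (per-percent components times percent concentrations),
anchoring the extraction tests at machine precision. Note that per-protein
area normalization is nonlinear across proteins, so the exact identity
holds on the unnormalized matrix; the normalized default is the realistic
condition.

What it does not emulate: instrument line-shape, water vapor and CO₂
interference, detector nonlinearity, environment-dependent band shifts
within one protein, ¹H/²H exchange, and the minor DSSP classes' spectral
signatures. Passing tests therefore demonstrate correctness of the
machinery and of the additive model's consequences, not performance on
real measured spectra.

## Problem sizes and numerical choices

Simulation-based checks use 92 proteins (the reference-set size) with 20
replicates for the planted-model recovery and the sheet-ζ comparison, and
50 replicates for the noise-scaling check at 46 vs 92 proteins; the
sheet-ζ comparison uses PLS with the LV count selected once per variant.
Rank tests use a relative SVD tolerance of 1e−10; LOO leverages are
clipped at 1−1e−12; Kennard–Stone ties break to the lower index, making
selection deterministic given input order; all generator randomness flows
from a single integer seed through `numpy.random.default_rng`, with no
global state.

## Known limitations

Band intensities are transcribed peak heights on a relative scale; only
their ratios and the single ε_amide calibration matter. The pH response
uses model-compound pKa values — real proteins shift them by several
units. The forward model is strictly additive, so the package can verify
the machinery of subtraction but cannot, by construction, measure how
badly environment variability degrades a single global parameter set on
real spectra. Headline numbers published for the original 92-protein
measured set are not reproducible here because those spectra were never
deposited; the synthetic study is calibrated to that set's printed summary
statistics instead.
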