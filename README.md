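# protir

Amino-acid side-chain contributions to protein FTIR spectra: modelling,
subtraction, pure-component extraction and chemometric secondary-structure
calibration in the amide I / amide II window (1720–1480 cm⁻¹).

## Who this is for

Protein infrared spectroscopists and chemometricians who estimate
secondary-structure content (α-helix, β-sheet, the rest) from amide-region
spectra. About 20% of the absorbance in that window is not backbone amide
at all but side chains — carboxylates, guanidinium, primary amides, the
tyrosine ring — and the fraction varies protein to protein with
composition. `protir` answers, end to end and fully testable without any
measured data: *what does the side-chain contribution look like, how do
you subtract it, and does subtracting it actually improve structure
prediction?*

## What it implements

* **Band model** — side-chain absorbance as sums of pseudo-Voigt
  (Lorentzian–Gaussian) bands, four parameters each (ν₀, FWHM, peak
  intensity, Gaussian fraction), with Henderson–Hasselbalch ionization
  weighting from sample pH and per-residue pKa. A built-in table covers
  Asp, Glu, Asn, Gln, Arg, Lys, Tyr, His, with the Glu ν_as(COO⁻) and Tyr
  ring positions at their in-protein values (1570, 1514 cm⁻¹) rather than
  the free-amino-acid ones (1559, 1518 cm⁻¹).
* **Preprocessing** — two-point baseline between 1720 and 1480 cm⁻¹,
  unit-area scaling, Savitzky–Golay second derivatives.
* **Concentrations** — DSSP-file parsing into percent contents
  (dH, dE, …, dOthers = 100 − dH − dE) and amino-acid composition from
  sequence, assembled into the concentration matrix **C**.
* **Pure components** — solve **A** = **S**·**C** by per-wavenumber least
  squares and read pure helix/sheet/others and per-residue spectra out of
  a protein set.
* **Correction** — scale the molar band model onto unit-area spectra via a
  single calibrated amide-area constant (mean side-chain share = 20%) and
  subtract; rank proteins by side-chain burden.
* **Chemometrics** — ascending stepwise linear regression (ASLR),
  single-response SIMPLS PLS, and LS-SVM (Suykens RBF formulation);
  leave-one-out cross-validation with selection nested in each fold, and a
  Kennard–Stone one-third test set; everything reported as RMSE and
  ζ = STDDEV_REF/RMSE.
* **Synthetic study generator** — 92-protein-scale datasets with
  Dirichlet structure contents (helix spread calibrated to 18.3%),
  logistic-normal compositions with tunable structure↔composition
  correlation, and spectra built as structure bases + side chains + drift
  + noise. The noiseless, unnormalized matrix is *exactly* **S**·**C**.

See `docs/methods.md` for the model details and conventions.

## Worked example

```python
import numpy as np
from protir import (GeneratorConfig, generate_dataset, extract_pure_spectra,
                    locate_band_maxima, subtract_sidechains, Spectrum)
from protir.chemometrics import pls_select_lv, pls_fit, loo_cv
from protir.correction import correct_matrix

cfg = GeneratorConfig(n_proteins=92, seed=1)
A, C, truth = generate_dataset(cfg)            # spectra + concentration matrix

pure = extract_pure_spectra(A, C)              # A = S.C by least squares
print(locate_band_maxima(pure, "dH", window=(1620, 1700))[0])

res = subtract_sidechains(Spectrum(A.grid, A.A[:, 0]), truth["compositions"][0])
print(round(res.sidechain_area_fraction, 3))

Acorr, shares = correct_matrix(A, truth["compositions"])
y = np.array([st.dE for st in truth["structures"]])
for name, M in (("raw", A), ("corrected", Acorr)):
    X = M.A.T
    lv = pls_select_lv(X, y, max_lv=12)
    r = loo_cv(lambda Xt, yt: pls_fit(Xt, yt, lv).predict, X, y)
    print(f"{name:9s} dE: n_LV={lv} RMSECV={r.rmse:.2f}% zeta={r.zeta:.2f}")
```

Output:

```
(1656.0, 0.00017105862979262593)
0.248
raw       dE: n_LV=6 RMSECV=1.29% zeta=11.38
corrected dE: n_LV=4 RMSECV=0.78% zeta=18.75
```

Reading it: the extracted helix component peaks at 1656 cm⁻¹ (the
canonical α-helix amide I position); the first protein's modelled
side-chain share of its spectrum is 24.8%; and subtracting side chains
improves leave-one-out β-sheet prediction — the error drops and
ζ (reference spread over prediction error; 1 means guessing the mean)
rises. On these low-noise synthetic spectra ζ is far higher than anything
achievable on measured data; the *direction* of the change is the point.

A command-line interface mirrors the stages:

```bash
protir synthesize --n 92 --seed 1 --out ds/
protir correct --spectra ds/spectra.csv --composition ds/compositions.csv --out corr.csv
protir extract --spectra ds/spectra.csv --concentrations ds/concentrations.csv --out pure.csv
protir calibrate --spectra raw ds/spectra.csv --spectra corrected corr.csv \
                 --structures ds/structures.csv --out report.csv
protir pipeline --out run/ --n 92 --seed 1        # all of the above + manifest
```

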