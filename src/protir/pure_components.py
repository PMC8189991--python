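"""Pure-component spectra by least-squares matrix division, A = S.C.

With the absorbance matrix **A** (wavenumbers x proteins) modelled as a
linear combination of concentrations **C** (proteins x components) and
"pure" spectra **S** (wavenumbers x components), **S** is recovered by
ordinary least squares per wavenumber.  No non-negativity is imposed by
default: artefacts in the extracted components are themselves informative
(a non-negative variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .preprocessing import SpectraMatrix
from .spectral_model import ParameterError, Spectrum, WavenumberGrid
from .structure_composition import ConcentrationMatrix

__all__ = ["PureComponentSet", "RankDeficiencyError", "extract_pure_spectra",
           "locate_band_maxima"]


class RankDeficiencyError(ValueError):
    """Concentration matrix is (numerically) rank deficient."""


@dataclass
class PureComponentSet:
    """Extracted component spectra plus fit diagnostics."""

    grid: WavenumberGrid
    components: pd.DataFrame      # index = wavenumber, one column per component
    residual: np.ndarray          # A - S.C^T, same shape as A
    condition_number: float

    @property
    def labels(self) -> list[str]:
        return [str(c) for c in self.components.columns]

    def component(self, label: str) -> Spectrum:
        if label not in self.components.columns:
            raise KeyError(f"no component {label!r}; have {self.labels}")
        return Spectrum(self.grid, self.components[label].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        out = self.components.copy()
        out.insert(0, "wavenumber", self.grid.values)
        out.to_csv(path, index=False)


def _collinear_columns(C: np.ndarray, labels: list[str], tol: float) -> list[str]:
    """Columns with large weight in the smallest singular vectors."""
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    bad = s <= tol * s[0]
    involved: set[str] = set()
    for v in vt[bad]:
        for j in np.flatnonzero(np.abs(v) > 0.3):
            involved.add(labels[j])
    return sorted(involved)


def extract_pure_spectra(
    A: SpectraMatrix,
    C: ConcentrationMatrix,
    *,
    nonnegative: bool = False,
    rank_rtol: float = 1e-10,
) -> PureComponentSet:
    """Solve ``S = argmin || A - S . C^T ||_F`` by per-wavenumber OLS.

    Protein order is taken from ``A``; ``C`` is realigned to it.  A
    tolerance-based rank test on C raises :class:`RankDeficiencyError`
    naming the collinear columns.  With ``nonnegative=True`` each
    wavenumber is solved by non-negative least squares instead.
    """
    Ca = C.aligned_to(A.ids)
    Cm = Ca.values                       # (n_proteins, n_components)
    labels = Ca.columns
    n_prot, n_comp = Cm.shape
    if n_prot < n_comp:
        raise ParameterError(
            f"need at least as many proteins ({n_prot}) as components ({n_comp})"
        )
    if np.linalg.matrix_rank(Cm, tol=rank_rtol * np.linalg.norm(Cm, 2)) < n_comp:
        raise RankDeficiencyError(
            "concentration matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(Cm, labels, 1e-8)}"
        )
    if nonnegative:
        S = np.column_stack([nnls(Cm, A.A[i, :])[0] for i in range(A.A.shape[0])]).T
    else:
        S, *_ = np.linalg.lstsq(Cm, A.A.T, rcond=None)
        S = S.T                          # (n_wavenumbers, n_components)
    residual = A.A - S @ Cm.T
    comps = pd.DataFrame(S, columns=labels, index=A.grid.values)
    return PureComponentSet(A.grid, comps, residual, float(np.linalg.cond(Cm)))


def locate_band_maxima(
    pure: PureComponentSet,
    component: str,
    window: tuple[float, float] | None = None,
) -> list[tuple[float, float]]:
    """Local maxima of one component, as (position, height), descending by height.

    Ties in height are broken by descending wavenumber.  A constant
    spectrum has no local maxima.  ``window`` is (low, high) in cm-1 and
    must lie inside the grid.
    """
    spec = pure.component(component)
    if window is not None:
        lo, hi = min(window), max(window)
        if not spec.grid.covers(lo, hi):
            raise ParameterError(f"window {window} outside grid")
        spec = spec.windowed(lo, hi)
    y = spec.absorbance
    x = spec.grid.values
    if not spec.grid.ascending:
        x, y = x[::-1], y[::-1]
    peaks, _ = find_peaks(y)
    out = [(float(x[i]), float(y[i])) for i in peaks]
    out.sort(key=lambda t: (-t[1], -t[0]))
    return out
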