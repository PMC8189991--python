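"""Subtracting the modelled side-chain contribution from protein spectra.

A measured spectrum is baseline-corrected and scaled to unit area over
1720-1480 cm-1 before analysis, so the side-chain model must be expressed
on the same scale.  The bridge is a single per-residue amide area constant
``amide_area`` (epsilon_amide): the model total area per residue is

    T = amide_area + sum_r fraction_r * area_r(pH)

where ``area_r`` is the integrated band area of residue r from the library.
Dividing the molar-scale side-chain spectrum by T puts it on the unit-area
scale of the measured spectrum, and the subtracted share of the total
absorbance equals ``sum_r fraction_r * area_r / T``.  The default
``amide_area`` is calibrated once so that this share is 20% for an average
soluble-protein composition, the accepted literature figure for the
side-chain contribution in the amide I / amide II region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral_model import (
    AMIDE_WINDOW,
    ParameterError,
    SideChainLibrary,
    Spectrum,
    WavenumberGrid,
    default_library,
    residue_spectrum,
)

__all__ = [
    "MEAN_COMPOSITION_PCT",
    "CorrectionResult",
    "sidechain_area_per_residue",
    "calibrate_amide_area",
    "subtract_sidechains",
    "correct_matrix",
    "rank_by_sidechain_burden",
]

#: reference mean amino-acid composition (percent of residues) of a soluble
#: protein set; used to calibrate the default amide area constant and as the
#: synthetic generator's mean composition.
MEAN_COMPOSITION_PCT: dict[str, float] = {
    "A": 8.5, "R": 4.3, "N": 4.5, "D": 5.9, "C": 1.5,
    "Q": 3.9, "E": 5.4, "G": 7.8, "H": 2.3, "I": 5.6,
    "L": 9.7, "K": 5.8, "M": 2.3, "F": 4.0, "P": 4.8,
    "S": 6.9, "T": 5.3, "W": 1.3, "Y": 3.3, "V": 6.9,
}

#: default target share of side-chain absorbance in the amide window
DEFAULT_SIDECHAIN_SHARE = 0.20

#: fine grid used for integrating library bands
_AREA_GRID = WavenumberGrid.regular(AMIDE_WINDOW[0], AMIDE_WINDOW[1], 0.5)


def _weights(comp) -> dict[str, float]:
    """Mole-fraction weights: composition objects expose them, mappings are taken as-is."""
    if hasattr(comp, "fractions"):
        return dict(comp.fractions)
    return {r: float(v) for r, v in comp.items()}


def _normalized(weights: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ParameterError("weights must have positive sum")
    return {r: v / total for r, v in weights.items()}


def _residue_window_area(lib: SideChainLibrary, res: str, pH: float) -> float:
    """Integrated absorbance of one residue's bands over the amide window."""
    return residue_spectrum(lib[res], pH, _AREA_GRID).area()


def sidechain_area_per_residue(comp, lib: SideChainLibrary, pH: float) -> float:
    """Weight-averaged side-chain band area over the amide window."""
    fr = _weights(comp)
    return sum(f * _residue_window_area(lib, r, pH)
               for r, f in fr.items() if f > 0 and r in lib)


def calibrate_amide_area(
    lib: SideChainLibrary | None = None,
    pH: float = 7.0,
    reference: Mapping[str, float] | None = None,
    target_share: float = DEFAULT_SIDECHAIN_SHARE,
) -> float:
    """Amide area constant making the reference composition's side-chain share equal the target."""
    if lib is None:
        lib = default_library()
    ref = _normalized(_weights(reference if reference is not None else MEAN_COMPOSITION_PCT))
    a = sidechain_area_per_residue(ref, lib, pH)
    if not 0 < target_share < 1:
        raise ParameterError("target share must lie in (0, 1)")
    return a * (1.0 - target_share) / target_share


@dataclass
class CorrectionResult:
    original: Spectrum
    sidechain_total: Spectrum
    per_residue: dict[str, Spectrum]
    corrected: Spectrum
    sidechain_area_fraction: float
    negativity_index: float  # most negative corrected absorbance


def subtract_sidechains(
    s: Spectrum,
    comp,
    lib: SideChainLibrary | None = None,
    pH: float = 7.0,
    amide_area: float | None = None,
    *,
    max_share: float = 0.5,
) -> CorrectionResult:
    """Subtract the composition-weighted side-chain model from a unit-area spectrum.

    ``s`` is expected baseline-corrected and area-normalized over the amide
    window.  ``amide_area`` defaults to the calibrated constant for the
    library at this pH.  A modelled side-chain share above ``max_share``
    raises, flagging implausible composition or band parameters.
    """
    if lib is None:
        lib = default_library()
    if amide_area is None:
        amide_area = calibrate_amide_area(lib, pH)
    fr = _weights(comp)
    per_res_molar: dict[str, Spectrum] = {}
    sc_area = 0.0
    for r, f in fr.items():
        if f <= 0 or r not in lib:
            continue
        spec = f * residue_spectrum(lib[r], pH, s.grid)
        per_res_molar[r] = spec
        sc_area += f * _residue_window_area(lib, r, pH)
    total_area = amide_area + sc_area
    share = sc_area / total_area
    if share > max_share:
        raise ParameterError(
            f"modelled side-chain share {share:.2f} exceeds cap {max_share}; "
            "check composition and band intensities"
        )
    k = 1.0 / total_area  # molar scale -> unit-area spectrum scale
    per_residue = {r: k * spec for r, spec in per_res_molar.items()}
    if per_residue:
        total_vals = np.sum([sp.absorbance for sp in per_residue.values()], axis=0)
    else:
        total_vals = np.zeros(len(s.grid))
    sidechain_total = Spectrum(s.grid, total_vals)
    corrected = s - sidechain_total
    return CorrectionResult(
        original=s.copy(),
        sidechain_total=sidechain_total,
        per_residue=per_residue,
        corrected=corrected,
        sidechain_area_fraction=float(share),
        negativity_index=float(corrected.absorbance.min()),
    )


def correct_matrix(A, comps: Sequence, lib: SideChainLibrary | None = None,
                   pH: float = 7.0, amide_area: float | None = None):
    """Apply :func:`subtract_sidechains` to every column of a SpectraMatrix."""
    from .preprocessing import SpectraMatrix  # local import avoids a cycle

    if len(comps) != A.n_proteins:
        raise ParameterError("one composition per protein required")
    if lib is None:
        lib = default_library()
    if amide_area is None:
        amide_area = calibrate_amide_area(lib, pH)
    cols, shares = [], []
    for j, comp in enumerate(comps):
        res = subtract_sidechains(Spectrum(A.grid, A.A[:, j]), comp, lib, pH, amide_area)
        cols.append(res.corrected.absorbance)
        shares.append(res.sidechain_area_fraction)
    return SpectraMatrix(A.grid, list(A.ids), np.column_stack(cols)), np.array(shares)


def rank_by_sidechain_burden(
    comps: Mapping[str, object],
    lib: SideChainLibrary | None = None,
    pH: float = 7.0,
) -> tuple[pd.DataFrame, float]:
    """Sort proteins by modelled side-chain absorbance per residue.

    The burden score is the amino-acid fraction of each residue multiplied
    by the integrated intensity of its library bands over the amide window,
    summed over residues.  Returns the table sorted descending and the
    max/min score ratio (inf when the minimum is zero).
    """
    if len(comps) < 2:
        raise ParameterError("need at least 2 proteins to rank")
    if lib is None:
        lib = default_library()
    scores = {pid: sidechain_area_per_residue(c, lib, pH) for pid, c in comps.items()}
    table = (pd.DataFrame({"burden": scores})
             .sort_values("burden", ascending=False, kind="stable"))
    smin, smax = table["burden"].min(), table["burden"].max()
    ratio = float("inf") if smin == 0 else float(smax / smin)
    return table, ratio
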