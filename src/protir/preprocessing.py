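"""Standard spectrum preprocessing for the amide I / amide II window.

Every spectrum entering the analysis is windowed to 1720-1480 cm-1, a
straight line interpolated between the absorbances at the two window edges
is subtracted, and the result is scaled to unit trapezoidal area over the
window.  Second derivatives (Savitzky-Golay) sharpen narrow features such
as the tyrosine ring mode near 1514 cm-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectral_model import AMIDE_WINDOW, ParameterError, Spectrum, WavenumberGrid

__all__ = [
    "SpectraMatrix",
    "baseline_correct",
    "area_normalize",
    "second_derivative",
    "assemble_matrix",
    "preprocess",
]


def baseline_correct(s: Spectrum, left: float = 1720.0, right: float = 1480.0) -> Spectrum:
    """Two-point linear baseline subtraction and windowing.

    The baseline is the chord through the absorbance values at the grid
    points nearest ``left`` and ``right``; the output is restricted to the
    window and is exactly zero at both anchor points.
    """
    lo, hi = min(left, right), max(left, right)
    if not s.grid.covers(lo, hi):
        raise ParameterError(
            f"anchors [{lo}, {hi}] outside grid range [{s.grid.lo}, {s.grid.hi}]"
        )
    v = s.grid.values
    i_left = s.grid.index_nearest(left)
    i_right = s.grid.index_nearest(right)
    x1, y1 = v[i_left], s.absorbance[i_left]
    x2, y2 = v[i_right], s.absorbance[i_right]
    slope = (y2 - y1) / (x2 - x1)
    chord = y1 + slope * (v - x1)
    out = Spectrum(s.grid, s.absorbance - chord)
    return out.windowed(min(x1, x2), max(x1, x2))


def area_normalize(s: Spectrum, left: float = 1720.0, right: float = 1480.0) -> Spectrum:
    """Scale so the trapezoidal area between ``right`` and ``left`` equals 1."""
    lo, hi = min(left, right), max(left, right)
    m = s.grid.window_mask(lo, hi)
    area = float(np.trapezoid(s.absorbance[m], s.grid.values[m]))
    if not s.grid.ascending:
        area = -area  # orientation of a descending grid flips the sign
    if area <= 0:
        raise ParameterError(f"non-positive window area {area:g}; cannot normalize")
    return Spectrum(s.grid, s.absorbance / area)


def second_derivative(s: Spectrum, window_pts: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative.

    Requires a uniformly spaced grid.  Narrow bands produce sharp negative
    lobes at their positions, which is what makes e.g. the tyrosine ring
    mode position directly readable.
    """
    if window_pts % 2 != 1 or window_pts <= polyorder or polyorder < 2:
        raise ParameterError("need odd window_pts > polyorder >= 2")
    if window_pts > len(s.grid):
        raise ParameterError("derivative window longer than spectrum")
    d = np.diff(s.grid.values)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("second derivative requires a uniform grid")
    der = savgol_filter(
        s.absorbance, window_length=window_pts, polyorder=polyorder,
        deriv=2, delta=abs(float(d[0])),
    )
    return Spectrum(s.grid, der)


def preprocess(s: Spectrum, left: float = 1720.0, right: float = 1480.0) -> Spectrum:
    """Baseline-correct then area-normalize over the amide window."""
    return area_normalize(baseline_correct(s, left, right), left, right)


@dataclass
class SpectraMatrix:
    """A set of spectra on one common grid: rows = wavenumbers, columns = proteins."""

    grid: WavenumberGrid
    ids: list[str]
    A: np.ndarray  # shape (n_wavenumbers, n_proteins)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.grid), len(self.ids)):
            raise ParameterError(
                f"matrix shape {self.A.shape} != (grid {len(self.grid)}, ids {len(self.ids)})"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError("duplicate protein ids")
        if not np.all(np.isfinite(self.A)):
            raise ParameterError("matrix contains non-finite values")

    @property
    def n_proteins(self) -> int:
        return len(self.ids)

    def column(self, pid: str) -> Spectrum:
        try:
            j = self.ids.index(pid)
        except ValueError:
            raise KeyError(f"protein {pid!r} not in matrix") from None
        return Spectrum(self.grid, self.A[:, j].copy())

    def spectra(self) -> list[Spectrum]:
        return [Spectrum(self.grid, self.A[:, j].copy()) for j in range(self.n_proteins)]

    def map(self, fn) -> "SpectraMatrix":
        """Apply a Spectrum -> Spectrum transform to every column."""
        cols = [fn(Spectrum(self.grid, self.A[:, j])) for j in range(self.n_proteins)]
        grid = cols[0].grid
        for c in cols[1:]:
            if not np.array_equal(c.grid.values, grid.values):
                raise ParameterError("transform produced inconsistent grids")
        return SpectraMatrix(grid, list(self.ids), np.column_stack([c.absorbance for c in cols]))

    def reorder(self, ids: Sequence[str]) -> "SpectraMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SpectraMatrix(self.grid, list(ids), self.A[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.A, columns=self.ids)
        df.insert(0, "wavenumber", self.grid.values)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraMatrix":
        grid = WavenumberGrid(df.iloc[:, 0].to_numpy(dtype=float))
        ids = [str(c) for c in df.columns[1:]]
        return cls(grid, ids, df.iloc[:, 1:].to_numpy(dtype=float))


def assemble_matrix(
    spectra: Sequence[Spectrum],
    ids: Sequence[str],
    *,
    window: tuple[float, float] = AMIDE_WINDOW,
) -> SpectraMatrix:
    """Put spectra on the first spectrum's grid (linear interpolation) and stack.

    Column order follows ``ids``.  Spectra whose range does not cover the
    window raise an error.
    """
    if len(spectra) == 0:
        raise ParameterError("cannot assemble an empty spectra list")
    if len(spectra) != len(ids):
        raise ParameterError("spectra and ids lengths differ")
    lo, hi = window
    ref = spectra[0]
    if not ref.grid.covers(lo, hi):
        raise ParameterError("reference spectrum does not cover the analysis window")
    ref_grid = WavenumberGrid(ref.grid.values[ref.grid.window_mask(lo, hi)])
    xs = ref_grid.values
    cols = []
    for s, pid in zip(spectra, ids):
        if not s.grid.covers(lo, hi):
            raise ParameterError(f"spectrum {pid!r} does not cover [{lo}, {hi}]")
        if np.array_equal(s.grid.values, ref.grid.values):
            y = s.absorbance[ref.grid.window_mask(lo, hi)]
        else:
            gv, av = s.grid.values, s.absorbance
            if not s.grid.ascending:
                gv, av = gv[::-1], av[::-1]
            y = np.interp(xs if ref_grid.ascending else xs[::-1], gv, av)
            if not ref_grid.ascending:
                y = y[::-1]
        cols.append(y)
    return SpectraMatrix(ref_grid, [str(i) for i in ids], np.column_stack(cols))
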