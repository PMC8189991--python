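"""CSV round-trip for spectra, structure tables and compositions.

All artifacts are plain CSV for auditability: spectra files have a
``wavenumber`` first column and one column per protein; structure and
composition tables are indexed by protein id.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import SpectraMatrix
from .spectral_model import ParameterError
from .structure_composition import AminoAcidComposition, ConcentrationMatrix, StructureContent

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
    "write_structures",
    "read_structures",
    "write_compositions",
    "read_compositions",
    "file_checksum",
]

_FLOAT_FMT = "%.12g"


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra CSV (wavenumber + one column per protein)."""
    path = Path(path)
    with open(path, newline="") as f:
        header = next(csv.reader(f))
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParameterError(f"duplicate protein ids in {path}: {dupes}")
    if not ids:
        raise ParameterError(f"{path} contains no protein columns")
    df = pd.read_csv(path)
    if df.shape[1] != len(header):
        raise ParameterError(f"ragged rows in {path}")
    bad = df.columns[~df.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        for col in bad:
            rows = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ParameterError(
                f"non-numeric values in {path}, column {col!r}, rows {rows[:5]}"
            )
    if df.isna().any().any():
        raise ParameterError(f"missing values in {path}")
    return SpectraMatrix.from_frame(df)


def write_spectra(m: SpectraMatrix, path) -> None:
    m.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_concentrations(path) -> ConcentrationMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConcentrationMatrix(df)


def write_concentrations(C: ConcentrationMatrix, path) -> None:
    C.frame.to_csv(path, index_label="protein", float_format=_FLOAT_FMT)


def write_structures(structures: Sequence[StructureContent], ids: Sequence[str], path) -> None:
    pd.DataFrame([s.as_dict() for s in structures], index=list(ids)).to_csv(
        path, index_label="protein", float_format=_FLOAT_FMT)


def read_structures(path) -> tuple[list[StructureContent], list[str]]:
    df = pd.read_csv(path, index_col=0)
    out = [
        StructureContent(dH=r["dH"], dE=r["dE"], dG=r["dG"], dI=r["dI"],
                         dT=r["dT"], dB=r["dB"], dS=r["dS"], dMinus=r["d-"])
        for _, r in df.iterrows()
    ]
    return out, [str(i) for i in df.index]


def write_compositions(comps: Sequence[AminoAcidComposition], ids: Sequence[str], path) -> None:
    rows = [{**{k: v for k, v in c.fractions.items()}, "n_residues": c.n_residues}
            for c in comps]
    pd.DataFrame(rows, index=list(ids)).to_csv(path, index_label="protein",
                                               float_format=_FLOAT_FMT)


def read_compositions(path) -> tuple[list[AminoAcidComposition], list[str]]:
    df = pd.read_csv(path, index_col=0)
    comps = []
    for _, r in df.iterrows():
        n = float(r.get("n_residues", 1.0))
        fr = {k: float(v) for k, v in r.items() if k != "n_residues"}
        comps.append(AminoAcidComposition.from_fractions(fr, n_residues=n))
    return comps, [str(i) for i in df.index]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
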