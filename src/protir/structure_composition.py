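"""Secondary-structure content and amino-acid composition: the C matrix.

Per-residue secondary structure comes from classic DSSP output files
(H, E, G, I, T, B, S and blank); contents are expressed as percent of the
residues in a protein, with ``dOthers = 100 - dH - dE`` lumping everything
that is neither alpha-helix nor beta-sheet.  Amino-acid composition comes
from the one-letter sequence.  Together they form the concentration matrix
used for pure-component extraction and as a non-spectroscopic predictor
block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict

from .spectral_model import STANDARD_RESIDUES

__all__ = [
    "DSSP_CLASSES",
    "StructureContent",
    "XtlsstrContent",
    "AminoAcidComposition",
    "ConcentrationMatrix",
    "DsspParseError",
    "parse_dssp",
    "summarize_structure",
    "composition_from_sequence",
    "build_concentration_matrix",
    "format_dssp",
]

#: the 8 DSSP classes; ' ' (blank) is the unassigned class, reported as d-
DSSP_CLASSES = ("H", "E", "G", "I", "T", "B", "S", " ")


class DsspParseError(ValueError):
    """Malformed DSSP output."""


@dataclass(frozen=True)
class StructureContent:
    """Percent of residues in each DSSP class; dOthers = 100 - dH - dE."""

    dH: float = 0.0
    dE: float = 0.0
    dG: float = 0.0
    dI: float = 0.0
    dT: float = 0.0
    dB: float = 0.0
    dS: float = 0.0
    dMinus: float = 0.0

    def __post_init__(self) -> None:
        total = self.dH + self.dE + self.dG + self.dI + self.dT + self.dB + self.dS + self.dMinus
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"structure contents sum to {total:.3f}, expected 100")

    @property
    def dOthers(self) -> float:
        return 100.0 - self.dH - self.dE

    def as_dict(self) -> dict[str, float]:
        return {
            "dH": self.dH, "dE": self.dE, "dG": self.dG, "dI": self.dI,
            "dT": self.dT, "dB": self.dB, "dS": self.dS, "d-": self.dMinus,
            "dOthers": self.dOthers,
        }


@dataclass(frozen=True)
class XtlsstrContent:
    """Percent content per XTLSSTR class (read from an external table).

    xH/xh are core/peripheral alpha-helix, xE/xe core/peripheral
    beta-strand; the totals are their sums.
    """

    xH: float = 0.0
    xh: float = 0.0
    xG: float = 0.0
    xE: float = 0.0
    xe: float = 0.0
    xT: float = 0.0
    xN: float = 0.0
    xP: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"{name} is negative")

    @property
    def helix_total(self) -> float:
        return self.xH + self.xh

    @property
    def sheet_total(self) -> float:
        return self.xE + self.xe

    def as_dict(self) -> dict[str, float]:
        return {
            "xH": self.xH, "xh": self.xh, "xG": self.xG, "xE": self.xE,
            "xe": self.xe, "xT": self.xT, "xN": self.xN, "xP": self.xP,
        }


@dataclass(frozen=True)
class AminoAcidComposition:
    """Counts and fractions over the 20 standard residues."""

    counts: Mapping[str, float]
    n_residues: float = field(default=0.0)

    def __post_init__(self) -> None:
        counts = {r: float(self.counts.get(r, 0.0)) for r in STANDARD_RESIDUES}
        extra = set(self.counts) - set(STANDARD_RESIDUES)
        if extra:
            raise ValueError(f"non-standard residues in composition: {sorted(extra)}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative residue count")
        n = self.n_residues or sum(counts.values())
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n_residues", float(n))

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {r: 0.0 for r in STANDARD_RESIDUES}
        return {r: v / total for r, v in self.counts.items()}

    def fraction(self, residue: str) -> float:
        return self.fractions[residue]

    def percent(self, residue: str) -> float:
        return 100.0 * self.fraction(residue)

    @classmethod
    def from_fractions(cls, fractions: Mapping[str, float], n_residues: float = 1.0
                       ) -> "AminoAcidComposition":
        total = sum(fractions.values())
        if total <= 0:
            raise ValueError("fractions must have positive sum")
        return cls({r: n_residues * v / total for r, v in fractions.items()},
                   n_residues=n_residues)


@dataclass
class ConcentrationMatrix:
    """Proteins x (dH, dE, dOthers, residue percents) table.

    Structure contents and residue contents are both on the percent scale;
    pure-component extraction is linear, so the unit convention only fixes
    the scale of the extracted components (per-percent).
    """

    frame: pd.DataFrame  # index = protein ids

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate protein ids in concentration matrix")
        if self.frame.isna().any().any():
            raise ValueError("concentration matrix contains missing values")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def aligned_to(self, ids: Sequence[str]) -> "ConcentrationMatrix":
        missing = [i for i in ids if i not in self.frame.index]
        if missing:
            raise ValueError(f"proteins missing from concentration matrix: {missing}")
        return ConcentrationMatrix(self.frame.loc[list(ids)])


def parse_dssp(path) -> list[str]:
    """Per-residue DSSP assignments, in file order.

    Reads the classic fixed-column DSSP text format (via Biopython's DSSP
    file reader); chain-break records are skipped.  Returns one character
    per residue from {H, E, G, I, T, B, S, ' '}.
    """
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:  # biopython raises bare ValueError/IndexError
        raise DsspParseError(f"cannot parse DSSP file {path}: {exc}") from exc
    if not keys:
        raise DsspParseError(f"DSSP file {path} contains no residue records")
    assignments = []
    for k in keys:
        ss = dssp_dict[k][1]
        ss = " " if ss == "-" else ss
        if ss not in DSSP_CLASSES:
            raise DsspParseError(f"unknown DSSP class {ss!r} in {path}")
        assignments.append(ss)
    return assignments


def summarize_structure(assignments: Sequence[str]) -> StructureContent:
    """Percent of residues per DSSP class."""
    if len(assignments) == 0:
        raise ValueError("empty assignment list")
    counts = Counter(assignments)
    unknown = set(counts) - set(DSSP_CLASSES)
    if unknown:
        raise ValueError(f"unknown DSSP classes {sorted(unknown)}")
    n = len(assignments)
    pct = {c: 100.0 * counts.get(c, 0) / n for c in DSSP_CLASSES}
    return StructureContent(
        dH=pct["H"], dE=pct["E"], dG=pct["G"], dI=pct["I"],
        dT=pct["T"], dB=pct["B"], dS=pct["S"], dMinus=pct[" "],
    )


def composition_from_sequence(seq: str, *, count_x: bool = False) -> AminoAcidComposition:
    """Amino-acid composition of a one-letter sequence.

    ``X`` (unknown) is tolerated and excluded from the denominator by
    default; any other non-standard letter raises with its position.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    counts: Counter[str] = Counter()
    n = 0
    for i, ch in enumerate(seq):
        if ch in STANDARD_RESIDUES:
            counts[ch] += 1
            n += 1
        elif ch == "X":
            if count_x:
                n += 1
        else:
            raise ValueError(f"illegal residue {ch!r} at position {i}")
    if n == 0:
        raise ValueError("sequence contains no standard residues")
    return AminoAcidComposition(dict(counts), n_residues=n)


def build_concentration_matrix(
    structures: Sequence[StructureContent],
    comps: Sequence[AminoAcidComposition],
    residues: Sequence[str],
    ids: Sequence[str],
) -> ConcentrationMatrix:
    """Assemble [dH, dE, dOthers, residue percents] per protein."""
    if not (len(structures) == len(comps) == len(ids)):
        raise ValueError(
            f"length mismatch: {len(structures)} structures, "
            f"{len(comps)} compositions, {len(ids)} ids"
        )
    rows = []
    for st, comp in zip(structures, comps):
        row = {"dH": st.dH, "dE": st.dE, "dOthers": st.dOthers}
        for r in residues:
            row[r] = comp.percent(r)
        rows.append(row)
    frame = pd.DataFrame(rows, index=[str(i) for i in ids])
    return ConcentrationMatrix(frame)


# ------------------------------------------------------------------ fixtures
_DSSP_HEADER = """\
==== Secondary Structure Definition by the program DSSP ====
REFERENCE
HEADER
COMPND
SOURCE
AUTHOR
{n:5d}  1  0  0  0 TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS, ...
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
"""


def format_dssp(assignments: Sequence[str], sequence: str | None = None,
                chain: str = "A", breaks: Sequence[int] = ()) -> str:
    """Render assignments as a classic full-width DSSP text file.

    Used to build parser fixtures and round-trip tests; ``breaks`` gives
    0-based positions before which a chain-break ('!') record is inserted.
    """
    if sequence is None:
        sequence = "A" * len(assignments)
    if len(sequence) != len(assignments):
        raise ValueError("sequence and assignments lengths differ")

    def _residue_line(idx: int, resseq: int, aa: str, ss: str) -> str:
        row = [" "] * 136
        row[0:5] = f"{idx:5d}"
        row[5:10] = f"{resseq:5d}"
        row[11] = chain
        row[13] = aa
        row[16] = ss
        row[34:38] = f"{0:4d}"          # ACC
        for a, b in ((38, 45), (50, 56), (61, 67), (72, 78)):   # H-bond relidx
            row[a:b] = f"{0:{b - a}d}"
        for a, b in ((46, 50), (57, 61), (68, 72), (79, 83)):   # H-bond energy
            row[a:b] = f"{0.0:{b - a}.1f}"
        row[103:109] = f"{60.0:6.1f}"   # PHI
        row[109:115] = f"{60.0:6.1f}"   # PSI
        return "".join(row) + "\n"

    lines = [_DSSP_HEADER.format(n=len(assignments))]
    idx = 1
    for i, (aa, ss) in enumerate(zip(sequence, assignments)):
        if i in breaks:
            lines.append(f"{idx:5d}        !\n")
            idx += 1
        lines.append(_residue_line(idx, i + 1, aa, ss))
        idx += 1
    return "".join(lines)
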