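"""Synthetic reference sets mimicking a 92-protein FTIR calibration study.

The generator draws secondary-structure contents (helix / sheet / others)
from a Dirichlet distribution whose concentration is calibrated so the
helix-content standard deviation across proteins matches the 18.3%
reference figure; amino-acid compositions from a logistic-normal model
whose latent means shift with structure content, giving a tunable
structure/composition correlation like the one observed in real protein
sets; and spectra as content-weighted structure basis bands plus
composition-weighted side-chain bands (scaled so an average composition
contributes 20% of the window area), plus linear baseline drift and
Gaussian noise.  With drift, noise and normalization off, the generated
matrix satisfies A = S.C exactly, which anchors the pure-component tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .correction import DEFAULT_SIDECHAIN_SHARE, MEAN_COMPOSITION_PCT, sidechain_area_per_residue
from .preprocessing import SpectraMatrix, preprocess
from .spectral_model import (
    AMIDE_WINDOW,
    BandParams,
    ParameterError,
    SideChainLibrary,
    Spectrum,
    WavenumberGrid,
    default_library,
    residue_spectrum,
)
from .structure_composition import (
    AminoAcidComposition,
    ConcentrationMatrix,
    StructureContent,
    build_concentration_matrix,
)

__all__ = [
    "StructureBasis",
    "GeneratorConfig",
    "calibrate_structure_concentration",
    "sample_structures",
    "sample_compositions",
    "synthesize_protein_spectrum",
    "generate_dataset",
    "STRUCTURE_CLASSES",
    "DEFAULT_CONC_RESIDUES",
]

STRUCTURE_CLASSES = ("helix", "sheet", "others")

#: residues carried as concentration columns by default: the 7 side chains
#: whose bands dominate the amide window (His is in the band library but its
#: contribution is comparatively minor and is left out of the default C).
DEFAULT_CONC_RESIDUES = ("D", "E", "Y", "Q", "N", "R", "K")

_AA = tuple(MEAN_COMPOSITION_PCT)


@dataclass(frozen=True)
class StructureBasis:
    """Amide I + amide II band sets per structure class.

    Defaults encode the canonical band topology: a narrow helix amide I at
    1656 cm-1 with amide II at 1544; sheet amide I at 1634 with its
    high-frequency component near 1690 and amide II at 1536; and a broad
    'others' amide I at 1654 with amide II at 1536.
    """

    helix: tuple[BandParams, ...] = (
        BandParams(1656.0, 28.0, 1.00, 0.7, "amide I, alpha-helix"),
        BandParams(1544.0, 40.0, 0.55, 0.7, "amide II, alpha-helix"),
    )
    sheet: tuple[BandParams, ...] = (
        BandParams(1634.0, 30.0, 1.00, 0.7, "amide I, beta-sheet"),
        BandParams(1690.0, 25.0, 0.25, 0.7, "amide I high-frequency, beta-sheet"),
        BandParams(1536.0, 42.0, 0.50, 0.7, "amide II, beta-sheet"),
    )
    others: tuple[BandParams, ...] = (
        BandParams(1654.0, 55.0, 1.00, 0.7, "amide I, irregular/turn"),
        BandParams(1536.0, 48.0, 0.50, 0.7, "amide II, irregular/turn"),
    )

    def bands(self, cls: str) -> tuple[BandParams, ...]:
        try:
            return getattr(self, cls)
        except AttributeError:
            raise ParameterError(f"unknown structure class {cls!r}") from None

    def class_spectrum(self, cls: str, grid: WavenumberGrid) -> Spectrum:
        """Unit-area basis spectrum of one class on the grid."""
        total = np.zeros(len(grid))
        for b in self.bands(cls):
            x = (2.0 * (grid.values - b.position) / b.fwhm) ** 2
            total += b.intensity * (b.gauss_fraction * np.exp(-np.log(2.0) * x)
                                    + (1 - b.gauss_fraction) / (1 + x))
        s = Spectrum(grid, total)
        return s * (1.0 / s.area(*AMIDE_WINDOW))


def calibrate_structure_concentration(
    target_std_pct: float = 18.3,
    mean: Sequence[float] = (0.30, 0.20, 0.50),
) -> tuple[float, float, float]:
    """Dirichlet parameters with given mean whose helix marginal has the target stddev.

    For Dirichlet(alpha0 * m) the helix content (in percent) has standard
    deviation ``100 * sqrt(m_H (1 - m_H) / (alpha0 + 1))``; solving for
    alpha0 is closed-form.
    """
    m = np.asarray(mean, float)
    if abs(m.sum() - 1.0) > 1e-9 or np.any(m <= 0):
        raise ParameterError("mean must be positive and sum to 1")
    mh = m[0]
    alpha0 = mh * (1 - mh) * 1e4 / target_std_pct**2 - 1.0
    if alpha0 <= 0:
        raise ParameterError(f"target stddev {target_std_pct}% is infeasible")
    return tuple(float(a) for a in alpha0 * m)


#: default structure/composition correlation targets (residue, class) -> r,
#: emulating the observed prevalence of certain residues in certain
#: structures (helix formers Leu/Ala, breaker Pro, sheet formers Val/Ile).
DEFAULT_COMPOSITION_CORR: dict[tuple[str, str], float] = {
    ("L", "helix"): 0.45,
    ("A", "helix"): 0.30,
    ("P", "helix"): -0.40,
    ("V", "sheet"): 0.40,
    ("I", "sheet"): 0.30,
    ("G", "others"): 0.30,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with reproducibility from one seed."""

    n_proteins: int = 92
    seed: int = 0
    structure_alpha: tuple[float, float, float] = field(
        default_factory=calibrate_structure_concentration)
    structure_mean: tuple[float, float, float] = (0.30, 0.20, 0.50)
    composition_mean_pct: Mapping[str, float] = field(
        default_factory=lambda: dict(MEAN_COMPOSITION_PCT))
    composition_corr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_CORR))
    composition_sigma: float = 0.5   # latent log-scale spread of fractions
    sidechain_share: float = DEFAULT_SIDECHAIN_SHARE
    noise_sigma: float = 0.005       # Gaussian noise, fraction of max absorbance
    drift_amplitude: float = 0.02    # baseline drift, fraction of max absorbance
    pH: float = 7.0
    grid_lo: float = 1448.0   # window anchors 1480/1720 fall on the 4 cm-1 grid
    grid_hi: float = 1752.0
    grid_step: float = 4.0
    normalize: bool = True           # run standard preprocessing on outputs
    conc_residues: tuple[str, ...] = DEFAULT_CONC_RESIDUES
    mean_residue_count: float = 300.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be positive")
        for (res, cls), r in self.composition_corr.items():
            if abs(r) >= 1:
                raise ParameterError(f"correlation target |r| >= 1 for {(res, cls)}")
            if res not in _AA or cls not in STRUCTURE_CLASSES:
                raise ParameterError(f"unknown correlation key {(res, cls)}")
        if not 0 <= self.sidechain_share < 1:
            raise ParameterError("sidechain_share must lie in [0, 1)")

    @property
    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.regular(self.grid_lo, self.grid_hi, self.grid_step)

    # -------------------------------------------------------------- serialization
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["structure_alpha"] = list(self.structure_alpha)
        d["structure_mean"] = list(self.structure_mean)
        d["conc_residues"] = list(self.conc_residues)
        d["composition_corr"] = {f"{r}:{c}": v for (r, c), v in self.composition_corr.items()}
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["structure_alpha"] = tuple(d["structure_alpha"])
        d["structure_mean"] = tuple(d["structure_mean"])
        d["conc_residues"] = tuple(d["conc_residues"])
        d["composition_corr"] = {tuple(k.split(":")): v
                                 for k, v in d["composition_corr"].items()}
        return cls(**d)


def sample_structures(cfg: GeneratorConfig, rng: np.random.Generator | None = None
                      ) -> list[StructureContent]:
    """Dirichlet draws of (helix, sheet, others) in percent.

    The non-helix, non-sheet mass is reported in the unassigned class
    (d-), so the 8-class total stays at 100; minor helical/turn classes
    are left at zero.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    draws = rng.dirichlet(np.asarray(cfg.structure_alpha, float), size=cfg.n_proteins)
    out = []
    for h, e, o in draws * 100.0:
        out.append(StructureContent(dH=h, dE=e, dMinus=o))
    return out


def _structure_fraction(st: StructureContent, cls: str) -> float:
    if cls == "helix":
        return st.dH / 100.0
    if cls == "sheet":
        return st.dE / 100.0
    if cls == "others":
        return st.dOthers / 100.0
    raise ParameterError(f"unknown structure class {cls!r}")


def sample_compositions(
    structures: Sequence[StructureContent],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[AminoAcidComposition]:
    """Logistic-normal compositions whose latent means track structure content.

    For each residue the latent variable is ``log(mean fraction) +
    c * s_tilde + sigma * eps`` with standardized structure content
    ``s_tilde`` and ``c = sigma * r / sqrt(1 - r**2)``, so the latent
    correlation with the structure class equals the target ``r``; the
    softmax then yields fractions summing to one.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    mean = np.array([cfg.composition_mean_pct[a] for a in _AA], float)
    mean = mean / mean.sum()
    sigma = cfg.composition_sigma

    alpha = np.asarray(cfg.structure_alpha, float)
    a0 = alpha.sum()
    m = alpha / a0
    theo_std = np.sqrt(m * (1 - m) / (a0 + 1))  # of the fractions

    cls_idx = {c: k for k, c in enumerate(STRUCTURE_CLASSES)}
    shift = np.zeros((len(structures), len(_AA)))
    svals = np.array([[_structure_fraction(st, c) for c in STRUCTURE_CLASSES]
                      for st in structures])
    stilde = (svals - m) / theo_std
    for (res, cls), r in cfg.composition_corr.items():
        c = sigma * r / np.sqrt(1.0 - r**2)
        shift[:, _AA.index(res)] += c * stilde[:, cls_idx[cls]]

    z = np.log(mean)[None, :] + shift + sigma * rng.standard_normal(shift.shape)
    expz = np.exp(z - z.max(axis=1, keepdims=True))
    fracs = expz / expz.sum(axis=1, keepdims=True)
    out = []
    for row in fracs:
        out.append(AminoAcidComposition.from_fractions(
            dict(zip(_AA, row)), n_residues=cfg.mean_residue_count))
    return out


def _sidechain_scale(cfg: GeneratorConfig, lib: SideChainLibrary) -> float:
    """Molar-to-spectrum scale putting the mean composition at the target share."""
    if cfg.sidechain_share == 0:
        return 0.0
    mean_fr = {a: v / 100.0 for a, v in cfg.composition_mean_pct.items()}
    a_mean = sidechain_area_per_residue(mean_fr, lib, cfg.pH)
    if a_mean <= 0:
        raise ParameterError("library has no absorbance over the window")
    return cfg.sidechain_share / (1.0 - cfg.sidechain_share) / a_mean


def synthesize_protein_spectrum(
    structure: StructureContent,
    comp: AminoAcidComposition,
    basis: StructureBasis,
    lib: SideChainLibrary,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    *,
    sidechain_scale: float | None = None,
    restrict_residues: Sequence[str] | None = None,
) -> Spectrum:
    """Forward model for one protein: structure bands + side chains + drift + noise."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    grid = cfg.grid
    if sidechain_scale is None:
        sidechain_scale = _sidechain_scale(cfg, lib)
    residues = cfg.conc_residues if restrict_residues is None else restrict_residues

    clean = np.zeros(len(grid))
    for cls in STRUCTURE_CLASSES:
        clean += _structure_fraction(structure, cls) * basis.class_spectrum(cls, grid).absorbance
    for r in residues:
        f = comp.fraction(r)
        if f > 0 and r in lib:
            clean += sidechain_scale * f * residue_spectrum(lib[r], cfg.pH, grid).absorbance

    amax = np.abs(clean).max()
    mid = 0.5 * (grid.lo + grid.hi)
    drift = (cfg.drift_amplitude * amax
             * (rng.uniform(-1, 1) + rng.uniform(-1, 1) * (grid.values - mid)
                / (grid.hi - grid.lo)))
    noise = cfg.noise_sigma * amax * rng.standard_normal(len(grid))
    raw = Spectrum(grid, clean + drift + noise)
    if cfg.normalize:
        return preprocess(raw)
    return raw.windowed(*AMIDE_WINDOW)


def generate_dataset(
    cfg: GeneratorConfig,
    basis: StructureBasis | None = None,
    lib: SideChainLibrary | None = None,
) -> tuple[SpectraMatrix, ConcentrationMatrix, dict]:
    """Full synthetic study: spectra, concentrations and ground truth.

    The truth bundle holds everything a test needs: sampled structures and
    compositions, the per-percent pure-component matrix ``S_true`` on the
    analysis window, and the exact noiseless product ``A_exact = S_true @
    C.T`` (which equals the returned spectra when noise, drift and
    normalization are switched off).
    """
    basis = StructureBasis() if basis is None else basis
    lib = default_library() if lib is None else lib
    rng = np.random.default_rng(cfg.seed)

    structures = sample_structures(cfg, rng)
    comps = sample_compositions(structures, cfg, rng)
    ids = [f"P{i + 1:03d}" for i in range(cfg.n_proteins)]
    scale = _sidechain_scale(cfg, lib)

    spectra = [
        synthesize_protein_spectrum(st, co, basis, lib, cfg, rng, sidechain_scale=scale)
        for st, co in zip(structures, comps)
    ]
    A = SpectraMatrix(spectra[0].grid, ids, np.column_stack([s.absorbance for s in spectra]))
    C = build_concentration_matrix(structures, comps, list(cfg.conc_residues), ids)

    # per-percent pure components on the analysis window
    wgrid = A.grid
    cols: dict[str, np.ndarray] = {
        "dH": basis.class_spectrum("helix", wgrid).absorbance / 100.0,
        "dE": basis.class_spectrum("sheet", wgrid).absorbance / 100.0,
        "dOthers": basis.class_spectrum("others", wgrid).absorbance / 100.0,
    }
    for r in cfg.conc_residues:
        cols[r] = scale * residue_spectrum(lib[r], cfg.pH, wgrid).absorbance / 100.0
    S_true = np.column_stack([cols[c] for c in C.columns])
    truth = {
        "structures": structures,
        "compositions": comps,
        "ids": ids,
        "S_true": S_true,
        "S_labels": C.columns,
        "A_exact": S_true @ C.values.T,
        "sidechain_scale": scale,
        "basis": basis,
        "library": lib,
        "config": cfg,
    }
    return A, C, truth
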