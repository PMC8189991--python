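"""Calibration and validation of structure-content prediction from spectra.

Three regression families are used to map a predictor block (absorbances
at each wavenumber, or amino-acid fractions) to a secondary-structure
content in percent:

* ascending stepwise linear regression (ASLR): greedy forward selection of
  single features into an ordinary least-squares model, the selection
  criterion being the leave-one-out RMSE of the augmented model;
* partial least squares (PLS): single-response SIMPLS, with the number of
  latent variables chosen at the first LOO-RMSECV minimum within 2% of the
  global minimum;
* least-squares support-vector regression (LS-SVM, Suykens formulation):
  an RBF-kernel model obtained from one dense linear system
  ``[[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]``.

Prediction quality is summarized as RMSE under leave-one-out
cross-validation (RMSECV) or on a Kennard-Stone selected test set (RMSEKS),
and as ``zeta = STDDEV_REF / RMSE`` -- how much better the model is than
always guessing the mean (zeta near 1 means no added value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral_model import ParameterError

__all__ = [
    "ZETA_CAP",
    "PredictorBlock",
    "AslrModel",
    "PlsModel",
    "LssvmModel",
    "CVResult",
    "ValidationReport",
    "aslr_fit",
    "pls_fit",
    "pls_select_lv",
    "lssvm_fit",
    "lssvm_tune",
    "rbf_kernel",
    "median_heuristic",
    "loo_cv",
    "kennard_stone_select",
    "evaluate_all",
]

#: reported zeta when the RMSE is (numerically) zero
ZETA_CAP = 99.0


@dataclass
class PredictorBlock:
    """Samples x features matrix with feature labels."""

    X: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ParameterError("predictor block must be 2-D")
        if self.X.shape[1] != len(self.labels):
            raise ParameterError("label count does not match feature count")
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("predictor block contains missing values")

    @classmethod
    def from_spectra(cls, m) -> "PredictorBlock":
        """Proteins x wavenumbers block from a SpectraMatrix."""
        return cls(m.A.T.copy(), [float(v) for v in m.grid.values])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictorBlock":
        return cls(df.to_numpy(dtype=float), list(df.columns))


# ---------------------------------------------------------------------------
# Ordinary least squares with fast leave-one-out
# ---------------------------------------------------------------------------

def _ols_loo_rmse(Z: np.ndarray, y: np.ndarray) -> float:
    """LOO RMSE of OLS on design Z (intercept included) via the hat matrix."""
    q, _ = np.linalg.qr(Z)
    h = np.sum(q * q, axis=1)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    e = y - Z @ beta
    denom = np.clip(1.0 - h, 1e-12, None)
    return float(np.sqrt(np.mean((e / denom) ** 2)))


@dataclass
class AslrModel:
    """Forward-selected linear model: y = intercept + X[:, idx] @ coef."""

    features: list          # selected labels, in selection order
    feature_idx: list[int]  # column indices into the training block
    coef: np.ndarray
    intercept: float
    criterion_path: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X[:, self.feature_idx] @ self.coef


def aslr_fit(
    block: PredictorBlock,
    y: np.ndarray,
    max_terms: int = 5,
    *,
    stop_when_worse: bool = True,
) -> AslrModel:
    """Ascending stepwise linear regression.

    One feature at a time is added to an OLS model, each step picking the
    candidate that minimizes the LOO RMSE of the augmented model (ties
    broken by lower feature index).  Selection stops at ``max_terms`` or,
    if ``stop_when_worse``, as soon as no candidate improves the criterion.
    """
    X = block.X
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= max_terms + 1:
        raise ParameterError(f"need more than max_terms + 1 = {max_terms + 1} samples")
    if np.std(y) == 0:
        raise ParameterError("constant response; nothing to regress")

    selected: list[int] = []
    # intercept-only LOO: leave-one-out mean prediction
    resid = y - np.mean(y)
    current = float(np.sqrt(np.mean((resid * n / (n - 1)) ** 2)))
    path = [current]
    while len(selected) < max_terms:
        best_j, best_rmse = -1, np.inf
        for j in range(p):
            if j in selected:
                continue
            Z = np.column_stack([np.ones(n), X[:, selected + [j]]])
            r = _ols_loo_rmse(Z, y)
            if r < best_rmse - 1e-15:
                best_j, best_rmse = j, r
        if best_j < 0 or (stop_when_worse and best_rmse >= current):
            break
        selected.append(best_j)
        current = best_rmse
        path.append(current)

    Z = np.column_stack([np.ones(n), X[:, selected]])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return AslrModel(
        features=[block.labels[j] for j in selected],
        feature_idx=list(selected),
        coef=beta[1:],
        intercept=float(beta[0]),
        criterion_path=path,
    )


# ---------------------------------------------------------------------------
# PLS (single-response SIMPLS)
# ---------------------------------------------------------------------------

def _simpls(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Single-y SIMPLS; returns coefficient vectors for 1..max_lv components.

    Data are mean-centered internally; returned ``B[:, a-1]`` applies to
    centered X and predicts centered y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    max_lv = int(min(max_lv, n - 1, p))
    s = Xc.T @ yc
    R = np.zeros((p, max_lv))
    V = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    for a in range(max_lv):
        r = s.copy()
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm <= 1e-13 * (np.linalg.norm(Xc) + 1e-300):
            max_lv = a
            break
        t /= tnorm
        r /= tnorm
        pvec = Xc.T @ t
        q[a] = yc @ t
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        vnorm = np.linalg.norm(v)
        if vnorm <= 0:
            max_lv = a
            break
        v /= vnorm
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
    B = np.cumsum(R[:, :max_lv] * q[:max_lv], axis=1)
    return B, xbar, ybar, max_lv


@dataclass
class PlsModel:
    """Fitted single-response PLS model with ``n_lv`` latent variables."""

    n_lv: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.coef


def pls_fit(block: PredictorBlock | np.ndarray, y: np.ndarray, n_lv: int) -> PlsModel:
    """Fit PLS with ``n_lv`` latent variables (mean-centered, no autoscaling)."""
    X = block.X if isinstance(block, PredictorBlock) else np.asarray(block, float)
    max_possible = min(X.shape[0] - 1, X.shape[1])
    if n_lv > max_possible:
        warnings.warn(f"n_lv={n_lv} exceeds rank bound {max_possible}; clipped")
        n_lv = max_possible
    if n_lv < 1:
        raise ParameterError("need at least 1 latent variable")
    B, xbar, ybar, got = _simpls(X, y, n_lv)
    return PlsModel(n_lv=min(n_lv, got), coef=B[:, min(n_lv, got) - 1],
                    x_mean=xbar, y_mean=float(ybar))


def _pls_loo_rmse_curve(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """LOO RMSECV for each number of latent variables, 1..max_lv."""
    n = X.shape[0]
    max_lv = int(min(max_lv, n - 2, X.shape[1]))
    sq = np.zeros((n, max_lv))
    for i in range(n):
        tr = np.arange(n) != i
        B, xbar, ybar, got = _simpls(X[tr], y[tr], max_lv)
        pred = ybar + (X[i] - xbar) @ B[:, :got]
        pred = np.pad(pred, (0, max_lv - got), mode="edge") if got < max_lv else pred
        sq[i] = (pred - y[i]) ** 2
    return np.sqrt(sq.mean(axis=0))


def pls_select_lv(block: PredictorBlock | np.ndarray, y: np.ndarray,
                  max_lv: int = 15, tol: float = 0.02) -> int:
    """Number of LVs at the first LOO-RMSECV minimum within ``tol`` of the global one."""
    X = block.X if isinstance(block, PredictorBlock) else np.asarray(block, float)
    curve = _pls_loo_rmse_curve(X, np.asarray(y, float), max_lv)
    best = curve.min()
    for a, r in enumerate(curve, start=1):
        if r <= (1.0 + tol) * best:
            return a
    return int(np.argmin(curve)) + 1  # pragma: no cover


# ---------------------------------------------------------------------------
# LS-SVM (Suykens formulation, RBF kernel)
# ---------------------------------------------------------------------------

def rbf_kernel(X1: np.ndarray, X2: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel ``exp(-||x - x'||^2 / (2 * bandwidth^2))``."""
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    d2 = (np.sum(X1**2, axis=1)[:, None] + np.sum(X2**2, axis=1)[None, :]
          - 2.0 * X1 @ X2.T)
    return np.exp(-np.clip(d2, 0, None) / (2.0 * bandwidth**2))


def median_heuristic(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (bandwidth scale)."""
    X = np.atleast_2d(np.asarray(X, float))
    d2 = (np.sum(X**2, axis=1)[:, None] + np.sum(X**2, axis=1)[None, :]
          - 2.0 * X @ X.T)
    iu = np.triu_indices(X.shape[0], k=1)
    med = float(np.sqrt(np.clip(np.median(d2[iu]), 1e-300, None)))
    return med if med > 0 else 1.0


@dataclass
class LssvmModel:
    """LS-SVM regressor: predict(x) = sum_i alpha_i k(x_i, x) + b."""

    X_train: np.ndarray
    alpha: np.ndarray
    b: float
    gamma: float
    bandwidth: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = rbf_kernel(np.atleast_2d(X), self.X_train, self.bandwidth)
        return K @ self.alpha + self.b


def _lssvm_system(K: np.ndarray, gamma: float) -> np.ndarray:
    n = K.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    return M


def lssvm_fit(X: np.ndarray, y: np.ndarray, gamma: float = 10.0,
              bandwidth: float | None = None) -> LssvmModel:
    """Solve the LS-SVM linear system for dual coefficients and bias."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if bandwidth is None:
        bandwidth = median_heuristic(X)
    K = rbf_kernel(X, X, bandwidth)
    M = _lssvm_system(K, gamma)
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            f"LS-SVM system is singular ({exc}); increase the ridge 1/gamma"
        ) from exc
    return LssvmModel(X_train=X.copy(), alpha=sol[1:], b=float(sol[0]),
                      gamma=gamma, bandwidth=bandwidth)


def _lssvm_loo_rmse(K: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Closed-form LOO RMSE: residual_i = alpha_i / (M^-1)_{ii}."""
    M = _lssvm_system(K, gamma)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.inf
    sol = Minv @ np.concatenate([[0.0], y])
    alpha = sol[1:]
    diag = np.diag(Minv)[1:]
    if np.any(np.abs(diag) < 1e-300):
        return np.inf
    return float(np.sqrt(np.mean((alpha / diag) ** 2)))


DEFAULT_GAMMAS = (0.1, 1.0, 10.0, 100.0, 1e3, 1e4)
DEFAULT_BW_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0)


def lssvm_tune(X: np.ndarray, y: np.ndarray,
               gammas: Sequence[float] = DEFAULT_GAMMAS,
               bw_factors: Sequence[float] = DEFAULT_BW_FACTORS,
               ) -> tuple[float, float]:
    """Grid-search (gamma, bandwidth) minimizing the closed-form LOO RMSE."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    base = median_heuristic(X)
    best = (np.inf, gammas[0], base)
    for f in bw_factors:
        bw = base * f
        K = rbf_kernel(X, X, bw)
        for g in gammas:
            r = _lssvm_loo_rmse(K, y, g)
            if r < best[0] - 1e-15:
                best = (r, g, bw)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    rmse: float
    stddev_ref: float
    zeta: float
    n: int
    n_failed: int = 0


def _zeta(stddev: float, rmse: float) -> float:
    if rmse <= 1e-12 * max(stddev, 1.0):
        return ZETA_CAP
    return min(stddev / rmse, ZETA_CAP)


def loo_cv(fit: Callable, X: np.ndarray, y: np.ndarray) -> CVResult:
    """Leave-one-out cross-validation of an arbitrary fit procedure.

    ``fit(X_train, y_train)`` must return a callable predicting from a 2-D
    array.  The whole fitting procedure -- including any feature or
    latent-variable selection -- runs inside each fold.  STDDEV_REF is the
    sample standard deviation (ddof=1) of y.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 3:
        raise ParameterError("need at least 3 samples for LOO")
    sq, failed = [], 0
    for i in range(n):
        tr = np.arange(n) != i
        try:
            predict = fit(X[tr], y[tr])
            pred = float(np.asarray(predict(X[i:i + 1])).ravel()[0])
        except Exception:
            failed += 1
            continue
        sq.append((pred - y[i]) ** 2)
    if failed > 0.1 * n:
        raise ParameterError(f"{failed}/{n} LOO folds failed")
    rmse = float(np.sqrt(np.mean(sq)))
    stddev = float(np.std(y, ddof=1))
    return CVResult(rmse=rmse, stddev_ref=stddev, zeta=_zeta(stddev, rmse),
                    n=n, n_failed=failed)


def kennard_stone_select(
    T: np.ndarray,
    fraction: float = 1.0 / 3.0,
    n_select: int | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Classic Kennard-Stone max-min selection.

    Starts from the two mutually most distant points, then repeatedly adds
    the point maximizing its minimum distance to the selected set, until
    ``ceil(fraction * n)`` (or ``n_select``) points are chosen.  Ties break
    toward the lower index.  Returns indices in selection order.
    """
    T = np.atleast_2d(np.asarray(T, float))
    n = T.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 points")
    if n_select is None:
        n_select = math.ceil(fraction * n)
    n_select = min(max(n_select, 2), n)
    if standardize:
        sd = T.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        T = (T - T.mean(axis=0)) / sd
    d2 = (np.sum(T**2, axis=1)[:, None] + np.sum(T**2, axis=1)[None, :]
          - 2.0 * T @ T.T)
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)  # row-major: lowest index first
    selected = [min(i, j), max(i, j)]
    np.fill_diagonal(d2, np.inf)
    while len(selected) < n_select:
        mind = d2[selected, :].min(axis=0)
        mind[selected] = -np.inf
        selected.append(int(np.argmax(mind)))
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# Full evaluation cross
# ---------------------------------------------------------------------------

def _make_fitter(method: str, selection: str, *, aslr_max_terms: int,
                 pls_max_lv: int, fixed: dict) -> Callable:
    """Return fit(X, y) -> predict for one method/selection mode.

    ``selection='nested'`` reruns feature/LV/hyperparameter selection on
    every training set it is handed; ``'global'`` reuses choices stored in
    ``fixed`` (made once, before splitting).
    """
    if method == "aslr":
        def fit(Xtr, ytr):
            if selection == "global" and "feature_idx" in fixed:
                idx = fixed["feature_idx"]
                Z = np.column_stack([np.ones(len(ytr)), Xtr[:, idx]])
                beta, *_ = np.linalg.lstsq(Z, ytr, rcond=None)
                return lambda X: beta[0] + np.atleast_2d(X)[:, idx] @ beta[1:]
            block = PredictorBlock(Xtr, list(range(Xtr.shape[1])))
            model = aslr_fit(block, ytr, max_terms=aslr_max_terms)
            return model.predict
        return fit
    if method == "pls":
        def fit(Xtr, ytr):
            if selection == "global" and "n_lv" in fixed:
                n_lv = fixed["n_lv"]
            else:
                n_lv = pls_select_lv(Xtr, ytr, max_lv=pls_max_lv)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = pls_fit(Xtr, ytr, n_lv)
            return model.predict
        return fit
    if method == "lssvm":
        def fit(Xtr, ytr):
            if selection == "global" and "gamma" in fixed:
                g, bw = fixed["gamma"], fixed["bandwidth"]
            else:
                g, bw = lssvm_tune(Xtr, ytr)
            return lssvm_fit(Xtr, ytr, gamma=g, bandwidth=bw).predict
        return fit
    raise ParameterError(f"unknown method {method!r}")


def _global_choices(method: str, X: np.ndarray, y: np.ndarray, *,
                    aslr_max_terms: int, pls_max_lv: int) -> dict:
    if method == "aslr":
        block = PredictorBlock(X, list(range(X.shape[1])))
        return {"feature_idx": aslr_fit(block, y, max_terms=aslr_max_terms).feature_idx}
    if method == "pls":
        return {"n_lv": pls_select_lv(X, y, max_lv=pls_max_lv)}
    if method == "lssvm":
        g, bw = lssvm_tune(X, y)
        return {"gamma": g, "bandwidth": bw}
    raise ParameterError(f"unknown method {method!r}")


@dataclass
class ValidationReport:
    """Long-format table: one row per class x method x variant x split."""

    frame: pd.DataFrame

    def check_consistency(self) -> bool:
        """Every stored zeta must equal stddev_ref / rmse (capped)."""
        f = self.frame
        expected = [_zeta(s, r) for s, r in zip(f["stddev_ref"], f["rmse"])]
        return bool(np.allclose(f["zeta"], expected, rtol=1e-9, atol=1e-12))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def evaluate_all(
    variants: Mapping[str, "object"],
    targets: pd.DataFrame,
    methods: Sequence[str] = ("aslr", "pls", "lssvm"),
    splits: Sequence[str] = ("loo", "ks"),
    *,
    selection: str = "nested",
    ks_fraction: float = 1.0 / 3.0,
    ks_space: pd.DataFrame | None = None,
    aslr_max_terms: int = 5,
    pls_max_lv: int = 12,
) -> ValidationReport:
    """Full cross of structure classes x methods x spectrum variants x splits.

    ``variants`` maps a name (e.g. 'raw', 'corrected') to a SpectraMatrix
    or a PredictorBlock; ``targets`` holds one percent-content column per
    structure class, indexed by protein id (or positionally aligned).  The
    Kennard-Stone test set is selected on standardized structure contents
    (``ks_space``; defaults to dH/dE/dOthers columns of ``targets`` when
    present, else all target columns), and its STDDEV_REF is computed on
    the test set, which generally differs from the LOO one.
    """
    if selection not in ("nested", "global"):
        raise ParameterError("selection must be 'nested' or 'global'")
    blocks: dict[str, PredictorBlock] = {}
    for name, v in variants.items():
        blocks[name] = v if isinstance(v, PredictorBlock) else PredictorBlock.from_spectra(v)
    n = len(targets)
    for name, b in blocks.items():
        if b.X.shape[0] != n:
            raise ParameterError(f"variant {name!r} has {b.X.shape[0]} rows, targets {n}")

    rows = []
    ks_test: np.ndarray | None = None
    if "ks" in splits:
        if ks_space is None:
            cols = [c for c in ("dH", "dE", "dOthers") if c in targets.columns]
            ks_space = targets[cols] if cols else targets
        ks_test = kennard_stone_select(ks_space.to_numpy(float), fraction=ks_fraction)

    for cls_label in targets.columns:
        y = targets[cls_label].to_numpy(float)
        for method in methods:
            for variant, block in blocks.items():
                X = block.X
                for split in splits:
                    if split == "loo":
                        fixed = (_global_choices(method, X, y,
                                                 aslr_max_terms=aslr_max_terms,
                                                 pls_max_lv=pls_max_lv)
                                 if selection == "global" else {})
                        fitter = _make_fitter(method, selection,
                                              aslr_max_terms=aslr_max_terms,
                                              pls_max_lv=pls_max_lv, fixed=fixed)
                        res = loo_cv(fitter, X, y)
                        info = str(fixed) if fixed else "nested"
                    elif split == "ks":
                        test = ks_test
                        train = np.setdiff1d(np.arange(n), test)
                        fixed = (_global_choices(method, X[train], y[train],
                                                 aslr_max_terms=aslr_max_terms,
                                                 pls_max_lv=pls_max_lv)
                                 if selection == "global" else {})
                        fitter = _make_fitter(method, selection,
                                              aslr_max_terms=aslr_max_terms,
                                              pls_max_lv=pls_max_lv, fixed=fixed)
                        predict = fitter(X[train], y[train])
                        pred = np.asarray(predict(X[test])).ravel()
                        rmse = float(np.sqrt(np.mean((pred - y[test]) ** 2)))
                        sd = float(np.std(y[test], ddof=1))
                        res = CVResult(rmse=rmse, stddev_ref=sd,
                                       zeta=_zeta(sd, rmse), n=len(test))
                        info = str(fixed) if fixed else "nested"
                    else:
                        raise ParameterError(f"unknown split {split!r}")
                    rows.append({
                        "structure": cls_label, "method": method,
                        "variant": variant, "split": split,
                        "rmse": res.rmse, "stddev_ref": res.stddev_ref,
                        "zeta": res.zeta, "n_eval": res.n, "model_info": info,
                    })
    return ValidationReport(pd.DataFrame(rows))
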