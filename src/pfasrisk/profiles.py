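"""Contamination-profile comparison by PCA.

Concentration profiles (samples x compounds, ng/L) are log10-transformed and
Pareto-scaled (column-centered, divided by the square root of the column SD
— the standard chemometrics companion to a log transform, damping dominant
high-concentration compounds without the noise inflation of full
unit-variance scaling), then decomposed by iterative deflation-based PCA
(NIPALS).  Model quality is reported as per-component and cumulative R2X and
a cumulative Q2 from element-wise deletion cross-validation; Q2 > 0.5 is the
usual rule of thumb for good predictive stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaModel", "preprocess", "pca_fit", "q2_cv"]


@dataclass
class PcaModel:
    """Scores/loadings decomposition with explained-variance bookkeeping."""

    n_components: int
    scores: pd.DataFrame      # samples x components (t)
    loadings: pd.DataFrame    # variables x components (p), orthonormal
    r2x: np.ndarray           # per-component explained fraction of total SS
    r2x_cum: np.ndarray       # cumulative

    def reconstruct(self) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def preprocess(
    matrix: pd.DataFrame,
    scaling: str = "pareto",
) -> pd.DataFrame:
    """Log10 transform followed by column scaling.

    Zeros (and censored cells left as NaN) are replaced by half the smallest
    positive value of their compound before taking logs; all-zero compounds
    are dropped with a warning.  ``scaling`` is ``"pareto"`` (center, divide
    by sqrt(SD)), ``"uv"`` (unit variance) or ``"none"`` (center only).
    """
    if scaling not in ("pareto", "uv", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.astype(float).copy()
    if (X.to_numpy() < 0).any():
        raise ValueError("concentrations must be non-negative")
    keep = []
    for col in X.columns:
        v = X[col]
        positive = v[v > 0]
        if positive.empty:
            warnings.warn(f"dropping all-zero compound column {col!r}")
            continue
        half_min = positive.min() / 2.0
        X[col] = v.where(v > 0, half_min).fillna(half_min)
        keep.append(col)
    X = np.log10(X[keep])
    X = X - X.mean(axis=0)
    if scaling != "none":
        sd = X.std(axis=0, ddof=1)
        sd = sd.where(sd > 0, 1.0)
        X = X / np.sqrt(sd) if scaling == "pareto" else X / sd
    return X


def _nipals(X: np.ndarray, n_components: int, tol: float = 1e-14,
            max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Deflation-based PCA on an already-centered matrix.

    Returns (scores T, loadings P) with orthonormal loading columns.  The
    sign convention fixes the largest-magnitude loading of each component
    positive, so results are reproducible across runs.
    """
    n, p = X.shape
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    E = X.copy()
    for k in range(n_components):
        # start from the column with the largest remaining SS
        t = E[:, np.argmax(np.sum(E ** 2, axis=0))].copy()
        if np.allclose(t, 0):
            break
        for _ in range(max_iter):
            pk = E.T @ t / (t @ t)
            pk /= np.linalg.norm(pk)
            t_new = E @ pk
            if np.sum((t_new - t) ** 2) < tol * max(np.sum(t_new ** 2), 1e-300):
                t = t_new
                break
            t = t_new
        j = np.argmax(np.abs(pk))
        if pk[j] < 0:
            pk, t = -pk, -t
        T[:, k], P[:, k] = t, pk
        E = E - np.outer(t, pk)
    return T, P


def pca_fit(X: pd.DataFrame | np.ndarray, n_components: int) -> PcaModel:
    """Iterative (NIPALS) PCA of a preprocessed (centered) matrix.

    R2X_k is the fraction of total sum of squares explained by component k.
    """
    Xdf = pd.DataFrame(X)
    A = Xdf.to_numpy(dtype=float)
    if n_components < 1 or n_components > min(A.shape):
        raise ValueError(
            f"n_components must be in [1, {min(A.shape)}], got {n_components}")
    total_ss = float(np.sum(A ** 2))
    if total_ss == 0:
        raise ValueError("zero-variance matrix")
    T, P = _nipals(A, n_components)
    r2x = np.array([np.sum(T[:, k] ** 2) / total_ss for k in range(n_components)])
    comp_index = [f"PC{k + 1}" for k in range(n_components)]
    return PcaModel(
        n_components=n_components,
        scores=pd.DataFrame(T, index=Xdf.index, columns=comp_index),
        loadings=pd.DataFrame(P, index=Xdf.columns, columns=comp_index),
        r2x=r2x,
        r2x_cum=np.cumsum(r2x),
    )


def _em_reconstruct(A: np.ndarray, mask: np.ndarray, n_components: int,
                    n_iter: int = 30) -> np.ndarray:
    """EM-style reconstruction of entries flagged True in ``mask``.

    Missing cells start at zero (the column mean of a centered matrix) and
    are refined by repeatedly refitting the PCA model and imputing from the
    reconstruction.
    """
    Afill = A.copy()
    Afill[mask] = 0.0
    recon = np.zeros_like(A)
    for _ in range(n_iter):
        T, P = _nipals(Afill, n_components, tol=1e-10, max_iter=200)
        recon = T @ P.T
        Afill[mask] = recon[mask]
    return recon


def q2_cv(
    X: pd.DataFrame | np.ndarray,
    n_components: int,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Cumulative Q2 by element-wise deletion cross-validation.

    Matrix entries are partitioned into ``n_folds`` scattered folds; each
    fold is deleted in turn, the model refit on the remainder (EM
    imputation), and the squared prediction error of the held-out entries
    accumulated into PRESS.  Q2 = 1 - PRESS / total SS.  Values above 0.5
    indicate good predictive stability; noise-only matrices give Q2 <= 0.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    A = pd.DataFrame(X).to_numpy(dtype=float)
    n, p = A.shape
    if n_folds > n * p:
        raise ValueError("more folds than matrix entries")
    if n_components < 1 or n_components > min(A.shape) - 1:
        raise ValueError(
            f"n_components must be in [1, {min(A.shape) - 1}] for cross-validation")
    total_ss = float(np.sum(A ** 2))
    if total_ss == 0:
        raise ValueError("zero-variance matrix")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n * p) % n_folds
    press = 0.0
    for fold in range(n_folds):
        mask = (assignment == fold).reshape(n, p)
        recon = _em_reconstruct(A, mask, n_components)
        press += float(np.sum((A[mask] - recon[mask]) ** 2))
    return 1.0 - press / total_ss
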