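"""Principal coordinates analysis (classical multidimensional scaling).

PCoA embeds a symmetric dissimilarity matrix D into orthogonal axes via the
eigendecomposition of the Gower double-centered matrix

    B = -1/2 * J (D o D) J,   J = I - 11'/n,

with coordinates given by eigenvectors scaled by the square roots of the
(positive) eigenvalues.  The per-population coordinates on the leading axes
of the F_ST and Morisita-Horn divergence matrices serve as explanatory
variables downstream.

Divergence matrices need not be Euclidean, so B may have negative
eigenvalues; by default those axes are dropped with a warning (the Cailliez
additive-constant correction is available as an option).  Axis signs are
fixed by forcing the largest-magnitude loading of each axis positive, so
results are reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # populations x axes_kept
    eigenvalues: np.ndarray  # all eigenvalues, descending
    axes_kept: int

    def to_frame(self, prefix: str = "axis") -> pd.DataFrame:
        cols = [f"{prefix}{i + 1}" for i in range(self.axes_kept)]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(
    D: DistanceMatrix | np.ndarray,
    n_axes: int,
    labels: list[str] | None = None,
    cailliez: bool = False,
) -> OrdinationResult:
    """Classical scaling of a symmetric zero-diagonal dissimilarity matrix.

    Coordinates for the top ``n_axes`` positive eigenvalues; if fewer positive
    eigenvalues exist, the remaining columns are zero-padded with a warning.
    """
    if isinstance(D, DistanceMatrix):
        labels = list(D.ids)
        mat = D.data.copy()
    else:
        mat = np.asarray(D, dtype=float).copy()
        if labels is None:
            labels = [str(i + 1) for i in range(mat.shape[0])]
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(mat, mat.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(mat) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(mat < 0):
            raise ValueError("dissimilarities must be non-negative")
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")

    if cailliez:
        mat = _cailliez(mat)

    b = _gower_center(mat**2)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals[0]), 1.0) * 1e-12
    n_pos = int(np.sum(evals > tol))
    if np.any(evals < -tol):
        neg = float(evals[evals < -tol].sum())
        logger.warning(
            "PCoA: dropping %d negative eigenvalue(s) (sum %.4g); "
            "matrix is non-Euclidean",
            int(np.sum(evals < -tol)), neg,
        )
    kept = min(n_axes, n_pos)
    coords = np.zeros((mat.shape[0], n_axes))
    for k in range(kept):
        v = evecs[:, k] * np.sqrt(evals[k])
        # sign convention: largest-magnitude loading positive
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = v
    if kept < n_axes:
        logger.warning(
            "PCoA: only %d positive axes available; zero-padding to %d",
            kept, n_axes,
        )
    return OrdinationResult(labels, coords, evals, n_axes)


def _cailliez(mat: np.ndarray) -> np.ndarray:
    """Smallest additive constant making the matrix Euclidean (Cailliez 1983)."""
    n = mat.shape[0]
    d2 = _gower_center(mat**2)
    d1 = _gower_center(mat)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d2])
    lower = np.hstack([-np.eye(n), -4.0 * d1])
    big = np.vstack([upper, lower])
    c = float(np.max(np.real(np.linalg.eigvals(big))))
    if c <= 0:
        return mat
    out = mat + c
    np.fill_diagonal(out, 0.0)
    return out


def write_ordination(res: OrdinationResult, out_prefix: str | Path,
                     prefix: str = "axis") -> None:
    res.to_frame(prefix).to_csv(f"{out_prefix}_coords.csv",
                                index_label="population")
    pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(
        f"{out_prefix}_eigenvalues.csv", index_label="axis"
    )
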