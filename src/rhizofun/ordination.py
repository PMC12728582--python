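"""Principal coordinate analysis (classical MDS) on a distance matrix.

Implemented directly (Gower double-centering + symmetric eigendecomposition)
so axis handling is explicit: negative eigenvalues — which arise for
non-Euclidean dissimilarities such as Bray–Curtis — are dropped and their
magnitude logged, with no Lingoes/Cailliez correction.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["pcoa", "bray_curtis_matrix"]


def bray_curtis_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity sum|a-b|/sum(a+b) between rows of a
    non-negative matrix. A pair of all-zero rows makes the measure 0/0."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def pcoa(distance: np.ndarray, n_axes: int | None = None):
    """Principal coordinates of a symmetric distance matrix.

    Returns ``(coords, eigenvalues)`` where coords has one column per retained
    positive-eigenvalue axis (at most ``n_axes``), columns sorted by
    decreasing eigenvalue. Coordinates are centered; column signs are as the
    eigensolver returns them (callers orient them).
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0.0)
    neg = eigvals[eigvals < -tol]
    if len(neg):
        logger.info("PCoA dropped %d negative eigenvalue(s); largest magnitude %.3g",
                    len(neg), float(-neg.min()))
    keep = eigvals > tol
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)
    return coords, eigvals
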