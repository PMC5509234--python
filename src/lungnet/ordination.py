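"""Bray-Curtis distances and principal coordinates analysis (PCoA).

PCoA is classical metric scaling: square the distances, double-centre,
eigendecompose, and scale eigenvectors by the square root of their (positive)
eigenvalues. Negative eigenvalues — which arise for non-Euclidean
dissimilarities such as Bray-Curtis — are reported but excluded from the
coordinates, and the proportion of variance explained is taken over the
positive eigenvalues only. Eigenvector signs are arbitrary, so each axis is
flipped to make its largest-magnitude coordinate positive; this makes runs
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import DataError, GenusAbundanceTable

_EIG_TOL = 1e-9


@dataclass
class OrdinationResult:
    """Sample coordinates with eigenvalues and variance proportions."""

    coordinates: pd.DataFrame  # samples x axes, columns PC1..PCk
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues, per kept axis


def bray_curtis(table: GenusAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    data = table.values.to_numpy(dtype=float).T
    condensed = pdist(data, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # two all-zero samples
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(d) -> OrdinationResult:
    """Classical scaling of a distance matrix (skbio ``DistanceMatrix`` or
    a square symmetric ndarray)."""
    dm = np.asarray(getattr(d, "data", d), dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    positive = eigvals > _EIG_TOL
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    # sign convention: largest-magnitude loading on each axis is positive
    for a in range(coords.shape[1]):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    ids = list(getattr(d, "ids", range(n)))
    frame = pd.DataFrame(coords, index=ids, columns=columns)
    return OrdinationResult(frame, eigvals, prop)
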