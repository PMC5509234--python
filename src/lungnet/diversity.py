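"""Alpha-diversity indices and rarefaction curves.

Pielou's evenness is Shannon entropy (natural log) of the relative
abundances divided by ``ln(S_obs)``; Chao1 estimates richness from the
singleton and doubleton counts. Rarefaction curves report the mean number
of taxa observed in without-replacement subsamples at increasing depth.
"""

from __future__ import annotations

import numpy as np

from .containers import DataError


def _positive_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise DataError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise DataError("counts must be non-negative")
    pos = arr[arr > 0]
    if pos.size == 0:
        raise DataError("all-zero count vector")
    return pos


def pielou_evenness(counts) -> float:
    """Shannon entropy / ln(observed richness), in [0, 1].

    Defined as 0 for a single-taxon community (entropy and its maximum are
    both zero there).
    """
    pos = _positive_counts(counts)
    if pos.size == 1:
        return 0.0
    p = pos / pos.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(pos.size))


def chao1_richness(counts) -> float:
    """Chao1: S_obs + F1^2 / (2 F2), with the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when there are no doubletons."""
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise DataError("Chao1 requires integer counts")
        arr = np.round(arr).astype(np.int64)
    pos = _positive_counts(arr)
    s_obs = pos.size
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def rarefaction_curve(counts, depths, reps: int = 100, seed: int | None = None) -> np.ndarray:
    """Mean observed richness per subsampling depth.

    For each depth, draws ``reps`` without-replacement subsamples (multivariate
    hypergeometric) and counts taxa with at least one read.
    """
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 or d > total for d in depths):
        raise DataError("depths must lie in [1, total count]")
    rng = np.random.default_rng(seed)
    out = np.empty(len(depths))
    for i, d in enumerate(depths):
        richness = np.empty(reps)
        for r in range(reps):
            sub = rng.multivariate_hypergeometric(arr, d)
            richness[r] = int((sub > 0).sum())
        out[i] = richness.mean()
    return out
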