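"""Hypothesis testing: PERMANOVA, Wilcoxon-Mann-Whitney, BH correction.

PERMANOVA is implemented from the pseudo-F definition on squared
distances: with N samples in a groups,

    SS_total = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a - 1)) / (SS_within / (N - a))

and the P-value is the add-one permutation estimate
``(#{F_perm >= F_obs} + 1) / (n_perm + 1)`` under label shuffling (or the
exhaustive fraction over all distinct label assignments when requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import DataError, GenusAbundanceTable, SampleMetadata
from .preprocess import season_correct

EXACT_WILCOXON_MAX_N = 20

GROUPINGS = ("severe-vs-rest", "case-vs-control", "gc-vs-no-gc")


@dataclass
class HypothesisTestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    n_permutations: int | None = None


def wilcoxon_mw(x, y) -> HypothesisTestResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_mw requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # no variation at all: the test carries no evidence
        return HypothesisTestResult(x.size * y.size / 2.0, 1.0, "mann-whitney (degenerate)")
    has_ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "mann-whitney (exact)"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "mann-whitney (normal approx., tie-corrected)"
    return HypothesisTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any():
        raise DataError("P-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _group_indices(groups) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    idx = [np.flatnonzero(labels == u) for u in uniq]
    return labels, idx


def _pseudo_f(d2: np.ndarray, group_indicators: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for a batch of label assignments.

    ``group_indicators``: array (n_groups, n_assignments, N) of 0/1.
    Returns F per assignment.
    """
    n = d2.shape[0]
    a = len(sizes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(group_indicators.shape[1])
    for g in range(a):
        w = group_indicators[g]
        ss_within += np.einsum("pi,ij,pj->p", w, d2, w) / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _multiset_permutations(labels: np.ndarray):
    """All distinct orderings of a label vector."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    out = np.empty(n, dtype=labels.dtype)

    def rec(pos, counts):
        if pos == n:
            yield out.copy()
            return
        for i, c in enumerate(counts):
            if c:
                counts[i] -= 1
                out[pos] = uniq[i]
                yield from rec(pos + 1, counts)
                counts[i] += 1

    yield from rec(0, list(counts))


def permanova(
    d,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> HypothesisTestResult:
    """Permutation multivariate analysis of variance on a distance matrix.

    ``d`` may be an skbio ``DistanceMatrix`` or a square ndarray aligned
    with ``groups``. With ``exact=True`` the P-value is the fraction of all
    distinct label assignments (including the observed one) whose pseudo-F
    reaches the observed value.
    """
    dm = np.asarray(getattr(d, "data", d), dtype=float)
    labels, idx = _group_indices(groups)
    if len(labels) != dm.shape[0]:
        raise DataError("groups length must match distance matrix size")
    if len(idx) < 2:
        raise DataError("PERMANOVA requires at least 2 groups")
    sizes = np.array([len(i) for i in idx])
    if (sizes < 2).any():
        raise DataError("every group needs at least 2 samples")
    d2 = dm**2
    n = dm.shape[0]
    uniq = pd.unique(labels)

    def indicators(label_matrix: np.ndarray) -> np.ndarray:
        return np.stack([(label_matrix == u).astype(float) for u in uniq])

    f_obs = float(_pseudo_f(d2, indicators(labels[None, :]), sizes)[0])

    if exact:
        total = math.factorial(n)
        for s in sizes:
            total //= math.factorial(s)
        if total > 200_000:
            raise DataError("exact PERMANOVA infeasible for this group layout")
        perms = np.stack(list(_multiset_permutations(labels)))
        f_all = _pseudo_f(d2, indicators(perms), sizes)
        p = float((f_all >= f_obs - 1e-12).sum() / len(f_all))
        return HypothesisTestResult(f_obs, p, "PERMANOVA (exhaustive)", n_permutations=len(f_all))

    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(labels) for _ in range(n_perm)])
    f_perm = _pseudo_f(d2, indicators(perms), sizes)
    p = float(((f_perm >= f_obs - 1e-12).sum() + 1) / (n_perm + 1))
    return HypothesisTestResult(f_obs, p, "PERMANOVA (permutation)", n_permutations=n_perm)


def grouping_masks(meta: SampleMetadata, grouping: str, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (group A, group B) over ``sample_ids`` for a scheme.

    severe-vs-rest: severe vs mild+control; case-vs-control: severe+mild vs
    control; gc-vs-no-gc: treated vs untreated.
    """
    meta.require_samples(sample_ids)
    sub = meta.frame.loc[list(sample_ids)]
    if grouping == "severe-vs-rest":
        a = (sub["group"] == "severe").to_numpy()
        b = ~a
    elif grouping == "case-vs-control":
        a = sub["group"].isin(["severe", "mild"]).to_numpy()
        b = ~a
    elif grouping == "gc-vs-no-gc":
        a = sub["gc_treatment"].astype(bool).to_numpy()
        b = ~a
    else:
        raise DataError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    if a.sum() == 0 or b.sum() == 0:
        raise DataError(f"grouping {grouping!r} leaves an empty group")
    return a, b


def group_comparison(
    table: GenusAbundanceTable,
    meta: SampleMetadata,
    grouping: str = "severe-vs-rest",
    season_correction: bool = True,
) -> pd.DataFrame:
    """Per-genus two-group Wilcoxon screen with BH correction.

    Expects Hellinger-transformed abundances. Each genus's per-sample vector
    is (optionally) season-median-centred before testing; BH adjustment is
    applied across all genera of the screen (one family per run).
    """
    table.require_transform("hellinger")
    mask_a, mask_b = grouping_masks(meta, grouping, table.sample_ids)
    rows = []
    for genus in table.genus_ids:
        values = table.values.loc[genus]
        if season_correction:
            values = season_correct(values, meta)
        arr = values.to_numpy(dtype=float)
        res = wilcoxon_mw(arr[mask_a], arr[mask_b])
        rows.append((genus, res.statistic, res.p_value, res.method))
    out = pd.DataFrame(rows, columns=["genus", "statistic", "p", "method"]).set_index("genus")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["season_corrected"] = season_correction
    return out
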