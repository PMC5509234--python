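"""From raw OTU counts to the analysis-ready genus table.

Stage order (enforced through table state and preconditions):

1. :func:`filter_contaminant_otus` — remove OTUs whose relative abundance
   correlates negatively (Spearman, P < alpha) with the amplicon
   concentration of any of the three library amplification runs; such OTUs
   behave like reagent contaminants, which make up a larger share of reads
   in low-biomass samples.
2. :func:`discard_low_depth_samples` — drop samples below a read threshold.
3. :func:`rarefy` — subsample every library without replacement to a common
   depth so read effort is comparable.
4. :func:`aggregate_to_genus` — sum OTUs classified at genus level.
5. :func:`filter_rare_genera` — drop genera below a fraction of all reads.
6. :func:`to_relative` / :func:`hellinger` — abundance transforms.

:func:`season_correct` centres any per-sample scalar on its season median,
removing the winter/summer processing-batch shift.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DataError,
    GenusAbundanceTable,
    OtuCountTable,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

N_RUNS = 3
EXACT_SPEARMAN_MAX_N = 10


@dataclass
class ContaminationReport:
    """Per-OTU screening statistics and the flagged-OTU summary."""

    stats: pd.DataFrame  # columns rho_run{r}, p_run{r} per run, and 'flagged'
    flagged_otus: set[str]
    reads_removed: int

    def to_frame(self) -> pd.DataFrame:
        return self.stats.copy()


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! rank permutations (no ties).

    Feasible for the small n this branch covers; the distribution is cached
    per n.
    """
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = []
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            d2 = ((np.asarray(chunk) + 1 - base) ** 2).sum(axis=1)
            rhos.append(1.0 - 6.0 * d2 / denom)
            chunk = []
    if chunk:
        d2 = ((np.asarray(chunk) + 1 - base) ** 2).sum(axis=1)
        rhos.append(1.0 - 6.0 * d2 / denom)
    return np.sort(np.abs(np.concatenate(rhos)))


def _exact_spearman_p(rho: float, n: int) -> float:
    null = _exact_spearman_null(n)
    # two-sided: mass of |rho_null| >= |rho_obs| (with float tolerance)
    idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return (len(null) - idx) / len(null)


def _spearman_vs_vector(data: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided P of each row of ``data`` against ``y``.

    Average ranks throughout; exact permutation P when n <= 10 and neither
    vector has ties, t-approximation otherwise.
    """
    n = data.shape[1]
    ry = stats.rankdata(y)
    rx = stats.rankdata(data, axis=1)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=1) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rxc @ ryc / np.where(denom > 0, denom, 1.0), np.nan)

    p = np.full(len(rho), np.nan)
    y_has_ties = len(np.unique(y)) < n
    for i, r in enumerate(rho):
        if not np.isfinite(r):
            continue
        x_has_ties = len(np.unique(data[i])) < n
        if n <= EXACT_SPEARMAN_MAX_N and not (x_has_ties or y_has_ties):
            p[i] = _exact_spearman_p(r, n)
        else:
            if abs(r) >= 1.0:
                p[i] = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p[i] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, p


def filter_contaminant_otus(
    table: OtuCountTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
) -> tuple[OtuCountTable, ContaminationReport]:
    """Remove OTUs negatively correlated with amplicon concentration.

    An OTU is flagged when any of the three library runs yields a Spearman
    correlation between the OTU's relative abundance and that run's
    concentration with rho < 0 and two-sided P < ``alpha``. All reads of
    flagged OTUs are removed.
    """
    n = len(table.sample_ids)
    if n < 4:
        raise DataError("contamination screen requires at least 4 samples")
    meta.require_samples(table.sample_ids)
    conc = meta.concentrations().loc[table.sample_ids]
    rel = table.relative_abundance().to_numpy(dtype=float)

    report = pd.DataFrame(index=pd.Index(table.otu_ids, name="otu_id"))
    flagged = np.zeros(len(table.otu_ids), dtype=bool)
    for r in range(N_RUNS):
        col = conc.iloc[:, r].to_numpy(dtype=float)
        if np.allclose(col, col[0]):
            warnings.warn(
                f"run {r + 1}: constant amplicon concentration, run skipped",
                stacklevel=2,
            )
            report[f"rho_run{r + 1}"] = np.nan
            report[f"p_run{r + 1}"] = np.nan
            continue
        rho, p = _spearman_vs_vector(rel, col)
        report[f"rho_run{r + 1}"] = rho
        report[f"p_run{r + 1}"] = p
        flagged |= (np.nan_to_num(rho, nan=0.0) < 0) & (np.nan_to_num(p, nan=1.0) < alpha)

    report["flagged"] = flagged
    flagged_ids = set(np.asarray(table.otu_ids)[flagged])
    reads_removed = int(table.counts.loc[sorted(flagged_ids)].to_numpy().sum())
    kept = [o for o in table.otu_ids if o not in flagged_ids]
    logger.info(
        "contamination screen: %d OTUs flagged, %d reads removed",
        len(flagged_ids),
        reads_removed,
    )
    return table.select_otus(kept), ContaminationReport(report, flagged_ids, reads_removed)


def discard_low_depth_samples(table: OtuCountTable, min_reads: int = 700) -> OtuCountTable:
    """Drop samples with fewer than ``min_reads`` total reads."""
    depths = table.depths()
    keep = [s for s in table.sample_ids if depths[s] >= min_reads]
    dropped = [s for s in table.sample_ids if depths[s] < min_reads]
    if not keep:
        raise DataError(f"all samples below {min_reads} reads; empty table")
    if dropped:
        logger.info("discarded %d samples below %d reads: %s", len(dropped), min_reads, dropped)
    return table.select_samples(keep)


def rarefy(table: OtuCountTable, depth: int = 722, seed: int | None = None) -> OtuCountTable:
    """Subsample each library without replacement to exactly ``depth`` reads.

    Draws are multivariate hypergeometric per sample. OTU rows that become
    all-zero are retained so ids stay stable.
    """
    depths = table.depths()
    low = depths[depths < depth]
    if len(low):
        raise DataError(
            f"samples below rarefaction depth {depth}: {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for s in range(counts.shape[1]):
        if depths.iloc[s] == depth:
            out[:, s] = counts[:, s]
        else:
            out[:, s] = rng.multivariate_hypergeometric(counts[:, s], depth)
    new = table.counts.copy()
    new.loc[:, :] = out
    return OtuCountTable(new, table.taxonomy.copy(), table.run_label)


def aggregate_to_genus(table: OtuCountTable) -> GenusAbundanceTable:
    """Sum OTU counts within each genus; unclassified OTUs are excluded."""
    genus = table.genus_series()
    classified = genus.notna()
    excluded_mass = int(table.counts.loc[~classified].to_numpy().sum())
    if excluded_mass:
        logger.info(
            "genus aggregation: %d reads from %d OTUs unclassified at genus level excluded",
            excluded_mass,
            int((~classified).sum()),
        )
    grouped = table.counts.loc[classified].groupby(genus[classified]).sum()
    grouped.index.name = "genus"
    return GenusAbundanceTable(grouped.astype(float), transform="counts")


def filter_rare_genera(
    table: GenusAbundanceTable,
    threshold_fraction: float = 1e-4,
    mode: str = "total_fraction",
) -> GenusAbundanceTable:
    """Drop genera below an abundance threshold.

    ``mode="total_fraction"`` (default) removes a genus when its total count
    across all samples is less than ``threshold_fraction`` of the grand
    total; ``mode="mean_relative"`` uses the mean per-sample relative
    abundance instead.
    """
    table.require_transform("counts")
    if table.values.size == 0:
        raise DataError("empty genus table")
    if mode == "total_fraction":
        totals = table.values.sum(axis=1)
        grand = float(totals.sum())
        if grand == 0:
            raise DataError("genus table has zero total count")
        frac = totals / grand
    elif mode == "mean_relative":
        colsum = table.values.sum(axis=0).replace(0, 1)
        frac = table.values.div(colsum, axis=1).mean(axis=1)
    else:
        raise DataError(f"unknown rare-genus mode {mode!r}")
    keep = frac[frac >= threshold_fraction].index
    removed = table.values.index.difference(keep)
    if len(removed):
        logger.info("rare-genus filter removed %d genera", len(removed))
    return GenusAbundanceTable(table.values.loc[keep].copy(), transform="counts")


def to_relative(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Per-sample relative abundances; all-zero columns stay zero."""
    table.require_transform("counts")
    colsum = table.values.sum(axis=0)
    safe = colsum.replace(0, 1)
    return GenusAbundanceTable(table.values.div(safe, axis=1), transform="relative")


def hellinger(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Square root of relative abundances (unit-norm columns)."""
    table.require_transform("counts", "relative")
    colsum = table.values.sum(axis=0)
    safe = colsum.replace(0, 1)
    return GenusAbundanceTable(
        np.sqrt(table.values.div(safe, axis=1)), transform="hellinger"
    )


def season_correct(values: pd.Series, meta: SampleMetadata) -> pd.Series:
    """Subtract the per-season median from each sample's value.

    Applicable to any per-sample scalar: a genus's (transformed) abundance,
    a diversity index, or a principal coordinate.
    """
    meta.require_samples(values.index)
    season = meta.season.reindex(values.index)
    medians = values.groupby(season).median()
    return values - season.map(medians).astype(float)
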