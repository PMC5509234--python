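"""Permutation-null Spearman co-occurrence networks with community detection.

The procedure, applied to per-sample relative genus abundances:

1. keep genera present (non-zero) in at least ``min_prevalence`` samples;
2. compute all pairwise Spearman correlations (average ranks);
3. assess significance against a compositionality-aware permutation null:
   each genus's abundances are permuted independently across samples and
   every sample's composition is re-closed (renormalized) before the
   correlation is recomputed, so the null carries the same closure-induced
   dependence as the observed data; the two-sided P-value is the add-one
   tail estimate over ``n_perm`` rounds;
4. set an edge when rho passes a threshold (positive-only by default) and
   P < alpha;
5. re-test every edge on season-median-corrected abundances and drop edges
   that do not remain significant — edges created purely by the
   winter/summer processing batch disappear here;
6. define communities as the connected components of the surviving graph;
   components with fewer than ``min_community_size_report`` genera are kept
   in the data but flagged as unreported.

Each node also carries a group-association score: mean relative abundance
in severe samples minus the mean in mild+control samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    ConfigurationError,
    DataError,
    GenusAbundanceTable,
    SampleMetadata,
)
from .stats import grouping_masks

_TOL = 1e-12


@dataclass(frozen=True)
class NetworkConfig:
    """Edge-calling and community-reporting thresholds."""

    min_prevalence: int = 5
    rho_threshold: float = 0.5
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    min_community_size_report: int = 3
    use_absolute_rho: bool = False  # threshold |rho| instead of rho
    robustness_p_only: bool = False  # season re-test checks only P, not rho

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.min_prevalence < 0:
            raise ConfigurationError("min_prevalence must be >= 0")


@dataclass
class CooccurrenceNetwork:
    """Nodes, retained edges and connected-component communities."""

    nodes: pd.DataFrame  # index genus: association, community, reported
    edges: pd.DataFrame  # genus_a, genus_b, rho, p_raw, robust
    communities: dict[str, int] = field(default_factory=dict)
    community_sizes: dict[int, int] = field(default_factory=dict)

    def reported_communities(self, min_size: int = 3) -> list[int]:
        return sorted(c for c, s in self.community_sizes.items() if s >= min_size)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for genus, row in self.nodes.iterrows():
            g.add_node(
                genus,
                association=float(row["association"]),
                community=int(row["community"]),
                reported=bool(row["reported"]),
            )
        for _, e in self.edges.iterrows():
            g.add_edge(e["genus_a"], e["genus_b"], rho=float(e["rho"]), p=float(e["p_raw"]))
        return g


def prevalence_filter(table: GenusAbundanceTable, min_prevalence: int = 5) -> GenusAbundanceTable:
    """Keep genera with non-zero abundance in at least ``min_prevalence`` samples."""
    table.require_transform("relative")
    prevalence = (table.values > 0).sum(axis=1)
    keep = prevalence[prevalence >= min_prevalence].index
    return GenusAbundanceTable(table.values.loc[keep].copy(), transform="relative")


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=-1)


def _row_correlation(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of the trailing two axes.

    Input (..., G, N); output (..., G, G). Constant rows give NaN.
    """
    c = ranks - ranks.mean(axis=-1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(norm > 0, c / np.where(norm > 0, norm, 1.0), np.nan)
    return c @ np.swapaxes(c, -1, -2)


def spearman_matrix(table: GenusAbundanceTable) -> pd.DataFrame:
    """Average-rank Spearman rho between all genus pairs.

    A genus constant across samples has undefined correlation; its entries
    are NaN (recorded as missing, never an edge).
    """
    if len(table.sample_ids) < 3:
        raise DataError("Spearman matrix requires at least 3 samples")
    rho = _row_correlation(_rank_rows(table.values.to_numpy(dtype=float)))
    np.fill_diagonal(rho, 1.0)
    constant = table.values.nunique(axis=1).to_numpy() == 1
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    return pd.DataFrame(rho, index=table.genus_ids, columns=table.genus_ids)


def permutation_pvalues(
    table: GenusAbundanceTable,
    n_perm: int = 1000,
    seed: int | None = None,
    renormalize: bool = True,
    _values_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-sided permutation P-values for all Spearman pairs.

    Each round permutes every genus independently across samples; with
    ``renormalize`` (the compositionality-aware default, which requires a
    relative-abundance table) every sample column is re-closed to sum 1
    before ranking. P = (#{|rho_null| >= |rho_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    if _values_override is not None:
        x = np.asarray(_values_override, dtype=float)
    else:
        if renormalize:
            table.require_transform("relative")
        x = table.values.to_numpy(dtype=float)
    g, n = x.shape
    rho_obs = _row_correlation(_rank_rows(x))
    np.fill_diagonal(rho_obs, 1.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros((g, g), dtype=np.int64)
    batch = max(1, min(n_perm, int(2e7 // max(1, g * n))))
    done = 0
    abs_obs = np.abs(rho_obs)
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.broadcast_to(x, (b, g, n)), axis=2)
        if renormalize:
            colsum = perm.sum(axis=1, keepdims=True)
            perm = perm / np.where(colsum > 0, colsum, 1.0)
        rho_null = _row_correlation(_rank_rows(perm))
        exceed += (np.abs(rho_null) >= abs_obs - _TOL).sum(axis=0)
        done += b

    p = (exceed + 1.0) / (n_perm + 1.0)
    p[~np.isfinite(rho_obs)] = np.nan
    np.fill_diagonal(p, np.nan)
    ids = table.genus_ids
    return pd.DataFrame(p, index=ids, columns=ids)


def build_network(rho: pd.DataFrame, p: pd.DataFrame, config: NetworkConfig) -> pd.DataFrame:
    """Edge list over genus pairs passing the rho and P criteria."""
    config.validate()
    if rho.shape != p.shape or list(rho.index) != list(p.index):
        raise DataError("rho and p matrices must be conformable")
    ids = list(rho.index)
    rows = []
    rv = rho.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r, q = rv[i, j], pv[i, j]
            if not (np.isfinite(r) and np.isfinite(q)):
                continue
            strength = abs(r) if config.use_absolute_rho else r
            if strength >= config.rho_threshold and q < config.alpha:
                rows.append((ids[i], ids[j], r, q))
    return pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p_raw"])


def _season_corrected_values(table: GenusAbundanceTable, meta: SampleMetadata) -> np.ndarray:
    meta.require_samples(table.sample_ids)
    season = meta.season.reindex(table.sample_ids)
    x = table.values.to_numpy(dtype=float).copy()
    for s in pd.unique(season):
        cols = (season == s).to_numpy()
        med = np.median(x[:, cols], axis=1, keepdims=True)
        x[:, cols] -= med
    return x


def season_robustness_filter(
    edges: pd.DataFrame,
    table: GenusAbundanceTable,
    meta: SampleMetadata,
    config: NetworkConfig,
) -> pd.DataFrame:
    """Re-test edges on season-corrected abundances; flag the survivors.

    Correlations and permutation P-values are recomputed on abundances with
    the per-season median removed; an edge is robust when it still passes
    the edge rule (or only the P criterion with ``robustness_p_only``).
    Corrected values can be negative, so the permutation null here does not
    renormalize compositions.
    """
    out = edges.copy()
    for col in ("rho_corrected", "p_corrected"):
        out[col] = np.nan
    out["robust"] = pd.Series(dtype=bool)
    if edges.empty:
        return out

    incident = sorted(set(edges["genus_a"]) | set(edges["genus_b"]))
    sub = GenusAbundanceTable(
        table.values.loc[incident].copy(), transform=table.transform
    )
    corrected = _season_corrected_values(sub, meta)
    ranks = _rank_rows(corrected)
    rho_c = pd.DataFrame(_row_correlation(ranks), index=incident, columns=incident)
    p_c = permutation_pvalues(
        sub,
        n_perm=config.n_perm,
        seed=np.random.SeedSequence([int(config.seed), 1]).generate_state(1)[0],
        renormalize=False,
        _values_override=corrected,
    )

    robust = []
    for k, e in edges.iterrows():
        r = float(rho_c.loc[e["genus_a"], e["genus_b"]])
        q = float(p_c.loc[e["genus_a"], e["genus_b"]])
        out.loc[k, "rho_corrected"] = r
        out.loc[k, "p_corrected"] = q
        strength = abs(r) if config.use_absolute_rho else r
        ok = np.isfinite(q) and q < config.alpha
        if not config.robustness_p_only:
            ok = ok and np.isfinite(r) and strength >= config.rho_threshold
        robust.append(bool(ok))
    out["robust"] = robust
    return out


def connected_components(
    edges: pd.DataFrame, min_community_size_report: int = 3
) -> tuple[dict[str, int], dict[int, int], set[int]]:
    """Communities as connected components of the retained edge set.

    Returns (genus -> community id, community id -> size, reported ids).
    Components are numbered by decreasing size (ties broken by smallest
    member name) so ids are deterministic.
    """
    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["genus_a"], e["genus_b"])
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    membership: dict[str, int] = {}
    sizes: dict[int, int] = {}
    reported: set[int] = set()
    for cid, comp in enumerate(comps):
        sizes[cid] = len(comp)
        for genus in comp:
            membership[genus] = cid
        if len(comp) >= min_community_size_report:
            reported.add(cid)
    return membership, sizes, reported


def node_association(table: GenusAbundanceTable, meta: SampleMetadata) -> pd.Series:
    """Mean relative abundance in severe minus mean in mild+control."""
    table.require_transform("relative")
    mask_a, mask_b = grouping_masks(meta, "severe-vs-rest", table.sample_ids)
    x = table.values.to_numpy(dtype=float)
    score = x[:, mask_a].mean(axis=1) - x[:, mask_b].mean(axis=1)
    return pd.Series(score, index=table.genus_ids, name="association")


def community_heatmap_data(
    rho: pd.DataFrame,
    communities: dict[str, int],
    edges: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlation matrix reordered for a community heatmap.

    Genera are grouped by community (in community-id order); within each
    community they are sorted by degree in the retained network, descending
    (ties by name). Returns the reordered matrix and a genus -> community
    band for plotting.
    """
    if not communities:
        empty = pd.DataFrame(index=[], columns=[])
        return empty, pd.Series(dtype=int)
    degree: dict[str, int] = {}
    for _, e in edges.iterrows():
        degree[e["genus_a"]] = degree.get(e["genus_a"], 0) + 1
        degree[e["genus_b"]] = degree.get(e["genus_b"], 0) + 1
    order = sorted(
        communities, key=lambda g: (communities[g], -degree.get(g, 0), g)
    )
    bands = pd.Series({g: communities[g] for g in order}, name="community")
    return rho.loc[order, order], bands


def build_cooccurrence_network(
    table: GenusAbundanceTable,
    meta: SampleMetadata,
    config: NetworkConfig | None = None,
) -> CooccurrenceNetwork:
    """Run the full network stage on a relative-abundance genus table."""
    config = config or NetworkConfig()
    config.validate()
    filtered = prevalence_filter(table, config.min_prevalence)
    rho = spearman_matrix(filtered)
    p = permutation_pvalues(filtered, n_perm=config.n_perm, seed=config.seed)
    candidate = build_network(rho, p, config)
    tested = season_robustness_filter(candidate, filtered, meta, config)
    retained = tested[tested["robust"]].reset_index(drop=True)
    membership, sizes, reported = connected_components(
        retained, config.min_community_size_report
    )
    association = node_association(filtered, meta)
    nodes = pd.DataFrame(index=pd.Index(filtered.genus_ids, name="genus"))
    nodes["association"] = association
    nodes["community"] = [membership.get(g, -1) for g in filtered.genus_ids]
    nodes["reported"] = [membership.get(g, -1) in reported for g in filtered.genus_ids]
    return CooccurrenceNetwork(nodes, retained, membership, sizes)
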