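"""Co-occurrence network: filters, permutation null, communities."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lungnet import (
    DataError,
    NetworkConfig,
    SimulationConfig,
    build_cooccurrence_network,
    build_network,
    community_heatmap_data,
    connected_components,
    generate_dataset,
    node_association,
    permutation_pvalues,
    prevalence_filter,
    season_robustness_filter,
    spearman_matrix,
    to_relative,
)
from lungnet.preprocess import aggregate_to_genus

from .conftest import make_genus_table, make_metadata


def _relative(matrix, **kw):
    m = np.asarray(matrix, dtype=float)
    return make_genus_table(m / m.sum(axis=0, keepdims=True), transform="relative", **kw)


class TestPrevalenceFilter:
    def test_boundary_of_rule(self):
        m = np.ones((2, 8))
        m[0, 4:] = 0  # genus present in exactly 4 samples
        table = _relative(m)
        assert prevalence_filter(table, 5).genus_ids == ["G1"]
        m[0, 4] = 1  # now 5 samples
        assert set(prevalence_filter(_relative(m), 5).genus_ids) == {"G0", "G1"}

    def test_zero_threshold_is_identity(self):
        table = _relative(np.eye(3) + 0.1)
        assert prevalence_filter(table, 0).genus_ids == table.genus_ids

    def test_ubiquitous_genus_always_kept(self):
        table = _relative(np.ones((3, 6)))
        assert "G0" in prevalence_filter(table, 6).genus_ids


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        table = _relative([[1, 2, 3, 4], [4, 3, 2, 1]])
        rho = spearman_matrix(table)
        assert rho.iloc[0, 0] == 1.0

    def test_opposite_monotone_is_minus_one(self):
        table = _relative([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert spearman_matrix(table).iloc[0, 1] == pytest.approx(-1.0)

    def test_average_ranks_with_ties(self):
        # co-monotone with matching tie pattern: identical rank vectors
        rho = spearman_matrix(
            make_genus_table(
                np.array([[1, 2, 2, 4], [1, 3, 3, 5], [9, 1, 4, 2]]) / 20.0,
                transform="relative",
            )
        )
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_genus_recorded_missing(self):
        rho = spearman_matrix(_relative([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]]))
        assert np.isnan(rho.loc["G0", "G1"])

    def test_too_few_samples_errors(self):
        with pytest.raises(DataError):
            spearman_matrix(_relative([[1, 2], [2, 1]]))


class TestPermutationPvalues:
    def test_uncorrelated_pair_not_significant(self):
        # ranks chosen so the pair's Spearman rho is ~0.05
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8]) / 40.0
        y = np.array([4.0, 8, 1, 5, 2, 7, 3, 6]) / 40.0
        filler = 1.0 - x - y
        table = make_genus_table(np.vstack([x, y, filler]), transform="relative")
        p = permutation_pvalues(table, n_perm=1000, seed=1)
        assert p.loc["G0", "G1"] >= 0.5

    def test_perfectly_comonotone_pair_minimal_p(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(1, 2, 25))
        table = _relative(np.vstack([x, x * 1.5, rng.uniform(1, 2, 25)]))
        p = permutation_pvalues(table, n_perm=1000, seed=7)
        assert p.loc["G0", "G1"] <= 0.005

    def test_reproducible_under_seed(self):
        table = _relative(np.random.default_rng(2).uniform(1, 5, size=(5, 10)))
        p1 = permutation_pvalues(table, n_perm=200, seed=42)
        p2 = permutation_pvalues(table, n_perm=200, seed=42)
        assert p1.equals(p2)

    def test_invalid_n_perm_errors(self):
        table = _relative(np.ones((2, 4)) + np.eye(2, 4))
        with pytest.raises(DataError):
            permutation_pvalues(table, n_perm=0)


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "rho, p, expect_edge",
        [(0.6, 0.01, True), (0.4, 0.001, False), (0.6, 0.2, False)],
    )
    def test_edge_rule(self, rho, p, expect_edge):
        ids = ["a", "b"]
        rho_m = pd.DataFrame([[1.0, rho], [rho, 1.0]], index=ids, columns=ids)
        p_m = pd.DataFrame([[np.nan, p], [p, np.nan]], index=ids, columns=ids)
        edges = build_network(rho_m, p_m, NetworkConfig())
        assert (len(edges) == 1) == expect_edge

    def test_absolute_mode_admits_negative_rho(self):
        ids = ["a", "b"]
        rho_m = pd.DataFrame([[1.0, -0.7], [-0.7, 1.0]], index=ids, columns=ids)
        p_m = pd.DataFrame([[np.nan, 0.01], [0.01, np.nan]], index=ids, columns=ids)
        assert len(build_network(rho_m, p_m, NetworkConfig())) == 0
        assert len(build_network(rho_m, p_m, NetworkConfig(use_absolute_rho=True))) == 1

    def test_missing_rho_never_forms_edge(self):
        ids = ["a", "b"]
        rho_m = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=ids, columns=ids)
        p_m = pd.DataFrame([[np.nan, 0.001], [0.001, np.nan]], index=ids, columns=ids)
        assert len(build_network(rho_m, p_m, NetworkConfig())) == 0


class TestSeasonRobustness:
    def _edges_for(self, table, meta, config):
        rho = spearman_matrix(table)
        p = permutation_pvalues(table, n_perm=500, seed=config.seed)
        return build_network(rho, p, config), rho

    def test_season_driven_edge_removed(self):
        # both genera elevated in winter, independent within season
        rng = np.random.default_rng(3)
        winter = np.arange(24) % 2 == 0
        a = np.where(winter, 20.0, 1.0) * rng.uniform(0.9, 1.1, 24)
        b = np.where(winter, 20.0, 1.0) * rng.uniform(0.9, 1.1, 24)
        filler = np.full(24, 40.0)
        table = _relative(np.vstack([a, b, filler]))
        meta = make_metadata(
            table.sample_ids,
            seasons=["winter" if w else "summer" for w in winter],
        )
        cfg = NetworkConfig(seed=0, n_perm=500)
        edges, _ = self._edges_for(table, meta, cfg)
        assert {"G0", "G1"} in [set(e) for e in edges[["genus_a", "genus_b"]].values]
        tested = season_robustness_filter(edges, table, meta, cfg)
        row = tested[(tested.genus_a == "G0") & (tested.genus_b == "G1")].iloc[0]
        assert not row.robust

    def test_season_free_comonotone_edge_retained(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 3, 24)
        table = _relative(np.vstack([x, x * 2.0, np.full(24, 10.0)]))
        meta = make_metadata(table.sample_ids)
        cfg = NetworkConfig(seed=1, n_perm=500)
        edges, _ = self._edges_for(table, meta, cfg)
        tested = season_robustness_filter(edges, table, meta, cfg)
        row = tested[(tested.genus_a == "G0") & (tested.genus_b == "G1")].iloc[0]
        assert row.robust

    def test_empty_edge_set_passes_through(self):
        table = _relative(np.random.default_rng(5).uniform(1, 2, (3, 8)))
        meta = make_metadata(table.sample_ids)
        empty = pd.DataFrame(columns=["genus_a", "genus_b", "rho", "p_raw"])
        out = season_robustness_filter(empty, table, meta, NetworkConfig())
        assert len(out) == 0


class TestConnectedComponents:
    def test_two_components_one_flagged_small(self):
        edges = pd.DataFrame(
            [("A", "B"), ("B", "C"), ("D", "E")], columns=["genus_a", "genus_b"]
        )
        membership, sizes, reported = connected_components(edges, 3)
        assert {g for g, c in membership.items() if c == membership["A"]} == {"A", "B", "C"}
        assert sizes[membership["D"]] == 2
        assert membership["A"] in reported and membership["D"] not in reported

    def test_no_edges_no_components(self):
        empty = pd.DataFrame(columns=["genus_a", "genus_b"])
        membership, sizes, reported = connected_components(empty)
        assert membership == {} and sizes == {} and reported == set()

    def test_complete_graph_single_component(self):
        pairs = [(a, b) for i, a in enumerate("wxyz") for b in "wxyz"[i + 1 :]]
        edges = pd.DataFrame(pairs, columns=["genus_a", "genus_b"])
        membership, sizes, _ = connected_components(edges)
        assert sizes == {0: 4}


class TestNodeAssociation:
    def test_equal_abundance_scores_zero(self):
        table = _relative(np.ones((2, 8)))
        meta = make_metadata(table.sample_ids, groups=["severe"] * 4 + ["control"] * 4)
        assert node_association(table, meta)["G0"] == pytest.approx(0.0)

    def test_severe_only_genus_scores_positive(self):
        m = np.ones((2, 8))
        m[0, 4:] = 0  # absent outside severe
        table = _relative(m)
        meta = make_metadata(table.sample_ids, groups=["severe"] * 4 + ["control"] * 4)
        assert node_association(table, meta)["G0"] > 0

    def test_planted_severe_enrichment_recovered(self):
        """A genus planted with a +1.5 severe log-fold effect scores
        positive in >=90% of seeds."""
        hits = 0
        for seed in range(20):
            cfg = replace(
                SimulationConfig(),
                seed=900 + seed,
                n_blocks=1,
                block_sizes=(1,),
                within_block_latent_sd=0.0,
                block_group_effect={0: 1.5},
                n_contaminant_otus=0,
                n_season_affected=0,
            )
            table, meta, truth = generate_dataset(cfg)
            rel = to_relative(aggregate_to_genus(table))
            scores = node_association(rel, meta)
            hits += scores[next(iter(truth.block_membership))] > 0
        assert hits >= 18


class TestHeatmapData:
    def test_single_community_orders_by_degree(self):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        edges = pd.DataFrame(
            [("a", "b"), ("b", "c")], columns=["genus_a", "genus_b"]
        )
        communities = {"a": 0, "b": 0, "c": 0}
        ordered, bands = community_heatmap_data(rho, communities, edges)
        assert list(ordered.index) == ["b", "a", "c"]  # b has degree 2
        assert list(bands) == [0, 0, 0]

    def test_block_diagonal_groups_contiguously(self):
        ids = list("abcdef")
        rho = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        edges = pd.DataFrame(
            [("a", "b"), ("c", "d"), ("d", "e")], columns=["genus_a", "genus_b"]
        )
        communities = {"a": 1, "b": 1, "c": 0, "d": 0, "e": 0}
        ordered, bands = community_heatmap_data(rho, communities, edges)
        assert list(bands) == [0, 0, 0, 1, 1]

    def test_empty_communities_give_empty_matrix(self):
        rho = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        ordered, bands = community_heatmap_data(rho, {}, pd.DataFrame(columns=["genus_a", "genus_b"]))
        assert ordered.empty and bands.empty


class TestEndToEnd:
    def test_edges_only_touch_prevalent_genera(self, default_dataset):
        table, meta, _ = default_dataset
        rel = to_relative(aggregate_to_genus(table))
        net = build_cooccurrence_network(rel, meta, NetworkConfig(seed=0, n_perm=200))
        kept = set(prevalence_filter(rel, 5).genus_ids)
        for _, e in net.edges.iterrows():
            assert e.genus_a in kept and e.genus_b in kept

    def test_network_bit_reproducible_under_seed(self, default_dataset):
        table, meta, _ = default_dataset
        rel = to_relative(aggregate_to_genus(table))
        cfg = NetworkConfig(seed=9, n_perm=300)
        n1 = build_cooccurrence_network(rel, meta, cfg)
        n2 = build_cooccurrence_network(rel, meta, cfg)
        assert n1.edges.equals(n2.edges)
        assert n1.communities == n2.communities
        assert n1.nodes.equals(n2.nodes)

    def test_retained_edges_pass_both_criteria(self, default_dataset):
        table, meta, _ = default_dataset
        rel = to_relative(aggregate_to_genus(table))
        cfg = NetworkConfig(seed=3, n_perm=300)
        net = build_cooccurrence_network(rel, meta, cfg)
        assert (net.edges["rho"] >= cfg.rho_threshold).all()
        assert (net.edges["p_raw"] < cfg.alpha).all()
        assert net.edges["robust"].all()
        # communities partition exactly the edge-incident genera
        incident = set(net.edges["genus_a"]) | set(net.edges["genus_b"])
        assert set(net.communities) == incident
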