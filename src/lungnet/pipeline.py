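"""End-to-end orchestration: counts in, statistics and network out.

Stage order follows the analysis narrative: contamination screen ->
depth filter -> rarefaction -> genus aggregation -> rare-genus filter ->
abundance transforms -> diversity -> ordination -> PERMANOVA -> per-genus
group tests -> co-occurrence network. Every intermediate artifact is
written as TSV/JSON under the output directory together with a
machine-readable run log of all filtering decisions.

All randomness flows from the single ``PipelineConfig.seed`` through named
per-stage substreams, so re-running one stage in isolation reproduces what
the full run produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .containers import (
    ConfigurationError,
    OtuCountTable,
    PipelineError,
    SampleMetadata,
)
from .diversity import chao1_richness, pielou_evenness
from .network import NetworkConfig, build_cooccurrence_network
from .ordination import bray_curtis, pcoa
from .preprocess import (
    aggregate_to_genus,
    discard_low_depth_samples,
    filter_contaminant_otus,
    filter_rare_genera,
    hellinger,
    rarefy,
    season_correct,
    to_relative,
)
from .stats import (
    GROUPINGS,
    bh_adjust,
    group_comparison,
    grouping_masks,
    permanova,
    wilcoxon_mw,
)

logger = logging.getLogger(__name__)

_STAGE_STREAMS = {"rarefy": 1, "permanova": 2, "network": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable across stage order)."""
    idx = _STAGE_STREAMS[stage]
    state = np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of a pipeline run; JSON round-trips losslessly."""

    min_reads: int = 700
    rarefy_depth: int = 722
    rare_genus_fraction: float = 1e-4
    contamination_alpha: float = 0.05
    permanova_n_perm: int = 999
    grouping: str = "severe-vs-rest"
    seed: int = 0
    season_correction: bool = True
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def validate(self) -> None:
        if self.min_reads <= 0:
            raise ConfigurationError("min_reads must be positive")
        if self.rarefy_depth <= 0:
            raise ConfigurationError("rarefy_depth must be positive")
        if not 0 < self.contamination_alpha < 1:
            raise ConfigurationError("contamination_alpha must lie in (0, 1)")
        if self.rare_genus_fraction < 0:
            raise ConfigurationError("rare_genus_fraction must be >= 0")
        if self.grouping not in GROUPINGS:
            raise ConfigurationError(f"grouping must be one of {GROUPINGS}")
        self.network.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        net = d.pop("network", {})
        cfg = cls(**d, network=NetworkConfig(**net))
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except (TypeError, ValueError, KeyError) as err:
            raise ConfigurationError(f"invalid config file {path}: {err}") from None


@dataclass
class PipelineResult:
    """Handles to every computed object of one run."""

    contamination_report: object
    rarefied: OtuCountTable
    genus_counts: object
    genus_relative: object
    genus_hellinger: object
    diversity: pd.DataFrame
    distances: object
    ordination: object
    permanova_result: object
    pc_tests: pd.DataFrame
    genus_tests: pd.DataFrame
    network: object
    run_log: dict


def run_pipeline(
    config: PipelineConfig,
    table: OtuCountTable,
    meta: SampleMetadata,
    outdir,
) -> PipelineResult:
    """Execute every stage and write all artifacts under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}}

    def run_stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError as err:
            lio.write_json(log, outdir / "run_log.json")
            raise PipelineError(f"stage {name!r} failed: {err}") from err

    # 1. contamination screen (on relative abundances at OTU level)
    filtered, report = run_stage(
        "contamination", filter_contaminant_otus, table, meta, config.contamination_alpha
    )
    lio.write_contamination_report(report, outdir / "contamination_report.tsv")
    log["stages"]["contamination"] = {
        "flagged_otus": sorted(report.flagged_otus),
        "reads_removed": report.reads_removed,
    }

    # 2. depth filter; a sample must support the rarefaction depth, so the
    # effective threshold is max(min_reads, rarefy_depth)
    effective_min = max(config.min_reads, config.rarefy_depth)
    if effective_min != config.min_reads:
        logger.info(
            "depth filter raised from %d to rarefaction depth %d",
            config.min_reads,
            effective_min,
        )
    before = set(filtered.sample_ids)
    deep = run_stage("depth_filter", discard_low_depth_samples, filtered, effective_min)
    log["stages"]["depth_filter"] = {
        "min_reads": config.min_reads,
        "effective_min_reads": effective_min,
        "samples_dropped": sorted(before - set(deep.sample_ids)),
    }
    meta_used = meta.loc(deep.sample_ids)

    # 3. rarefaction
    rarefied = run_stage(
        "rarefy", rarefy, deep, config.rarefy_depth, stage_seed(config.seed, "rarefy")
    )
    lio.write_count_table(rarefied, outdir / "rarefied_counts.tsv")
    log["stages"]["rarefy"] = {
        "depth": config.rarefy_depth,
        "column_sums": {s: int(v) for s, v in rarefied.depths().items()},
    }

    # 4-6. genus aggregation, rare filter, transforms
    genus_counts = run_stage("aggregate", aggregate_to_genus, rarefied)
    genus_counts = run_stage(
        "rare_filter", filter_rare_genera, genus_counts, config.rare_genus_fraction
    )
    genus_rel = to_relative(genus_counts)
    genus_hel = hellinger(genus_counts)
    lio.write_genus_table(genus_counts, outdir / "genus_counts.tsv")
    lio.write_genus_table(genus_rel, outdir / "genus_relative.tsv")
    lio.write_genus_table(genus_hel, outdir / "genus_hellinger.tsv")
    log["stages"]["genus"] = {"genera_retained": len(genus_counts.genus_ids)}

    # 7. alpha diversity on genus counts
    div = pd.DataFrame(
        {
            "pielou_evenness": [
                pielou_evenness(genus_counts.values[s]) for s in genus_counts.sample_ids
            ],
            "chao1_richness": [
                chao1_richness(genus_counts.values[s].astype(int))
                for s in genus_counts.sample_ids
            ],
        },
        index=pd.Index(genus_counts.sample_ids, name="sample_id"),
    )
    div.to_csv(outdir / "diversity.tsv", sep="\t")

    # 8. ordination on Hellinger-transformed abundances
    dist = run_stage("bray_curtis", bray_curtis, genus_hel)
    lio.write_distance_matrix(dist, outdir / "bray_curtis.tsv")
    ord_res = run_stage("pcoa", pcoa, dist)
    lio.write_ordination(ord_res, outdir / "pcoa_coordinates.tsv", outdir / "pcoa_eigenvalues.tsv")

    # 9. PERMANOVA (uncorrected distances, per the analysis design)
    mask_a, _ = grouping_masks(meta_used, config.grouping, genus_hel.sample_ids)
    labels = np.where(mask_a, "A", "B")
    perm_res = run_stage(
        "permanova",
        permanova,
        dist,
        labels,
        config.permanova_n_perm,
        stage_seed(config.seed, "permanova"),
    )
    lio.write_json(
        {
            "grouping": config.grouping,
            "pseudo_F": perm_res.statistic,
            "p_value": perm_res.p_value,
            "n_permutations": perm_res.n_permutations,
        },
        outdir / "permanova.json",
    )

    # 10. principal-coordinate and per-genus group tests
    pc_rows = []
    n_axes = min(2, ord_res.coordinates.shape[1])
    for axis in ord_res.coordinates.columns[:n_axes]:
        values = ord_res.coordinates[axis]
        if config.season_correction:
            values = season_correct(values, meta_used)
        arr = values.to_numpy(dtype=float)
        res = wilcoxon_mw(arr[mask_a], arr[~mask_a])
        pc_rows.append((axis, res.statistic, res.p_value))
    pc_tests = pd.DataFrame(pc_rows, columns=["axis", "statistic", "p"]).set_index("axis")
    pc_tests["p_adj"] = bh_adjust(pc_tests["p"].to_numpy())
    pc_tests["season_corrected"] = config.season_correction
    pc_tests.to_csv(outdir / "pc_tests.tsv", sep="\t")

    genus_tests = run_stage(
        "group_tests",
        group_comparison,
        genus_hel,
        meta_used,
        config.grouping,
        config.season_correction,
    )
    genus_tests.to_csv(outdir / "genus_tests.tsv", sep="\t")

    # 11. co-occurrence network on relative abundances
    net_config = replace(config.network, seed=stage_seed(config.seed, "network"))
    net = run_stage("network", build_cooccurrence_network, genus_rel, meta_used, net_config)
    lio.write_edges(net, outdir / "edges.tsv")
    lio.write_communities(net, outdir / "communities.tsv")
    lio.write_graphml(net, outdir / "network.graphml")
    log["stages"]["network"] = {
        "n_edges": int(len(net.edges)),
        "n_communities": len(net.community_sizes),
        "reported_communities": net.reported_communities(
            config.network.min_community_size_report
        ),
        "community_sizes": {str(k): v for k, v in net.community_sizes.items()},
    }

    log["stages"]["tests"] = {
        "p_value_mode": "season-corrected" if config.season_correction else "uncorrected",
        "permanova_p": perm_res.p_value,
    }
    lio.write_json(log, outdir / "run_log.json")

    return PipelineResult(
        contamination_report=report,
        rarefied=rarefied,
        genus_counts=genus_counts,
        genus_relative=genus_rel,
        genus_hellinger=genus_hel,
        diversity=div,
        distances=dist,
        ordination=ord_res,
        permanova_result=perm_res,
        pc_tests=pc_tests,
        genus_tests=genus_tests,
        network=net,
        run_log=log,
    )
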