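"""Synthetic OTU tables with planted co-occurrence, batch and contamination structure.

The generator emulates the statistical features a genus-level 16S analysis of
a small bronchial-brush cohort has to cope with:

* compositional count data at uneven sequencing depth (multinomial draws at a
  per-sample depth, so columns are closed by construction);
* blocks of positively co-varying genera, driven by a shared per-sample
  Gaussian latent factor on the log scale (detectable by rank correlation);
* block-level disease association: a signed log-fold effect added to severe
  samples only, so positive effects mean severe-enriched blocks and negative
  effects mean blocks enriched in mild cases and controls;
* a seasonal processing batch shift on a subset of genera;
* reagent-contaminant OTUs whose expected relative abundance scales as
  ``concentration ** -strength`` with the per-sample amplicon concentration.

Every random draw flows from one :class:`numpy.random.Generator` seeded by
``SimulationConfig.seed``, so a fixed configuration is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONC_COLUMNS,
    ConfigurationError,
    OtuCountTable,
    SampleMetadata,
)

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Fusobacteria")


def _default_groups() -> dict[str, int]:
    # cohort sizes: 12 severe, 4 mild, 9 controls
    return {"severe": 12, "mild": 4, "control": 9}


def _default_block_effect() -> dict[int, float]:
    # one severe-enriched block, three enriched in mild+control
    return {0: 1.2, 1: -1.2, 2: -1.2, 3: -1.2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 25-sample cohort (12 severe / 4 mild / 9 control)
    with four planted genus blocks of sizes 6/6/5/5, a dominant stable
    community core of four genera, raw library sizes between 900 and 4800
    reads, ten reagent-contaminant OTUs and a seasonal batch shift on four
    genera.
    """

    n_samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    n_genera: int = 30
    n_blocks: int = 4
    block_sizes: tuple[int, ...] = (6, 6, 5, 5)
    within_block_latent_sd: float = 2.0
    block_group_effect: dict[int, float] = field(default_factory=_default_block_effect)
    genus_noise_sd: float = 0.8
    baseline_sd: float = 1.0
    block_baseline_boost: float = 0.0
    n_core_genera: int = 4
    core_log_boost: float = 3.0
    core_noise_sd: float = 0.8
    n_contaminant_otus: int = 10
    contaminant_strength: float = 2.0
    n_season_affected: int = 4
    season_shift: float = 1.2
    depth_range: tuple[int, int] = (900, 4800)
    otus_per_genus: int = 2
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_samples_per_group.values()):
            raise ConfigurationError("n_samples_per_group: counts must be >= 0")
        if self.n_genera <= 0:
            raise ConfigurationError("n_genera must be positive")
        if self.n_blocks != len(self.block_sizes):
            raise ConfigurationError("block_sizes length must equal n_blocks")
        if any(b <= 0 for b in self.block_sizes):
            raise ConfigurationError("block_sizes entries must be positive")
        if sum(self.block_sizes) > self.n_genera:
            raise ConfigurationError("block_sizes: sum exceeds n_genera")
        if self.n_core_genera < 0:
            raise ConfigurationError("n_core_genera must be >= 0")
        if sum(self.block_sizes) + self.n_core_genera > self.n_genera:
            raise ConfigurationError("block_sizes + n_core_genera exceed n_genera")
        if self.core_noise_sd < 0:
            raise ConfigurationError("core_noise_sd must be >= 0")
        if self.within_block_latent_sd < 0:
            raise ConfigurationError("within_block_latent_sd must be >= 0")
        if self.genus_noise_sd < 0:
            raise ConfigurationError("genus_noise_sd must be >= 0")
        if self.n_contaminant_otus < 0:
            raise ConfigurationError("n_contaminant_otus must be >= 0")
        if self.n_season_affected < 0:
            raise ConfigurationError("n_season_affected must be >= 0")
        if self.n_season_affected > self.n_genera:
            raise ConfigurationError("n_season_affected exceeds n_genera")
        lo, hi = self.depth_range
        if lo < 1 or lo > hi:
            raise ConfigurationError("depth_range must satisfy 1 <= lo <= hi")
        if self.otus_per_genus <= 0:
            raise ConfigurationError("otus_per_genus must be positive")
        for b in self.block_group_effect:
            if not (0 <= b < self.n_blocks):
                raise ConfigurationError(f"block_group_effect: unknown block id {b}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated dataset."""

    block_membership: dict[str, int]
    contaminant_otus: set[str]
    differential_genera: dict[str, str]  # genus -> "severe" | "mild_control"
    season_affected: set[str]

    def to_dict(self) -> dict:
        return {
            "block_membership": dict(sorted(self.block_membership.items())),
            "contaminant_otus": sorted(self.contaminant_otus),
            "differential_genera": dict(sorted(self.differential_genera.items())),
            "season_affected": sorted(self.season_affected),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            block_membership={k: int(v) for k, v in d["block_membership"].items()},
            contaminant_otus=set(d["contaminant_otus"]),
            differential_genera=dict(d["differential_genera"]),
            season_affected=set(d["season_affected"]),
        )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize planted truth as JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))


def _genus_names(n: int) -> list[str]:
    return [f"Genus{i + 1:03d}" for i in range(n)]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[OtuCountTable, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic cohort.

    Genus latent log-abundances are ``baseline + block factor + group effect
    + season shift + noise``; per-sample compositions are the softmax over
    genera, split across ``otus_per_genus`` OTUs with fixed Dirichlet
    weights, augmented with contaminant OTUs whose unnormalized intensity is
    ``exp(c0 - strength * log(concentration) + noise)``, and closed by a
    single multinomial draw per sample at a depth uniform in ``depth_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- samples and metadata -------------------------------------------
    groups: list[str] = []
    sample_ids: list[str] = []
    for g in ("severe", "mild", "control"):
        n = config.n_samples_per_group.get(g, 0)
        for i in range(n):
            sample_ids.append(f"{g[:2].upper()}{i + 1:02d}")
            groups.append(g)
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ConfigurationError("n_samples_per_group: no samples requested")

    # alternate seasons so both occur in every group of reasonable size
    seasons = np.array(["winter", "summer"])[np.arange(n_samples) % 2]
    gc = np.array(
        [g != "control" and rng.random() < 0.55 for g in groups], dtype=bool
    )
    # amplicon concentration, one value reused for the three library runs
    conc = rng.lognormal(mean=np.log(10.0), sigma=0.6, size=n_samples)

    meta_frame = pd.DataFrame(
        {
            "group": groups,
            "season": seasons,
            "gc_treatment": gc,
            CONC_COLUMNS[0]: conc,
            CONC_COLUMNS[1]: conc,
            CONC_COLUMNS[2]: conc,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = SampleMetadata(meta_frame)

    # --- genus latent log-abundances ------------------------------------
    genera = _genus_names(config.n_genera)
    block_of = np.full(config.n_genera, -1, dtype=int)
    pos = 0
    for b, size in enumerate(config.block_sizes):
        block_of[pos : pos + size] = b
        pos += size

    # the last n_core_genera act as the dominant, stable community core
    # (high baseline, low sample-to-sample variation), which keeps the
    # compositional denominator from being driven by any single taxon
    core = np.zeros(config.n_genera, dtype=bool)
    if config.n_core_genera:
        core[config.n_genera - config.n_core_genera :] = True

    baseline = rng.normal(0.0, config.baseline_sd, size=config.n_genera)
    baseline[block_of >= 0] += config.block_baseline_boost
    baseline[core] = config.core_log_boost + rng.normal(
        0.0, 0.3, size=config.n_core_genera
    )

    log_abund = np.tile(baseline[:, None], (1, n_samples))

    if config.n_blocks:
        factors = rng.normal(
            0.0, config.within_block_latent_sd, size=(config.n_blocks, n_samples)
        )
        # centre the factors per sample so blocks trade off against each
        # other instead of jointly swinging the compositional denominator;
        # this yields within-block co-occurrence plus between-block
        # co-exclusion, the pattern these networks show in real data
        if config.n_blocks > 1:
            factors -= factors.mean(axis=0, keepdims=True)
        member = block_of >= 0
        log_abund[member] += factors[block_of[member]]

    severe_mask = np.array([g == "severe" for g in groups])
    differential: dict[str, str] = {}
    for b, effect in config.block_group_effect.items():
        if effect == 0:
            continue
        rows = np.flatnonzero(block_of == b)
        log_abund[np.ix_(rows, np.flatnonzero(severe_mask))] += effect
        direction = "severe" if effect > 0 else "mild_control"
        for r in rows:
            differential[genera[r]] = direction

    # season-affected genera drawn from non-block, non-core genera first, so
    # the batch shift creates correlation structure disjoint from the blocks
    free = np.flatnonzero((block_of < 0) & ~core)
    pool = free if len(free) >= config.n_season_affected else np.arange(config.n_genera)
    season_rows = rng.choice(pool, size=config.n_season_affected, replace=False)
    winter_mask = seasons == "winter"
    if config.n_season_affected:
        log_abund[np.ix_(season_rows, np.flatnonzero(winter_mask))] += config.season_shift

    noise_sd = np.where(core, config.core_noise_sd, config.genus_noise_sd)
    log_abund += rng.normal(0.0, 1.0, size=log_abund.shape) * noise_sd[:, None]

    # per-sample genus composition by closure (softmax)
    comp = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    comp /= comp.sum(axis=0, keepdims=True)

    # --- split genera into OTUs -----------------------------------------
    k = config.otus_per_genus
    otu_ids: list[str] = []
    lineages: list[str] = []
    intensities = np.empty((config.n_genera * k, n_samples))
    split = rng.dirichlet(np.full(k, 5.0), size=config.n_genera)  # fixed per genus
    for gi, genus in enumerate(genera):
        phylum = _PHYLA[gi % len(_PHYLA)]
        for j in range(k):
            otu_ids.append(f"OTU{gi * k + j + 1:04d}")
            lineages.append(
                f"k__Bacteria;p__{phylum};c__C{gi % 7 + 1};o__O{gi % 9 + 1};"
                f"f__Family{gi % 11 + 1:02d};g__{genus}"
            )
            intensities[gi * k + j] = comp[gi] * split[gi, j]

    # --- contaminant OTUs ------------------------------------------------
    contaminant_ids: list[str] = []
    if config.n_contaminant_otus:
        # c0 puts each contaminant near ~0.5% of reads at the median
        # concentration (10 units); low-concentration samples get far more
        c0 = np.log(0.005) + config.contaminant_strength * np.log(10.0)
        base = rng.normal(c0, 0.3, size=config.n_contaminant_otus)
        noise = rng.normal(0.0, 0.3, size=(config.n_contaminant_otus, n_samples))
        contam = np.exp(
            base[:, None] - config.contaminant_strength * np.log(conc)[None, :] + noise
        )
        for j in range(config.n_contaminant_otus):
            oid = f"CONT{j + 1:03d}"
            contaminant_ids.append(oid)
            otu_ids.append(oid)
            lineages.append(
                f"k__Bacteria;p__Proteobacteria;c__Cx;o__Ox;f__ReagentFamily;"
                f"g__ContamGenus{j + 1:02d}"
            )
        intensities = np.vstack([intensities, contam])

    probs = intensities / intensities.sum(axis=0, keepdims=True)

    # --- multinomial counts ----------------------------------------------
    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.empty((len(otu_ids), n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], probs[:, s])

    table = OtuCountTable(
        counts=pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids),
        taxonomy=pd.Series(lineages, index=pd.Index(otu_ids, name="otu_id")),
        run_label=pd.Series("run1", index=pd.Index(sample_ids, name="sample_id")),
    )

    truth = SyntheticTruth(
        block_membership={
            genera[i]: int(block_of[i]) for i in range(config.n_genera) if block_of[i] >= 0
        },
        contaminant_otus=set(contaminant_ids),
        differential_genera=differential,
        season_affected={genera[i] for i in season_rows},
    )
    return table, meta, truth
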