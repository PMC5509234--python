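"""Shared fixtures: tiny hand-built tables and generated cohorts."""

import numpy as np
import pandas as pd
import pytest

from lungnet import (
    GenusAbundanceTable,
    OtuCountTable,
    SampleMetadata,
    SimulationConfig,
    generate_dataset,
)
from lungnet.containers import CONC_COLUMNS


def make_metadata(
    sample_ids,
    groups=None,
    seasons=None,
    gc=None,
    conc=None,
) -> SampleMetadata:
    n = len(sample_ids)
    groups = groups if groups is not None else ["severe"] * (n // 2) + ["control"] * (n - n // 2)
    seasons = seasons if seasons is not None else ["winter", "summer"] * (n // 2 + 1)
    conc = np.asarray(conc if conc is not None else np.linspace(5, 20, n), dtype=float)
    frame = pd.DataFrame(
        {
            "group": groups[:n],
            "season": list(seasons)[:n],
            "gc_treatment": gc if gc is not None else [False] * n,
            CONC_COLUMNS[0]: conc,
            CONC_COLUMNS[1]: conc,
            CONC_COLUMNS[2]: conc,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)


def make_counts(matrix, otu_ids=None, sample_ids=None, genera=None) -> OtuCountTable:
    matrix = np.asarray(matrix)
    otu_ids = otu_ids or [f"OTU{i}" for i in range(matrix.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(matrix.shape[1])]
    genera = genera or [f"G{i}" for i in range(matrix.shape[0])]
    taxonomy = pd.Series(
        [f"k__Bacteria;p__P;f__F;g__{g}" if g else "k__Bacteria;p__P;f__F" for g in genera],
        index=pd.Index(otu_ids, name="otu_id"),
    )
    counts = pd.DataFrame(matrix, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids)
    return OtuCountTable(counts, taxonomy)


def make_genus_table(matrix, genera=None, sample_ids=None, transform="counts"):
    matrix = np.asarray(matrix, dtype=float)
    genera = genera or [f"G{i}" for i in range(matrix.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(matrix.shape[1])]
    return GenusAbundanceTable(
        pd.DataFrame(matrix, index=pd.Index(genera, name="genus"), columns=sample_ids),
        transform=transform,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic cohort at the default study conditions."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def small_meta():
    return make_metadata([f"S{j}" for j in range(8)])
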