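"""Plain-text (TSV/JSON) readers and writers for every pipeline artifact.

TSV is the canonical interchange format so every intermediate can be
inspected with standard tools. The count-table layout is::

    otu_id  taxonomy                 SampleA  SampleB ...
    OTU0001 k__Bacteria;...;g__X     13       0

Metadata is one row per sample with columns ``group``, ``season``,
``gc_treatment`` and ``conc_run1..3``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    CONC_COLUMNS,
    ConfigurationError,
    DataError,
    GenusAbundanceTable,
    OtuCountTable,
    SampleMetadata,
    validate_lineage,
)


def write_count_table(table: OtuCountTable, path) -> None:
    frame = table.counts.copy()
    frame.insert(0, "taxonomy", table.taxonomy)
    frame.to_csv(path, sep="\t", index_label="otu_id")


def read_count_table(path, format: str = "tsv") -> OtuCountTable:
    """Parse an OTU count table; duplicate ids and negative counts are rejected."""
    if format == "biom":
        raise ConfigurationError(
            "BIOM input is not supported in this build; convert to TSV first"
        )
    if format != "tsv":
        raise ConfigurationError(f"unknown count-table format {format!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    if "otu_id" not in frame.columns or "taxonomy" not in frame.columns:
        raise DataError("count table needs 'otu_id' and 'taxonomy' columns")
    if frame["otu_id"].duplicated().any():
        dup = frame.loc[frame["otu_id"].duplicated(), "otu_id"].iloc[0]
        raise DataError(f"duplicate OTU id {dup!r}")
    for offset, lineage in enumerate(frame["taxonomy"]):
        try:
            validate_lineage(lineage)
        except DataError as err:
            # +2: header line plus 1-based numbering
            raise DataError(f"{path}:{offset + 2}: {err}") from None
    frame = frame.set_index("otu_id")
    taxonomy = frame.pop("taxonomy")
    counts = frame.astype("int64")
    if (counts.to_numpy() < 0).any():
        raise DataError("negative count in OTU table")
    return OtuCountTable(counts, taxonomy)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(Path(path), sep="\t", index_col="sample_id")
    frame["gc_treatment"] = frame["gc_treatment"].astype(bool)
    frame[list(CONC_COLUMNS)] = frame[list(CONC_COLUMNS)].astype(float)
    return SampleMetadata(frame)


def write_genus_table(table: GenusAbundanceTable, path) -> None:
    frame = table.values.copy()
    frame.insert(0, "transform", table.transform)
    frame.to_csv(path, sep="\t", index_label="genus")


def read_genus_table(path) -> GenusAbundanceTable:
    frame = pd.read_csv(Path(path), sep="\t", index_col="genus")
    transforms = frame.pop("transform").unique()
    if len(transforms) != 1:
        raise DataError("genus table has inconsistent transform column")
    return GenusAbundanceTable(frame.astype(float), transform=str(transforms[0]))


def write_distance_matrix(d, path) -> None:
    pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_ordination(result, path_coords, path_eigen) -> None:
    result.coordinates.to_csv(path_coords, sep="\t", index_label="sample_id")
    n_axes = len(result.proportion_explained)
    eig = pd.DataFrame(
        {
            "eigenvalue": result.eigenvalues,
            "proportion_explained": list(result.proportion_explained)
            + [float("nan")] * (len(result.eigenvalues) - n_axes),
        }
    )
    eig.index = [f"axis{i + 1}" for i in range(len(eig))]
    eig.to_csv(path_eigen, sep="\t", index_label="axis")


def write_contamination_report(report, path) -> None:
    report.stats.to_csv(path, sep="\t", index_label="otu_id")


def write_edges(network, path) -> None:
    edges = network.edges.copy()
    edges["community_a"] = edges["genus_a"].map(network.communities).astype("Int64")
    edges["community_b"] = edges["genus_b"].map(network.communities).astype("Int64")
    edges.to_csv(path, sep="\t", index=False)


def write_communities(network, path) -> None:
    network.nodes.to_csv(path, sep="\t", index_label="genus")


def write_graphml(network, path) -> None:
    nx.write_graphml(network.to_graph(), path)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
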