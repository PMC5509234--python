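"""In-memory containers for OTU tables, sample metadata and genus tables.

The pipeline passes three table types between stages:

``OtuCountTable``
    Integer read counts, OTUs x samples, with a ranked taxonomy string per
    OTU ("k__...;p__...;g__Genus"; the genus rank may be absent for OTUs
    that could not be classified that deep).
``SampleMetadata``
    One record per sample: disease group (severe / mild / control), the
    processing season (winter / summer, a batch surrogate), an inhaled
    glucocorticoid flag, and the amplicon concentration measured in each of
    the three library amplification runs.
``GenusAbundanceTable``
    Genera x samples real matrix carrying an explicit ``transform`` state
    (counts / relative / hellinger) so stages can refuse inputs that are in
    the wrong state, which enforces the intended pipeline order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("severe", "mild", "control")
SEASONS = ("winter", "summer")
TRANSFORMS = ("counts", "relative", "hellinger")

CONC_COLUMNS = ("conc_run1", "conc_run2", "conc_run3")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError):
    """An invalid configuration value; the message names the field."""


class DataError(PipelineError):
    """Structurally invalid or inconsistent input data."""


_GENUS_RE = re.compile(r"(?:^|;)\s*g__([^;]*)")


def genus_from_lineage(lineage: str) -> str | None:
    """Extract the genus from a greengenes-style lineage string.

    Returns ``None`` when the genus rank is absent or empty (the OTU is
    unclassified at genus level).
    """
    m = _GENUS_RE.search(lineage)
    if m is None:
        return None
    genus = m.group(1).strip()
    return genus or None


def validate_lineage(lineage: str) -> None:
    """A lineage must contain at least one ``rank__name`` token."""
    if not isinstance(lineage, str) or "__" not in lineage:
        raise DataError(f"malformed taxonomy string: {lineage!r}")


@dataclass
class OtuCountTable:
    """Non-negative integer counts, OTUs x samples, with taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with one column per sample.
    taxonomy
        Series mapping OTU id -> ranked lineage string.
    run_label
        Optional Series mapping sample id -> library-run id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    run_label: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate OTU ids in count table")
        if self.counts.columns.has_duplicates:
            raise DataError("duplicate sample ids in count table")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise DataError("negative counts in OTU table")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            raise DataError(f"taxonomy missing for OTUs: {list(missing)[:5]}")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        for lineage in self.taxonomy:
            validate_lineage(lineage)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero columns stay zero."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=1)

    def genus_series(self) -> pd.Series:
        """Genus per OTU (``None`` when unclassified at genus level)."""
        return self.taxonomy.map(genus_from_lineage)

    def select_otus(self, otu_ids) -> "OtuCountTable":
        run = None if self.run_label is None else self.run_label.copy()
        return OtuCountTable(
            counts=self.counts.loc[list(otu_ids)].copy(),
            taxonomy=self.taxonomy.loc[list(otu_ids)].copy(),
            run_label=run,
        )

    def select_samples(self, sample_ids) -> "OtuCountTable":
        run = None
        if self.run_label is not None:
            run = self.run_label.reindex(list(sample_ids))
        return OtuCountTable(
            counts=self.counts[list(sample_ids)].copy(),
            taxonomy=self.taxonomy.copy(),
            run_label=run,
        )


@dataclass
class SampleMetadata:
    """Per-sample clinical and processing covariates.

    Wraps a DataFrame indexed by sample id with columns ``group``,
    ``season``, ``gc_treatment`` and ``conc_run1..3`` (amplicon
    concentration per library amplification run).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "season", "gc_treatment", *CONC_COLUMNS}
        missing = required.difference(self.frame.columns)
        if missing:
            raise DataError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise DataError("duplicate sample ids in metadata")
        bad_group = set(self.frame["group"]) - set(GROUPS)
        if bad_group:
            raise DataError(f"unknown group labels: {sorted(bad_group)}")
        bad_season = set(self.frame["season"]) - set(SEASONS)
        if bad_season:
            raise DataError(f"unknown season labels: {sorted(bad_season)}")
        conc = self.frame[list(CONC_COLUMNS)].to_numpy(dtype=float)
        if (conc < 0).any():
            raise DataError("negative amplicon concentration")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    @property
    def season(self) -> pd.Series:
        return self.frame["season"]

    @property
    def gc_treatment(self) -> pd.Series:
        return self.frame["gc_treatment"]

    def concentrations(self) -> pd.DataFrame:
        """Samples x 3 concentrations, one column per library run."""
        return self.frame[list(CONC_COLUMNS)].astype(float)

    def require_samples(self, sample_ids) -> None:
        missing = set(sample_ids) - set(self.frame.index)
        if missing:
            raise DataError(f"metadata missing for samples: {sorted(missing)[:5]}")

    def loc(self, sample_ids) -> "SampleMetadata":
        self.require_samples(sample_ids)
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


@dataclass
class GenusAbundanceTable:
    """Genera x samples abundances with an explicit transform state."""

    values: pd.DataFrame
    transform: str = "counts"

    _TOL = 1e-9

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"transform must be one of {TRANSFORMS}")
        if self.values.index.has_duplicates:
            raise DataError("duplicate genus ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr < 0).any():
            raise DataError("negative abundances")
        if arr.size and self.transform == "relative":
            # columns sum to 1 when freshly closed; subsetting rows (e.g. a
            # prevalence filter) leaves sums below 1, which stays valid
            sums = arr.sum(axis=0)
            if (sums > 1.0 + self._TOL).any() or (arr > 1.0 + self._TOL).any():
                raise DataError("relative-transform values must lie in [0, 1]")
        if arr.size and self.transform == "hellinger":
            norms = np.sqrt((arr**2).sum(axis=0))
            ok = np.isclose(norms, 1.0, atol=self._TOL) | (norms == 0)
            if not ok.all():
                raise DataError("hellinger-transform columns must have unit norm")

    @property
    def genus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_transform(self, *allowed: str) -> None:
        if self.transform not in allowed:
            raise DataError(
                f"operation requires transform in {allowed}, got {self.transform!r}"
            )
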