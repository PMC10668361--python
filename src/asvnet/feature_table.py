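"""Feature-table container, TSV I/O, and count-table filters.

The :class:`FeatureTable` is the pipeline's root object: a samples x ASVs
matrix of non-negative integer counts.  Filters implemented here are the
standard amplicon preprocessing steps: a grand-total relative-abundance
floor, a prevalence (fraction-of-samples) floor, and rarefaction
(subsampling without replacement to even depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from asvnet._util import logger

REQUIRED_METADATA_COLUMNS = ("group",)


class FeatureTableError(ValueError):
    """Raised for malformed tables or invalid filter parameters."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x ASVs non-negative integer count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are ASVs, values are integer counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicate ASV ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FeatureTableError("non-numeric values in count table")
        if np.any(values < 0):
            raise FeatureTableError("negative counts in feature table")
        if not np.allclose(values, np.round(values)):
            raise FeatureTableError("non-integer counts in feature table")
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def asv_ids(self) -> list[str]:
        return [str(a) for a in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample annotations: at minimum a ``group`` column.

    Optional columns (``timepoint``, ``temperature``, ``treatment``) pass
    through untouched.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.data.columns:
                raise FeatureTableError(f"metadata missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise FeatureTableError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def groups(self) -> pd.Series:
        return self.data["group"]

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise FeatureTableError(
                f"metadata does not cover samples: {sorted(missing)}"
            )

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[sample_ids].copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, samples_as_rows: bool = True) -> FeatureTable:
    """Read a TSV count table into canonical samples-as-rows form.

    ``samples_as_rows=False`` declares that the file stores ASVs as rows
    (the common deposited-table orientation); the table is transposed on
    read so downstream code always sees samples as rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FeatureTableError(f"empty feature table: {path}")
    try:
        df = df.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FeatureTableError(f"non-numeric cell in {path}: {exc}") from exc
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_min_relative_abundance(
    table: FeatureTable, threshold: float = 0.00005
) -> FeatureTable:
    """Drop ASVs whose share of the grand total is below ``threshold``.

    An ASV is removed when ``total_count / grand_total < threshold``
    (strictly less than: an ASV sitting exactly on the floor is retained).
    The default of 0.005% is the conventional low-abundance ASV floor.
    """
    if threshold < 0:
        raise FeatureTableError("threshold must be non-negative")
    grand_total = int(table.counts.sum())
    if grand_total == 0:
        raise FeatureTableError("grand total of counts is zero")
    asv_totals = table.data.sum(axis=0)
    keep = asv_totals / grand_total >= threshold
    kept = table.data.loc[:, keep]
    logger.info(
        "abundance filter (threshold=%g): %d -> %d ASVs",
        threshold, table.n_asvs, kept.shape[1],
    )
    return FeatureTable(kept)


def filter_prevalence(table: FeatureTable, min_fraction: float = 0.30) -> FeatureTable:
    """Keep ASVs with nonzero counts in at least ``min_fraction`` of samples.

    Inclusive threshold: an ASV present in exactly ``min_fraction * n``
    samples survives.
    """
    if not 0 <= min_fraction <= 1:
        raise FeatureTableError("min_fraction must lie in [0, 1]")
    if table.n_samples == 0:
        raise FeatureTableError("empty table")
    prevalence = (table.data > 0).sum(axis=0) / table.n_samples
    # guard against float round-off at the boundary (e.g. 3/10 >= 0.3)
    keep = prevalence >= min_fraction - 1e-12
    kept = table.data.loc[:, keep]
    logger.info(
        "prevalence filter (min_fraction=%g): %d -> %d ASVs",
        min_fraction, table.n_asvs, kept.shape[1],
    )
    return FeatureTable(kept)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged).
    Deterministic under ``seed`` via a multivariate hypergeometric draw.
    """
    if depth <= 0:
        raise FeatureTableError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep_samples = totals[totals >= depth].index.tolist()
    dropped = sorted(set(table.sample_ids) - set(map(str, keep_samples)))
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not keep_samples:
        raise FeatureTableError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for sid in keep_samples:
        counts = table.data.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(rows, index=keep_samples, columns=table.data.columns)
    return FeatureTable(out)


def default_rarefaction_depth(table: FeatureTable) -> int:
    """Minimum sample total: the deepest even depth that keeps all samples."""
    return int(table.sample_totals().min())
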