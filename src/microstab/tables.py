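"""On-disk artifacts: genus count tables, metadata, symptom panels.

All readers/writers share one sample-identity convention: a study sample
id is ``<subject>_<timepoint>`` with timepoint in {T0, T1, T2, T3};
sequencing blanks are named ``BLANK_<k>``.  Count tables are TSV with
genus rows and sample columns; metadata and symptom panels are CSV with
one row per sample (subject x timepoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIMEPOINTS = ("T0", "T1", "T2", "T3")
COHORTS = ("cancer", "healthy")
PH_RANGE = (4.0, 7.7)  # pH strip scoring range

#: columns a metadata table must provide (beyond the sample-id index)
METADATA_REQUIRED = ["subject", "cohort", "timepoint", "age", "BMI", "race", "pH"]
METADATA_BEHAVIORS = [
    "antibiotics_4w",
    "estrogen_4w",
    "HRT_4w",
    "douching_4w",
    "lubricant_4w",
    "probiotics_4w",
    "intercourse_4w",
]
METADATA_TREATMENT = ["surgery", "chemo", "radiation"]


class SchemaError(ValueError):
    """A table violates its on-disk schema."""


def parse_sample_id(sample_id: str) -> tuple[str, str | None, bool]:
    """Split a sample id into (subject, timepoint, is_blank).

    Blanks have no subject/timepoint structure; any other id must end in
    a recognised timepoint label.
    """
    if sample_id.startswith("BLANK_"):
        return sample_id, None, True
    subject, _, timepoint = sample_id.rpartition("_")
    if not subject or timepoint not in TIMEPOINTS:
        raise SchemaError(
            f"sample id {sample_id!r} does not parse as <subject>_<timepoint> "
            f"with timepoint in {TIMEPOINTS}"
        )
    return subject, timepoint, False


@dataclass
class GenusCountTable:
    """Integer genus x sample count matrix with sample identity.

    Parameters
    ----------
    data:
        DataFrame of non-negative integer counts, genera as the row index,
        sample ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate genus labels: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise SchemaError("count table contains non-numeric cells")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            i, j = bad[0]
            raise SchemaError(
                f"cell ({df.index[i]!r}, {df.columns[j]!r}) = {arr[i, j]} is not a "
                "non-negative integer"
            )
        self.data = df.astype(np.int64)
        # validate ids eagerly so malformed tables fail at construction
        for sid in self.data.columns:
            parse_sample_id(str(sid))

    # -- basic accessors -------------------------------------------------
    @property
    def genera(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_index(self) -> pd.DataFrame:
        """Per-sample (subject, timepoint, is_blank) records."""
        rows = [parse_sample_id(str(s)) for s in self.samples]
        return pd.DataFrame(
            rows, columns=["subject", "timepoint", "is_blank"], index=self.samples
        )

    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        tot = self.data.sum(axis=0)
        if (tot == 0).any():
            empty = tot.index[tot == 0].tolist()
            raise SchemaError(f"samples with zero total reads: {empty}")
        return self.data / tot

    def subset_samples(self, sample_ids) -> "GenusCountTable":
        return GenusCountTable(self.data.loc[:, list(sample_ids)].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenusCountTable) and self.data.equals(other.data)


@dataclass
class MetadataTable:
    """Per-sample clinical/behavioral metadata, indexed by sample id."""

    data: pd.DataFrame
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in METADATA_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"metadata missing mandatory columns: {missing}")
        bad_cohort = set(df["cohort"].dropna()) - set(COHORTS)
        if bad_cohort:
            raise SchemaError(
                f"cohort values outside vocabulary {COHORTS}: {sorted(bad_cohort)}"
            )
        bad_tp = set(df["timepoint"].dropna()) - set(TIMEPOINTS)
        if bad_tp:
            raise SchemaError(
                f"timepoint values outside vocabulary {TIMEPOINTS}: {sorted(bad_tp)}"
            )
        ph = pd.to_numeric(df["pH"], errors="coerce")
        out = ph.dropna()[(ph.dropna() < PH_RANGE[0]) | (ph.dropna() > PH_RANGE[1])]
        if len(out):
            warnings.warn(
                f"{len(out)} pH value(s) outside the strip range {PH_RANGE}; "
                "retained as-is",
                stacklevel=2,
            )
        known = set(METADATA_REQUIRED + METADATA_BEHAVIORS + METADATA_TREATMENT)
        self.extra_columns = [c for c in df.columns if c not in known]
        if self.extra_columns:
            warnings.warn(
                f"unknown metadata columns preserved: {self.extra_columns}",
                stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


@dataclass
class Study:
    """Counts joined with metadata on sample id (intersection join)."""

    counts: GenusCountTable
    metadata: MetadataTable
    dropped_counts: list[str]
    dropped_metadata: list[str]


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_count_table(path: str | Path) -> GenusCountTable:
    """Read a genus-rows x sample-columns TSV count table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna().argmax()]
            raise SchemaError(
                f"non-numeric count at genus {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    return GenusCountTable(df)


def write_count_table(table: GenusCountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="genus")


def read_metadata(path: str | Path) -> MetadataTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return MetadataTable(df)


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    meta.data.to_csv(path, index_label="sample")


def read_symptoms(path: str | Path) -> pd.DataFrame:
    """Read a symptom panel CSV (one row per subject x timepoint)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_symptoms(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index_label="sample")


def align_tables(counts: GenusCountTable, meta: MetadataTable) -> Study:
    """Join counts and metadata on sample id; report drops on both sides.

    Blanks carry no metadata and are not counted as drops.
    """
    count_ids = [s for s in counts.samples if not parse_sample_id(s)[2]]
    shared = [s for s in count_ids if s in set(meta.samples)]
    if not shared:
        raise SchemaError("no sample ids shared between counts and metadata")
    dropped_counts = [s for s in count_ids if s not in set(shared)]
    dropped_meta = [s for s in meta.samples if s not in set(shared)]
    return Study(
        counts=counts.subset_samples(shared),
        metadata=MetadataTable(meta.data.loc[shared].copy()),
        dropped_counts=dropped_counts,
        dropped_metadata=dropped_meta,
    )
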