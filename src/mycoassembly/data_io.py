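"""Reading, validation, filtering, rarefaction and aggregation of ASV
tables, sample metadata, taxonomy and differential-abundance results.

All tabular formats are plain TSV (UTF-8, header row).  Count tables are
held samples-as-rows internally; the reader accepts either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._utils import as_rng

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"

METADATA_COLUMNS = (
    "sample_id",
    "site_code",
    "ocean",
    "sample_type",
    "latitude",
    "longitude",
)

SAMPLE_TYPES = ("leaf", "root", "sediment")


class FormatError(ValueError):
    """A file did not parse as the expected tabular dialect."""


class ValidationError(ValueError):
    """Parsed content violated a table invariant."""


@dataclass(frozen=True)
class CountTable:
    """Integer reads per (sample, ASV); the pipeline's universal currency.

    ``counts`` is a samples x ASVs DataFrame with unique string ids on
    both axes and nonnegative integer entries.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts.rename_axis(index="sample_id", columns=None)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        object.__setattr__(self, "counts", df)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dupes}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            bad = ~np.isfinite(arr) | (arr != np.floor(arr))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer count at sample {df.index[i]!r}, "
                    f"ASV {df.columns[j]!r}: {arr[i, j]!r}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, "
                f"ASV {df.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)])

    def drop_empty_asvs(self) -> "CountTable":
        keep = self.counts.sum(axis=0) > 0
        return CountTable(self.counts.loc[:, keep])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class FilterReport:
    """Samples/ASVs removed by a filtering step, with the rule applied."""

    rule: str
    dropped_samples: list[str] = field(default_factory=list)
    dropped_asvs: list[str] = field(default_factory=list)


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    orientation : {"samples_as_rows", "taxa_as_rows"}
        Hint resolving which axis holds samples; tables are normalized to
        samples-as-rows internally.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation hint: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "taxa_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count at sample {bad.index[0]!r}, "
                f"ASV {col!r}: {bad.iloc[0]!r}"
            ) from None
    df.index.name = "sample_id"
    return CountTable(numeric)


def write_count_table(table: CountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate per-sample metadata (TSV)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_code": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    lat, lon = meta["latitude"], meta["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValidationError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValidationError("longitude outside [-180, 180]")
    bad_types = set(meta["sample_type"]) - set(SAMPLE_TYPES)
    if bad_types:
        raise ValidationError(f"unknown sample types: {sorted(bad_types)}")
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy table (asv_id plus one column per rank)."""
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in tax.columns:
        raise ValidationError("taxonomy table must have an 'asv_id' column")
    if tax["asv_id"].duplicated().any():
        dupes = tax["asv_id"][tax["asv_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate ASV ids in taxonomy: {dupes}")
    tax = tax.set_index("asv_id")
    tax = tax.fillna(UNCLASSIFIED)
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index_label="asv_id")


def read_differential_abundance(path) -> pd.DataFrame:
    """Read a differential-abundance result table (asv_id, comparison,
    log2fc, padj)."""
    da = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "comparison": str})
    required = {"asv_id", "comparison", "log2fc", "padj"}
    missing = required - set(da.columns)
    if missing:
        raise ValidationError(f"DA table missing columns: {sorted(missing)}")
    if ((da["padj"] < 0) | (da["padj"] > 1)).any():
        raise ValidationError("adjusted p values must lie in [0, 1]")
    for comp in da["comparison"]:
        parts = comp.split("_vs_")
        if len(parts) != 2 or not set(parts) <= set(SAMPLE_TYPES):
            raise ValidationError(
                f"comparison {comp!r} is not of the form '<type>_vs_<type>'"
            )
    return da


def filter_by_taxonomy(
    table: CountTable,
    tax: pd.DataFrame,
    keep: str | Callable[[pd.Series], bool],
    rank: str = "domain",
) -> tuple[CountTable, FilterReport]:
    """Retain only ASVs whose taxonomy satisfies a predicate.

    ``keep`` is either a label matched case-insensitively at ``rank``
    (the typical use: keep="Fungi" at the domain level) or a callable on
    the ASV's rank vector.  Samples left with zero reads are dropped and
    reported, mirroring the loss of samples whose only reads were
    nonfungal.
    """
    missing = [a for a in table.asv_ids if a not in tax.index]
    if missing:
        raise ValidationError(f"ASVs missing from taxonomy: {missing[:10]}")
    sub = tax.loc[table.asv_ids]
    if callable(keep):
        mask = sub.apply(keep, axis=1).to_numpy(dtype=bool)
        rule = f"taxonomy predicate {getattr(keep, '__name__', 'callable')}"
    else:
        if rank not in sub.columns:
            raise ValueError(f"unknown rank {rank!r}")
        mask = (
            sub[rank].astype(str).str.casefold() == str(keep).casefold()
        ).to_numpy()
        rule = f"{rank} == {keep!r}"
    kept = table.counts.loc[:, mask]
    row_sums = kept.sum(axis=1)
    dropped_samples = row_sums.index[row_sums == 0].tolist()
    report = FilterReport(
        rule=rule,
        dropped_samples=dropped_samples,
        dropped_asvs=[a for a, m in zip(table.asv_ids, mask) if not m],
    )
    return CountTable(kept.loc[row_sums > 0]), report


def rarefy(
    table: CountTable, depth: int, seed=None
) -> tuple[CountTable, FilterReport]:
    """Subsample every sample to ``depth`` reads without replacement.

    Per-sample draws are multivariate hypergeometric, so each retained
    row sums exactly to ``depth``.  Samples with fewer than ``depth``
    reads are dropped and reported, never padded.  Deterministic under a
    fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = as_rng(seed)
    totals = table.sample_sums()
    keep = totals >= depth
    rows = []
    for sid in totals.index[keep]:
        counts = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    kept_ids = totals.index[keep]
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(kept_ids), -1)
        if rows
        else np.empty((0, table.shape[1]), dtype=np.int64),
        index=kept_ids,
        columns=table.counts.columns,
    )
    report = FilterReport(
        rule=f"total reads < rarefaction depth {depth}",
        dropped_samples=totals.index[~keep].tolist(),
    )
    return CountTable(out), report


def aggregate_taxa(table: CountTable, tax: pd.DataFrame, rank: str) -> CountTable:
    """Sum ASV columns sharing the same label at ``rank``.

    Per-sample totals are conserved exactly; unclassified labels pool
    into a single column.
    """
    if rank not in tax.columns:
        raise ValueError(f"unknown rank {rank!r}; available: {list(tax.columns)}")
    missing = [a for a in table.asv_ids if a not in tax.index]
    if missing:
        raise ValidationError(f"ASVs missing from taxonomy: {missing[:10]}")
    labels = tax.loc[table.asv_ids, rank].astype(str)
    grouped = table.counts.T.groupby(labels.to_numpy()).sum().T
    return CountTable(grouped)


def filter_by_mean_proportion(table: CountTable, threshold: float) -> CountTable:
    """Drop columns whose mean per-sample relative abundance is below
    ``threshold`` (e.g. 0.01 for the 1 % display rule)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    sums = table.sample_sums().to_numpy()
    if (sums == 0).any():
        raise ValidationError("table has all-zero sample rows")
    props = table.matrix() / sums[:, None]
    keep = props.mean(axis=0) >= threshold
    return CountTable(table.counts.loc[:, keep])
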