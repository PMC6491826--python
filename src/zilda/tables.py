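"""Reading, validating and writing abundance tables and sample metadata.

Tables are plain TSV: features in rows, samples in columns, first column
``feature_id``.  Metadata is TSV with columns ``sample_id``, ``group``,
``stage``.  Lines starting with ``#`` are comments (writers use them to
record provenance).  Missing cells are errors, not imputed values: the
zero-inflated model downstream is the zero-handling mechanism, so inputs
must be complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Disease-state vocabulary, ordered by progression.
GROUPS = ("healthy", "small_adenoma", "large_adenoma", "crc")

#: Cancer stages, valid only for the ``crc`` group.
STAGES = ("I", "II", "III", "IV")


class TableError(ValueError):
    """Raised for malformed or invalid tables / metadata."""


@dataclass
class CountTable:
    """Features x samples matrix of nonnegative abundances.

    ``values`` may hold integer counts or relative abundances; both occur in
    practice because upstream abundance estimators emit reals.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.feature_ids), len(self.sample_ids)
        if self.values.shape != (n, m):
            raise TableError(
                f"values shape {self.values.shape} does not match "
                f"{n} features x {m} samples"
            )
        if n < 2 or m < 2:
            raise TableError("a table needs at least 2 features and 2 samples")
        if len(set(self.feature_ids)) != n:
            dup = _first_duplicate(self.feature_ids)
            raise TableError(f"duplicate feature id {dup!r}")
        if len(set(self.sample_ids)) != m:
            dup = _first_duplicate(self.sample_ids)
            raise TableError(f"duplicate sample id {dup!r}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise TableError(
                f"missing value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise TableError(
                f"negative value {self.values[i, j]} at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.feature_ids), list(sample_ids), self.values[:, idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountTable":
        idx = [self.feature_index(f) for f in feature_ids]
        return CountTable(list(feature_ids), list(self.sample_ids), self.values[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class SampleMetadata:
    """One sample's disease-state record; ``stage`` only for CRC samples."""

    sample_id: str
    group: str
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TableError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"allowed groups: {', '.join(GROUPS)}"
            )
        if self.stage == "":
            self.stage = None
        if self.stage is not None:
            if self.group != "crc":
                raise TableError(
                    f"sample {self.sample_id!r}: stage {self.stage!r} given but "
                    f"group is {self.group!r} (stage is valid only for crc)"
                )
            if self.stage not in STAGES:
                raise TableError(
                    f"sample {self.sample_id!r}: unknown stage {self.stage!r}; "
                    f"allowed stages: {', '.join(STAGES)}"
                )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate present")


def _read_tsv_rows(path) -> list[list[str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise TableError(f"{path}: file is empty")
    return rows


def read_count_table(path) -> CountTable:
    """Read a TSV count table (first column feature id, header = sample ids)."""
    rows = _read_tsv_rows(path)
    header = rows[0]
    if len(header) < 2:
        raise TableError(f"{path}: header must contain at least one sample column")
    sample_ids = header[1:]
    feature_ids = []
    values = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise TableError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        feature_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise TableError(
                    f"{path}: non-numeric cell {cell!r} at feature {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            if math.isnan(v):
                raise TableError(
                    f"{path}: missing value at feature {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            if v < 0:
                raise TableError(
                    f"{path}: negative value {cell!r} at feature {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            values[i, j] = v
    return CountTable(feature_ids, sample_ids, values)


def write_count_table(table: CountTable, path, comment: str | None = None) -> None:
    """Write a table as TSV; ``%.17g`` formatting round-trips floats exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.values):
            fh.write(fid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_metadata(path) -> list[SampleMetadata]:
    """Read sample metadata TSV (columns sample_id, group, stage)."""
    rows = _read_tsv_rows(path)
    header = rows[0]
    try:
        i_sid = header.index("sample_id")
        i_grp = header.index("group")
    except ValueError:
        raise TableError(
            f"{path}: metadata header must contain 'sample_id' and 'group'"
        ) from None
    i_stg = header.index("stage") if "stage" in header else None
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for row in rows[1:]:
        sid = row[i_sid]
        if sid in seen:
            raise TableError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        stage = row[i_stg] if (i_stg is not None and i_stg < len(row)) else ""
        records.append(SampleMetadata(sid, row[i_grp], stage or None))
    return records


def write_metadata(records: Iterable[SampleMetadata], path, comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("sample_id\tgroup\tstage\n")
        for rec in records:
            fh.write(f"{rec.sample_id}\t{rec.group}\t{rec.stage or ''}\n")


def group_map(records: Iterable[SampleMetadata]) -> dict[str, str]:
    """sample_id -> group lookup."""
    return {rec.sample_id: rec.group for rec in records}


def samples_in_group(records: Iterable[SampleMetadata], group: str) -> list[str]:
    return [rec.sample_id for rec in records if rec.group == group]


def to_relative_abundance(table: CountTable) -> CountTable:
    """Normalise each sample column to sum 1; zeros stay zeros.

    Idempotent within floating tolerance, so it is safe to call on a table
    that is already compositional.
    """
    sums = table.values.sum(axis=0)
    if (sums <= 0).any():
        j = int(np.argmax(sums <= 0))
        raise TableError(f"sample {table.sample_ids[j]!r} has zero total abundance")
    return CountTable(
        list(table.feature_ids), list(table.sample_ids), table.values / sums
    )


def write_commented_tsv(frame: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a result DataFrame as TSV with an optional '#' provenance line."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
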