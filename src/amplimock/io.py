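"""Readers and writers for the plain-text formats the pipeline touches.

FASTA for sequences (ASVs, reference database, mock references), TSV for
count tables and sample metadata, YAML for the run configuration. Count
tables follow the common denoiser export convention: ASVs as rows, samples
as columns (a flag accepts the transposed orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import SequenceRecord, TaxonomyLineage, parse_lineage

DEFAULT_DEPTH_STRATA = (50, 150, 300, 500, 1000, 1500, 2000)
SAMPLE_ROLES = frozenset({"environmental", "mock"})

METADATA_COLUMNS = ["sample", "island", "depth_m", "transect", "library_id", "sample_role"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T. Duplicate ids and empty
    files are rejected. If a header carries a ``;``-separated lineage after
    the first whitespace, it is parsed and attached.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        lineage = None
        desc = rec.description[len(rec.id):].strip()
        if ";" in desc:
            lineage = parse_lineage(desc)
        records.append(SequenceRecord(rec.id, str(rec.seq), lineage))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.seq),
            id=r.id,
            description=str(r.lineage) if r.lineage is not None else "",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Count matrices

@dataclass
class CountMatrix:
    """Integer read counts for samples × ASVs.

    Thin validated wrapper around a pandas DataFrame whose index holds sample
    ids and whose columns hold ASV ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate ASV ids")
        if not np.issubdtype(df.values.dtype, np.integer):
            if not np.allclose(df.values, np.round(df.values)):
                raise ValueError("counts must be integers")
            df = df.astype(np.int64)
        if (df.values < 0).any():
            raise ValueError("negative counts")
        self.counts = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.values

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def drop_empty_asvs(self) -> "CountMatrix":
        keep = self.counts.sum(axis=0) > 0
        return CountMatrix(self.counts.loc[:, keep])

    def subset_asvs(self, asv_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, [a for a in self.asv_ids if a in set(asv_ids)]])

    def presence(self) -> pd.DataFrame:
        """Binary presence/absence (≥1 read) view."""
        return (self.counts > 0).astype(np.int8)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


def read_count_table(path: str | Path, *, samples_as_rows: bool = False) -> CountMatrix:
    """Read a TSV count table (ASVs as rows, samples as columns by default).

    Cells must be non-negative integers; missing or ragged cells, floats and
    negative values are rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(f"non-integer cell {cell!r} at row {row!r}, column {col!r} in {path}") from None
            if value < 0:
                raise ValueError(f"negative cell {cell!r} at row {row!r}, column {col!r} in {path}")
            out.loc[row, col] = value
    if not samples_as_rows:
        out = out.T
    out.index.name = "sample"
    out.columns.name = "asv"
    return CountMatrix(out)


def write_count_table(cm: CountMatrix, path: str | Path, *, samples_as_rows: bool = False) -> None:
    df = cm.counts if samples_as_rows else cm.counts.T
    df.to_csv(path, sep="\t", index_label="asv" if not samples_as_rows else "sample")


# ---------------------------------------------------------------------------
# Sample metadata

@dataclass
class SampleMetadata:
    """Per-sample design variables: island, depth, transect, library, role.

    Every environmental sample must share its ``library_id`` with exactly one
    mock sample — the mock sequenced on the same lane calibrates that
    library's read-proportion thresholds.
    """

    table: pd.DataFrame
    depth_strata: tuple[int, ...] = DEFAULT_DEPTH_STRATA

    def __post_init__(self) -> None:
        t = self.table
        missing = set(METADATA_COLUMNS[1:]) - set(t.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        bad_role = set(t["sample_role"]) - SAMPLE_ROLES
        if bad_role:
            raise ValueError(f"unknown sample_role values {sorted(bad_role)}")
        env = t[t["sample_role"] == "environmental"]
        bad_depth = set(env["depth_m"]) - set(self.depth_strata)
        if bad_depth:
            raise ValueError(f"depth_m values {sorted(bad_depth)} outside declared strata {self.depth_strata}")
        mock_libs = t.loc[t["sample_role"] == "mock", "library_id"]
        if mock_libs.duplicated().any():
            raise ValueError("more than one mock sample per library")
        orphans = set(env["library_id"]) - set(mock_libs)
        if orphans:
            raise ValueError(f"environmental samples reference libraries without a mock: {sorted(orphans)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def environmental(self) -> pd.DataFrame:
        return self.table[self.table["sample_role"] == "environmental"]

    def mocks(self) -> pd.DataFrame:
        return self.table[self.table["sample_role"] == "mock"]

    def library_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "library_id"])


def read_metadata(path: str | Path, *, depth_strata: Sequence[int] = DEFAULT_DEPTH_STRATA) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "island": str, "transect": str,
                                            "library_id": str, "sample_role": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns {sorted(missing)}")
    df["depth_m"] = df["depth_m"].astype(int)
    df = df.set_index("sample")
    return SampleMetadata(df, tuple(depth_strata))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Run configuration

def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration (paths, groupings, thresholds, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg
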