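"""Per-read normalized current-level tables.

The input to XNA calling is the tabular product of signal-to-sequence
mapping: for every read, its mapped reference sequence and one
median-normalized current level per reference base, alongside two QC
fields — the basecall q-score and the signal match score (lower = better
signal fit). Raw-signal segmentation and normalization happen upstream in
external resquiggle software; this module only reads, writes, filters and
aggregates the resulting tables.

CSV dialect: header-required UTF-8 with columns ``read_id``,
``reference_name``, ``reference_seq``, ``levels`` (semicolon-joined
floats, one per reference base), ``q_score``, ``match_score``. Lines
starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LevelFormatError",
    "ReadLevelRecord",
    "LevelTable",
    "read_level_table",
    "write_level_table",
    "filter_reads",
    "aggregate_per_sequence",
    "median_mad_normalize",
]

REQUIRED_COLUMNS = ("read_id", "reference_name", "reference_seq", "levels", "q_score", "match_score")

#: Read-filter defaults: q-score < 9 and signal match score > 3 removed.
DEFAULT_MIN_Q = 9.0
DEFAULT_MAX_MATCH_SCORE = 3.0


class LevelFormatError(ValueError):
    """A level table file violates the format contract."""


@dataclass(frozen=True)
class ReadLevelRecord:
    """One read: mapped reference sequence plus one level per base."""

    read_id: str
    reference_name: str
    reference_seq: str
    levels: np.ndarray
    q_score: float
    match_score: float

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if levels.shape != (len(self.reference_seq),):
            raise LevelFormatError(
                f"read {self.read_id!r}: {levels.size} levels for "
                f"{len(self.reference_seq)}-base reference"
            )
        if not np.all(np.isfinite(levels)):
            raise LevelFormatError(f"read {self.read_id!r}: non-finite level")


class LevelTable:
    """Collection of read-level records, indexed by reference name.

    Storage is columnar (a DataFrame of scalar fields plus one float array
    of levels per read) so that simulation-scale tables stay cheap;
    :class:`ReadLevelRecord` views are materialized on iteration.
    """

    def __init__(self, df: pd.DataFrame, levels: "np.ndarray | list[np.ndarray]"):
        if len(df) != len(levels):
            raise LevelFormatError("scalar fields and levels disagree in length")
        if df["read_id"].duplicated().any():
            dup = df["read_id"][df["read_id"].duplicated()].iloc[0]
            raise LevelFormatError(f"duplicate read_id {dup!r}")
        self._df = df.reset_index(drop=True)
        self._levels = levels

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ReadLevelRecord]) -> "LevelTable":
        records = list(records)
        df = pd.DataFrame(
            {
                "read_id": [r.read_id for r in records],
                "reference_name": [r.reference_name for r in records],
                "reference_seq": [r.reference_seq for r in records],
                "q_score": [r.q_score for r in records],
                "match_score": [r.match_score for r in records],
            }
        )
        return cls(df, [r.levels for r in records])

    @classmethod
    def empty(cls) -> "LevelTable":
        df = pd.DataFrame({c: [] for c in REQUIRED_COLUMNS if c != "levels"})
        return cls(df, [])

    # -- access ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def frame(self) -> pd.DataFrame:
        """Scalar fields as a DataFrame (no levels)."""
        return self._df

    def levels_at(self, i: int) -> np.ndarray:
        return np.asarray(self._levels[i], dtype=float)

    def levels_matrix(self) -> np.ndarray:
        """All levels as an (n_reads, seq_len) matrix; requires uniform length."""
        if isinstance(self._levels, np.ndarray) and self._levels.ndim == 2:
            return self._levels
        return np.vstack([np.asarray(v, dtype=float) for v in self._levels])

    def record(self, i: int) -> ReadLevelRecord:
        row = self._df.iloc[i]
        return ReadLevelRecord(
            read_id=str(row.read_id),
            reference_name=str(row.reference_name),
            reference_seq=str(row.reference_seq),
            levels=self.levels_at(i),
            q_score=float(row.q_score),
            match_score=float(row.match_score),
        )

    def __iter__(self) -> Iterator[ReadLevelRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def reference_names(self) -> list[str]:
        return sorted(self._df["reference_name"].unique())

    def by_reference(self, name: str) -> "LevelTable":
        mask = (self._df["reference_name"] == name).to_numpy()
        return self._subset(np.flatnonzero(mask))

    def _subset(self, idx: np.ndarray) -> "LevelTable":
        if isinstance(self._levels, np.ndarray) and self._levels.ndim == 2:
            levels = self._levels[idx]
        else:
            levels = [self._levels[i] for i in idx]
        return LevelTable(self._df.iloc[idx], levels)


def _parse_levels(text: str) -> np.ndarray:
    return np.array([float(x) for x in str(text).split(";")], dtype=float)


def read_level_table(path: str | Path) -> LevelTable:
    """Read a level CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # count leading comment lines so error messages carry file line numbers
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype={"read_id": str, "reference_name": str, "reference_seq": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LevelFormatError(f"{path}: missing required column(s) {missing}")
    levels = []
    bad: list[str] = []
    for i, row in df.iterrows():
        lineno = n_comment + 2 + i  # header occupies one line
        try:
            lv = _parse_levels(row["levels"])
        except ValueError:
            bad.append(f"line {lineno}: unparseable levels field")
            levels.append(np.array([]))
            continue
        if lv.size != len(str(row["reference_seq"])):
            bad.append(
                f"line {lineno}: {lv.size} levels for "
                f"{len(str(row['reference_seq']))}-base reference"
            )
        elif not np.all(np.isfinite(lv)):
            bad.append(f"line {lineno}: non-finite level")
        levels.append(lv)
    if bad:
        raise LevelFormatError(f"{path}: " + "; ".join(bad))
    return LevelTable(df[list(c for c in df.columns if c != "levels")], levels)


def write_level_table(table: LevelTable, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a level CSV (lossless round-trip of all fields)."""
    df = table.frame.copy()
    df["levels"] = [";".join(repr(float(x)) for x in table.levels_at(i)) for i in range(len(table))]
    df = df[list(REQUIRED_COLUMNS)]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def filter_reads(
    table: LevelTable,
    min_q: float = DEFAULT_MIN_Q,
    max_match_score: float = DEFAULT_MAX_MATCH_SCORE,
) -> LevelTable:
    """Drop reads with q-score below ``min_q`` or match score above
    ``max_match_score``; boundary values are retained. Order-preserving
    and idempotent."""
    df = table.frame
    keep = (df["q_score"].to_numpy() >= min_q) & (df["match_score"].to_numpy() <= max_match_score)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_reads removed %d of %d reads", removed, len(table))
    return table._subset(np.flatnonzero(keep))


def aggregate_per_sequence(table: LevelTable) -> LevelTable:
    """Average levels position-wise across all reads mapping to the same
    reference, yielding one record per reference name.

    The aggregated record's q_score/match_score are the means of the
    contributing reads'; read_id becomes ``<reference>|n=<count>``.
    """
    records = []
    for name in table.reference_names():
        sub = table.by_reference(name)
        seqs = set(sub.frame["reference_seq"])
        if len(seqs) != 1:
            raise LevelFormatError(f"reference {name!r}: inconsistent reference sequences")
        (seq,) = seqs
        mat = sub.levels_matrix()
        records.append(
            ReadLevelRecord(
                read_id=f"{name}|n={len(sub)}",
                reference_name=name,
                reference_seq=seq,
                levels=mat.mean(axis=0),
                q_score=float(sub.frame["q_score"].mean()),
                match_score=float(sub.frame["match_score"].mean()),
            )
        )
    return LevelTable.from_records(records)


def median_mad_normalize(signal: np.ndarray) -> np.ndarray:
    """Per-read median/MAD normalization (simulator-path helper only).

    Real data arrives already normalized by the upstream resquiggle step.
    """
    signal = np.asarray(signal, dtype=float)
    med = np.median(signal)
    mad = np.median(np.abs(signal - med))
    if mad == 0:
        return signal - med
    return (signal - med) / mad
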