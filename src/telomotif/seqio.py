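"""Read streaming and tandem-repeat tables.

Reads come from FASTA or FASTQ, optionally gzip-compressed; the format is
sniffed from content, quality strings are ignored.  Repeat annotations are
exchanged in the TideHunter tabular dialect: tab-separated, one repeat per
row, with 1-based inclusive coordinates on disk.  Internally everything is
0-based half-open; conversion happens at the file boundary.
"""

from __future__ import annotations

import csv
import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .errors import SequenceParseError, TableFormatError

__all__ = [
    "Read",
    "RepeatInterval",
    "TableDialect",
    "FilterStats",
    "read_sequences",
    "parse_repeat_table",
    "write_repeat_table",
    "subsample_reads",
]

logger = logging.getLogger(__name__)

_SEQ_TRANS = str.maketrans("acgtunU", "ACGTTNT")


@dataclass
class Read:
    """One sequencing read: identifier plus uppercase DNA over {A,C,G,T,N}."""

    read_id: str
    sequence: str
    length: int = -1

    def __post_init__(self) -> None:
        if self.length < 0:
            self.length = len(self.sequence)
        if not self.read_id:
            raise ValueError("read_id must be nonempty")
        if self.length != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class RepeatInterval:
    """A tandem-repeat annotation on one read.

    Coordinates are 0-based half-open.  ``motif`` is the consensus in the
    rotation and strand the detector happened to report.  ``covered`` lists
    the sub-spans actually occupied by repeat copies when gap-merging has
    fused nearby intervals; ``None`` means the whole span is covered.
    ``extra`` preserves dialect columns we do not interpret, for round-trip.
    """

    read_id: str
    start: int
    end: int
    period: int
    motif: str
    copy_number: float
    read_length: int
    covered: Optional[tuple[tuple[int, int], ...]] = None
    extra: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= self.read_length):
            raise ValueError(
                f"{self.read_id}: invalid interval "
                f"[{self.start},{self.end}) on read of {self.read_length} bp"
            )
        if self.period < 1:
            raise ValueError(f"{self.read_id}: period must be >= 1")
        if len(self.motif) != self.period:
            raise ValueError(
                f"{self.read_id}: motif length {len(self.motif)} != "
                f"period {self.period}"
            )
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"{self.read_id}: motif must be over ACGT")
        if self.copy_number < 1:
            raise ValueError(f"{self.read_id}: copy_number must be >= 1")

    def covered_spans(self) -> tuple[tuple[int, int], ...]:
        return self.covered if self.covered is not None else ((self.start, self.end),)

    def covered_bases(self) -> int:
        return sum(e - s for s, e in self.covered_spans())


@dataclass(frozen=True)
class TableDialect:
    """Column layout of the on-disk repeat table (TideHunter dialect).

    The default order matches TideHunter's tabular output; ``columns`` can
    be overridden when a producer emits a different column order.  Only the
    named fields below are interpreted; other columns ride along in
    ``RepeatInterval.extra``.
    """

    columns: tuple[str, ...] = (
        "read_name",
        "repeat_ordinal",
        "copy_number",
        "read_length",
        "start",
        "end",
        "consensus_length",
        "average_match_percent",
        "full_length_flag",
        "subpositions",
        "consensus_sequence",
    )

    _USED = frozenset(
        {"read_name", "copy_number", "read_length", "start", "end", "consensus_sequence"}
    )

    def index(self, name: str) -> int:
        return self.columns.index(name)


DEFAULT_DIALECT = TableDialect()


@dataclass
class FilterStats:
    """Counters filled in by :func:`read_sequences`."""

    n_yielded: int = 0
    n_skipped_short: int = 0

    @property
    def n_records(self) -> int:
        return self.n_yielded + self.n_skipped_short


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> str:
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            return "fasta"  # empty file: parse as FASTA, yields nothing
        if line.strip():
            handle.seek(pos)
            if line[0] == ">":
                return "fasta"
            if line[0] == "@":
                return "fastq"
            raise SequenceParseError(
                f"unrecognized sequence format (first record starts with "
                f"{line[0]!r}, expected '>' or '@')"
            )


def read_sequences(
    path: str | Path,
    min_length: int = 0,
    stats: Optional[FilterStats] = None,
) -> Iterator[Read]:
    """Stream reads of at least ``min_length`` bp from FASTA/FASTQ(.gz).

    Sequences are uppercased and U is mapped to T.  Records shorter than
    ``min_length`` are counted (``stats``/log) but not yielded.  Quality
    strings are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read sequence file: {path}")
    if stats is None:
        stats = FilterStats()
    handle = _open_maybe_gzip(path)
    try:
        fmt = _sniff_format(handle)
        ordinal = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                ordinal += 1
                seq = str(record.seq).translate(_SEQ_TRANS)
                if len(seq) >= min_length:
                    stats.n_yielded += 1
                    yield Read(read_id=record.id, sequence=seq)
                else:
                    stats.n_skipped_short += 1
        except ValueError as exc:
            raise SequenceParseError(
                f"{path}: malformed record #{ordinal + 1}: {exc}"
            ) from exc
    finally:
        handle.close()
    logger.info(
        "%s: %d records, %d yielded (>= %d bp), %d skipped",
        path, stats.n_records, stats.n_yielded, min_length, stats.n_skipped_short,
    )


def parse_repeat_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    strict: bool = True,
) -> list[RepeatInterval]:
    """Parse a tab-separated repeat table into 0-based half-open intervals.

    On-disk start/end are 1-based inclusive.  In strict mode (default) any
    malformed row aborts with a :class:`TableFormatError` listing the row
    numbers; in lenient mode bad rows are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read repeat table: {path}")
    ncol = len(dialect.columns)
    intervals: list[RepeatInterval] = []
    bad_rows: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for row_num, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != ncol:
                bad_rows.append((row_num, f"expected {ncol} columns, got {len(row)}"))
                continue
            rec = dict(zip(dialect.columns, row))
            try:
                start = int(rec["start"]) - 1  # to 0-based half-open
                end = int(rec["end"])
                motif = rec["consensus_sequence"].upper()
                extra = {
                    k: v for k, v in rec.items() if k not in TableDialect._USED
                }
                intervals.append(
                    RepeatInterval(
                        read_id=rec["read_name"],
                        start=start,
                        end=end,
                        period=len(motif),
                        motif=motif,
                        copy_number=float(rec["copy_number"]),
                        read_length=int(rec["read_length"]),
                        extra=extra or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                bad_rows.append((row_num, str(exc)))
    if bad_rows:
        msg = "; ".join(f"row {n}: {why}" for n, why in bad_rows[:20])
        if strict:
            raise TableFormatError(f"{path}: {len(bad_rows)} bad row(s): {msg}")
        warnings.warn(f"{path}: skipped {len(bad_rows)} bad row(s): {msg}")
    return intervals


def write_repeat_table(
    intervals: Sequence[RepeatInterval],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write intervals in the tabular dialect; inverse of parse_repeat_table."""
    path = Path(path)
    per_read_ordinal: dict[str, int] = {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in intervals:
            per_read_ordinal[iv.read_id] = per_read_ordinal.get(iv.read_id, 0) + 1
            extra = iv.extra or {}
            row = []
            for col in dialect.columns:
                if col == "read_name":
                    row.append(iv.read_id)
                elif col == "copy_number":
                    row.append(repr(iv.copy_number))
                elif col == "read_length":
                    row.append(str(iv.read_length))
                elif col == "start":
                    row.append(str(iv.start + 1))  # back to 1-based inclusive
                elif col == "end":
                    row.append(str(iv.end))
                elif col == "consensus_sequence":
                    row.append(iv.motif)
                elif col in extra:
                    row.append(extra[col])
                elif col == "repeat_ordinal":
                    row.append(str(per_read_ordinal[iv.read_id]))
                elif col == "consensus_length":
                    row.append(str(iv.period))
                elif col == "average_match_percent":
                    row.append("100.00")
                elif col == "full_length_flag":
                    row.append("0")
                else:
                    row.append(".")
            writer.writerow(row)


def subsample_reads(
    reads: Iterable[Read],
    fraction: float,
    seed: int,
) -> Iterator[Read]:
    """Keep each read independently with probability ``fraction``.

    Deterministic for a fixed seed and input order (one uniform draw per
    read, in order), emulating coverage down-sampling of a library.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    for read in reads:
        if rng.random() < fraction:
            yield read
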