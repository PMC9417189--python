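"""Reference sequence access, interval arithmetic and sequence-context predicates.

Coordinate conventions: variant positions and homopolymer runs are 1-based
inclusive (VCF style); intervals are 0-based half-open (BED style).  All
conversions between the two happen inside this module.
"""
from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError

_NON_ACGTN = re.compile(r"[^ACGTN]")

__all__ = [
    "ReferenceSet",
    "GenomicInterval",
    "IntervalSet",
    "HomopolymerRun",
    "read_fasta",
    "write_fasta",
    "scan_homopolymers",
    "is_homopolymer_proximal",
    "in_interval_set",
    "read_bed",
]


@dataclass
class ReferenceSet:
    """An in-memory reference genome: ordered contig-name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise InputError("empty contig name")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        try:
            return len(self.contigs[contig])
        except KeyError:
            raise InputError(f"unknown contig {contig!r}") from None

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs.items()}

    def base_at(self, contig: str, pos1: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.contigs.get(contig)
        if seq is None:
            raise InputError(f"unknown contig {contig!r}")
        if not 1 <= pos1 <= len(seq):
            raise InputError(f"position {contig}:{pos1} outside contig bounds")
        return seq[pos1 - 1]

    def slice(self, contig: str, pos1: int, end1: int) -> str:
        """Sequence of the 1-based inclusive range [pos1, end1]."""
        seq = self.contigs.get(contig)
        if seq is None:
            raise InputError(f"unknown contig {contig!r}")
        return seq[pos1 - 1 : end1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InputError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Sorted, merged collection of genomic intervals with O(log n) membership.

    Overlapping or abutting input intervals are merged at construction, so the
    stored representation is canonical.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_contig: dict[str, list[list[int]]] = {}
        for iv in sorted(intervals):
            rows = by_contig.setdefault(iv.contig, [])
            if rows and iv.start <= rows[-1][1]:  # overlap or abut: merge
                rows[-1][1] = max(rows[-1][1], iv.end)
            else:
                rows.append([iv.start, iv.end])
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for contig, rows in by_contig.items():
            self._starts[contig] = [r[0] for r in rows]
            self._ends[contig] = [r[1] for r in rows]

    def __iter__(self) -> Iterator[GenomicInterval]:
        for contig in self._starts:
            for s, e in zip(self._starts[contig], self._ends[contig]):
                yield GenomicInterval(contig, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains(self, contig: str, pos1: int) -> bool:
        """True iff the 1-based position falls inside any interval."""
        starts = self._starts.get(contig)
        if not starts:
            return False
        pos0 = pos1 - 1
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[contig][i]

    def total_length(self, contig: str | None = None) -> int:
        contigs = [contig] if contig is not None else list(self._starts)
        return sum(
            e - s
            for c in contigs
            for s, e in zip(self._starts.get(c, []), self._ends.get(c, []))
        )

    def complement(self, contig_lengths: dict[str, int]) -> "IntervalSet":
        """Intervals covering everything the set does not, per contig."""
        out: list[GenomicInterval] = []
        for contig, length in contig_lengths.items():
            cursor = 0
            for s, e in zip(self._starts.get(contig, []), self._ends.get(contig, [])):
                if s > cursor:
                    out.append(GenomicInterval(contig, cursor, s))
                cursor = max(cursor, e)
            if cursor < length:
                out.append(GenomicInterval(contig, cursor, length))
        return IntervalSet(out)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


@dataclass(frozen=True)
class HomopolymerRun:
    """Maximal run of >= min_run identical bases, 1-based inclusive coordinates."""

    contig: str
    start1: int
    end1: int
    base: str

    @property
    def length(self) -> int:
        return self.end1 - self.start1 + 1


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a FASTA file into a :class:`ReferenceSet`.

    Sequences are uppercased (soft-masking is discarded); characters outside
    A/C/G/T/N become N.  Duplicate contig names are an input error.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            return ReferenceSet({})
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise InputError(f"{path}: duplicate contig name {record.id!r}")
        contigs[record.id] = _NON_ACGTN.sub("N", str(record.seq).upper())
    return ReferenceSet(contigs)


def write_fasta(ref: ReferenceSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def scan_homopolymers(ref: ReferenceSet, min_run: int = 4) -> list[HomopolymerRun]:
    """All maximal homopolymer runs of length >= ``min_run``, sorted by start.

    Runs of N never count: N is uncertainty, not sequence.
    """
    if min_run < 2:
        raise InputError(f"min_run must be >= 2, got {min_run}")
    pattern = re.compile(
        "|".join(f"{b}{{{min_run},}}" for b in "ACGT")
    )
    runs: list[HomopolymerRun] = []
    for contig, seq in ref.contigs.items():
        for m in pattern.finditer(seq):
            runs.append(
                HomopolymerRun(contig, m.start() + 1, m.end(), m.group()[0])
            )
    return runs


def is_homopolymer_proximal(
    contig: str,
    pos1: int,
    runs: list[HomopolymerRun],
    distance: int = 1,
    ref: ReferenceSet | None = None,
) -> bool:
    """True iff ``pos1`` lies within a run or within ``distance`` nt of one."""
    if ref is not None and contig not in ref:
        raise InputError(f"unknown contig {contig!r}")
    for run in runs:
        if run.contig == contig and run.start1 - distance <= pos1 <= run.end1 + distance:
            return True
    return False


def in_interval_set(contig: str, pos1: int, intervals: IntervalSet) -> bool:
    """True iff the 1-based position falls inside any interval of the set."""
    return intervals.contains(contig, pos1)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a merged IntervalSet."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["contig", "start", "end"],
            dtype={"contig": str},
        )
    except pd.errors.EmptyDataError:
        return IntervalSet()
    except ValueError as exc:
        raise FormatError(f"{path}: not a BED3+ file: {exc}") from exc
    intervals = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
        if start >= end:
            raise FormatError(
                f"{path}: line {i}: start {start} >= end {end}"
            )
        intervals.append(GenomicInterval(str(row.contig), start, end))
    return IntervalSet(intervals)
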