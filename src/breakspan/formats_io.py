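"""Genomic file formats used by the pipeline.

All coordinates are 0-based half-open throughout the package; 1-based
conventions are never used internally. Supported formats: FASTA (reference
sequences), BED3/BED6 (read and site intervals), bedGraph (binned signal)
and, as an input adapter only, BAM.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np

VALID_BASES = frozenset("ACGTN")
VALID_STRANDS = frozenset({"+", "-", "."})


class ParseError(ValueError):
    """A malformed input file, with file/line context in the message."""


@dataclass(frozen=True)
class ReadInterval:
    """One aligned read as a contig plus 0-based half-open interval."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceSequence:
    """Ordered named contigs over the alphabet {A, C, G, T, N}."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        if len(self.contigs) == 0:
            raise ValueError("reference must contain at least one contig")
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)


@dataclass
class SignalTrack:
    """Binned non-negative signal over contigs.

    ``values[contig]`` holds one float per ``bin_size``-bp bin starting at
    position 0; ``contig_lengths`` records the true (possibly non-multiple)
    contig lengths so bedGraph output does not overrun contig ends.
    """

    bin_size: int
    values: Dict[str, np.ndarray]
    contig_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for contig, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"values for {contig!r} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative signal values on contig {contig!r}")
            self.values[contig] = arr
        for contig in self.values:
            self.contig_lengths.setdefault(
                contig, len(self.values[contig]) * self.bin_size
            )

    @property
    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def base_values(self, contig: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); bases beyond the stored bins are 0."""
        if contig not in self.values:
            raise KeyError(f"unknown contig {contig!r}")
        if not (0 <= start <= end):
            raise ValueError("require 0 <= start <= end")
        bins = self.values[contig]
        out = np.zeros(end - start, dtype=float)
        avail_end = min(end, len(bins) * self.bin_size)
        if avail_end > start:
            idx = np.arange(start, avail_end) // self.bin_size
            out[: avail_end - start] = bins[idx]
        return out

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            dict(self.contig_lengths),
        )


def read_fasta(path: str | os.PathLike) -> ReferenceSequence:
    """Read a FASTA file into a :class:`ReferenceSequence`.

    Sequences are uppercased; any character outside {A, C, G, T, N} raises a
    :class:`ParseError` naming the offending line.
    """
    from Bio import SeqIO

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contigs: Dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {record.id!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            line_no = _find_offending_line(path, bad)
            raise ParseError(
                f"{path}:{line_no}: illegal character(s) {sorted(bad)} "
                f"in record {record.id!r}"
            )
        if record.id in contigs:
            raise ParseError(f"{path}: duplicate contig name {record.id!r}")
        contigs[record.id] = seq
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return ReferenceSequence(contigs)


def _find_offending_line(path: str, bad_chars: set) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return i
    return 0


def write_fasta(ref: ReferenceSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(
    path: str | os.PathLike, dialect: str = "bed"
) -> Iterator[ReadInterval]:
    """Stream aligned-read intervals from a BED (default) or BAM file.

    BED is taken as 0-based half-open verbatim. BAM alignments are converted
    to their reference-space span (including deletions, excluding soft
    clips); unmapped records are skipped.
    """
    if dialect == "bed":
        yield from _read_bed(path)
    elif dialect == "bam":
        yield from _read_bam(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'bed' or 'bam'")


def _read_bed(path: str | os.PathLike) -> Iterator[ReadInterval]:
    path = os.fspath(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{line_no}: BED line has fewer than 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{line_no}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            yield ReadInterval(fields[0], start, end, name, strand)


def _read_bam(path: str | os.PathLike) -> Iterator[ReadInterval]:
    import pysam  # input adapter only; the pipeline is fully operable on BED

    with pysam.AlignmentFile(os.fspath(path), "rb", check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            yield ReadInterval(
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                aln.query_name,
                strand,
            )


def write_intervals_bed(
    intervals: Iterable[ReadInterval], path: str | os.PathLike
) -> None:
    """Write intervals as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued bins."""
    with open(path, "w") as fh:
        for contig, arr in track.values.items():
            clen = track.contig_lengths.get(contig, len(arr) * track.bin_size)
            if len(arr) == 0:
                continue
            run_start = 0
            run_val = arr[0]
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != run_val:
                    start_bp = run_start * track.bin_size
                    end_bp = min(i * track.bin_size, clen)
                    if end_bp > start_bp:
                        fh.write(f"{contig}\t{start_bp}\t{end_bp}\t{float(run_val)!r}\n")
                    if i < len(arr):
                        run_start, run_val = i, arr[i]


def read_bedgraph(
    path: str | os.PathLike, bin_size: Optional[int] = None
) -> SignalTrack:
    """Read a bedGraph into a binned :class:`SignalTrack`.

    Records on a contig must not overlap; gaps become zero bins. When
    ``bin_size`` is omitted it is inferred as the GCD of all record
    boundaries (falling back to 1).
    """
    path = os.fspath(path)
    records: Dict[str, List[tuple]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{line_no}: bedGraph needs 4 columns")
            contig = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: malformed record") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{line_no}: invalid interval [{start}, {end})")
            if value < 0:
                raise ParseError(f"{path}:{line_no}: negative signal value")
            records.setdefault(contig, []).append((start, end, value, line_no))

    if not records:
        raise ParseError(f"{path}: no bedGraph records found")

    for contig, recs in records.items():
        recs.sort(key=lambda r: r[0])
        for (s1, e1, _, _), (s2, e2, _, ln) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}:{ln}: overlapping records on contig {contig!r}"
                )

    if bin_size is None:
        g = 0
        for recs in records.values():
            for start, end, _, _ in recs:
                g = math.gcd(g, start)
                g = math.gcd(g, end)
        bin_size = max(g, 1)

    values: Dict[str, np.ndarray] = {}
    lengths: Dict[str, int] = {}
    for contig, recs in records.items():
        clen = recs[-1][1]
        n_bins = -(-clen // bin_size)
        arr = np.zeros(n_bins, dtype=float)
        for start, end, value, ln in recs:
            if start % bin_size != 0 or (end % bin_size != 0 and end != clen):
                raise ParseError(
                    f"{path}:{ln}: record [{start}, {end}) not aligned to "
                    f"bin size {bin_size}"
                )
            arr[start // bin_size : -(-end // bin_size)] = value
        values[contig] = arr
        lengths[contig] = clen
    return SignalTrack(bin_size, values, lengths)
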