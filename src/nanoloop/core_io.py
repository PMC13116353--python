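"""Domain types and readers/writers for the standard genomic formats.

Every coordinate in the package is 0-based half-open (BED convention);
conversion, if any, happens only at file boundaries. Loop distance is the
midpoint-to-midpoint separation of the two anchors in bp, which is invariant
to anchor width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("nanoloop")

VALID_ALPHABET = frozenset("ACGTN")

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
_LABELS = frozenset({POSITIVE, NEGATIVE, UNKNOWN})


class FormatError(ValueError):
    """A malformed input file (names the offending line where possible)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class LoopPair:
    """Two same-chromosome anchors, the unit of loop prediction.

    Anchors are stored left-before-right; ``distance`` is the (positive)
    midpoint separation in bp.
    """

    left: GenomicInterval
    right: GenomicInterval
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.left.start >= self.right.start:
            raise ValueError("left anchor must precede right anchor")
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.distance <= 0:
            raise ValueError("anchor midpoints must be separated")

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def distance(self) -> int:
        return self.right.midpoint - self.left.midpoint


def make_loop(
    a: GenomicInterval, b: GenomicInterval, label: str = UNKNOWN
) -> LoopPair:
    """Build a LoopPair, normalizing anchor order so left precedes right."""
    if b.start < a.start or (b.start == a.start and b.end < a.end):
        a, b = b, a
    return LoopPair(a, b, label)


@dataclass(frozen=True, order=True)
class MethylationRecord:
    """One CpG cytosine with its called methylation probability."""

    chrom: str
    position: int
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"methylation probability out of [0,1]: {self.probability}"
            )
        if self.position < 0:
            raise ValueError("position must be >= 0")


class MethylationIndex:
    """Per-chromosome sorted position/probability arrays for fast range queries."""

    def __init__(self, records: Iterable[MethylationRecord]):
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(
                (rec.position, rec.probability)
            )
        self._positions: dict[str, np.ndarray] = {}
        self._probs: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate CpG positions on {chrom}")
            self._positions[chrom] = pos
            self._probs[chrom] = np.array([q for _, q in pairs], dtype=float)

    def chroms(self) -> list[str]:
        return sorted(self._positions)

    def probabilities(self, chrom: str) -> np.ndarray:
        return self._probs.get(chrom, np.array([], dtype=float))

    def query(self, iv: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """Positions and probabilities of CpGs falling inside ``iv``."""
        pos = self._positions.get(iv.chrom)
        if pos is None:
            empty = np.array([], dtype=np.int64)
            return empty, np.array([], dtype=float)
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        return pos[lo:hi], self._probs[iv.chrom][lo:hi]


@dataclass
class SignalTrack:
    """Non-overlapping valued intervals per chromosome (e.g. a histone mark)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (n,2) int
    values: dict[str, np.ndarray] = field(default_factory=dict)  # (n,) float


ChromSizes = Mapping[str, int]


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"empty FASTA record {name!r}")
    cleaned = []
    for ch in seq:
        if ch in "ACGT":
            cleaned.append(ch)
        elif ch.isalpha():  # other IUPAC ambiguity codes
            cleaned.append("N")
        else:
            raise FormatError(f"non-nucleotide character {ch!r} in {name!r}")
    return "".join(cleaned)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {chrom: uppercase ACGTN sequence}."""
    path = Path(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED / BEDPE


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path: str | Path, label: str = UNKNOWN) -> list[LoopPair]:
    """Parse a 6+ column BEDPE into normalized intra-chromosomal LoopPairs.

    Inter-chromosomal rows are skipped; the skip count is logged.
    """
    loops = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected >=6 BEDPE columns")
            try:
                a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if a.chrom != b.chrom:
                skipped += 1
                continue
            loops.append(make_loop(a, b, label))
    if skipped:
        log.info("read_bedpe(%s): skipped %d inter-chromosomal rows", path, skipped)
    return loops


def write_bedpe(loops: Iterable[LoopPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.left.chrom}\t{lp.left.start}\t{lp.left.end}\t"
                f"{lp.right.chrom}\t{lp.right.start}\t{lp.right.end}\n"
            )


def write_predictions_tsv(
    loops: Iterable[LoopPair], probabilities: Iterable[float], path: str | Path
) -> None:
    """BEDPE columns plus a final loop-probability column."""
    with open(path, "w") as fh:
        for lp, p in zip(loops, probabilities, strict=True):
            fh.write(
                f"{lp.left.chrom}\t{lp.left.start}\t{lp.left.end}\t"
                f"{lp.right.chrom}\t{lp.right.start}\t{lp.right.end}\t"
                f"{p:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Methylation TSV (chrom, position, probability; extra columns ignored)


def read_methylation_tsv(path: str | Path) -> list[MethylationRecord]:
    records = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 columns")
            try:
                chrom, pos, prob = parts[0], int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            key = (chrom, pos)
            if key in seen:
                raise FormatError(f"{path}:{ln}: duplicate CpG {chrom}:{pos}")
            seen.add(key)
            try:
                records.append(MethylationRecord(chrom, pos, prob))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    records.sort()
    return records


def write_methylation_tsv(
    records: Iterable[MethylationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.position}\t{rec.probability:.4f}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    float(parts[3]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            if not np.isfinite(value):
                raise FormatError(f"{path}:{ln}: non-finite value")
            by_chrom.setdefault(chrom, []).append((start, end, value))
    track = SignalTrack()
    for chrom, rows in by_chrom.items():
        rows.sort()
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise FormatError(
                    f"{path}: overlapping bedGraph intervals on {chrom} "
                    f"([{s1},{e1}) and starting {s2})"
                )
        arr = np.array([(s, e) for s, e, _ in rows], dtype=np.int64)
        track.intervals[chrom] = arr
        track.values[chrom] = np.array([v for _, _, v in rows], dtype=float)
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for (s, e), v in zip(track.intervals[chrom], track.values[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns")
            length = int(parts[1])
            if length <= 0:
                raise FormatError(f"{path}:{ln}: chromosome length must be > 0")
            sizes[parts[0]] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
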