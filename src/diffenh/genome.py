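"""Genomic intervals, gene models and binned coverage tracks.

Coordinates are 0-based half-open throughout ([start, end), BED
convention).  Coverage is held as one dense numpy vector of bin values
per chromosome; tracks are either raw read counts or RPKM
(reads per kilobase per million mapped reads).  On disk the canonical
formats are BED (intervals), a small TSV (gene annotation) and
bedGraph (tracks); all three round-trip losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED / annotation / bedGraph input."""


class NormalizationError(ValueError):
    """Raised when a track cannot be (de)normalized."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
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

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand, self.name
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS/TTS.

    On the + strand the transcription start site (TSS) is ``start`` and
    the termination site (TTS) is ``end - 1``; on the − strand the two
    are swapped.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "+" else self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class CoverageTrack:
    """Binned signal over a genome.

    ``data`` maps chromosome name to a vector of per-bin values; bin i
    covers [i*bin_size, (i+1)*bin_size).  ``total_mapped`` is the
    library size used for RPKM scaling; it need not equal the sum of
    the stored bins (a track may cover a subset of the genome).
    """

    bin_size: int
    data: dict[str, np.ndarray]
    total_mapped: float
    units: str = "raw"  # "raw" | "RPKM"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.units not in ("raw", "RPKM"):
            raise ValueError(f"unknown units {self.units!r}")
        for chrom, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative bin values on {chrom}")
            self.data[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            self.total_mapped,
            self.units,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as on disk)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a gene-annotation TSV with columns gene_id, chrom, start, end, strand."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "chrom", "start", "end", "strand"]
        if header[:5] != expected:
            raise BedParseError(f"{path}: header must start with {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                iv = GenomicInterval(
                    fields[1], int(fields[2]), int(fields[3]), fields[4], fields[0]
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(fields[0], iv))
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, runs of equal value collapsed.

    A comment header preserves bin_size / total_mapped / units so that
    ``read_bedgraph`` restores the track exactly.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# bin_size={track.bin_size} total_mapped={float(track.total_mapped)!r} "
            f"units={track.units}\n"
        )
        for chrom in track.chroms:
            values = track.data[chrom]
            n = len(values)
            i = 0
            while i < n:
                j = i
                while j + 1 < n and values[j + 1] == values[i]:
                    j += 1
                fh.write(
                    f"{chrom}\t{i * track.bin_size}\t{(j + 1) * track.bin_size}"
                    f"\t{float(values[i])!r}\n"
                )
                i = j + 1


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph written by :func:`write_bedgraph`."""
    bin_size: int | None = None
    total_mapped = 0.0
    units = "raw"
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        if key == "bin_size":
                            bin_size = int(val)
                        elif key == "total_mapped":
                            total_mapped = float(val)
                        elif key == "units":
                            units = val
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    if bin_size is None:
        raise BedParseError(f"{path}: missing '# bin_size=' header")
    data: dict[str, np.ndarray] = {}
    for chrom, segments in per_chrom.items():
        length = max(end for _, end, _ in segments)
        if length % bin_size:
            raise BedParseError(f"{path}: {chrom} extent not a multiple of bin_size")
        arr = np.zeros(length // bin_size)
        for start, end, value in segments:
            if start % bin_size or end % bin_size:
                raise BedParseError(
                    f"{path}: segment {chrom}:{start}-{end} off the bin grid"
                )
            arr[start // bin_size : end // bin_size] = value
        data[chrom] = arr
    if total_mapped == 0.0:
        total_mapped = float(sum(arr.sum() for arr in data.values()))
    return CoverageTrack(bin_size, data, total_mapped, units)


# ---------------------------------------------------------------------------
# coverage operations
# ---------------------------------------------------------------------------

def bin_coverage(
    reads: Iterable[tuple[str, int]] | Iterable[GenomicInterval],
    bin_size: int,
    chrom_lengths: dict[str, int],
) -> CoverageTrack:
    """Bin reads into a raw-count track; each read counts once, at its 5' end.

    ``reads`` is either (chrom, position) pairs or intervals (an
    interval's 5' end is its start on +/., its end-1 on −).  Reads
    beyond chromosome bounds are clipped into the terminal bin with a
    warning; reads on unknown chromosomes raise.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    data = {
        chrom: np.zeros(int(np.ceil(length / bin_size)))
        for chrom, length in chrom_lengths.items()
    }
    n_clipped = 0
    n_reads = 0
    for read in reads:
        if isinstance(read, GenomicInterval):
            chrom = read.chrom
            pos = read.start if read.strand != "-" else read.end - 1
        else:
            chrom, pos = read
        if chrom not in data:
            raise KeyError(f"read on unknown chromosome {chrom!r}")
        n_bins = len(data[chrom])
        idx = pos // bin_size
        if idx < 0 or idx >= n_bins:
            n_clipped += 1
            idx = min(max(idx, 0), n_bins - 1)
        data[chrom][idx] += 1
        n_reads += 1
    if n_clipped:
        warnings.warn(f"{n_clipped} reads beyond chromosome bounds were clipped")
    return CoverageTrack(bin_size, data, float(n_reads), "raw")


def rpkm_normalize(track: CoverageTrack, total_mapped: float | None = None) -> CoverageTrack:
    """Convert raw counts to RPKM: count / (bin_size/1e3) / (total_mapped/1e6)."""
    if track.units != "raw":
        raise NormalizationError("track is already normalized")
    total = track.total_mapped if total_mapped is None else total_mapped
    if total <= 0:
        raise NormalizationError("total_mapped must be positive for RPKM")
    scale = 1.0 / (track.bin_size / 1e3) / (total / 1e6)
    data = {chrom: arr * scale for chrom, arr in track.data.items()}
    return CoverageTrack(track.bin_size, data, float(total), "RPKM")


def rpkm_denormalize(track: CoverageTrack) -> CoverageTrack:
    """Invert :func:`rpkm_normalize`, recovering raw counts."""
    if track.units != "RPKM":
        raise NormalizationError("track is not RPKM-normalized")
    scale = (track.bin_size / 1e3) * (track.total_mapped / 1e6)
    data = {chrom: arr * scale for chrom, arr in track.data.items()}
    return CoverageTrack(track.bin_size, data, track.total_mapped, "raw")


def mean_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Base-weighted mean bin value over an interval.

    Bins partially covered by the interval contribute in proportion to
    the number of covered bases, so the result equals the per-base
    average of the bin-step signal.
    """
    if interval.chrom not in track.data:
        raise KeyError(f"no coverage for chromosome {interval.chrom!r}")
    values = track.data[interval.chrom]
    bs = track.bin_size
    start = max(interval.start, 0)
    end = min(interval.end, len(values) * bs)
    if end <= start:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "does not overlap the track"
        )
    first, last = start // bs, (end - 1) // bs
    if first == last:
        return float(values[first])
    # overlap-weighted average across the spanned bins
    weights = np.full(last - first + 1, float(bs))
    weights[0] = (first + 1) * bs - start
    weights[-1] = end - last * bs
    segment = values[first : last + 1]
    return float(np.dot(segment, weights) / weights.sum())


def mean_signal_many(
    track: CoverageTrack, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Vectorized :func:`mean_signal` over a sequence of intervals."""
    return np.array([mean_signal(track, iv) for iv in intervals])
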