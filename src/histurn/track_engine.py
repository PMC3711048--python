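"""Coverage tracks: read parsing, pileup, per-million scaling, log ratios.

A :class:`CoverageTrack` is a per-base, per-chromosome signal vector with an
attached library size, either in raw read counts or reads-per-million.
Comparisons between samples are expressed as elementwise
``log2((treat + c) / (control + c))`` tracks with a pseudocount ``c`` that
keeps the ratio bounded over read-free regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from .core import BoundsError, ConfigError, ParseError, ReadAlignment, UnitsError

logger = logging.getLogger(__name__)

RAW = "raw"
PER_MILLION = "per-million"

#: default pseudocount for log2 ratio tracks, in per-million units
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CoverageTrack:
    data: Dict[str, np.ndarray]
    library_size: int
    units: str = RAW

    def __post_init__(self):
        if self.units not in (RAW, PER_MILLION):
            raise UnitsError(f"unknown units {self.units!r}")
        for chrom, arr in self.data.items():
            self.data[chrom] = np.asarray(arr, dtype=float)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))


@dataclass
class RatioTrack:
    data: Dict[str, np.ndarray]
    pseudocount: float


# ---------------------------------------------------------------------------
# read parsing
# ---------------------------------------------------------------------------

def read_alignments(
    path,
    format: str,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[ReadAlignment]:
    """Parse aligned reads from BED6 or SAM into 0-based half-open intervals.

    SAM records flagged unmapped are skipped (and counted in the log);
    coordinates beyond ``chrom_sizes``, when given, raise :class:`BoundsError`.
    """
    fmt = format.upper()
    if fmt == "BED":
        reads = _read_bed(path)
    elif fmt == "SAM":
        reads = _read_sam(path)
    else:
        raise ConfigError(f"unknown read format {format!r}")
    if chrom_sizes is not None:
        for r in reads:
            if r.chrom not in chrom_sizes or r.end > chrom_sizes[r.chrom]:
                raise BoundsError(
                    f"read {r.chrom}:{r.start}-{r.end} outside declared genome"
                )
    return reads


def _read_bed(path) -> List[ReadAlignment]:
    reads: List[ReadAlignment] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected >= 3 BED columns", i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", i) from None
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", i)
            strand = parts[5] if len(parts) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ParseError(f"invalid strand {strand!r}", i)
            reads.append(ReadAlignment(parts[0], start, end, strand))
    return reads


def _read_sam(path) -> List[ReadAlignment]:
    reads: List[ReadAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped += 1
                continue
            reads.append(
                ReadAlignment(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    if skipped:
        logger.info("skipped %d unmapped SAM records", skipped)
    return reads


# ---------------------------------------------------------------------------
# pileup and track math
# ---------------------------------------------------------------------------

def pileup(
    reads: Sequence[ReadAlignment],
    chrom_sizes: Mapping[str, int],
    extend_to: Optional[int] = None,
) -> CoverageTrack:
    """Per-base coverage of reads, optionally extended to fragment length.

    Extension is applied in the read's strand direction (3' of the 5' end)
    and clipped at chromosome boundaries. ``library_size`` is the number of
    reads piled up.
    """
    diffs = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise BoundsError(f"read on unknown chromosome {r.chrom}")
        n = chrom_sizes[r.chrom]
        if r.end > n:
            raise BoundsError(f"read {r.chrom}:{r.start}-{r.end} out of bounds")
        start, end = r.start, r.end
        if extend_to is not None:
            if extend_to < r.length:
                raise ConfigError("extend_to must be >= read length")
            if r.strand == "+":
                end = min(n, start + extend_to)
            else:
                start = max(0, end - extend_to)
        diffs[r.chrom][start] += 1
        diffs[r.chrom][end] -= 1
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(data=data, library_size=len(reads), units=RAW)


def normalize_fpm(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track to reads per million mapped reads."""
    if track.units != RAW:
        raise UnitsError("track is already per-million")
    if track.library_size <= 0:
        raise ConfigError("library_size must be > 0 to normalize")
    scale = 1e6 / track.library_size
    return CoverageTrack(
        data={c: a * scale for c, a in track.data.items()},
        library_size=track.library_size,
        units=PER_MILLION,
    )


def log2_ratio(
    treat: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RatioTrack:
    """Elementwise log2((treat + c) / (control + c)) of per-million tracks."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    if treat.chrom_sizes != control.chrom_sizes:
        raise ConfigError("treat and control chromosome lengths differ")
    data = {
        c: np.log2((treat.data[c] + pseudocount)
                   / (control.data[c] + pseudocount))
        for c in treat.data
    }
    return RatioTrack(data=data, pseudocount=pseudocount)


def bin_track(
    values: np.ndarray, width: int, stat: str = "mean"
) -> Tuple[np.ndarray, np.ndarray]:
    """Bin a per-base vector into fixed-width bins (0-based half-open).

    Returns (bin_starts, binned_values); a trailing partial bin is averaged
    over its true width.
    """
    if width < 1:
        raise ConfigError("bin width must be >= 1")
    if stat not in ("mean", "sum"):
        raise ConfigError(f"unknown stat {stat!r}")
    values = np.asarray(values, dtype=float)
    n = len(values)
    starts = np.arange(0, n, width)
    sums = np.add.reduceat(values, starts) if n else np.zeros(0)
    if stat == "sum":
        return starts, sums
    widths = np.minimum(starts + width, n) - starts
    return starts, sums / widths


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal value; zeros omitted."""
    with open(path, "w") as fh:
        fh.write(f"#library_size={track.library_size}\t#units={track.units}\n")
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a bedGraph back into a dense track; overlaps are a format error."""
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    library_size = 0
    units = RAW
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split("\t"):
                    key, _, val = tok.lstrip("#").partition("=")
                    if key == "library_size":
                        library_size = int(val)
                    elif key == "units":
                        units = val
                continue
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("expected 4 bedGraph columns", i)
            chrom = parts[0]
            if chrom not in data:
                raise ParseError(f"unknown chromosome {chrom!r}", i)
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError("malformed bedGraph fields", i) from None
            if not (0 <= start < end <= len(data[chrom])):
                raise ParseError(f"interval [{start}, {end}) out of bounds", i)
            if covered[chrom][start:end].any():
                raise ParseError("overlapping bedGraph intervals", i)
            covered[chrom][start:end] = True
            data[chrom][start:end] = value
    return CoverageTrack(data=data, library_size=library_size, units=units)


def write_ratio_bedgraph(track: RatioTrack, path) -> None:
    """Write a log2-ratio track as bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        fh.write(f"#pseudocount={track.pseudocount:.10g}\n")
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")
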