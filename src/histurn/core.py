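"""Shared primitives: read alignments, exceptions, chrom.sizes I/O.

All genomic intervals in this package are 0-based half-open. Formats that
use other conventions (SAM, GFF3) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping


class HisturnError(Exception):
    """Base class for all package errors."""


class ConfigError(HisturnError):
    """Invalid configuration or precondition violation."""


class SizingError(ConfigError):
    """Requested genome layout cannot fit on the available sequence."""


class UnsampleableTargetError(HisturnError):
    """ChIP target has zero density and no background to sample from."""


class ParseError(HisturnError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class BoundsError(HisturnError):
    """Coordinates fall outside the declared chromosome."""


class UnitsError(HisturnError):
    """Track units do not match the requested operation."""


class StratificationError(HisturnError):
    """Too few genes to form expression strata."""


class PairingError(HisturnError):
    """Replicate series cannot be paired index-wise."""


class QpcrReferenceError(HisturnError):
    """Wrong reference measurement for a per-histone normalization."""


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped single-end read as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected two tab-separated columns", i)
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer length {parts[1]!r}", i) from None
            if length <= 0:
                raise ParseError(f"non-positive length {length}", i)
            sizes[parts[0]] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
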