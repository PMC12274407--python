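"""Deletion-interval arithmetic for the knockout genotype design.

Deletion notation of the form ``chr13:13,630,083_13,778,965del`` is
parsed as a 1-based inclusive genomic interval, so the deleted length
is ``end - start + 1`` bp; with coordinates of this size the rounded-kb
length is insensitive to a one-off convention difference.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = ["GenomicInterval", "parse_deletion", "interval_length_kb"]

_DELETION_RE = re.compile(r"^(chr[0-9A-Za-z_]+):([\d,]+)_([\d,]+)del$")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("coordinates are 1-based positive integers")
        if self.end < self.start:
            raise ValueError("end must be >= start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def parse_deletion(notation: str) -> GenomicInterval:
    """Parse ``chr<name>:<start>_<end>del`` (thousands separators allowed)."""
    m = _DELETION_RE.match(notation.strip())
    if m is None:
        raise ValueError(f"malformed deletion notation: {notation!r}")
    chrom, start, end = m.groups()
    return GenomicInterval(
        chromosome=chrom,
        start=int(start.replace(",", "")),
        end=int(end.replace(",", "")),
    )


def interval_length_kb(iv: GenomicInterval) -> tuple[int, int]:
    """(length in bp, length rounded to the nearest kb, half away from zero)."""
    bp = iv.length_bp
    return bp, int(math.floor(bp / 1000 + 0.5))
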