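"""Genomic intervals with an explicit 0-based half-open convention.

Every coordinate held in memory by this package is 0-based half-open
(BED-style).  Printed, human-facing coordinates (genome-browser views,
cytogenetic reports) are 1-based inclusive; :func:`from_printed` and
:meth:`GenomicInterval.to_printed` convert at the boundary so arithmetic
inside the package never mixes conventions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Parameters
    ----------
    chrom : str
        Chromosome or contig name (non-empty).
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        """True if ``position`` (0-based) lies inside the interval."""
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open intersection test; different chromosomes never overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_printed(self) -> tuple[int, int]:
        """Return the 1-based inclusive (start, end) a browser would print."""
        return self.start + 1, self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def from_printed(chrom: str, start: int, end: int) -> GenomicInterval:
    """Build an interval from printed 1-based inclusive coordinates."""
    return GenomicInterval(chrom, start - 1, end)
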