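"""Parsing and arithmetic for ISCN-style array-CNV coordinate strings.

Cytogenetic reports print array findings as e.g.
``arr[hg19] Xp22.33(426,377-517,515)x1 pat``: genome build, chromosome band,
1-based inclusive coordinates with thousands separators, copy state, and an
optional inheritance token.  Coordinates are converted to the package's
internal 0-based half-open convention on parse and back on format.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .intervals import GenomicInterval, from_printed

# en dash, em dash, minus and plain hyphen all accepted between coordinates
_DASHES = "–—−-"

_ISCN_RE = re.compile(
    r"^\s*arr\[(?P<build>[^\]]+)\]\s*"
    r"(?P<chrom>[0-9]{1,2}|[XYxy])(?P<band>[pq][0-9.]+)"
    r"\((?P<start>[0-9][0-9,]*)\s*[" + _DASHES + r"]\s*(?P<end>[0-9][0-9,]*)\)"
    r"x(?P<copies>[0-9]+)"
    r"(?:\s+(?P<inheritance>\w+))?\s*$"
)


@dataclass(frozen=True)
class IscnRecord:
    build: str
    band: str  # e.g. "Xp22.33"
    interval: GenomicInterval  # internal 0-based half-open, chrom e.g. "chrX"
    printed_start: int  # 1-based inclusive, as printed
    printed_end: int
    copy_number: int
    inheritance: str | None = None


def parse_iscn(text: str) -> IscnRecord:
    """Parse an ISCN-like array CNV string.

    Accepts comma thousands separators and hyphen/en-dash/em-dash/minus
    between coordinates.  Raises ValueError with the offset of the first
    mismatch for malformed strings.
    """
    m = _ISCN_RE.match(text)
    if m is None:
        raise ValueError(
            f"malformed ISCN string at offset {_mismatch_offset(text)}: {text!r}"
        )
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if start >= end:
        raise ValueError(f"ISCN start {start} >= end {end}")
    chrom_symbol = m["chrom"].upper() if m["chrom"].isalpha() else m["chrom"]
    return IscnRecord(
        build=m["build"],
        band=f"{chrom_symbol}{m['band']}",
        interval=from_printed(f"chr{chrom_symbol}", start, end),
        printed_start=start,
        printed_end=end,
        copy_number=int(m["copies"]),
        inheritance=m["inheritance"],
    )


def _mismatch_offset(text: str) -> int:
    """Offset where the string stops looking like an ISCN annotation.

    Matches progressively longer structural prefixes so the error points at
    the first token that breaks the ``arr[build] band(start-end)xN`` shape.
    """
    prefixes = [
        r"\s*arr\[[^\]]+\]",
        r"\s*(?:[0-9]{1,2}|[XYxy])[pq][0-9.]+",
        r"\([0-9][0-9,]*\s*[" + _DASHES + r"]\s*[0-9][0-9,]*\)",
        r"x[0-9]+",
    ]
    pos = 0
    for p in prefixes:
        m = re.compile(p).match(text, pos)
        if m is None:
            return pos
        pos = m.end()
    return pos


def format_iscn(record: IscnRecord) -> str:
    """Render a record back to its printed form (comma grouping, en dash)."""
    s = f"{record.printed_start:,}"
    e = f"{record.printed_end:,}"
    out = f"arr[{record.build}] {record.band}({s}–{e})x{record.copy_number}"
    if record.inheritance:
        out += f" {record.inheritance}"
    return out


def interval_length_kb(record_or_printed: IscnRecord | tuple[int, int]) -> int:
    """CNV length in integer kb from printed coordinates.

    Computed as round((printed_end - printed_start) / 1000); the +-1 bp
    inclusive/exclusive ambiguity of printed coordinates cannot change a value
    rounded to whole kb.
    """
    if isinstance(record_or_printed, IscnRecord):
        start, end = record_or_printed.printed_start, record_or_printed.printed_end
    else:
        start, end = record_or_printed
    return int(math.floor((end - start) / 1000.0 + 0.5))
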