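"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA in/out goes through biopython; BED, bedGraph and the qPCR/luciferase
CSV dialects are parsed line-by-line so malformed records can be rejected,
counted and reported with their line numbers instead of silently dropped.
All outputs are deterministic plain text (diff-able between reruns).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fourc import AlignedRead, ContactProfile, DomainCall, FeatureOverlap
from .fragmap import FragmentMap
from .intervals import GenomicInterval
from .qpcr import LuciferaseRecord


def _open_text(path: str | Path):
    """Open plain or gzip-compressed text transparently (by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into an ordered dict.

    Sequences are uppercased; duplicate record names and empty files are
    errors.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# BED


@dataclass
class BedReport:
    """Per-line accounting of a BED parse."""

    n_valid: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def read_bed(
    path: str | Path, kind: str = "features"
) -> tuple[list, BedReport]:
    """Read a BED3-6 file as annotation features or read alignments.

    ``kind="features"`` yields ``(name, GenomicInterval)`` tuples (name
    defaults to ``chrom:start-end``); ``kind="alignments"`` yields
    :class:`AlignedRead` (strand defaults to ``+``).  Malformed lines are
    rejected and reported with their line numbers.
    """
    if kind not in ("features", "alignments"):
        raise ValueError(f"kind must be 'features' or 'alignments', got {kind!r}")
    out: list = []
    report = BedReport()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError(f"expected >= 3 tab-delimited fields, got {len(fields)}")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(f"start {start} >= end {end}")
                iv = GenomicInterval(chrom, start, end)
                if kind == "features":
                    name = fields[3] if len(fields) > 3 and fields[3] else str(iv)
                    out.append((name, iv))
                else:
                    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
                    out.append(AlignedRead(chrom, start, end, strand))
                report.n_valid += 1
            except ValueError as exc:
                report.errors.append((lineno, str(exc)))
    return out, report


def write_bed(
    path: str | Path, records: list[tuple[str, GenomicInterval]]
) -> None:
    """Write named intervals as BED4, sorted by (chrom, start)."""
    ordered = sorted(records, key=lambda r: (r[1].chrom, r[1].start, r[1].end))
    with open(path, "w") as fh:
        for name, iv in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_reads_bed(path: str | Path, reads: list[AlignedRead]) -> None:
    """Write aligned reads as BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# fragment map / profile serialization


def write_fragment_map(fmap: FragmentMap, path: str | Path) -> None:
    """BED-like table: chrom, start, end, category, left_flank, right_flank."""
    with open(path, "w") as fh:
        for chrom in fmap.chrom_order:
            for f in fmap.fragments[chrom]:
                fh.write(
                    f"{chrom}\t{f.interval.start}\t{f.interval.end}\t"
                    f"{f.category}\t{f.left_flank}\t{f.right_flank}\n"
                )


def write_fragends(fmap: FragmentMap, path: str | Path) -> None:
    """Fragend BED: one record per informative fragment's primary end."""
    with open(path, "w") as fh:
        for g, fe in enumerate(fmap.fragends):
            iv = fmap.fragend_fragment(g).interval
            fh.write(
                f"{fe.chrom}\t{iv.start}\t{iv.end}\t"
                f"fragend_{g}\t{fe.anchor_position}\t"
                f"{'+' if fe.primary_side == 'left' else '-'}\n"
            )


def write_bedgraph(
    profile: ContactProfile, which: str, path: str | Path
) -> None:
    """Write one signal track (raw|normalized|smoothed) as bedGraph.

    One line per unmasked fragend over its fragment interval, 6-decimal
    values, sorted by (chrom, start).
    """
    tracks = {
        "raw": profile.raw.astype(float),
        "normalized": profile.normalized,
        "smoothed": profile.smoothed,
    }
    if which not in tracks:
        raise ValueError(f"which must be one of {sorted(tracks)}, got {which!r}")
    values = tracks[which]
    if values is None:
        raise ValueError(f"profile has no {which!r} track yet")
    rows = []
    for g in range(profile.fmap.n_fragends):
        if profile.masked[g]:
            continue
        iv = profile.fmap.fragend_fragment(g).interval
        rows.append((iv.chrom, iv.start, iv.end, values[g]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, v in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6f}\n")


def write_domain_bed(domain: DomainCall, path: str | Path) -> None:
    iv = domain.interval
    with open(path, "w") as fh:
        fh.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
            f"contact_domain\t{domain.signal_fraction:.6f}\t.\n"
        )


def write_overlaps_tsv(overlaps: list[FeatureOverlap], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\tchrom\tstart\tend\tinside_domain\tn_fragends_overlapped\t"
            "mean_smoothed_signal\tmax_smoothed_signal\n"
        )
        for o in overlaps:
            mean_s = "" if o.mean_smoothed_signal is None else f"{o.mean_smoothed_signal:.6f}"
            max_s = "" if o.max_smoothed_signal is None else f"{o.max_smoothed_signal:.6f}"
            fh.write(
                f"{o.name}\t{o.interval.chrom}\t{o.interval.start}\t{o.interval.end}\t"
                f"{o.inside_domain}\t{o.n_fragends_overlapped}\t{mean_s}\t{max_s}\n"
            )


# ---------------------------------------------------------------------------
# qPCR / luciferase CSV


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Replicate-level qPCR table: sample_id, target_id, efficiency, cq.

    Optional columns (role, known_cn, replicate) pass through untouched.
    Empty cq cells become NaN (failed amplification).
    """
    df = pd.read_csv(path)
    required = {"sample_id", "target_id", "efficiency", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {sorted(missing)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    df["efficiency"] = pd.to_numeric(df["efficiency"])
    return df


def read_luciferase_csv(path: str | Path) -> dict[str, list[LuciferaseRecord]]:
    """Luciferase CSV (construct_id, firefly, renilla[, replicate]) grouped by
    construct."""
    df = pd.read_csv(path)
    required = {"construct_id", "firefly", "renilla"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"luciferase CSV missing columns: {sorted(missing)}")
    out: dict[str, list[LuciferaseRecord]] = {}
    for i, row in df.iterrows():
        rec = LuciferaseRecord(
            construct_id=str(row["construct_id"]),
            firefly_units=float(row["firefly"]),
            renilla_units=float(row["renilla"]),
            replicate=int(row["replicate"]) if "replicate" in df.columns else int(i),
        )
        out.setdefault(rec.construct_id, []).append(rec)
    return out
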