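"""4C-seq contact profiles: counting, filtering, normalization, smoothing,
domain calling and feature overlap.

The pipeline mirrors the standard viewpoint-anchored 4C analysis:

1. aligned reads are assigned to the double-digest fragment containing their
   5'-most coordinate;
2. reads in blind (same-enzyme-flanked), too-short and terminal fragments are
   filtered out, leaving counts per informative fragend;
3. fragends nearest the viewpoint are masked (self-ligation / undigested
   template artefacts);
4. counts are converted to reads-per-million over unmasked fragends;
5. the normalized track is smoothed with a running mean over a fixed, odd
   number of fragends (fragend-index space, which equalizes restriction-site
   density);
6. the contact domain around the viewpoint is called as the maximal
   above-threshold run of smoothed fragends containing the viewpoint, with a
   bounded gap tolerance, against a background-quantile threshold;
7. annotation features (enhancer elements, chromatin-mark peaks) are scored
   by the fragends their intervals overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragmap import (
    BLIND,
    INFORMATIVE,
    TERMINAL,
    TOO_SHORT,
    FragmentMap,
    ViewpointLocation,
)
from .intervals import GenomicInterval


@dataclass(frozen=True)
class AlignedRead:
    """A mapped 4C read; only its 5' coordinate matters for assignment."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if not self.chrom:
            raise ValueError("read chrom must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ReadAssignment:
    """Raw per-fragment counts (all categories) plus the unassigned tally."""

    counts: dict[str, np.ndarray]  # per chromosome, one entry per fragment
    unassigned: int
    n_reads: int

    @property
    def assigned(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))


def assign_reads(reads: list[AlignedRead], fmap: FragmentMap) -> ReadAssignment:
    """Assign each read to the fragment containing its 5'-most coordinate.

    Reads on chromosomes absent from the map, or with a 5' coordinate outside
    ``[0, chrom_length)``, are counted as unassigned.  Conservation holds:
    ``assigned + unassigned == len(reads)``.
    """
    counts = {
        chrom: np.zeros(len(frags), dtype=np.int64)
        for chrom, frags in fmap.fragments.items()
    }
    unassigned = 0
    # bucket reads per chromosome, then vectorise the containment search
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        if r.chrom not in counts:
            unassigned += 1
            continue
        by_chrom.setdefault(r.chrom, []).append(r.five_prime)
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        length = fmap.chrom_lengths[chrom]
        inside = (pos >= 0) & (pos < length)
        unassigned += int((~inside).sum())
        starts = fmap._fragment_starts[chrom]
        idx = np.searchsorted(starts, pos[inside], side="right") - 1
        np.add.at(counts[chrom], idx, 1)
    return ReadAssignment(counts=counts, unassigned=unassigned, n_reads=len(reads))


@dataclass
class FilterReport:
    """Read accounting for the blind/short/terminal fragment filter."""

    retained: int
    removed: dict[str, int]  # category (+ "unassigned") -> reads removed

    @property
    def total(self) -> int:
        return self.retained + sum(self.removed.values())


def filter_counts(
    assignment: ReadAssignment, fmap: FragmentMap
) -> tuple[np.ndarray, FilterReport]:
    """Restrict fragment counts to informative fragends.

    Returns the per-fragend raw count vector (global fragend order) and a
    report of reads removed per discarded category.  Raises if the assignment
    does not match the map's fragment universe.
    """
    if set(assignment.counts) != set(fmap.fragments) or any(
        len(assignment.counts[c]) != len(fmap.fragments[c]) for c in fmap.fragments
    ):
        raise ValueError("assignment does not match the fragment map universe")

    removed = {BLIND: 0, TOO_SHORT: 0, TERMINAL: 0, "unassigned": assignment.unassigned}
    fragend_counts = np.zeros(fmap.n_fragends, dtype=np.int64)
    for g, fe in enumerate(fmap.fragends):
        fragend_counts[g] = assignment.counts[fe.chrom][fe.fragment_index]
    for chrom, frags in fmap.fragments.items():
        cvec = assignment.counts[chrom]
        for i, f in enumerate(frags):
            if f.category != INFORMATIVE:
                removed[f.category] += int(cvec[i])
    report = FilterReport(retained=int(fragend_counts.sum()), removed=removed)
    if report.total != assignment.n_reads:
        raise AssertionError("read conservation violated in filter_counts")
    return fragend_counts, report


@dataclass
class ContactProfile:
    """Per-fragend contact signal anchored at a viewpoint.

    Arrays are indexed by global fragend index (map order).  ``masked`` marks
    fragends excluded from normalization, smoothing and domain calling;
    ``normalized`` and ``smoothed`` are NaN at masked fragends once computed.
    """

    fmap: FragmentMap
    viewpoint: ViewpointLocation
    raw: np.ndarray
    masked: np.ndarray  # bool
    mask_k: int | None = None
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    window_size: int | None = None
    filter_report: FilterReport | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def cis_chrom(self) -> str:
        return self.viewpoint.fragend.chrom

    def cis_indices(self, unmasked_only: bool = True) -> np.ndarray:
        lo, hi = self.fmap.fragend_range(self.cis_chrom)
        idx = np.arange(lo, hi)
        if unmasked_only:
            idx = idx[~self.masked[idx]]
        return idx

    def anchors(self, indices: np.ndarray) -> np.ndarray:
        return np.array(
            [self.fmap.fragends[g].anchor_position for g in indices], dtype=np.int64
        )


def make_profile(
    fmap: FragmentMap,
    viewpoint: ViewpointLocation,
    fragend_counts: np.ndarray,
    filter_report: FilterReport | None = None,
) -> ContactProfile:
    """Wrap per-fragend counts into a profile with only the viewpoint masked."""
    if len(fragend_counts) != fmap.n_fragends:
        raise ValueError("fragend count vector does not match the map")
    masked = np.zeros(fmap.n_fragends, dtype=bool)
    masked[viewpoint.global_index] = True
    return ContactProfile(
        fmap=fmap,
        viewpoint=viewpoint,
        raw=np.asarray(fragend_counts, dtype=np.int64),
        masked=masked,
        mask_k=0,
        filter_report=filter_report,
    )


def mask_viewpoint(profile: ContactProfile, k: int) -> ContactProfile:
    """Mask the viewpoint fragend plus the ``k`` nearest fragends on each side.

    Proximity is in fragend-index space on the viewpoint chromosome.  Masked
    fragends are excluded from normalization, smoothing and domain calling.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    lo, hi = profile.fmap.fragend_range(profile.cis_chrom)
    vp = profile.viewpoint.global_index
    masked = profile.masked.copy()
    masked[vp] = True
    masked[max(lo, vp - k) : min(hi, vp + k + 1)] = True
    profile.masked = masked
    profile.mask_k = k
    # masking invalidates derived tracks
    profile.normalized = None
    profile.smoothed = None
    return profile


def normalize(profile: ContactProfile) -> ContactProfile:
    """Convert raw counts to reads per million over unmasked fragends."""
    unmasked = ~profile.masked
    total = profile.raw[unmasked].sum()
    normalized = np.full(len(profile.raw), np.nan)
    if total == 0:
        normalized[unmasked] = 0.0
        profile.warnings.append("normalize: all unmasked raw counts are zero")
    else:
        normalized[unmasked] = 1e6 * profile.raw[unmasked] / total
    profile.normalized = normalized
    return profile


def running_mean_truncated(values: np.ndarray, window_size: int) -> np.ndarray:
    """Centred running mean with truncated windows at the edges.

    ``window_size`` must be odd and >= 1.  At positions where the full window
    does not fit, the mean of whatever fits is taken (no padding).
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and >= 1, got {window_size}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or window_size == 1:  # identity window, exactly
        return v.copy()
    half = window_size // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth(profile: ContactProfile, window_size: int = 21) -> ContactProfile:
    """Running-mean smoothing over unmasked fragends, per chromosome.

    The window is counted in fragend-index space (unmasked fragends ordered by
    anchor position), not in bp, so smoothing bandwidth tracks restriction-site
    density.  Windows truncate at chromosome edges and around masked runs.
    """
    if profile.normalized is None:
        normalize(profile)
    smoothed = np.full(len(profile.raw), np.nan)
    for chrom in profile.fmap.chrom_order:
        lo, hi = profile.fmap.fragend_range(chrom)
        idx = np.arange(lo, hi)
        idx = idx[~profile.masked[idx]]
        if len(idx) == 0:
            continue
        smoothed[idx] = running_mean_truncated(profile.normalized[idx], window_size)
    profile.smoothed = smoothed
    profile.window_size = window_size
    return profile


@dataclass(frozen=True)
class DomainCall:
    """Contiguous region of elevated contact containing the viewpoint."""

    interval: GenomicInterval
    threshold_value: float
    background_quantile: float
    gap_tolerance: int
    signal_fraction: float
    first_fragend: int  # global fragend indices bounding the qualifying run
    last_fragend: int


def call_domain(
    profile: ContactProfile,
    background_quantile: float = 0.75,
    gap_tolerance: int = 25,
) -> DomainCall:
    """Call the viewpoint contact domain against a background-quantile threshold.

    The threshold is the ``background_quantile`` quantile of smoothed values
    over unmasked cis fragends.  The call is the maximal run of fragends
    containing the viewpoint in which smoothed signal stays at or above the
    threshold, tolerating up to ``gap_tolerance`` consecutive sub-threshold
    fragends inside the run.  The reported interval is the span of the
    qualifying fragends' fragments; ``signal_fraction`` is the fraction of
    unmasked cis normalized signal inside it.
    """
    if not (0 < background_quantile < 1):
        raise ValueError("background_quantile must be in (0, 1)")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if profile.smoothed is None:
        raise ValueError("profile must be smoothed before domain calling")

    chrom = profile.cis_chrom
    idx = profile.cis_indices()
    if len(idx) == 0:
        raise ValueError(f"no unmasked fragends on viewpoint chromosome {chrom!r}")
    vals = profile.smoothed[idx]
    if not np.any(vals > 0):
        raise ValueError("no signal: all smoothed cis values are zero")

    threshold = float(np.quantile(vals, background_quantile))
    above = vals >= threshold
    anchors = profile.anchors(idx)
    vp_anchor = profile.viewpoint.fragend.anchor_position
    pos = int(np.searchsorted(anchors, vp_anchor))

    def extend(start: int, step: int) -> int | None:
        last = None
        gap = 0
        j = start
        while 0 <= j < len(vals):
            if above[j]:
                last = j
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
            j += step
        return last

    right = extend(pos, +1)
    left = extend(pos - 1, -1)
    if left is None and right is None:
        raise ValueError(
            "no fragends above the background threshold adjacent to the viewpoint"
        )

    first = idx[left] if left is not None else idx[right]
    last = idx[right] if right is not None else idx[left]
    frag_a = profile.fmap.fragend_fragment(int(first)).interval
    frag_b = profile.fmap.fragend_fragment(int(last)).interval
    start = min(frag_a.start, vp_anchor)
    end = max(frag_b.end, vp_anchor + 1)
    interval = GenomicInterval(chrom, start, end)

    inside = (idx >= first) & (idx <= last)
    cis_total = float(np.nansum(profile.normalized[idx]))
    inside_total = float(np.nansum(profile.normalized[idx[inside]]))
    signal_fraction = inside_total / cis_total if cis_total > 0 else 0.0

    return DomainCall(
        interval=interval,
        threshold_value=threshold,
        background_quantile=background_quantile,
        gap_tolerance=gap_tolerance,
        signal_fraction=signal_fraction,
        first_fragend=int(first),
        last_fragend=int(last),
    )


@dataclass(frozen=True)
class FeatureOverlap:
    """Contact-signal summary for one annotation feature."""

    name: str
    interval: GenomicInterval
    inside_domain: bool
    n_fragends_overlapped: int
    mean_smoothed_signal: float | None
    max_smoothed_signal: float | None


def overlap_features(
    profile: ContactProfile,
    domain: DomainCall | None,
    features: list[tuple[str, GenomicInterval]],
) -> list[FeatureOverlap]:
    """Score annotation features by the fragends their intervals overlap.

    A fragend overlaps a feature when its fragment's interval intersects the
    feature interval (half-open).  Signal statistics are taken over unmasked
    overlapped fragends; they are None when no fragend is overlapped (or all
    overlapped fragends are masked).  ``inside_domain`` is a plain interval
    intersection test against the domain call.
    """
    if profile.smoothed is None:
        raise ValueError("profile must be smoothed before overlap scoring")
    out: list[FeatureOverlap] = []
    for name, feat in features:
        overlapped: list[int] = []
        if feat.chrom in profile.fmap.fragments:
            lo, hi = profile.fmap.fragend_range(feat.chrom)
            for g in range(lo, hi):
                if profile.fmap.fragend_fragment(g).interval.overlaps(feat):
                    overlapped.append(g)
        unmasked = [g for g in overlapped if not profile.masked[g]]
        if unmasked:
            sm = profile.smoothed[unmasked]
            mean_s, max_s = float(np.mean(sm)), float(np.max(sm))
        else:
            mean_s = max_s = None
        inside = bool(domain is not None and feat.overlaps(domain.interval))
        out.append(
            FeatureOverlap(
                name=name,
                interval=feat,
                inside_domain=inside,
                n_fragends_overlapped=len(overlapped),
                mean_smoothed_signal=mean_s,
                max_smoothed_signal=max_s,
            )
        )
    return out


def build_profile(
    fmap: FragmentMap,
    reads: list[AlignedRead],
    viewpoint: ViewpointLocation,
    mask_k: int = 2,
    window_size: int = 21,
) -> ContactProfile:
    """Convenience chain: assign -> filter -> mask -> normalize -> smooth."""
    assignment = assign_reads(reads, fmap)
    fragend_counts, report = filter_counts(assignment, fmap)
    profile = make_profile(fmap, viewpoint, fragend_counts, filter_report=report)
    mask_viewpoint(profile, mask_k)
    normalize(profile)
    smooth(profile, window_size)
    return profile
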