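"""Double-digest restriction fragment maps and fragment-end (fragend) catalogs.

A 4C-seq library is built by digesting crosslinked chromatin with a primary
(first) restriction enzyme, ligating, then digesting with a secondary enzyme
and ligating again.  Captured contacts are therefore counted per *fragend* —
the primary-enzyme end of each retained double-digest fragment.  This module
digests a genome in silico with two enzymes, classifies the resulting
fragments (informative / blind / too short / terminal) and derives the
ordered fragend catalog that anchors all downstream counting.

Fragments flanked by two sites of the same enzyme ("blind" fragments carry no
usable ligation junction for the second digestion) and fragments shorter than
``min_fragment_length`` (default 40 bp) are excluded from the fragend catalog,
mirroring standard 4C read filtering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

# Flank labels
PRIMARY = "primary"
SECONDARY = "secondary"
CHROM_END = "chrom_end"

# Fragment categories
INFORMATIVE = "informative"
BLIND = "blind_same_enzyme"
TOO_SHORT = "too_short"
TERMINAL = "terminal"

CATEGORIES = (INFORMATIVE, BLIND, TOO_SHORT, TERMINAL)

_VALID_DNA = re.compile(r"[^ACGTNacgtn]")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by an exact recognition sequence.

    ``cut_offset`` is the distance in bp from the 5' end of the recognition
    sequence to the cut position on the forward strand.  Both default 4C
    enzymes recognise reverse-complement-palindromic sites, so a single
    forward-strand scan finds every site.
    """

    name: str
    recognition_sequence: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_sequence.upper()
        object.__setattr__(self, "recognition_sequence", site)
        if len(site) < 4 or set(site) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition sequence must be >= 4 bp of A/C/G/T, "
                f"got {site!r}"
            )
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(
                f"{self.name}: cut_offset must lie within the recognition "
                f"sequence (0..{len(site)}), got {self.cut_offset}"
            )


#: 4-cutter used for the first digestion round (blunt GATC convention).
DPNII = RestrictionEnzyme("DpnII", "GATC", 0)
#: 4-cutter used for the second digestion round (G^TAC).
CSP6I = RestrictionEnzyme("Csp6I", "GTAC", 1)


@dataclass(frozen=True)
class Fragment:
    interval: GenomicInterval
    left_flank: str
    right_flank: str
    category: str

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Fragend:
    """The primary-enzyme end of one informative fragment.

    ``anchor_position`` is the coordinate of the primary cut site bounding the
    fragment; ``primary_side`` records whether that site flanks the fragment
    on its left or right.
    """

    chrom: str
    anchor_position: int
    primary_side: str  # "left" | "right"
    fragment_index: int  # index into FragmentMap.fragments[chrom]

    def fragment(self, fmap: "FragmentMap") -> Fragment:
        return fmap.fragments[self.chrom][self.fragment_index]


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Scan ``sequence`` for enzyme cut positions (0-based, strictly increasing).

    Every exact occurrence of the recognition sequence contributes a cut at
    ``occurrence_start + cut_offset``; overlapping occurrences are allowed.
    ``N`` (and lowercase) bases are accepted in the input but never match.
    Cuts falling on a sequence boundary (position 0 or len) are dropped since
    they delimit no fragment.
    """
    bad = _VALID_DNA.search(sequence)
    if bad is not None:
        raise ValueError(
            f"non-DNA character {bad.group()!r} at offset {bad.start()}"
        )
    seq = sequence.upper()
    site = enzyme.recognition_sequence
    cuts: list[int] = []
    i = seq.find(site)
    while i != -1:
        cut = i + enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
        i = seq.find(site, i + 1)
    return cuts


@dataclass
class FragmentMap:
    """Ordered, genome-tiling double-digest fragment map plus fragend catalog.

    Per chromosome the fragments are disjoint, sorted, and tile exactly
    ``[0, chromosome_length)``.  Fragends (one per informative fragment) are
    kept both per chromosome and as flat arrays in (chromosome order, anchor)
    order for vectorised counting.
    """

    primary: RestrictionEnzyme
    secondary: RestrictionEnzyme
    min_fragment_length: int
    chrom_order: list[str]
    chrom_lengths: dict[str, int]
    fragments: dict[str, list[Fragment]]
    fragends: list[Fragend] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    # ---- derived lookups (built in __post_init__) -----------------------
    def __post_init__(self) -> None:
        self._fragment_starts = {
            chrom: np.array([f.interval.start for f in frags], dtype=np.int64)
            for chrom, frags in self.fragments.items()
        }
        # global fragend index ranges per chromosome
        self._fragend_index: dict[str, tuple[int, int]] = {}
        i = 0
        for chrom in self.chrom_order:
            n = sum(1 for fe in self.fragends if fe.chrom == chrom)
            self._fragend_index[chrom] = (i, i + n)
            i += n

    @property
    def n_fragends(self) -> int:
        return len(self.fragends)

    def fragend_range(self, chrom: str) -> tuple[int, int]:
        """Global [lo, hi) fragend index range for one chromosome."""
        return self._fragend_index[chrom]

    def fragend_fragment(self, global_index: int) -> Fragment:
        fe = self.fragends[global_index]
        return fe.fragment(self)

    def fragment_index_at(self, chrom: str, position: int) -> int | None:
        """Index of the fragment containing ``position``, or None if outside."""
        if chrom not in self.fragments:
            return None
        if not (0 <= position < self.chrom_lengths[chrom]):
            return None
        starts = self._fragment_starts[chrom]
        return int(np.searchsorted(starts, position, side="right") - 1)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for frags in self.fragments.values():
            for f in frags:
                out[f.category] += 1
        return out


def _classify(left: str, right: str, length: int, min_len: int) -> str:
    if CHROM_END in (left, right):
        return TERMINAL
    if left == right:
        return BLIND
    if length < min_len:
        return TOO_SHORT
    return INFORMATIVE


def build_fragment_map(
    genome: dict[str, str],
    primary: RestrictionEnzyme = DPNII,
    secondary: RestrictionEnzyme = CSP6I,
    min_fragment_length: int = 40,
) -> FragmentMap:
    """Digest ``genome`` with both enzymes and build the fragment/fragend map.

    Cut positions of both enzymes are merged per chromosome; consecutive cuts
    plus the chromosome ends delimit fragments, each flank labelled by the
    enzyme that produced it.  Coincident primary/secondary cuts collapse to a
    single boundary labelled primary (deterministic tie-break).  Chromosomes
    with no site of either enzyme yield one terminal fragment and a warning.
    """
    if not genome:
        raise ValueError("empty genome: no sequences provided")
    if primary.name == secondary.name:
        raise ValueError("primary and secondary enzymes must differ in name")
    if primary.recognition_sequence == secondary.recognition_sequence:
        raise ValueError("primary and secondary recognition sequences must differ")

    chrom_order = list(genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    fragments: dict[str, list[Fragment]] = {}
    fragends: list[Fragend] = []
    warnings: list[str] = []

    for chrom in chrom_order:
        seq = genome[chrom]
        p_cuts = find_sites(seq, primary)
        s_cuts = find_sites(seq, secondary)
        p_set = set(p_cuts)
        boundaries: list[tuple[int, str]] = [(0, CHROM_END)]
        boundaries += [(c, PRIMARY) for c in p_cuts]
        boundaries += [(c, SECONDARY) for c in s_cuts if c not in p_set]
        boundaries.append((len(seq), CHROM_END))
        boundaries.sort()
        if len(boundaries) == 2:
            warnings.append(f"{chrom}: no restriction site of either enzyme")

        frags: list[Fragment] = []
        for (a, la), (b, lb) in zip(boundaries[:-1], boundaries[1:]):
            iv = GenomicInterval(chrom, a, b)
            cat = _classify(la, lb, iv.length, min_fragment_length)
            frag = Fragment(iv, la, lb, cat)
            frags.append(frag)
            if cat == INFORMATIVE:
                side = "left" if la == PRIMARY else "right"
                anchor = a if side == "left" else b
                fragends.append(Fragend(chrom, anchor, side, len(frags) - 1))
        fragments[chrom] = frags

    return FragmentMap(
        primary=primary,
        secondary=secondary,
        min_fragment_length=min_fragment_length,
        chrom_order=chrom_order,
        chrom_lengths=chrom_lengths,
        fragments=fragments,
        fragends=fragends,
        warnings=warnings,
    )


@dataclass(frozen=True)
class ViewpointLocation:
    """Result of anchoring a viewpoint primer region on the fragend catalog.

    ``substituted`` is True when the primer fell in a non-informative fragment
    and the nearest informative fragend was returned instead.
    """

    fragend: Fragend
    global_index: int
    substituted: bool


def locate_viewpoint(
    fmap: FragmentMap, primer_region: GenomicInterval
) -> ViewpointLocation:
    """Find the fragend whose fragment overlaps the viewpoint primer region.

    If the primer region overlaps exactly one informative fragment, its
    fragend is returned.  If it overlaps only non-informative fragments, the
    nearest informative fragend (by anchor distance to the primer region) is
    returned with ``substituted=True``.  Overlap with more than one
    informative fragment is an error (the primer region is too wide to define
    a unique viewpoint).
    """
    chrom = primer_region.chrom
    if chrom not in fmap.fragments:
        raise ValueError(f"viewpoint chromosome {chrom!r} not in fragment map")
    if primer_region.start >= fmap.chrom_lengths[chrom]:
        raise ValueError(
            f"primer region {primer_region} beyond chromosome length "
            f"{fmap.chrom_lengths[chrom]}"
        )

    overlapping = [
        i
        for i, f in enumerate(fmap.fragments[chrom])
        if f.interval.overlaps(primer_region)
    ]
    if not overlapping:
        raise ValueError(f"primer region {primer_region} overlaps no fragment")

    informative = [
        i for i in overlapping if fmap.fragments[chrom][i].category == INFORMATIVE
    ]
    if len(informative) > 1:
        raise ValueError(
            f"primer region {primer_region} overlaps {len(informative)} "
            "informative fragments; narrow the primer region"
        )

    if len(informative) == 1:
        for g, fe in enumerate(fmap.fragends):
            if fe.chrom == chrom and fe.fragment_index == informative[0]:
                return ViewpointLocation(fe, g, substituted=False)
        raise AssertionError("informative fragment without fragend")  # unreachable

    # primer in a blind/short/terminal fragment: fall back to nearest fragend
    lo, hi = fmap.fragend_range(chrom)
    if lo == hi:
        raise ValueError(f"no informative fragend on chromosome {chrom!r}")
    best_g = min(
        range(lo, hi),
        key=lambda g: _distance(fmap.fragends[g].anchor_position, primer_region),
    )
    return ViewpointLocation(fmap.fragends[best_g], best_g, substituted=True)


def _distance(position: int, region: GenomicInterval) -> int:
    if region.contains(position):
        return 0
    return min(abs(position - region.start), abs(position - (region.end - 1)))
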