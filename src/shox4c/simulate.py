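"""Seeded synthetic data with known ground truth for every pipeline stage.

Three generators cover the inputs the pipeline consumes:

* :func:`make_genome` — random DNA with planted restriction sites at
  approximately Poisson spacing, so in-silico digestion yields a realistic
  fragment map without any reference download;
* :func:`simulate_4c_reads` — 4C read sets drawn from an explicit contact
  model (power-law distance decay around the viewpoint, a contact-domain
  plateau, discrete enhancer-like peaks, and a flat trans floor), together
  with the exact per-fragend sampling probabilities;
* :func:`simulate_qpcr_plate` — Cq tables generated from integer copy
  numbers with replicate noise and per-sample DNA-input offsets (which
  cancel through reference-gene normalization).

All generators are bit-reproducible under a fixed seed.  Default model
parameters describe the study conditions the test-suite measures against:
a 2 Mb cis chromosome with the viewpoint at its centre and a 500 kb plateau
domain around it, three narrow high-enrichment peaks inside the domain, and
qPCR plates of the default assay layout (three enhancer amplicons, two
reference genes, three calibrators at copy number 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragmap import FragmentMap
from .fourc import AlignedRead
from .intervals import GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ContactPeak:
    position: int
    enrichment: float
    width: int

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("peak enrichment must be >= 1")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")


@dataclass(frozen=True)
class ContactModel:
    """Generative model of a viewpoint-anchored cis contact profile.

    Contact weight at cis coordinate x:
    ``w(x) = max(decay(x), plateau inside domain)``, with
    ``decay(x) = (1 + |x - viewpoint| / decay_scale) ** -decay_exponent``.
    Peaks are discrete: each peak multiplies the weight of the single
    informative fragend nearest its position (enhancer-like point contacts on
    the fragment map); ``width`` sizes the matching annotation feature.
    Every fragend (cis and trans) additionally receives ``trans_floor``.
    """

    viewpoint_position: int
    decay_exponent: float = 1.0
    decay_scale: int = 10_000
    domain: GenomicInterval | None = None
    plateau_level: float = 0.5
    peaks: tuple[ContactPeak, ...] = ()
    trans_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        if self.trans_floor < 0:
            raise ValueError("trans_floor must be >= 0")

    def cis_weight(self, positions: np.ndarray) -> np.ndarray:
        """Contact weight (before the trans floor) at cis coordinates."""
        x = np.abs(np.asarray(positions, dtype=float) - self.viewpoint_position)
        w = (1.0 + x / self.decay_scale) ** (-self.decay_exponent)
        if self.domain is not None:
            inside = (np.asarray(positions) >= self.domain.start) & (
                np.asarray(positions) < self.domain.end
            )
            w = np.where(inside, np.maximum(w, self.plateau_level), w)
        return w


SIM_CHROM = "chrX_sim"


def default_contact_model(genome_length: int = 2_000_000) -> ContactModel:
    """Study-condition contact model for a genome of ``genome_length`` bp.

    Viewpoint at the centre; plateau domain covering the central quarter of
    the chromosome (500 kb on the 2 Mb default); three 600 bp peaks of
    10-fold enrichment inside the domain.
    """
    vp = genome_length // 2
    half_domain = genome_length // 8
    return ContactModel(
        viewpoint_position=vp,
        decay_exponent=1.0,
        decay_scale=10_000,
        domain=GenomicInterval(SIM_CHROM, vp - half_domain, vp + half_domain),
        plateau_level=0.5,
        peaks=(
            ContactPeak(vp - int(half_domain * 0.8), 10.0, 600),
            ContactPeak(vp - int(half_domain * 0.45), 10.0, 600),
            ContactPeak(vp + int(half_domain * 0.6), 10.0, 600),
        ),
        trans_floor=1e-4,
    )


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated read set."""

    probabilities: np.ndarray  # per informative fragend, sums to 1
    domain: GenomicInterval | None
    peak_fragends: list[int]  # one global fragend index per planted peak
    model: ContactModel


def make_genome(
    length: int,
    primary_site_rate: float = 4.0,
    secondary_site_rate: float = 1.0,
    seed: int = 0,
    primary_site: str = "GATC",
    secondary_site: str = "GTAC",
) -> str:
    """Random DNA with planted restriction sites at Poisson-like spacing.

    Rates are in sites per kb.  Sites are planted at cumulative exponential
    gaps; a site that would overlap an already-planted one is skipped (the
    realized rate stays within Poisson fluctuation at sane rates).  The
    random background also contains accidental site occurrences — digestion
    is scan-based, so these are simply additional genuine sites.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if primary_site_rate <= 0 or secondary_site_rate <= 0:
        raise ValueError("site rates must be > 0")
    site_len = max(len(primary_site), len(secondary_site))
    total_rate = primary_site_rate + secondary_site_rate
    if 1000.0 / total_rate < 2 * site_len:
        raise ValueError(
            f"site rates too high to place {site_len} bp sites without overlap"
        )
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].copy()

    planted: list[tuple[int, str]] = []
    for site, rate in ((primary_site, primary_site_rate), (secondary_site, secondary_site_rate)):
        mean_gap = 1000.0 / rate
        n_draws = int(length / mean_gap * 1.5) + 10
        gaps = rng.exponential(mean_gap, size=n_draws)
        positions = np.cumsum(gaps).astype(np.int64)
        positions = positions[positions < length - len(site)]
        planted.extend((int(p), site) for p in positions)
    planted.sort()
    last_end = -1
    for pos, site in planted:
        if pos < last_end:  # would overwrite a previously planted site
            continue
        seq[pos : pos + len(site)] = np.frombuffer(site.encode(), dtype="S1")
        last_end = pos + len(site)
    return seq.tobytes().decode()


def simulate_4c_reads(
    model: ContactModel,
    fmap: FragmentMap,
    n_reads: int,
    seed: int = 0,
    cis_chrom: str = SIM_CHROM,
    read_length: int = 36,
) -> tuple[list[AlignedRead], SimTruth]:
    """Draw a multinomial 4C read set from the contact model.

    Each informative fragend receives probability proportional to the model
    weight at its fragment midpoint (cis) or the trans floor alone (other
    chromosomes); each model peak multiplies the weight of the informative
    fragend whose fragment midpoint is nearest the peak position.  Reads are
    placed uniformly inside the chosen fragment with a random strand.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if fmap.n_fragends == 0:
        raise ValueError("fragment map has no informative fragends")
    if cis_chrom not in fmap.fragments:
        raise ValueError(f"cis chromosome {cis_chrom!r} not in the fragment map")
    if not (0 <= model.viewpoint_position < fmap.chrom_lengths[cis_chrom]):
        raise ValueError("viewpoint position outside the mapped genome")

    mids = np.empty(fmap.n_fragends, dtype=np.int64)
    weights = np.empty(fmap.n_fragends, dtype=float)
    cis_mask = np.zeros(fmap.n_fragends, dtype=bool)
    for g, fe in enumerate(fmap.fragends):
        iv = fmap.fragend_fragment(g).interval
        mids[g] = (iv.start + iv.end) // 2
        cis_mask[g] = fe.chrom == cis_chrom
    weights[:] = model.trans_floor
    weights[cis_mask] += model.cis_weight(mids[cis_mask])
    cis_idx = np.nonzero(cis_mask)[0]
    peak_fragends: list[int] = []
    for p in model.peaks:
        g = int(cis_idx[np.argmin(np.abs(mids[cis_idx] - p.position))])
        weights[g] *= p.enrichment
        peak_fragends.append(g)
    probs = weights / weights.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    reads: list[AlignedRead] = []
    for g in np.nonzero(counts)[0]:
        fe = fmap.fragends[g]
        iv = fmap.fragend_fragment(g).interval
        rl = min(read_length, iv.length)
        starts = iv.start + rng.integers(0, iv.length - rl + 1, size=counts[g])
        strands = rng.choice(np.array(["+", "-"]), size=counts[g])
        reads.extend(
            AlignedRead(fe.chrom, int(s), int(s) + rl, str(st))
            for s, st in zip(starts, strands)
        )
    truth = SimTruth(
        probabilities=probs,
        domain=model.domain,
        peak_fragends=list(map(int, peak_fragends)),
        model=model,
    )
    return reads, truth


def make_features(
    fmap: FragmentMap,
    model: ContactModel,
    seed: int = 0,
    min_decoy_distance: int = 50_000,
    cis_chrom: str = SIM_CHROM,
) -> list[tuple[str, GenomicInterval]]:
    """Named features at the planted peak positions plus matched decoys.

    One feature per model peak (same width), plus an equal number of decoy
    features placed at least ``min_decoy_distance`` from every peak.  Names
    encode the truth (``peak_i`` / ``decoy_i``) for testing.
    """
    if not model.peaks:
        raise ValueError("contact model defines no peaks")
    length = fmap.chrom_lengths[cis_chrom]
    rng = np.random.default_rng(seed)
    features: list[tuple[str, GenomicInterval]] = []
    for i, p in enumerate(model.peaks, 1):
        start = max(0, p.position - p.width // 2)
        features.append(
            ("peak_%d" % i, GenomicInterval(cis_chrom, start, start + p.width))
        )
    width = model.peaks[0].width
    placed = 0
    attempts = 0
    while placed < len(model.peaks):
        attempts += 1
        if attempts > 10_000:
            raise ValueError("genome too small to place decoys away from peaks")
        pos = int(rng.integers(0, length - width))
        if all(abs(pos - p.position) >= min_decoy_distance for p in model.peaks):
            placed += 1
            features.append(
                ("decoy_%d" % placed, GenomicInterval(cis_chrom, pos, pos + width))
            )
    return features


def simulate_qpcr_plate(
    samples: list[tuple[str, dict[str, int]]],
    efficiency: float = 2.0,
    cq_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    base_cq: float = 25.0,
    input_sd: float = 0.2,
    test_targets: tuple[str, ...] = ("CNE-5", "CNE-3", "CNE-2"),
    reference_targets: tuple[str, str] = ("ZNF80", "GPR15"),
    calibrator_samples: tuple[str, ...] = ("CAL_1", "CAL_2", "CAL_3"),
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Generate a replicate-level Cq table from known integer copy numbers.

    Test-target Cq = base_cq - log_E(cn / 2) + input offset + replicate noise;
    reference targets amplify at constant abundance (copy-number independent);
    calibrator samples carry copy number 2 at every test target.  A true copy
    number of 0 yields no-amplification rows (NaN Cq).  Returns the plate
    table (one row per replicate) and the per-sample true copy numbers.
    """
    if not (1.0 < efficiency <= 2.2):
        raise ValueError("efficiency must be in (1, 2.2]")
    if cq_sd < 0 or input_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    log_e = np.log(efficiency)

    all_samples: list[tuple[str, dict[str, int]]] = [
        (cal, {t: 2 for t in test_targets}) for cal in calibrator_samples
    ] + list(samples)

    rows: list[dict] = []
    truth: dict[str, dict[str, int]] = {}
    for sample_id, cns in all_samples:
        truth[sample_id] = dict(cns)
        offset = rng.normal(0.0, input_sd) if input_sd > 0 else 0.0
        for target in (*test_targets, *reference_targets):
            if target in reference_targets:
                mu = base_cq + offset
            else:
                cn = cns.get(target, 2)
                if cn == 0:
                    for rep in range(n_replicates):
                        rows.append(
                            dict(
                                sample_id=sample_id,
                                target_id=target,
                                efficiency=efficiency,
                                replicate=rep,
                                cq=np.nan,
                            )
                        )
                    continue
                mu = base_cq + offset - np.log(cn / 2.0) / log_e
            noise = rng.normal(0.0, cq_sd, size=n_replicates) if cq_sd > 0 else np.zeros(n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    dict(
                        sample_id=sample_id,
                        target_id=target,
                        efficiency=efficiency,
                        replicate=rep,
                        cq=float(mu + noise[rep]),
                    )
                )
    return pd.DataFrame(rows), truth
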