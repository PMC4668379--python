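"""End-to-end 4C run: digest -> assign -> filter -> mask -> normalize ->
smooth -> domain -> overlap, with full read-conservation accounting and
deterministic, diff-able outputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import io as sio
from .config import RunConfig
from .fourc import (
    AlignedRead,
    ContactProfile,
    DomainCall,
    FeatureOverlap,
    assign_reads,
    call_domain,
    filter_counts,
    make_profile,
    mask_viewpoint,
    normalize,
    overlap_features,
    smooth,
)
from .fragmap import (
    FragmentMap,
    RestrictionEnzyme,
    build_fragment_map,
    locate_viewpoint,
)
from .intervals import GenomicInterval


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that raised."""

    #: stage name -> process exit code
    EXIT_CODES = {
        "ingest": 2,
        "digest": 3,
        "viewpoint": 4,
        "assign": 5,
        "filter": 6,
        "profile": 7,
        "domain": 8,
        "overlap": 9,
        "write": 10,
    }

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = self.EXIT_CODES.get(stage, 1)


@dataclass
class PipelineResult:
    fmap: FragmentMap
    profile: ContactProfile
    domain: DomainCall
    overlaps: list[FeatureOverlap]
    output_dir: Path | None


def _enzyme(cfg_enzyme) -> RestrictionEnzyme:
    return RestrictionEnzyme(cfg_enzyme.name, cfg_enzyme.site, cfg_enzyme.cut_offset)


def run_pipeline(
    config: RunConfig,
    genome: dict[str, str],
    reads: list[AlignedRead],
    viewpoint_region: GenomicInterval,
    features: list[tuple[str, GenomicInterval]] | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every 4C stage in order and optionally write the result bundle.

    Outputs (fragment map, fragend BED, three bedGraph tracks, domain BED,
    overlap TSV, filter report, resolved config, stage log) land in
    ``output_dir``; reruns with the same config and inputs are
    byte-identical.  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    config.validate()
    log: list[str] = []

    def stage(name: str, fn):
        try:
            result = fn()
        except (ValueError, KeyError) as exc:
            raise StageError(name, str(exc)) from exc
        log.append(f"stage={name} ok")
        return result

    fmap = stage(
        "digest",
        lambda: build_fragment_map(
            genome,
            _enzyme(config.primary_enzyme),
            _enzyme(config.secondary_enzyme),
            config.min_fragment_length,
        ),
    )
    viewpoint = stage("viewpoint", lambda: locate_viewpoint(fmap, viewpoint_region))
    assignment = stage("assign", lambda: assign_reads(reads, fmap))
    fragend_counts, report = stage("filter", lambda: filter_counts(assignment, fmap))

    def build() -> ContactProfile:
        p = make_profile(fmap, viewpoint, fragend_counts, filter_report=report)
        mask_viewpoint(p, config.mask_k)
        normalize(p)
        smooth(p, config.window_size)
        return p

    profile = stage("profile", build)
    domain = stage(
        "domain",
        lambda: call_domain(profile, config.background_quantile, config.gap_tolerance),
    )
    overlaps = stage(
        "overlap", lambda: overlap_features(profile, domain, features or [])
    )

    log.append(
        "conservation: reads=%d assigned=%d unassigned=%d retained=%d "
        "removed_blind=%d removed_too_short=%d removed_terminal=%d"
        % (
            assignment.n_reads,
            assignment.assigned,
            assignment.unassigned,
            report.retained,
            report.removed["blind_same_enzyme"],
            report.removed["too_short"],
            report.removed["terminal"],
        )
    )
    if report.total != assignment.n_reads:
        raise StageError("filter", "read conservation accounting does not balance")

    out = None
    if output_dir is not None:
        out = Path(output_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            sio.write_fragment_map(fmap, out / "fragment_map.tsv")
            sio.write_fragends(fmap, out / "fragends.bed")
            for which in ("raw", "normalized", "smoothed"):
                sio.write_bedgraph(profile, which, out / f"signal_{which}.bedgraph")
            sio.write_domain_bed(domain, out / "domain.bed")
            sio.write_overlaps_tsv(overlaps, out / "feature_overlaps.tsv")
            with open(out / "filter_report.tsv", "w") as fh:
                fh.write("category\treads\n")
                fh.write(f"retained\t{report.retained}\n")
                for cat in sorted(report.removed):
                    fh.write(f"{cat}\t{report.removed[cat]}\n")
            config.to_json(out / "config.json")
            (out / "run.log").write_text("\n".join(log) + "\n")
        except OSError as exc:
            raise StageError("write", str(exc)) from exc

    return PipelineResult(
        fmap=fmap, profile=profile, domain=domain, overlaps=overlaps, output_dir=out
    )
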