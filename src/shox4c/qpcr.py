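"""qPCR relative quantification and copy-number calling.

Implements the standard efficiency-corrected, multi-reference-gene relative
quantification model: per target, a relative quantity RQ = E^(Cq_cal - Cq)
against the calibrator mean Cq; per sample, the test-target RQ is divided by
the geometric mean of two reference-gene RQs (NRQ); copy numbers are scaled
from NRQs using calibrator samples of known copy number (default three
calibrators at copy number 2).  Calls are deterministic quantities with
standard deviations and flags, not hypothesis tests.

The default assay layout profiles three amplicons over the conserved
non-coding enhancer elements upstream of SHOX (CNE-5, CNE-3, CNE-2) with
reference genes ZNF80 and GPR15.  SHOX lies in pseudoautosomal region 1, so
the expected copy number is 2 in both sexes and no sex correction is applied.

Also houses the cohort/reporter arithmetic used alongside copy-number
profiling: cohort carrier frequency and dual-luciferase fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_TARGETS = ("ZNF80", "GPR15")
DEFAULT_TEST_TARGETS = ("CNE-5", "CNE-3", "CNE-2")
DEFAULT_CALIBRATOR_CN = 2
DEFAULT_AMBIGUITY_BAND = 0.15

DELETION = "deletion"
NORMAL = "normal"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Cq values for one sample x amplicon reaction."""

    sample_id: str
    target_id: str
    cq_replicates: tuple[float, ...]
    efficiency: float

    def __post_init__(self) -> None:
        if len(self.cq_replicates) < 1:
            raise ValueError("at least one Cq replicate required")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(
                f"efficiency must be in (1, 2.2], got {self.efficiency}"
            )
        finite = [c for c in self.cq_replicates if not math.isnan(c)]
        if any(not (0 < c < 50) for c in finite):
            raise ValueError(f"Cq values must lie in (0, 50): {self.cq_replicates}")

    @property
    def amplified(self) -> bool:
        """False when every replicate failed to amplify (NaN Cq)."""
        return any(not math.isnan(c) for c in self.cq_replicates)

    @property
    def mean_cq(self) -> float:
        vals = [c for c in self.cq_replicates if not math.isnan(c)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd_cq(self) -> float:
        vals = [c for c in self.cq_replicates if not math.isnan(c)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


@dataclass(frozen=True)
class PlateDesign:
    """Target roles and calibrator samples of a copy-number qPCR plate."""

    reference_targets: tuple[str, str] = DEFAULT_REFERENCE_TARGETS
    test_targets: tuple[str, ...] = DEFAULT_TEST_TARGETS
    calibrator_samples: tuple[str, ...] = ("CAL_1", "CAL_2", "CAL_3")
    calibrator_cn: int = DEFAULT_CALIBRATOR_CN

    def __post_init__(self) -> None:
        if len(self.reference_targets) != 2:
            raise ValueError("exactly two reference targets required")
        if len(self.calibrator_samples) < 1:
            raise ValueError("at least one calibrator sample required")


@dataclass(frozen=True)
class RelativeQuantity:
    value: float
    sd: float
    no_amplification: bool = False


def relative_quantity(
    measurement: QpcrMeasurement, calibrator_mean_cq: float
) -> RelativeQuantity:
    """Efficiency-corrected relative quantity RQ = E^(Cq_cal - Cq_sample).

    The SD is propagated from the replicate Cq SD in log space:
    sd(RQ)/RQ = ln(E) * sd(Cq).  A measurement with no amplified replicate
    yields RQ 0 with the no-amplification flag set.
    """
    if not measurement.amplified:
        return RelativeQuantity(0.0, 0.0, no_amplification=True)
    e = measurement.efficiency
    rq = e ** (calibrator_mean_cq - measurement.mean_cq)
    sd = rq * math.log(e) * measurement.sd_cq
    return RelativeQuantity(float(rq), float(sd))


def normalized_relative_quantity(
    rq_test: float, rq_ref1: float, rq_ref2: float
) -> float:
    """NRQ: test RQ divided by the geometric mean of the two reference RQs."""
    if rq_ref1 <= 0 or rq_ref2 <= 0:
        raise ValueError("reference amplification failure: reference RQ <= 0")
    return rq_test / math.sqrt(rq_ref1 * rq_ref2)


def copy_number(
    nrq_sample: float, calibrator_nrqs: list[float], calibrator_cn: int = 2
) -> float:
    """Scale a sample NRQ to a copy-number estimate via calibrator NRQs."""
    usable = [x for x in calibrator_nrqs if x > 0]
    if not usable:
        raise ValueError("all calibrators failed to amplify")
    return calibrator_cn * nrq_sample / float(np.mean(usable))


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    target_id: str
    nrq: float
    nrq_sd: float
    copy_number_estimate: float
    copy_number_class: str
    integer_copy_number: int
    ambiguous: bool = False
    no_amplification: bool = False


def classify_call(
    estimate: float, ambiguity_band: float = DEFAULT_AMBIGUITY_BAND
) -> tuple[str, int, bool]:
    """Round a copy-number estimate to an integer and a CNV class.

    Returns (class, integer copy number, ambiguous flag).  Estimates within
    ``ambiguity_band`` of a half-integer boundary are flagged ambiguous
    (still classified, but borderline).
    """
    if estimate < 0:
        raise ValueError("copy-number estimate must be >= 0")
    integer = int(math.floor(estimate + 0.5))
    if integer < 2:
        cls = DELETION
    elif integer == 2:
        cls = NORMAL
    else:
        cls = DUPLICATION
    dist_to_boundary = abs((estimate % 1.0) - 0.5)
    ambiguous = dist_to_boundary <= ambiguity_band
    return cls, integer, ambiguous


@dataclass(frozen=True)
class RegionCall:
    """Per-sample summary over the upstream enhancer amplicons."""

    sample_id: str
    positive: bool
    direction: str | None  # deletion | duplication when positive
    discordant: bool
    calls: tuple[CopyNumberCall, ...] = field(default=())


def region_call(calls: list[CopyNumberCall]) -> RegionCall:
    """Label a sample upstream-CNV-positive from its per-amplicon calls.

    Positive iff at least two amplicon calls are non-normal and concordant in
    direction; non-normal calls in opposite directions are flagged discordant
    for manual review.
    """
    if not calls:
        raise ValueError("at least one amplicon call required")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    non_normal = [c for c in calls if c.copy_number_class != NORMAL]
    directions = {c.copy_number_class for c in non_normal}
    discordant = len(directions) > 1
    positive = len(non_normal) >= 2 and not discordant
    direction = non_normal[0].copy_number_class if positive else None
    return RegionCall(
        sample_id=calls[0].sample_id,
        positive=positive,
        direction=direction,
        discordant=discordant,
        calls=tuple(calls),
    )


# ---------------------------------------------------------------------------
# plate-level driver


def _measurements_from_frame(plate: pd.DataFrame) -> dict[tuple[str, str], QpcrMeasurement]:
    """Collapse replicate rows (sample_id, target_id, efficiency, cq) into
    QpcrMeasurement objects."""
    required = {"sample_id", "target_id", "efficiency", "cq"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], QpcrMeasurement] = {}
    for (sample, target), grp in plate.groupby(["sample_id", "target_id"], sort=False):
        eff = grp["efficiency"].astype(float).unique()
        if len(eff) != 1:
            raise ValueError(
                f"inconsistent efficiency for {sample}/{target}: {eff}"
            )
        out[(str(sample), str(target))] = QpcrMeasurement(
            sample_id=str(sample),
            target_id=str(target),
            cq_replicates=tuple(grp["cq"].astype(float)),
            efficiency=float(eff[0]),
        )
    return out


def call_plate(
    plate: pd.DataFrame,
    design: PlateDesign = PlateDesign(),
    ambiguity_band: float = DEFAULT_AMBIGUITY_BAND,
) -> tuple[list[CopyNumberCall], list[RegionCall]]:
    """Run the full relative-quantification pipeline on one plate.

    ``plate`` has one row per replicate with columns sample_id, target_id,
    efficiency, cq (NaN cq = failed amplification).  Returns per sample x
    test-target copy-number calls and per-sample region summaries.
    """
    meas = _measurements_from_frame(plate)
    samples = list(dict.fromkeys(s for s, _ in meas))
    targets = list(dict.fromkeys(t for _, t in meas))
    for ref in design.reference_targets:
        if ref not in targets:
            raise ValueError(f"reference target {ref!r} absent from plate")
    calibrators = [s for s in design.calibrator_samples if s in samples]
    if not calibrators:
        raise ValueError("no calibrator sample present on the plate")

    # per-target calibrator mean Cq (mean over calibrator replicate means)
    cal_cq: dict[str, float] = {}
    for t in targets:
        means = [
            meas[(s, t)].mean_cq
            for s in calibrators
            if (s, t) in meas and meas[(s, t)].amplified
        ]
        if not means:
            raise ValueError(f"no amplified calibrator measurement for target {t!r}")
        cal_cq[t] = float(np.mean(means))

    # RQ for every sample x target
    rq: dict[tuple[str, str], RelativeQuantity] = {
        key: relative_quantity(m, cal_cq[key[1]]) for key, m in meas.items()
    }

    def nrq_of(sample: str, target: str) -> tuple[float, float, bool]:
        r1 = rq[(sample, design.reference_targets[0])]
        r2 = rq[(sample, design.reference_targets[1])]
        rt = rq[(sample, target)]
        value = normalized_relative_quantity(rt.value, r1.value, r2.value)
        if rt.no_amplification:
            return 0.0, 0.0, True
        # relative SDs combine in quadrature; each reference enters at power 1/2
        rel = math.sqrt(
            (rt.sd / rt.value) ** 2
            + 0.25 * (r1.sd / r1.value) ** 2
            + 0.25 * (r2.sd / r2.value) ** 2
        )
        return value, value * rel, False

    test_targets = [t for t in design.test_targets if t in targets]
    cal_nrqs = {
        t: [nrq_of(s, t)[0] for s in calibrators if (s, t) in meas]
        for t in test_targets
    }

    calls: list[CopyNumberCall] = []
    regions: list[RegionCall] = []
    for s in samples:
        sample_calls = []
        for t in test_targets:
            if (s, t) not in meas:
                continue
            value, sd, no_amp = nrq_of(s, t)
            estimate = copy_number(value, cal_nrqs[t], design.calibrator_cn)
            cls, integer, ambiguous = classify_call(estimate, ambiguity_band)
            call = CopyNumberCall(
                sample_id=s,
                target_id=t,
                nrq=value,
                nrq_sd=sd,
                copy_number_estimate=estimate,
                copy_number_class=cls,
                integer_copy_number=integer,
                ambiguous=ambiguous,
                no_amplification=no_amp,
            )
            sample_calls.append(call)
        if sample_calls:
            calls.extend(sample_calls)
            regions.append(region_call(sample_calls))
    return calls, regions


def calls_to_frame(calls: list[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "target_id": [c.target_id for c in calls],
            "nrq": [c.nrq for c in calls],
            "nrq_sd": [c.nrq_sd for c in calls],
            "copy_number_estimate": [c.copy_number_estimate for c in calls],
            "copy_number_class": [c.copy_number_class for c in calls],
            "integer_copy_number": [c.integer_copy_number for c in calls],
            "ambiguous": [c.ambiguous for c in calls],
            "no_amplification": [c.no_amplification for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# cohort and reporter-assay arithmetic


def cohort_frequency(carriers: int, cohort_size: int) -> float:
    """Carrier frequency as a percentage rounded to one decimal."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be > 0")
    if not (0 <= carriers <= cohort_size):
        raise ValueError("carriers must lie in [0, cohort_size]")
    return round(100.0 * carriers / cohort_size, 1)


@dataclass(frozen=True)
class LuciferaseRecord:
    construct_id: str
    firefly_units: float
    renilla_units: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.renilla_units <= 0:
            raise ValueError("renilla_units must be > 0")

    @property
    def ratio(self) -> float:
        return self.firefly_units / self.renilla_units


def luciferase_fold_change(
    sample: list[LuciferaseRecord], empty_vector: list[LuciferaseRecord]
) -> tuple[float, float]:
    """Fold increase of a reporter construct over the empty vector.

    Each replicate is first normalized to its Renilla internal control; the
    fold change is the ratio of mean normalized activities, with a
    delta-method SD for the ratio of means.
    """
    if not sample or not empty_vector:
        raise ValueError("both replicate sets must be non-empty")
    rs = np.array([r.ratio for r in sample], dtype=float)
    re_ = np.array([r.ratio for r in empty_vector], dtype=float)
    fold = float(rs.mean() / re_.mean())
    var_ms = rs.var(ddof=1) / len(rs) if len(rs) > 1 else 0.0
    var_me = re_.var(ddof=1) / len(re_) if len(re_) > 1 else 0.0
    sd = fold * math.sqrt(var_ms / rs.mean() ** 2 + var_me / re_.mean() ** 2)
    return fold, float(sd)
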