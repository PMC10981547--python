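"""Paired sitting/supine comparison and cohort summary.

For each patient the edge-region Lab color measured sitting is the reference
and the supine color the sample, so the signed CIEDE2000 components read
supine minus sitting. A color difference is "acceptable" when it falls
strictly below the 50:50% acceptability threshold (AT); the default AT of
4.1 dE00 units is the value commonly used for gingival color, taken here as
an approximation for tongue tissue (alternatives reported in that literature
are 4.0 and 2.8). A perceptibility threshold (PT) may be configured as well
but has no default.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .colorimetry import (
    ColorDifferenceResult,
    LabColor,
    ParametricCoefficients,
    ciede2000,
)

__all__ = [
    "PositionMeasurement",
    "ThresholdSet",
    "PatientComparison",
    "CohortSummary",
    "PairingError",
    "compare_positions",
    "classify_acceptability",
    "compare_patient",
    "summarize_cohort",
]

DEFAULT_ACCEPTABILITY_THRESHOLD = 4.1


class PairingError(ValueError):
    """Sitting/supine measurements do not form a valid pair."""


@dataclass(frozen=True)
class PositionMeasurement:
    """Region-wise Lab colors for one patient in one position."""

    patient_id: str
    position: str  # "sitting" | "supine"
    region_colors: dict[str, LabColor]
    seconds_since_position_change: float | None = None

    def __post_init__(self) -> None:
        if self.position not in ("sitting", "supine"):
            raise ValueError("position must be 'sitting' or 'supine'")


@dataclass(frozen=True)
class ThresholdSet:
    """Acceptability (AT) and optional perceptibility (PT) thresholds."""

    AT: float = DEFAULT_ACCEPTABILITY_THRESHOLD
    PT: float | None = None

    def __post_init__(self) -> None:
        if self.AT <= 0:
            raise ValueError("AT must be positive")
        if self.PT is not None and not (0 < self.PT <= self.AT):
            raise ValueError("PT must be positive and <= AT")


@dataclass(frozen=True)
class PatientComparison:
    patient_id: str
    result: ColorDifferenceResult
    acceptable: bool
    threshold_used: float
    sitting: LabColor | None = None
    supine: LabColor | None = None


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_dE00: float
    median_dE00: float
    proportion_acceptable: float
    threshold_used: float
    per_patient: tuple[PatientComparison, ...]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_dE00": self.mean_dE00,
            "median_dE00": self.median_dE00,
            "proportion_acceptable": self.proportion_acceptable,
            "threshold_used": self.threshold_used,
            "per_patient": [
                {
                    "patient_id": c.patient_id,
                    "dE00": c.result.dE00,
                    "dL_prime": c.result.dL_prime,
                    "dC_prime": c.result.dC_prime,
                    "dH_prime": c.result.dH_prime,
                    "acceptable": c.acceptable,
                }
                for c in self.per_patient
            ],
        }


def compare_positions(
    sitting: PositionMeasurement,
    supine: PositionMeasurement,
    region: str = "edge",
    k: ParametricCoefficients = ParametricCoefficients(),
) -> ColorDifferenceResult:
    """CIEDE2000 between a patient's sitting (reference) and supine (sample)
    color in one region.

    Raises ``PairingError`` on mismatched patient IDs or positions, and
    ``KeyError`` if the region is missing from either measurement.
    """
    if sitting.patient_id != supine.patient_id:
        raise PairingError(
            f"patient IDs differ: {sitting.patient_id!r} vs {supine.patient_id!r}"
        )
    if sitting.position != "sitting" or supine.position != "supine":
        raise PairingError("arguments must be a (sitting, supine) pair, in that order")
    for m in (sitting, supine):
        if region not in m.region_colors:
            raise KeyError(
                f"region {region!r} missing from {m.position} measurement of "
                f"patient {m.patient_id!r}"
            )
    return ciede2000(sitting.region_colors[region], supine.region_colors[region], k)


def classify_acceptability(
    result: ColorDifferenceResult, thresholds: ThresholdSet = ThresholdSet()
) -> bool:
    """True iff dE00 < AT, strictly.

    The strict inequality matters at the boundary: a difference exactly equal
    to the threshold is counted as not acceptable.
    """
    return result.dE00 < thresholds.AT


def compare_patient(
    sitting: PositionMeasurement,
    supine: PositionMeasurement,
    region: str = "edge",
    thresholds: ThresholdSet = ThresholdSet(),
    k: ParametricCoefficients = ParametricCoefficients(),
) -> PatientComparison:
    """Full per-patient record: CIEDE2000 result plus acceptability flag."""
    result = compare_positions(sitting, supine, region=region, k=k)
    return PatientComparison(
        patient_id=sitting.patient_id,
        result=result,
        acceptable=classify_acceptability(result, thresholds),
        threshold_used=thresholds.AT,
        sitting=sitting.region_colors[region],
        supine=supine.region_colors[region],
    )


def summarize_cohort(comparisons: list[PatientComparison]) -> CohortSummary:
    """Cohort-level summary: mean and median dE00 and acceptable proportion.

    The median for even n is the mean of the two central order statistics.
    """
    if not comparisons:
        raise ValueError("no patients: cannot summarize an empty cohort")
    thresholds = {c.threshold_used for c in comparisons}
    if len(thresholds) != 1:
        raise ValueError(f"mixed acceptability thresholds in cohort: {thresholds}")
    values = [c.result.dE00 for c in comparisons]
    return CohortSummary(
        n=len(values),
        mean_dE00=statistics.fmean(values),
        median_dE00=statistics.median(values),
        proportion_acceptable=sum(c.acceptable for c in comparisons) / len(values),
        threshold_used=thresholds.pop(),
        per_patient=tuple(comparisons),
    )
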