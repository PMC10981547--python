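"""Associations between color difference and patient covariates, and
reference-value flagging.

Numeric covariates are related to dE00 with the Pearson correlation (two-sided
p-value from the t transform with n-2 degrees of freedom); categorical
covariates with the correlation ratio eta^2 = between-group sum of squares /
total sum of squares (p-value from the one-way ANOVA F statistic). Missing
values are dropped pairwise per covariate and the n actually used is reported.
No multiple-testing correction is applied; p-values are reported as-is.

Reference-value flags mark laboratory items at the prompt-consultation level
of the hypertension / dyslipidemia / diabetes guidelines: grade II-III blood
pressure (SBP >= 160 mmHg or DBP >= 100 mmHg, counting as a single item),
triglycerides >= 500 mg/dL, fasting plasma glucose >= 126 mg/dL and
HbA1c >= 6.5%, plus LDL-C >= 180 mg/dL (high-risk dyslipidemia); an
HDL-C >= 100 mg/dL item is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PatientBiometrics",
    "ReferenceCriterion",
    "ReferenceCriteria",
    "AssociationResult",
    "DEFAULT_CRITERIA",
    "HDL_CRITERION",
    "pearson_r",
    "eta_squared",
    "flag_above_reference",
    "count_flags_by_group",
]


@dataclass(frozen=True)
class PatientBiometrics:
    """One patient's characteristics; any field may be missing (None)."""

    patient_id: str
    age: float | None = None          # years
    sex: str | None = None            # "M" | "F"
    bmi: float | None = None          # kg/m^2
    smoking: str | None = None        # "yes" | "no"
    cvd_drug: str | None = None       # "yes" | "no"
    sbp: float | None = None          # mmHg
    dbp: float | None = None          # mmHg
    tg: float | None = None           # mg/dL
    hdl_c: float | None = None        # mg/dL
    ldl_c: float | None = None        # mg/dL
    hba1c: float | None = None        # %
    fpg: float | None = None          # mg/dL

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("patient_id", "sex", "smoking", "cvd_drug") or v is None:
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")


@dataclass(frozen=True)
class ReferenceCriterion:
    """One named flag rule; missing fields never satisfy a rule."""

    name: str
    predicate: Callable[[PatientBiometrics], bool]
    description: str = ""

    def applies(self, p: PatientBiometrics) -> bool:
        return bool(self.predicate(p))


def _ge(value: float | None, cutoff: float) -> bool:
    return value is not None and value >= cutoff


def _bp_rule(p: PatientBiometrics) -> bool:
    # grade II-III hypertension; SBP and DBP together count as one item
    return _ge(p.sbp, 160.0) or _ge(p.dbp, 100.0)


DEFAULT_CRITERIA: tuple[ReferenceCriterion, ...] = (
    ReferenceCriterion("blood_pressure", _bp_rule, "SBP >= 160 mmHg or DBP >= 100 mmHg"),
    ReferenceCriterion("tg", lambda p: _ge(p.tg, 500.0), "triglycerides >= 500 mg/dL"),
    ReferenceCriterion("fpg", lambda p: _ge(p.fpg, 126.0), "fasting plasma glucose >= 126 mg/dL"),
    ReferenceCriterion("hba1c", lambda p: _ge(p.hba1c, 6.5), "HbA1c >= 6.5%"),
    ReferenceCriterion("ldl_c", lambda p: _ge(p.ldl_c, 180.0), "LDL-C >= 180 mg/dL"),
)

#: optional extra item, not part of the default set
HDL_CRITERION = ReferenceCriterion(
    "hdl_c", lambda p: _ge(p.hdl_c, 100.0), "HDL-C >= 100 mg/dL"
)

ReferenceCriteria = Sequence[ReferenceCriterion]


@dataclass(frozen=True)
class AssociationResult:
    covariate: str
    kind: str  # "pearson_r" | "eta_squared"
    value: float
    p_value: float
    n_used: int


def _pairwise_complete(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    xs, ys = [], []
    for xi, yi in zip(x, y):
        if xi is None or yi is None:
            continue
        if isinstance(xi, float) and math.isnan(xi):
            continue
        if isinstance(yi, float) and math.isnan(yi):
            continue
        xs.append(xi)
        ys.append(yi)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def pearson_r(x: Sequence, y: Sequence, covariate: str = "") -> AssociationResult:
    """Sample Pearson correlation with a two-sided t-based p-value.

    Missing entries (None/NaN) are deleted pairwise; n_used reports the pairs
    that remain. Raises on n < 3 or zero variance in either vector.
    """
    xs, ys = _pairwise_complete(x, y)
    n = xs.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance in an input vector")
    res = stats.pearsonr(xs, ys)
    return AssociationResult(
        covariate=covariate,
        kind="pearson_r",
        value=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=int(n),
    )


def eta_squared(
    values: Sequence, groups: Sequence, covariate: str = ""
) -> AssociationResult:
    """Correlation ratio eta^2 with a one-way ANOVA F-test p-value.

    eta^2 = SS_between / SS_total in [0, 1]. Requires n >= 3 complete pairs,
    at least two non-empty groups and non-zero total variance.
    """
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    vals, grps = [], []
    for v, g in zip(values, groups):
        if v is None or g is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            continue
        vals.append(float(v))
        grps.append(g)
    v = np.asarray(vals)
    n = v.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    labels = sorted(set(grps), key=str)
    if len(labels) < 2:
        raise ValueError("eta_squared needs at least two non-empty groups")
    ss_total = float(np.sum((v - v.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("undefined correlation ratio: zero total variance")
    by_group = [v[np.asarray([g == lab for g in grps])] for lab in labels]
    ss_between = float(sum(gv.size * (gv.mean() - v.mean()) ** 2 for gv in by_group))
    eta2 = ss_between / ss_total
    # F-test degenerates when every within-group variance is 0; p -> 0 then
    if all(np.ptp(gv) == 0 for gv in by_group):
        p = 0.0
    else:
        p = float(stats.f_oneway(*by_group).pvalue)
    return AssociationResult(
        covariate=covariate,
        kind="eta_squared",
        value=eta2,
        p_value=p,
        n_used=int(n),
    )


def flag_above_reference(
    biometrics: PatientBiometrics,
    criteria: ReferenceCriteria = DEFAULT_CRITERIA,
) -> list[str]:
    """Names of the reference criteria this patient's values satisfy."""
    if not criteria:
        raise ValueError("criteria set is empty")
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise ValueError("criterion names must be unique")
    return [c.name for c in criteria if c.applies(biometrics)]


#: covariates treated as categorical (correlation ratio) in the standard report
CATEGORICAL_COVARIATES = ("sex", "smoking", "cvd_drug")
NUMERIC_COVARIATES = ("age", "bmi", "sbp", "dbp", "tg", "hdl_c", "ldl_c", "hba1c", "fpg")


def association_table(
    de00_by_patient: dict[str, float],
    records: Sequence[PatientBiometrics],
) -> list[AssociationResult]:
    """Standard association report: dE00 vs every covariate.

    Pearson r for the numeric covariates, correlation ratio eta^2 for the
    categorical ones (sex, smoking and drug status). Patients without a dE00
    entry are skipped; per-covariate missing values are dropped pairwise.
    """
    recs = [r for r in records if r.patient_id in de00_by_patient]
    de = [de00_by_patient[r.patient_id] for r in recs]
    out: list[AssociationResult] = []
    for cov in NUMERIC_COVARIATES:
        vals = [getattr(r, cov) for r in recs]
        out.append(pearson_r(de, vals, covariate=cov))
    for cov in CATEGORICAL_COVARIATES:
        groups = [getattr(r, cov) for r in recs]
        out.append(eta_squared(de, groups, covariate=cov))
    return out


def count_flags_by_group(
    comparisons,
    flag_counts: dict[str, int],
) -> dict[str, dict]:
    """Cross-tabulate flagged-item counts by acceptability group.

    ``comparisons`` is a list of PatientComparison; ``flag_counts`` maps
    patient_id -> number of flagged items. For each group ("acceptable",
    "not_acceptable") reports n, the count and percentage of patients with
    <= 1 flagged item, and with >= 2. Percentages are None for empty groups.
    """
    missing = [c.patient_id for c in comparisons if c.patient_id not in flag_counts]
    if missing:
        raise ValueError(f"no flag count for patient(s): {missing}")
    out: dict[str, dict] = {}
    for key, keep in (("acceptable", True), ("not_acceptable", False)):
        counts = [flag_counts[c.patient_id] for c in comparisons if c.acceptable is keep]
        n = len(counts)
        at_most_1 = sum(1 for c in counts if c <= 1)
        at_least_2 = n - at_most_1
        out[key] = {
            "n": n,
            "at_most_one_item": at_most_1,
            "at_least_two_items": at_least_2,
            "pct_at_most_one": (100.0 * at_most_1 / n) if n else None,
            "pct_at_least_two": (100.0 * at_least_2 / n) if n else None,
        }
    return out
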