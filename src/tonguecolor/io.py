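"""Tabular and image I/O, run configuration, and the bundled example cohort.

CSV is the tabular interchange format (UTF-8, "." decimal separator); Unicode
minus signs (U+2212), as found in typeset tables, are normalized to ASCII on
read. Images are read as PNG/TIFF (8- or 16-bit RGB) and scaled to [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .biometrics import PatientBiometrics
from .colorimetry import LabColor, ParametricCoefficients
from .comparison import PatientComparison, PositionMeasurement, ThresholdSet
from .segmentation import PartitionRatios

__all__ = [
    "RunConfig",
    "read_biometrics_csv",
    "read_lab_pairs_csv",
    "read_image",
    "write_comparison_csv",
    "write_label_png",
    "load_example_biometrics",
    "load_example_lab_pairs",
]

_BIOMETRIC_NUMERIC = (
    "age", "bmi", "sbp", "dbp", "tg", "hdl_c", "ldl_c", "hba1c", "fpg",
)
_BIOMETRIC_CATEGORICAL = ("sex", "smoking", "cvd_drug")

#: header aliases, lowercase, unit suffixes stripped before lookup
_COLUMN_ALIASES = {
    "no": "patient_id",
    "id": "patient_id",
    "patient": "patient_id",
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    "bmi": "bmi",
    "smoking": "smoking",
    "cvd_drug": "cvd_drug",
    "cvd drug": "cvd_drug",
    "sbp": "sbp",
    "dbp": "dbp",
    "tg": "tg",
    "hdl_c": "hdl_c",
    "hdl-c": "hdl_c",
    "ldl_c": "ldl_c",
    "ldl-c": "ldl_c",
    "hba1c": "hba1c",
    "fpg": "fpg",
}


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run; round-trips through JSON."""

    white_point: str = "D65"
    ratios: PartitionRatios = PartitionRatios()
    thresholds: ThresholdSet = ThresholdSet()
    k: ParametricCoefficients = ParametricCoefficients()
    region: str = "edge"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "white_point": self.white_point,
                "ratios": dataclasses.asdict(self.ratios),
                "thresholds": dataclasses.asdict(self.thresholds),
                "k": dataclasses.asdict(self.k),
                "region": self.region,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(
            white_point=d.get("white_point", "D65"),
            ratios=PartitionRatios(**d.get("ratios", {})),
            thresholds=ThresholdSet(**d.get("thresholds", {})),
            k=ParametricCoefficients(**d.get("k", {})),
            region=d.get("region", "edge"),
            seed=int(d.get("seed", 0)),
        )


def _normalize_cell(s: str) -> str:
    return s.replace("−", "-").strip()


def _canonical_columns(columns) -> dict[str, str]:
    """Map raw headers to canonical names; unknown headers map to None."""
    out = {}
    for col in columns:
        key = str(col).strip().lower()
        # strip unit suffixes like "(mmhg)" or "(mg/dl)"
        if "(" in key:
            key = key.split("(", 1)[0].strip()
        key = key.replace("*", "").strip()
        out[col] = _COLUMN_ALIASES.get(key)
    return out


def read_biometrics_csv(path) -> list[PatientBiometrics]:
    """Read a patient-characteristics table into typed records.

    Headers are matched case-insensitively with unit suffixes ignored;
    unknown columns are skipped with a warning on stderr; blank cells become
    missing values. A non-numeric cell in a numeric column raises with the
    row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = _canonical_columns(df.columns)
    unknown = [c for c, v in mapping.items() if v is None]
    if unknown:
        import sys

        print(f"warning: ignoring unknown column(s) {unknown} in {path}", file=sys.stderr)
    df = df.rename(columns=mapping)[[v for v in mapping.values() if v]]
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: no patient-id column found")
    records = []
    for idx, row in df.iterrows():
        kwargs = {"patient_id": str(row["patient_id"]).strip()}
        for col in _BIOMETRIC_NUMERIC:
            if col not in df.columns:
                continue
            cell = _normalize_cell(str(row[col]))
            if cell == "":
                continue
            try:
                kwargs[col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: row {idx + 2}, column {col!r}: "
                    f"cannot parse {cell!r} as a number"
                ) from None
        for col in _BIOMETRIC_CATEGORICAL:
            if col in df.columns:
                cell = str(row[col]).strip()
                if cell:
                    kwargs[col] = cell.lower() if col != "sex" else cell.upper()
        records.append(PatientBiometrics(**kwargs))
    return records


_LAB_PAIR_COLUMNS = ("L_sit", "a_sit", "b_sit", "L_sup", "a_sup", "b_sup")


def read_lab_pairs_csv(path) -> list[tuple[PositionMeasurement, PositionMeasurement]]:
    """Read paired sitting/supine Lab triples, one patient per row.

    Expects columns patient_id, L_sit, a_sit, b_sit, L_sup, a_sup, b_sup
    (case-sensitive on the Lab part, tolerant on patient id). Duplicate
    patient ids raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {str(c).strip(): c for c in df.columns}
    id_col = next(
        (cols[c] for c in cols if c.lower() in ("patient_id", "no", "id")), None
    )
    if id_col is None:
        raise ValueError(f"{path}: no patient-id column found")
    missing = [c for c in _LAB_PAIR_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    pairs = []
    seen = set()
    for idx, row in df.iterrows():
        pid = str(row[id_col]).strip()
        if pid in seen:
            raise ValueError(f"{path}: duplicate patient_id {pid!r} at row {idx + 2}")
        seen.add(pid)
        try:
            vals = [float(_normalize_cell(str(row[cols[c]]))) for c in _LAB_PAIR_COLUMNS]
        except ValueError:
            raise ValueError(
                f"{path}: row {idx + 2}: cannot parse Lab triple for patient {pid!r}"
            ) from None
        sit = PositionMeasurement(pid, "sitting", {"edge": LabColor(*vals[:3])})
        sup = PositionMeasurement(pid, "supine", {"edge": LabColor(*vals[3:])})
        pairs.append((sit, sup))
    return pairs


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float RGB in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_label_png(path, labels: np.ndarray) -> None:
    """Write a region label map (0 background, 1-4 regions) as 8-bit PNG."""
    iio.imwrite(path, np.asarray(labels, dtype=np.uint8))


def write_comparison_csv(path, comparisons: list[PatientComparison]) -> None:
    """Write a per-patient comparison table mirroring the standard report
    layout: sitting/supine triples, signed components, dE00, acceptability."""
    rows = []
    for c in comparisons:
        r = c.result
        row = {"patient_id": c.patient_id}
        if c.sitting is not None:
            row.update(L_sit=c.sitting.L, a_sit=c.sitting.a, b_sit=c.sitting.b)
        if c.supine is not None:
            row.update(L_sup=c.supine.L, a_sup=c.supine.a, b_sup=c.supine.b)
        row.update(
            dL_prime=round(r.dL_prime, 2),
            dC_prime=round(r.dC_prime, 2),
            dH_prime=round(r.dH_prime, 2),
            dE00=round(r.dE00, 1),
            acceptable=c.acceptable,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _example_path(name: str):
    return resources.files("tonguecolor.data").joinpath(name)


def load_example_biometrics() -> list[PatientBiometrics]:
    """The bundled 18-patient example cohort's characteristics table."""
    with resources.as_file(_example_path("example_cohort_biometrics.csv")) as p:
        return read_biometrics_csv(p)


def load_example_lab_pairs() -> list[tuple[PositionMeasurement, PositionMeasurement]]:
    """The bundled example cohort's paired sitting/supine edge Lab triples."""
    with resources.as_file(_example_path("example_cohort_lab_pairs.csv")) as p:
        return read_lab_pairs_csv(p)
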