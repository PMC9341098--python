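"""CSV ingestion and emission for per-eye biometry tables.

Dialect: header row, comma separator, decimal point, UTF-8, empty cells
for missing values.  Lines starting with '#' are provenance comments and
are skipped on read.  Recognised columns:

    participant_id, eye, k1_mm, k2_mm, k_mean_mm, k_power_d,
    sphere_d, cylinder_d, se_d, cycloplegic, al_act_mm, faza_mm2, sqi

Keratometry resolution order per row: k_mean_mm, else mean of
(k1_mm, k2_mm), else 337.5/k_power_d.  SE resolution: se_d, else
sphere_d + cylinder_d/2.  Column names are fixed; a rename map handles
user CSVs deterministically instead of header sniffing.
"""

from __future__ import annotations

import math
import os
import tempfile
from typing import List, Optional, Tuple

import pandas as pd

from .biometry import (
    BiometryRecord,
    Eye,
    diopters_to_radius_mm,
    mean_keratometry,
    spherical_equivalent,
)
from .errors import DataValidationError, InvalidMeasurementError

COLUMNS = [
    "participant_id", "eye", "k1_mm", "k2_mm", "k_mean_mm", "k_power_d",
    "sphere_d", "cylinder_d", "se_d", "cycloplegic", "al_act_mm",
    "faza_mm2", "sqi",
]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _get(row, col) -> Optional[float]:
    if col not in row or row[col] is None:
        return None
    v = row[col]
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and not v.strip():
        return None
    return float(v)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise InvalidMeasurementError(f"unparseable boolean: {value!r}")


def record_from_row(row: dict) -> BiometryRecord:
    """Build a BiometryRecord from one CSV row (a mapping)."""
    pid = str(row.get("participant_id", "")).strip()
    if not pid or pid == "nan":
        raise InvalidMeasurementError("missing participant_id")
    eye = Eye.parse(row.get("eye", ""))

    k_mean = _get(row, "k_mean_mm")
    if k_mean is None:
        k1, k2 = _get(row, "k1_mm"), _get(row, "k2_mm")
        if k1 is not None and k2 is not None:
            k_mean = mean_keratometry(k1, k2)
        else:
            k_power = _get(row, "k_power_d")
            if k_power is not None:
                k_mean = diopters_to_radius_mm(k_power)
    if k_mean is None:
        raise InvalidMeasurementError(f"{pid}: no keratometry column resolvable")

    sphere = _get(row, "sphere_d")
    cylinder = _get(row, "cylinder_d")
    se = _get(row, "se_d")
    if se is None:
        if sphere is not None and cylinder is not None:
            se = spherical_equivalent(sphere, cylinder)
        else:
            raise InvalidMeasurementError(f"{pid}: no spherical equivalent resolvable")

    sqi = _get(row, "sqi")
    return BiometryRecord(
        participant_id=pid,
        eye=eye,
        k_mean=k_mean,
        se=se,
        cycloplegic=_parse_bool(row.get("cycloplegic")),
        sphere=sphere,
        cylinder=cylinder,
        al_act=_get(row, "al_act_mm"),
        faza_measured=_get(row, "faza_mm2"),
        sqi=int(sqi) if sqi is not None else None,
    )


def read_biometry_csv(
    path,
    strict: bool = False,
    column_map: Optional[dict] = None,
) -> Tuple[List[BiometryRecord], List[Tuple[int, str]]]:
    """Read a biometry CSV.

    Returns ``(records, skipped)`` where ``skipped`` lists
    (1-based data row number, reason) for unparseable rows.  With
    ``strict`` the first bad row raises instead.
    """
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    records: List[BiometryRecord] = []
    skipped: List[Tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            records.append(record_from_row(row))
        except DataValidationError as exc:
            if strict:
                raise
            skipped.append((i, str(exc)))
    return records, skipped


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "eye": r.eye.value,
            "k_mean_mm": r.k_mean,
            "sphere_d": r.sphere,
            "cylinder_d": r.cylinder,
            "se_d": r.se,
            "cycloplegic": r.cycloplegic,
            "al_act_mm": r.al_act,
            "faza_mm2": r.faza_measured,
            "sqi": r.sqi,
        })
    return pd.DataFrame(rows)


def write_csv_atomic(df: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    """Write a CSV atomically (temp file + rename), with an optional
    '#'-prefixed provenance comment line."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
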