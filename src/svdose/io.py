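"""File formats: long-format dose-table CSV, precision-curve CSV, fit JSON.

Dose table: one row per SV, columns
``patient_id,kidney_side,filter_sigma_mm,sv_volume_ml,wkp_dose_gy,sv_index,sv_dose_gy,true_dose_gy``
with the WKP dose repeated on every row of a (patient, kidney, filter,
volume) group and ``sv_index`` 1-based; ``true_dose_gy`` is empty for real
data.  Floats are written with shortest round-trip (repr) formatting, so a
write/read cycle reproduces the records exactly.  All writers go through a
temp-file-then-rename so a failure never leaves a partial output file.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

from .cohort import CohortConfig
from .noise_model import KidneyRecord
from .powerlaw import PowerLawFit
from .precision_stats import PrecisionCurve

__all__ = [
    "DOSE_TABLE_COLUMNS",
    "read_dose_table",
    "write_dose_table",
    "read_curve",
    "write_curve",
    "read_fit",
    "write_fit",
    "read_config",
    "write_config",
]

DOSE_TABLE_COLUMNS = [
    "patient_id",
    "kidney_side",
    "filter_sigma_mm",
    "sv_volume_ml",
    "wkp_dose_gy",
    "sv_index",
    "sv_dose_gy",
    "true_dose_gy",
]

CURVE_COLUMNS = ["sv_volume_ml", "filter_sigma_mm", "k", "u_percent", "n_samples"]


def _atomic_write(path: str | Path, write_fn) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as handle:
            write_fn(handle)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_dose_table(records: Iterable[KidneyRecord], path: str | Path) -> None:
    """Write records as a long-format CSV, one row per SV, in deterministic
    (patient, kidney, filter, volume, sv_index) order."""
    ordered = sorted(
        records,
        key=lambda r: (r.patient_id, r.kidney_side, r.filter_sigma_mm, r.sv_volume_ml),
    )

    def write(handle):
        writer = csv.writer(handle)
        writer.writerow(DOSE_TABLE_COLUMNS)
        for rec in ordered:
            for i, sv in enumerate(rec.sv_doses_gy, start=1):
                writer.writerow(
                    [
                        rec.patient_id,
                        rec.kidney_side,
                        _fmt(rec.filter_sigma_mm),
                        _fmt(rec.sv_volume_ml),
                        _fmt(rec.wkp_dose_gy),
                        i,
                        _fmt(sv),
                        _fmt(rec.true_dose_gy),
                    ]
                )

    _atomic_write(path, write)


def read_dose_table(path: str | Path) -> list[KidneyRecord]:
    """Read a long-format dose table into KidneyRecords, grouping rows by
    (patient, kidney, filter, volume) and validating group consistency."""
    groups: dict[tuple, list[tuple[int, int, float, float | None]]] = {}
    wkp_by_group: dict[tuple, tuple[int, float]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != DOSE_TABLE_COLUMNS:
            raise ValueError(
                f"bad header: expected {','.join(DOSE_TABLE_COLUMNS)}, "
                f"got {','.join(reader.fieldnames or [])}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (
                    row["patient_id"],
                    row["kidney_side"],
                    float(row["filter_sigma_mm"]),
                    float(row["sv_volume_ml"]),
                )
                wkp = float(row["wkp_dose_gy"])
                sv_index = int(row["sv_index"])
                sv = float(row["sv_dose_gy"])
                true = float(row["true_dose_gy"]) if row["true_dose_gy"] else None
            except (KeyError, ValueError) as exc:
                raise ValueError(f"row {lineno}: unparseable field ({exc})") from exc
            if wkp <= 0 or sv <= 0:
                raise ValueError(f"row {lineno}: non-positive dose")
            if sv_index < 1:
                raise ValueError(f"row {lineno}: sv_index must be >= 1")
            if key in wkp_by_group and wkp_by_group[key][1] != wkp:
                first = wkp_by_group[key][0]
                raise ValueError(
                    f"row {lineno}: wkp_dose_gy {wkp!r} differs from row {first} "
                    f"({wkp_by_group[key][1]!r}) within group {key}"
                )
            wkp_by_group.setdefault(key, (lineno, wkp))
            groups.setdefault(key, []).append((sv_index, lineno, sv, true))

    records = []
    for key, rows in groups.items():
        rows.sort()
        indices = [r[0] for r in rows]
        if indices != list(range(1, len(rows) + 1)):
            raise ValueError(f"group {key}: sv_index values {indices} are not 1..{len(rows)}")
        trues = {r[3] for r in rows}
        if len(trues) > 1:
            raise ValueError(f"group {key}: inconsistent true_dose_gy values")
        records.append(
            KidneyRecord(
                patient_id=key[0],
                kidney_side=key[1],
                filter_sigma_mm=key[2],
                sv_volume_ml=key[3],
                wkp_dose_gy=wkp_by_group[key][1],
                sv_doses_gy=tuple(r[2] for r in rows),
                true_dose_gy=trues.pop(),
            )
        )
    return records


def write_curve(curve: PrecisionCurve, path: str | Path) -> None:
    vol, filt = curve.condition if curve.condition is not None else (float("nan"), float("nan"))

    def write(handle):
        writer = csv.writer(handle)
        writer.writerow(CURVE_COLUMNS)
        for k, u, n in zip(curve.k_values, curve.u_percent, curve.n_samples):
            writer.writerow([_fmt(vol), _fmt(filt), k, _fmt(u), n])

    _atomic_write(path, write)


def read_curve(path: str | Path) -> PrecisionCurve:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != CURVE_COLUMNS:
            raise ValueError(f"bad curve header: {reader.fieldnames}")
        rows = [
            (int(r["k"]), float(r["u_percent"]), int(r["n_samples"]),
             float(r["sv_volume_ml"]), float(r["filter_sigma_mm"]))
            for r in reader
        ]
    if not rows:
        raise ValueError("empty curve file")
    conditions = {(r[3], r[4]) for r in rows}
    cond = conditions.pop() if len(conditions) == 1 else None
    if cond is not None and any(c != c for c in cond):  # NaN marker: no condition
        cond = None
    return PrecisionCurve(
        k_values=tuple(r[0] for r in rows),
        u_percent=tuple(r[1] for r in rows),
        n_samples=tuple(r[2] for r in rows),
        condition=cond,
    )


def write_fit(fit: PowerLawFit, path: str | Path, extra: dict | None = None) -> None:
    payload = fit.to_dict()
    if extra:
        payload.update(extra)
    _atomic_write(path, lambda h: h.write(json.dumps(payload, indent=2) + "\n"))


def read_fit(path: str | Path) -> PowerLawFit:
    with open(path) as handle:
        return PowerLawFit.from_dict(json.load(handle))


def write_config(config: CohortConfig, path: str | Path) -> None:
    _atomic_write(path, lambda h: h.write(config.model_dump_json(indent=2) + "\n"))


def read_config(path: str | Path) -> CohortConfig:
    with open(path) as handle:
        return CohortConfig.model_validate_json(handle.read())
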