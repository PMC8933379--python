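"""Reading and writing the delimited-text study schema.

Concentration table columns: subject_id, sequence, period, treatment,
analyte, nominal_time_h, actual_time_h, conc_ng_ml, blq (0/1).
Dose table columns: subject_id, period, treatment, route, dose_mg,
infusion_duration_h (empty for oral rows).

Comma-separated, dot decimal, UTF-8. Parsing is strict: every malformed
field is reported with its 1-based file line number, and all offending
lines are listed before failing.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .datamodel import (
    Analyte,
    AnalyteSpec,
    ConcentrationPoint,
    DoseEvent,
    PKProfile,
    Route,
    Treatment,
    TreatmentSequence,
    ValidationError,
    validate_profile,
)
from .simulate import StudyData

CONC_COLUMNS = ["subject_id", "sequence", "period", "treatment", "analyte",
                "nominal_time_h", "actual_time_h", "conc_ng_ml", "blq"]
DOSE_COLUMNS = ["subject_id", "period", "treatment", "route", "dose_mg",
                "infusion_duration_h"]


class SchemaError(ValidationError):
    """Raised with a list of per-line problems."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def _read_table(path, columns: List[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError([f"{path}: missing column(s) {', '.join(missing)}"])
    return df


def _parse_float(raw: str, field: str, line: int, problems: List[str],
                 allow_empty: bool = False) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        if allow_empty:
            return None
        problems.append(f"line {line}: empty {field}")
        return None
    try:
        return float(raw)
    except ValueError:
        problems.append(f"line {line}: unparseable {field} {raw!r}")
        return None


def read_study(conc_path, dose_path,
               analyte_specs: Optional[Dict[str, AnalyteSpec]] = None
               ) -> List[PKProfile]:
    """Read and validate a study; returns validated profiles.

    Raises :class:`SchemaError` listing every offending line when any row
    fails to parse.
    """
    conc = _read_table(conc_path, CONC_COLUMNS)
    dose = _read_table(dose_path, DOSE_COLUMNS)
    problems: List[str] = []

    doses: Dict[Tuple[str, int], DoseEvent] = {}
    for i, row in dose.iterrows():
        line = i + 2  # header is line 1
        try:
            route = Route(row["route"].strip())
        except ValueError:
            problems.append(f"line {line}: unknown route {row['route']!r}")
            continue
        amt = _parse_float(row["dose_mg"], "dose_mg", line, problems)
        dur = _parse_float(row["infusion_duration_h"], "infusion_duration_h",
                           line, problems, allow_empty=True)
        period = _parse_float(row["period"], "period", line, problems)
        if amt is None or period is None:
            continue
        try:
            doses[(row["subject_id"].strip(), int(period))] = DoseEvent(
                route=route, amount=amt, infusion_duration=dur)
        except ValidationError as exc:
            problems.append(f"line {line}: {exc}")

    groups: Dict[Tuple[str, int, str], List] = {}
    meta: Dict[Tuple[str, int, str], Tuple] = {}
    for i, row in conc.iterrows():
        line = i + 2
        try:
            seq = TreatmentSequence(row["sequence"].strip())
            trt = Treatment(row["treatment"].strip())
            analyte = Analyte(row["analyte"].strip())
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
            continue
        period = _parse_float(row["period"], "period", line, problems)
        t_nom = _parse_float(row["nominal_time_h"], "nominal_time_h", line, problems)
        t_act = _parse_float(row["actual_time_h"], "actual_time_h", line, problems)
        c = _parse_float(row["conc_ng_ml"], "conc_ng_ml", line, problems)
        blq_raw = row["blq"].strip()
        if blq_raw not in ("0", "1"):
            problems.append(f"line {line}: blq must be 0 or 1, got {blq_raw!r}")
            continue
        if None in (period, t_nom, t_act, c):
            continue
        key = (row["subject_id"].strip(), int(period), analyte.value)
        groups.setdefault(key, []).append(
            ConcentrationPoint(t_nom, t_act, c, blq_raw == "1"))
        meta[key] = (seq, trt)
    if problems:
        raise SchemaError(problems)

    profiles: List[PKProfile] = []
    for key, points in groups.items():
        sid, period, analyte = key
        seq, trt = meta[key]
        dose_event = doses.get((sid, period))
        if dose_event is None:
            problems.append(f"missing dose row for subject {sid} period {period}")
            continue
        spec = (analyte_specs or {}).get(
            analyte, AnalyteSpec(name=analyte, molecular_weight=406.4))
        try:
            profiles.append(validate_profile(PKProfile(
                subject_id=sid, sequence=seq, period=period, treatment=trt,
                analyte=Analyte(analyte), dose=dose_event,
                points=tuple(points)), spec))
        except ValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise SchemaError(problems)
    profiles.sort(key=lambda p: (p.subject_id, p.period, p.analyte.value))
    return profiles


def study_frames(profiles) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Profiles -> (concentration table, dose table) DataFrames."""
    conc_rows, dose_rows, seen = [], [], set()
    for p in profiles:
        for pt in p.points:
            conc_rows.append(dict(
                subject_id=p.subject_id, sequence=p.sequence.value,
                period=p.period, treatment=p.treatment.value,
                analyte=p.analyte.value, nominal_time_h=pt.nominal_time,
                actual_time_h=pt.actual_time, conc_ng_ml=pt.concentration,
                blq=int(pt.blq)))
        key = (p.subject_id, p.period)
        if key not in seen:
            seen.add(key)
            dose_rows.append(dict(
                subject_id=p.subject_id, period=p.period,
                treatment=p.treatment.value, route=p.dose.route.value,
                dose_mg=p.dose.amount,
                infusion_duration_h=(
                    "" if p.dose.infusion_duration is None
                    else p.dose.infusion_duration)))
    return pd.DataFrame(conc_rows, columns=CONC_COLUMNS), \
        pd.DataFrame(dose_rows, columns=DOSE_COLUMNS)


def write_study(profiles, conc_path, dose_path) -> None:
    """Write profiles to the two-table text schema (round-trips read_study)."""
    conc, dose = study_frames(profiles)
    conc.to_csv(conc_path, index=False)
    dose.to_csv(dose_path, index=False)


def write_parameter_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)


def read_scenario(path) -> Dict[str, str]:
    """Parse a key = value scenario file (comments with '#')."""
    out: Dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path} line {i}: expected key = value")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
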