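"""Descriptive study summaries: geometric mean/CV, dose normalization,
and the per-treatment parameter table conventions (geometric mean and
geometric CV% for exposures, clearances and volumes; arithmetic mean +- SD
for the terminal half-life; median and range for Tmax)."""
from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import PKParameterSet, ValidationError


class SummaryConvention(str, Enum):
    GEO_MEAN_CV = "geo_mean_cv"
    ARITH_MEAN_SD = "arith_mean_sd"
    MEDIAN_RANGE = "median_range"


#: Reporting convention per parameter column.
PARAMETER_CONVENTIONS = {
    "cmax": SummaryConvention.GEO_MEAN_CV,
    "auc_last": SummaryConvention.GEO_MEAN_CV,
    "auc_inf": SummaryConvention.GEO_MEAN_CV,
    "cl_or_clf": SummaryConvention.GEO_MEAN_CV,
    "vz_or_vzf": SummaryConvention.GEO_MEAN_CV,
    "vss": SummaryConvention.GEO_MEAN_CV,
    "tmax": SummaryConvention.MEDIAN_RANGE,
    "t_half": SummaryConvention.ARITH_MEAN_SD,
}


@dataclass(frozen=True)
class SummaryRow:
    parameter: str
    treatment: str
    n: int
    point_estimate: float
    dispersion: Optional[object]  # CV% or SD (float) or (min, max) range
    convention: SummaryConvention


def geometric_summary(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Geometric mean and geometric CV% of a strictly positive sample.

    gm = exp(mean(ln x)); gcv% = 100*sqrt(exp(s^2) - 1) with s the sample
    (n-1 denominator) SD of ln x. For n = 1 the CV is undefined (None).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("geometric summary of an empty sample")
    if (x <= 0).any():
        raise ValidationError("geometric summary requires strictly positive values")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    if x.size == 1:
        return gm, None
    s2 = float(logs.var(ddof=1))
    return gm, 100.0 * float(np.sqrt(np.expm1(s2)))


def dose_normalize(params: PKParameterSet, reference_dose: float) -> PKParameterSet:
    """Scale exposure metrics to a common reference dose (linear kinetics).

    AUC_last, AUC_inf and Cmax are multiplied by reference_dose/administered
    dose; all other fields are untouched.
    """
    if params.dose_mg is None:
        raise ValidationError("dose normalization requires a recorded dose")
    f = reference_dose / params.dose_mg
    return replace(
        params,
        cmax=params.cmax * f,
        auc_last=params.auc_last * f,
        auc_inf=None if params.auc_inf is None else params.auc_inf * f,
        dose_normalized_to=reference_dose,
    )


def summarize_study(
    table: pd.DataFrame,
    parameters: Optional[Iterable[str]] = None,
) -> List[SummaryRow]:
    """Per-treatment summary rows from a parameter table.

    ``table`` holds one row per subject-treatment with a ``treatment``
    column and parameter columns named as in :data:`PARAMETER_CONVENTIONS`;
    missing (NaN) parameter values are excluded from that parameter's n.
    """
    if table.empty:
        raise ValidationError("empty parameter table")
    if parameters is None:
        parameters = [p for p in PARAMETER_CONVENTIONS if p in table.columns]
    rows: List[SummaryRow] = []
    for treatment, grp in table.groupby("treatment", sort=False):
        if grp.empty:
            raise ValidationError(f"empty treatment group {treatment!r}")
        for param in parameters:
            conv = PARAMETER_CONVENTIONS[param]
            vals = grp[param].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            if conv is SummaryConvention.GEO_MEAN_CV:
                gm, gcv = geometric_summary(vals)
                rows.append(SummaryRow(param, str(treatment), vals.size, gm, gcv, conv))
            elif conv is SummaryConvention.ARITH_MEAN_SD:
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
                rows.append(SummaryRow(param, str(treatment), vals.size,
                                       float(np.mean(vals)), sd, conv))
            else:
                rows.append(SummaryRow(
                    param, str(treatment), vals.size, float(np.median(vals)),
                    (float(vals.min()), float(vals.max())), conv,
                ))
    return rows


def summary_frame(rows: List[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a tidy DataFrame (dispersion split into columns)."""
    recs = []
    for r in rows:
        lo = hi = cv = sd = None
        if r.convention is SummaryConvention.MEDIAN_RANGE and r.dispersion:
            lo, hi = r.dispersion
        elif r.convention is SummaryConvention.GEO_MEAN_CV:
            cv = r.dispersion
        elif r.convention is SummaryConvention.ARITH_MEAN_SD:
            sd = r.dispersion
        recs.append(dict(parameter=r.parameter, treatment=r.treatment, n=r.n,
                         convention=r.convention.value,
                         point_estimate=r.point_estimate,
                         geo_cv_pct=cv, sd=sd, range_min=lo, range_max=hi))
    return pd.DataFrame.from_records(recs)


def round_sig(x: float, sig: int = 4) -> float:
    """Round to ``sig`` significant figures (report output only)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def summary_markdown(rows: List[SummaryRow], sig: int = 4) -> str:
    """Markdown rendering of the summary table, one row per parameter."""
    df = summary_frame(rows)
    lines = ["| parameter | treatment | n | estimate | dispersion |",
             "|---|---|---|---|---|"]
    for _, r in df.iterrows():
        if r["convention"] == "geo_mean_cv":
            disp = "" if r["geo_cv_pct"] is None else f"{r['geo_cv_pct']:.0f}% gCV"
        elif r["convention"] == "arith_mean_sd":
            disp = "" if r["sd"] is None else f"± {round_sig(r['sd'], sig)}"
        else:
            disp = f"({round_sig(r['range_min'], sig)}–{round_sig(r['range_max'], sig)})"
        lines.append(
            f"| {r['parameter']} | {r['treatment']} | {r['n']} | "
            f"{round_sig(r['point_estimate'], sig)} | {disp} |"
        )
    return "\n".join(lines)
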