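"""Non-compartmental analysis of a single concentration-time profile.

Implements terminal-phase (lambda-z) estimation by best-fit window search,
linear and linear-up/log-down trapezoidal AUC/AUMC, extrapolation to
infinity, and the derived exposure/disposition parameters (Cmax, Tmax,
AUC_last, AUC_inf, t1/2, CL or CL/F, Vz or Vz/F, and for IV infusions MRT
and Vss with the T_I/2 infusion correction).

BLQ samples enter as zero concentrations; AUC_last runs from the first
sample to the last quantifiable (positive) one. Terminal-phase-dependent
parameters are reported only when the phase is well characterized: at least
three regression points, r^2 >= 0.9, and extrapolated area <= 20% of
AUC_inf (boundary values accepted).
"""
from __future__ import annotations

import math
from dataclasses import replace
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    AnalyteSpec,
    DoseEvent,
    PKParameterSet,
    PKProfile,
    Route,
    TerminalPhaseFit,
    ValidationError,
)

MG_TO_NG = 1.0e6
ML_PER_L = 1.0e3

#: Gating rules for a well-characterized terminal phase.
MIN_LAMBDA_Z_POINTS = 3
R_SQUARED_THRESHOLD = 0.9
MAX_EXTRAPOLATION_PCT = 20.0


class TrapezoidPolicy(str, Enum):
    """AUC interval rule.

    ``linear`` applies the arithmetic-mean chord everywhere.
    ``linear_up_log_down`` (industry default) applies the logarithmic rule on
    strictly declining, strictly positive segments and the linear rule
    otherwise (rising, flat, or touching zero).
    """

    LINEAR = "linear"
    LINEAR_UP_LOG_DOWN = "linear_up_log_down"


def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> Tuple[float, float, float]:
    """OLS of ln(c) on t; returns (slope, intercept, r_squared)."""
    y = np.log(c)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def estimate_terminal_phase(
    profile: PKProfile,
    *,
    exclude_tmax: bool = True,
    min_points: int = MIN_LAMBDA_Z_POINTS,
    r2_threshold: float = R_SQUARED_THRESHOLD,
    manual_window: Optional[Tuple[float, float]] = None,
) -> TerminalPhaseFit:
    """Fit the terminal elimination rate constant by log-linear regression.

    Candidate windows are contiguous runs of quantifiable points ending at
    the last quantifiable sample and starting strictly after Tmax (Tmax
    itself excluded by default). Among windows with ``min_points`` or more
    points and a negative slope, the one maximizing adjusted r^2 is chosen;
    ties go to the window with more points. ``manual_window=(t_lo, t_hi)``
    overrides the search and uses the quantifiable points inside [t_lo, t_hi].

    Never raises on numeric data: an inestimable phase comes back with
    ``well_characterized=False`` and a reason.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    pos = c > 0
    if not pos.any():
        return TerminalPhaseFit(None, None, None, 0, None, None, False,
                                "no quantifiable concentrations")
    t_last = float(t[pos][-1])

    if manual_window is not None:
        lo, hi = manual_window
        sel = pos & (t >= lo) & (t <= hi)
        candidates = [np.flatnonzero(sel)] if sel.sum() >= 2 else []
        if not candidates:
            return TerminalPhaseFit(None, None, None, int(sel.sum()), None, None,
                                    False, "insufficient points")
    else:
        imax = int(np.argmax(c))  # Tmax: first occurrence of the maximum
        tail = np.flatnonzero(pos & (np.arange(len(t)) > (imax if exclude_tmax else imax - 1)))
        if len(tail) < min_points:
            n = len(tail)
            return TerminalPhaseFit(None, None, None, n, None, None, False,
                                    "insufficient points")
        candidates = [tail[i:] for i in range(len(tail) - min_points + 1)]

    best = None  # (adj_r2, n, slope, intercept, r2, idx)
    for idx in candidates:
        ts, cs = t[idx], c[idx]
        n = len(idx)
        slope, intercept, r2 = _loglinear_fit(ts, cs)
        if slope >= 0:
            continue
        adj_r2 = r2 if n <= 2 else 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        key = (adj_r2, n)
        if best is None or key > best[0]:
            best = (key, slope, intercept, r2, idx)
    if best is None:
        return TerminalPhaseFit(None, None, None, 0, None, None, False,
                                "no declining terminal phase")

    _, slope, intercept, r2, idx = best
    n = len(idx)
    kel = -slope
    c_last_pred = math.exp(intercept + slope * t_last)
    window = (float(t[idx][0]), float(t[idx][-1]))
    ok = n >= min_points and r2 >= r2_threshold
    reason = "" if ok else (
        "insufficient points" if n < min_points else
        f"r_squared {r2:.4f} below {r2_threshold}"
    )
    return TerminalPhaseFit(
        kel=kel, intercept_ln=float(intercept), r_squared=r2, n_points=n,
        time_range=window, c_last_pred=c_last_pred,
        well_characterized=ok, reason=reason,
    )


def _interval_auc(t1, t2, c1, c2, policy: TrapezoidPolicy) -> float:
    dt = t2 - t1
    if (
        policy is TrapezoidPolicy.LINEAR_UP_LOG_DOWN
        and c1 > 0.0 and c2 > 0.0 and c2 < c1
    ):
        return dt * (c1 - c2) / math.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def _interval_aumc(t1, t2, c1, c2, policy: TrapezoidPolicy) -> float:
    dt = t2 - t1
    if (
        policy is TrapezoidPolicy.LINEAR_UP_LOG_DOWN
        and c1 > 0.0 and c2 > 0.0 and c2 < c1
    ):
        k = math.log(c1 / c2) / dt
        return (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
    return dt * 0.5 * (t1 * c1 + t2 * c2)


def auc_trapezoidal(
    times: Sequence[float],
    concentrations: Sequence[float],
    policy: TrapezoidPolicy = TrapezoidPolicy.LINEAR_UP_LOG_DOWN,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> float:
    """Trapezoidal AUC over [t_start, t_end] (both must be observation times).

    The logarithmic rule is applied only between two strictly positive,
    strictly decreasing concentrations under ``linear_up_log_down``; any
    segment touching zero uses the linear rule.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t_start is None:
        t_start = float(t[0])
    if t_end is None:
        t_end = float(t[-1])
    if t_start >= t_end:
        raise ValidationError("t_start must be < t_end")
    i0 = np.flatnonzero(np.isclose(t, t_start))
    i1 = np.flatnonzero(np.isclose(t, t_end))
    if len(i0) == 0 or len(i1) == 0:
        raise ValidationError("t_start and t_end must be observation times")
    i0, i1 = int(i0[0]), int(i1[0])
    total = 0.0
    for j in range(i0, i1):
        total += _interval_auc(t[j], t[j + 1], c[j], c[j + 1], policy)
    return total


def aumc_trapezoidal(
    times: Sequence[float],
    concentrations: Sequence[float],
    policy: TrapezoidPolicy = TrapezoidPolicy.LINEAR_UP_LOG_DOWN,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> float:
    """Trapezoidal area under the first-moment curve t*C(t)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t_start is None:
        t_start = float(t[0])
    if t_end is None:
        t_end = float(t[-1])
    if t_start >= t_end:
        raise ValidationError("t_start must be < t_end")
    i0 = int(np.flatnonzero(np.isclose(t, t_start))[0])
    i1 = int(np.flatnonzero(np.isclose(t, t_end))[0])
    total = 0.0
    for j in range(i0, i1):
        total += _interval_aumc(t[j], t[j + 1], c[j], c[j + 1], policy)
    return total


def extrapolate_auc_inf(
    auc_last: float, fit: TerminalPhaseFit
) -> Tuple[float, float]:
    """AUC to infinity: AUC_last + C_last_pred/kel, and the extrapolated %.

    ``C_last_pred`` is the regression-predicted concentration at the last
    quantifiable time, not the observed one.
    """
    if fit.kel is None or fit.kel <= 0:
        raise ValidationError("extrapolation requires kel > 0")
    if auc_last <= 0:
        raise ValidationError("extrapolation requires auc_last > 0")
    c_last = fit.c_last_pred or 0.0
    auc_inf = auc_last + c_last / fit.kel
    extrap = 100.0 * (auc_inf - auc_last) / auc_inf
    return auc_inf, extrap


def clearance(dose_mg: float, auc_inf: float) -> float:
    """CL (IV) or CL/F (oral) in L/h from dose in mg and AUC in ng*h/mL."""
    return dose_mg * MG_TO_NG / auc_inf / ML_PER_L


def compute_pk_parameters(
    profile: PKProfile,
    fit: Optional[TerminalPhaseFit] = None,
    policy: TrapezoidPolicy = TrapezoidPolicy.LINEAR_UP_LOG_DOWN,
) -> PKParameterSet:
    """Assemble the full per-profile parameter set.

    Cmax and Tmax come from observed values. AUC_last runs to the last
    quantifiable concentration. When ``fit`` is well characterized and the
    extrapolated fraction is within bounds, AUC_inf, t1/2, CL (or CL/F),
    Vz (or Vz/F), and for IV infusions MRT = AUMC_inf/AUC_inf - T_I/2 and
    Vss = CL*MRT are filled in; otherwise those fields stay ``None`` and
    ``reason`` says why.
    """
    if fit is None:
        fit = estimate_terminal_phase(profile)
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    pos = np.flatnonzero(c > 0)
    if len(pos) == 0:
        raise ValidationError(f"no quantifiable concentrations in {profile.label()}")
    t_last = float(t[pos[-1]])
    auc_last = (
        0.0 if t_last <= float(t[0])
        else auc_trapezoidal(t, c, policy, float(t[0]), t_last)
    )

    base = dict(cmax=cmax, tmax=tmax, auc_last=auc_last,
                dose_mg=profile.dose.amount)
    if not fit.well_characterized:
        return PKParameterSet(**base, well_characterized=False,
                              reason=fit.reason or "terminal phase not characterized")

    auc_inf, extrap = extrapolate_auc_inf(auc_last, fit)
    if extrap > MAX_EXTRAPOLATION_PCT:
        return PKParameterSet(
            **base, well_characterized=False,
            reason=f"extrapolated area {extrap:.1f}% exceeds {MAX_EXTRAPOLATION_PCT:g}%",
        )

    kel = fit.kel
    cl = clearance(profile.dose.amount, auc_inf)
    vz = cl / kel
    mrt = vss = None
    if profile.dose.route is Route.IV_INFUSION:
        aumc_last = aumc_trapezoidal(t, c, policy, float(t[0]), t_last)
        c_pred = fit.c_last_pred or 0.0
        aumc_inf = aumc_last + c_pred * t_last / kel + c_pred / kel**2
        mrt = aumc_inf / auc_inf - profile.dose.infusion_duration / 2.0
        vss = cl * mrt
    return PKParameterSet(
        **base,
        auc_inf=auc_inf,
        auc_extrap_pct=extrap,
        t_half=math.log(2.0) / kel,
        cl_or_clf=cl,
        vz_or_vzf=vz,
        vss=vss,
        mrt=mrt,
        well_characterized=True,
    )


def metabolite_parent_ratio(
    auc_metabolite: float,
    auc_parent: float,
    spec_metabolite: AnalyteSpec,
    spec_parent: AnalyteSpec,
) -> float:
    """Molar metabolite-to-parent AUC ratio, adjusted for molecular weights."""
    if auc_parent <= 0:
        raise ValidationError("parent AUC must be > 0")
    return (auc_metabolite / spec_metabolite.molecular_weight) / (
        auc_parent / spec_parent.molecular_weight
    )
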