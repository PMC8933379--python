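"""Domain types and validation for crossover PK datasets.

Units are fixed package-wide: time in hours, concentration in ng/mL, dose in
mg, clearance in L/h, volume in L. Conversions (mg -> ng, L -> mL) happen only
inside the formulas that need them, never in stored data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Tuple


class Route(str, Enum):
    ORAL = "oral"
    IV_INFUSION = "iv_infusion"


class Treatment(str, Enum):
    ORAL = "oral"
    IV = "iv"


class TreatmentSequence(str, Enum):
    IV_THEN_ORAL = "IV_then_oral"
    ORAL_THEN_IV = "oral_then_IV"

    def treatment_in_period(self, period: int) -> Treatment:
        order = (
            (Treatment.IV, Treatment.ORAL)
            if self is TreatmentSequence.IV_THEN_ORAL
            else (Treatment.ORAL, Treatment.IV)
        )
        return order[period - 1]


class Analyte(str, Enum):
    PARENT = "parent"
    METABOLITE = "metabolite"


class ValidationError(ValueError):
    """Raised when a profile or table violates the data contract."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Assay/compound constants for one analyte."""

    name: str
    molecular_weight: float  # g/mol
    lloq: float = 2.50  # ng/mL

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValidationError("molecular_weight must be > 0")
        if self.lloq <= 0:
            raise ValidationError("lloq must be > 0")


@dataclass(frozen=True)
class DoseEvent:
    """A single dose administration.

    For a constant-rate infusion, ``infusion_duration`` is the infusion
    length T_I in hours; oral doses have no duration.
    """

    route: Route
    amount: float  # mg
    infusion_duration: Optional[float] = None  # h
    start_time: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError("dose amount must be > 0 mg")
        if self.route is Route.IV_INFUSION:
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise ValidationError(
                    "iv_infusion dose requires infusion_duration > 0 h"
                )
        elif self.infusion_duration is not None:
            raise ValidationError("oral dose must not carry an infusion_duration")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h (infusion doses only)."""
        if self.route is not Route.IV_INFUSION:
            raise ValidationError("rate is defined only for infusion doses")
        return self.amount / self.infusion_duration  # type: ignore[operator]


@dataclass(frozen=True)
class ConcentrationPoint:
    nominal_time: float  # h
    actual_time: float  # h
    concentration: float  # ng/mL
    blq: bool = False

    def __post_init__(self) -> None:
        if self.actual_time < 0:
            raise ValidationError("actual_time must be >= 0")


@dataclass(frozen=True)
class PKProfile:
    """One analyte's concentration-time series for one subject-period."""

    subject_id: str
    sequence: TreatmentSequence
    period: int
    treatment: Treatment
    analyte: Analyte
    dose: DoseEvent
    points: Tuple[ConcentrationPoint, ...]

    def __post_init__(self) -> None:
        if self.period not in (1, 2):
            raise ValidationError("period must be 1 or 2")
        if not self.points:
            raise ValidationError("profile must contain at least one point")
        expected_route = (
            Route.ORAL if self.treatment is Treatment.ORAL else Route.IV_INFUSION
        )
        if self.dose.route is not expected_route:
            raise ValidationError(
                f"treatment {self.treatment.value!r} inconsistent with dose route "
                f"{self.dose.route.value!r}"
            )
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def times(self):
        return tuple(p.actual_time for p in self.points)

    @property
    def concentrations(self):
        return tuple(p.concentration for p in self.points)

    def label(self) -> str:
        return f"subject {self.subject_id} period {self.period} ({self.analyte.value})"


@dataclass(frozen=True)
class TerminalPhaseFit:
    """Log-linear regression over the terminal phase.

    ``kel`` is the terminal elimination rate constant (negated slope of
    ln C vs t); ``c_last_pred`` is the regression-predicted concentration at
    the last quantifiable time. ``well_characterized`` applies the gating
    rules n >= 3 and r^2 >= 0.9 (the extrapolation-fraction rule is applied
    downstream once AUC_inf is known).
    """

    kel: Optional[float]  # 1/h
    intercept_ln: Optional[float]  # ln(ng/mL)
    r_squared: Optional[float]
    n_points: int
    time_range: Optional[Tuple[float, float]]  # h
    c_last_pred: Optional[float]  # ng/mL
    well_characterized: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.well_characterized:
            if self.kel is None or self.kel <= 0:
                raise ValidationError("well-characterized fit requires kel > 0")
            if self.n_points < 3:
                raise ValidationError("well-characterized fit requires >= 3 points")

    @property
    def t_half(self) -> Optional[float]:
        import math

        return math.log(2.0) / self.kel if self.kel and self.kel > 0 else None


@dataclass(frozen=True)
class PKParameterSet:
    """Per-profile NCA outputs (one Table-2 row before summarisation).

    Terminal-phase-dependent fields (auc_inf, t_half, cl_or_clf, vz_or_vzf,
    vss, mrt) are ``None`` unless the terminal phase was well characterized.
    """

    cmax: float  # ng/mL
    tmax: float  # h, an observed sampling time
    auc_last: float  # ng*h/mL
    auc_inf: Optional[float] = None
    auc_extrap_pct: Optional[float] = None
    t_half: Optional[float] = None  # h
    cl_or_clf: Optional[float] = None  # L/h
    vz_or_vzf: Optional[float] = None  # L
    vss: Optional[float] = None  # L, IV only
    mrt: Optional[float] = None  # h, IV only
    dose_mg: Optional[float] = None
    dose_normalized_to: Optional[float] = None  # mg
    well_characterized: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.auc_inf is not None and self.auc_inf < self.auc_last - 1e-9:
            raise ValidationError("auc_inf must be >= auc_last")
        if self.auc_extrap_pct is not None and not (
            0.0 <= self.auc_extrap_pct <= 100.0
        ):
            raise ValidationError("auc_extrap_pct must lie in [0, 100]")


def validate_profile(profile: PKProfile, spec: AnalyteSpec) -> PKProfile:
    """Return a cleaned copy of ``profile`` ready for NCA.

    Points are sorted by actual time, BLQ concentrations are set to 0, and the
    oral pre-dose sample is checked for carryover. Idempotent: validating a
    validated profile returns an equal profile.

    Raises
    ------
    ValidationError
        On duplicate sampling times, negative concentrations, or a
        quantifiable oral pre-dose concentration (carryover violation).
    """
    pts = sorted(profile.points, key=lambda p: p.actual_time)
    for a, b in zip(pts, pts[1:]):
        if b.actual_time <= a.actual_time:
            raise ValidationError(
                f"duplicate sampling time {b.actual_time} h in {profile.label()}"
            )
    cleaned = []
    for p in pts:
        conc = p.concentration
        if conc < 0:
            raise ValidationError(
                f"negative concentration {conc} at t={p.actual_time} h "
                f"in {profile.label()}"
            )
        if p.blq:
            conc = 0.0
        elif (
            profile.treatment is Treatment.ORAL
            and p.actual_time == pts[0].actual_time
            and p.actual_time <= 0.0
            and conc > 0
        ):
            raise ValidationError(
                f"carryover violation: quantifiable pre-dose concentration "
                f"{conc} ng/mL in {profile.label()}"
            )
        cleaned.append(replace(p, concentration=conc))
    return replace(profile, points=tuple(cleaned))
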