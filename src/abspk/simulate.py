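"""Synthetic two-sequence, two-period crossover PK studies.

Closed-form one- and two-compartment disposition (first-order oral
absorption, constant-rate IV infusion) with lognormal between-subject
variability on clearance and volumes, proportional residual error, and
LLOQ censoring. A subject's disposition parameters are shared across the
two periods, so the only within-subject variability between periods is
residual (assay/occasion) error — the correlation structure the crossover
analysis exploits.

Defaults emulate a healthy-volunteer absolute-bioavailability study of a
slowly eliminated oral kinase inhibitor: 100 mg oral vs 50 mg IV infused
over 1.25 h, sampling out to 144 h, LLOQ 2.5 ng/mL, typical CL 9.713 L/h,
Vss ~305 L, terminal half-life ~25 h, Tmax ~1.5 h, exposure CV ~30-38%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

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
)

ORAL_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 12.0, 24.0, 48.0, 72.0,
              96.0, 120.0, 144.0)
IV_TIMES = (0.0, 0.75, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0, 12.0, 24.0, 48.0,
            72.0, 96.0, 120.0, 144.0)


@dataclass(frozen=True)
class PopulationModel:
    """Population PK model generating individual profiles.

    ``omega_ln`` maps parameter names (cl, v_central, v_peripheral, q, ka)
    to between-subject ln-scale SDs; unlisted parameters have no BSV.
    ``sigma_prop`` is the proportional residual error SD applied
    multiplicatively to every sampled concentration (assay error).
    ``omega_iov_exposure`` is the inter-occasion ln-scale SD of a whole-period
    exposure multiplier — the dominant component of the within-subject SD of
    ln AUC that the crossover design's sample-size reasoning is built on.
    """

    n_compartments: int = 2
    cl_typ: float = 9.713  # L/h
    v_central_typ: float = 100.0  # L
    v_peripheral_typ: float = 205.0  # L
    q_intercompartmental: float = 30.0  # L/h
    ka_typ: float = 0.9  # 1/h
    f_oral_true: float = 0.81
    omega_ln: Dict[str, float] = field(
        default_factory=lambda: {"cl": 0.30, "v_central": 0.30,
                                 "v_peripheral": 0.30}
    )
    sigma_prop: float = 0.06
    omega_iov_exposure: float = 0.10
    lloq: float = 2.50  # ng/mL
    # metabolite side-model (first-order formation fraction of CL)
    metabolite_fraction: float = 0.21
    metabolite_v: float = 60.0  # L
    metabolite_k: float = 0.08  # 1/h
    mw_parent: float = 406.4  # g/mol
    mw_metabolite: float = 203.2  # g/mol

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValidationError("n_compartments must be 1 or 2")
        if not 0 < self.f_oral_true <= 1:
            raise ValidationError("f_oral_true must lie in (0, 1]")
        for name, val in (("cl_typ", self.cl_typ),
                          ("v_central_typ", self.v_central_typ),
                          ("ka_typ", self.ka_typ)):
            if val <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class IndividualPK:
    """One subject's realized disposition parameters."""

    cl: float
    v_central: float
    v_peripheral: float = 0.0
    q: float = 0.0
    ka: float = 2.0
    f_oral: float = 1.0
    n_compartments: int = 1


@dataclass(frozen=True)
class StudyTemplate:
    n_subjects: int = 12
    sequence_allocation: Optional[Sequence[str]] = None  # per-subject codes
    oral_times: Sequence[float] = ORAL_TIMES
    iv_times: Sequence[float] = IV_TIMES
    oral_dose_mg: float = 100.0
    iv_dose_mg: float = 50.0
    infusion_duration_h: float = 1.25
    washout_days: float = 10.0
    period2_exposure_ratio: float = 1.0  # multiplicative period effect
    sequence_exposure_ratio: float = 1.0  # multiplicative sequence effect
    seed: int = 0

    def __post_init__(self) -> None:
        for times in (self.oral_times, self.iv_times):
            arr = np.asarray(times, dtype=float)
            if (arr < 0).any() or (np.diff(arr) <= 0).any():
                raise ValidationError("sampling times must be nonnegative, increasing")
        if self.washout_days < 10:
            raise ValidationError("washout must be at least 10 days")

    def allocation(self) -> List[TreatmentSequence]:
        if self.sequence_allocation is not None:
            return [TreatmentSequence(s) for s in self.sequence_allocation]
        if self.n_subjects % 2:
            raise ValidationError(
                "odd n_subjects requires an explicit sequence_allocation"
            )
        half = self.n_subjects // 2
        return ([TreatmentSequence.IV_THEN_ORAL] * half
                + [TreatmentSequence.ORAL_THEN_IV] * half)


def _macro_constants(p: IndividualPK) -> Tuple[float, float, float, float]:
    """(alpha, beta, A, B): unit-bolus bi-exponential macro constants (per L)."""
    k10 = p.cl / p.v_central
    k12 = p.q / p.v_central
    k21 = p.q / p.v_peripheral
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    A = (alpha - k21) / (p.v_central * (alpha - beta))
    B = (k21 - beta) / (p.v_central * (alpha - beta))
    return alpha, beta, A, B


def _bolus_terms(p: IndividualPK) -> List[Tuple[float, float]]:
    """Unit IV bolus response as a sum of (coefficient per L, rate) terms."""
    if p.n_compartments == 1:
        return [(1.0 / p.v_central, p.cl / p.v_central)]
    alpha, beta, A, B = _macro_constants(p)
    return [(A, alpha), (B, beta)]


def disposition_concentration(
    params: IndividualPK, dose: DoseEvent, t
) -> np.ndarray:
    """Exact closed-form plasma concentration (ng/mL) at time(s) ``t``.

    Oral: first-order absorption into the central compartment (ka = k
    handled by the limiting form). IV: zero-order infusion over T_I by
    superposition of the bolus exponentials.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValidationError("time must be >= 0")
    dose_ng = dose.amount * 1.0e6  # mg -> ng; volumes in L -> ng/L
    terms = _bolus_terms(params)

    if dose.route is Route.IV_INFUSION:
        t_i = dose.infusion_duration
        rate = dose_ng / t_i  # ng/h
        c = np.zeros_like(t)
        for coef, lam in terms:
            during = (rate * coef / lam) * (1.0 - np.exp(-lam * np.minimum(t, t_i)))
            after = np.where(
                t > t_i, np.exp(-lam * np.clip(t - t_i, 0.0, None)), 1.0
            )
            c = c + during * after
    else:
        ka = params.ka
        c = np.zeros_like(t)
        for coef, lam in terms:
            if abs(ka - lam) < 1e-12 * max(ka, lam):
                # limiting form: ka == lambda
                c = c + params.f_oral * dose_ng * coef * ka * t * np.exp(-lam * t)
            else:
                c = c + (
                    params.f_oral * dose_ng * coef * ka / (ka - lam)
                ) * (np.exp(-lam * t) - np.exp(-ka * t))
    return c / 1.0e3  # ng/L -> ng/mL


def metabolite_concentration(
    params: IndividualPK,
    dose: DoseEvent,
    t,
    population: PopulationModel,
    grid_points: int = 4000,
) -> np.ndarray:
    """Metabolite plasma concentration under first-order formation.

    The metabolite is formed at rate fm*CL*Cp(t) and eliminated first-order
    (rate k_m, volume V_m). The amount is propagated on a dense grid with
    exact exponential decay between grid nodes and trapezoidal input, then
    interpolated at ``t``; exact in the fine-grid limit for any route.
    """
    t = np.asarray(t, dtype=float)
    t_max = float(t.max()) if t.size else 0.0
    if t_max == 0.0:
        return np.zeros_like(t)
    # molar correction: formation converts parent mass to metabolite mass
    mw_ratio = population.mw_metabolite / population.mw_parent
    grid = np.linspace(0.0, t_max, grid_points)
    cp = disposition_concentration(params, dose, grid)  # ng/mL
    km = population.metabolite_k
    fm_cl = population.metabolite_fraction * params.cl * mw_ratio
    rate_in = fm_cl * cp * 1.0e3  # (L/h)*(ng/mL)=ng*L/(mL*h) -> ng/h
    dt = grid[1] - grid[0]
    decay = math.exp(-km * dt)
    amount = np.zeros_like(grid)
    for i in range(1, grid_points):
        amount[i] = amount[i - 1] * decay + dt * 0.5 * (
            rate_in[i - 1] * decay + rate_in[i]
        )
    cm = amount / (population.metabolite_v * 1.0e3)  # ng / mL
    return np.interp(t, grid, cm)


def draw_individual(
    population: PopulationModel, rng: np.random.Generator
) -> IndividualPK:
    """Draw one subject's parameters lognormally around the typicals."""
    def draw(typ: float, name: str) -> float:
        om = population.omega_ln.get(name, 0.0)
        return typ * math.exp(rng.normal(0.0, om)) if om > 0 else typ

    return IndividualPK(
        cl=draw(population.cl_typ, "cl"),
        v_central=draw(population.v_central_typ, "v_central"),
        v_peripheral=draw(population.v_peripheral_typ, "v_peripheral"),
        q=draw(population.q_intercompartmental, "q"),
        ka=draw(population.ka_typ, "ka"),
        f_oral=population.f_oral_true,
        n_compartments=population.n_compartments,
    )


def simulate_subject_profile(
    population: PopulationModel,
    individual: IndividualPK,
    dose: DoseEvent,
    times: Sequence[float],
    rng: np.random.Generator,
    *,
    subject_id: str = "S1",
    sequence: TreatmentSequence = TreatmentSequence.IV_THEN_ORAL,
    period: int = 1,
    analyte: Analyte = Analyte.PARENT,
    exposure_multiplier: float = 1.0,
) -> PKProfile:
    """Sample one observed profile: model + proportional error + LLOQ.

    Observed concentration is model*(1 + eps), eps ~ N(0, sigma_prop),
    truncated below at 0; values under the LLOQ are flagged BLQ and stored
    as 0. With sigma_prop = 0 and lloq = 0 the profile equals the model
    exactly.
    """
    times = np.asarray(times, dtype=float)
    if analyte is Analyte.METABOLITE:
        c_model = metabolite_concentration(individual, dose, times, population)
    else:
        c_model = disposition_concentration(individual, dose, times)
    c_model = c_model * exposure_multiplier
    if population.sigma_prop > 0:
        eps = rng.normal(0.0, population.sigma_prop, size=times.shape)
        c_obs = np.maximum(c_model * (1.0 + eps), 0.0)
    else:
        c_obs = c_model.copy()
    points = []
    for tt, cc in zip(times, c_obs):
        blq = cc < population.lloq
        points.append(ConcentrationPoint(
            nominal_time=float(tt), actual_time=float(tt),
            concentration=0.0 if blq else float(cc), blq=bool(blq),
        ))
    treatment = Treatment.IV if dose.route is Route.IV_INFUSION else Treatment.ORAL
    return PKProfile(
        subject_id=subject_id, sequence=sequence, period=period,
        treatment=treatment, analyte=analyte, dose=dose, points=tuple(points),
    )


@dataclass(frozen=True)
class StudyData:
    """A complete simulated crossover study."""

    profiles: Tuple[PKProfile, ...]
    template: StudyTemplate
    population: PopulationModel
    individuals: Tuple[IndividualPK, ...] = ()


def simulate_crossover_study(
    template: StudyTemplate,
    population: PopulationModel,
    include_metabolite: bool = False,
) -> StudyData:
    """Simulate the full two-period study.

    Each subject gets an independent RNG substream spawned from the study
    seed, so adding subjects never perturbs existing ones. Disposition
    parameters are drawn once per subject and reused in both periods;
    optional period/sequence effects and the inter-occasion exposure
    multiplier enter as multiplicative shifts on the whole profile.
    """
    allocation = template.allocation()
    if len(allocation) != template.n_subjects:
        raise ValidationError("sequence_allocation length must equal n_subjects")
    streams = np.random.SeedSequence(template.seed).spawn(template.n_subjects)
    profiles: List[PKProfile] = []
    individuals: List[IndividualPK] = []
    for i, (seq, stream) in enumerate(zip(allocation, streams), start=1):
        rng = np.random.default_rng(stream)
        indiv = draw_individual(population, rng)
        individuals.append(indiv)
        sid = f"S{i:02d}"
        for period in (1, 2):
            treatment = seq.treatment_in_period(period)
            if treatment is Treatment.IV:
                dose = DoseEvent(Route.IV_INFUSION, template.iv_dose_mg,
                                 template.infusion_duration_h)
                times = template.iv_times
            else:
                dose = DoseEvent(Route.ORAL, template.oral_dose_mg)
                times = template.oral_times
            mult = 1.0
            if period == 2:
                mult *= template.period2_exposure_ratio
            if seq is TreatmentSequence.ORAL_THEN_IV:
                mult *= template.sequence_exposure_ratio
            if population.omega_iov_exposure > 0:
                mult *= math.exp(rng.normal(0.0, population.omega_iov_exposure))
            analytes = [Analyte.PARENT] + (
                [Analyte.METABOLITE] if include_metabolite else []
            )
            for analyte in analytes:
                profiles.append(simulate_subject_profile(
                    population, indiv, dose, times, rng,
                    subject_id=sid, sequence=seq, period=period,
                    analyte=analyte, exposure_multiplier=mult,
                ))
    return StudyData(tuple(profiles), template, population, tuple(individuals))
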