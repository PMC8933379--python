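import math

import numpy as np
import pytest

from abspk.datamodel import Analyte, DoseEvent, Route, Treatment, ValidationError
from abspk.nca import (
    TrapezoidPolicy,
    compute_pk_parameters,
    estimate_terminal_phase,
)
from abspk.simulate import (
    IndividualPK,
    PopulationModel,
    StudyTemplate,
    disposition_concentration,
    draw_individual,
    metabolite_concentration,
    simulate_crossover_study,
    simulate_subject_profile,
)

ONE_CPT = IndividualPK(cl=9.713, v_central=300.0, n_compartments=1)

NOISELESS = PopulationModel(
    n_compartments=1, cl_typ=9.713, v_central_typ=300.0, omega_ln={},
    sigma_prop=0.0, omega_iov_exposure=0.0, lloq=0.0,
)


class TestDisposition:
    def test_bolus_limit_c0_is_dose_over_volume(self):
        indiv = IndividualPK(cl=9.713, v_central=100.0, n_compartments=1)
        dose = DoseEvent(Route.IV_INFUSION, 50.0, 1e-7)
        c0 = disposition_concentration(indiv, dose, 1e-7)
        assert float(c0) == pytest.approx(500.0, rel=1e-5)

    def test_end_of_infusion_closed_form(self):
        dose = DoseEvent(Route.IV_INFUSION, 50.0, 1.25)
        c = float(disposition_concentration(ONE_CPT, dose, 1.25))
        k = 9.713 / 300.0
        expected = (40.0 / 9.713) * (1.0 - math.exp(-k * 1.25)) * 1e3
        assert c == pytest.approx(expected, rel=1e-12)
        assert c == pytest.approx(163.4, abs=0.15)

    def test_superposition_of_split_doses(self):
        t = np.array([0.5, 2.0, 24.0, 72.0])
        full = disposition_concentration(
            ONE_CPT, DoseEvent(Route.IV_INFUSION, 50.0, 1.25), t)
        half = disposition_concentration(
            ONE_CPT, DoseEvent(Route.IV_INFUSION, 25.0, 1.25), t)
        np.testing.assert_allclose(2.0 * half, full, rtol=1e-12)

    def test_oral_ka_equals_k_limiting_form(self):
        k = 9.713 / 300.0
        indiv = IndividualPK(cl=9.713, v_central=300.0, ka=k, f_oral=1.0,
                             n_compartments=1)
        near = IndividualPK(cl=9.713, v_central=300.0, ka=k * (1 + 1e-9),
                            f_oral=1.0, n_compartments=1)
        dose = DoseEvent(Route.ORAL, 100.0)
        t = np.array([0.5, 2.0, 10.0])
        np.testing.assert_allclose(
            disposition_concentration(indiv, dose, t),
            disposition_concentration(near, dose, t), rtol=1e-5)

    def test_end_of_infusion_is_concentration_maximum(self):
        t = np.linspace(0.0, 12.0, 2401)
        c = disposition_concentration(
            ONE_CPT, DoseEvent(Route.IV_INFUSION, 50.0, 1.25), t)
        assert t[int(np.argmax(c))] == pytest.approx(1.25, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            disposition_concentration(ONE_CPT, DoseEvent(Route.ORAL, 100.0),
                                      [-1.0])

    def test_two_compartment_terminal_slope_matches_beta(self):
        indiv = IndividualPK(cl=9.713, v_central=100.0, v_peripheral=205.0,
                             q=30.0, n_compartments=2)
        dose = DoseEvent(Route.IV_INFUSION, 50.0, 1.25)
        t = np.array([96.0, 120.0, 144.0])
        c = disposition_concentration(indiv, dose, t)
        slope = np.polyfit(t, np.log(c), 1)[0]
        k10, k12, k21 = 9.713 / 100.0, 30.0 / 100.0, 30.0 / 205.0
        s = k10 + k12 + k21
        beta = (s - math.sqrt(s * s - 4 * k10 * k21)) / 2.0
        assert -slope == pytest.approx(beta, rel=1e-4)


class TestAnalyticAUCIdentity:
    @pytest.mark.parametrize("route", ["oral", "iv"])
    def test_nca_auc_inf_matches_dose_over_cl(self, route):
        """Dense noise-free sampling: AUC_inf = F*D/CL (oral) or D/CL (IV)."""
        f = 0.81
        if route == "oral":
            dose = DoseEvent(Route.ORAL, 100.0)
            expected = f * 100.0 * 1e6 / 9.713 / 1e3
            treatment = Treatment.ORAL
        else:
            dose = DoseEvent(Route.IV_INFUSION, 50.0, 1.25)
            expected = 50.0 * 1e6 / 9.713 / 1e3
            treatment = Treatment.IV
        indiv = IndividualPK(cl=9.713, v_central=300.0, ka=0.9, f_oral=f,
                             n_compartments=1)
        times = np.concatenate([np.linspace(0, 12, 49), np.arange(14, 241, 2.0)])
        rng = np.random.default_rng(0)
        prof = simulate_subject_profile(NOISELESS, indiv, dose, times, rng)
        assert prof.treatment is treatment
        params = compute_pk_parameters(prof)
        assert params.auc_inf == pytest.approx(expected, rel=0.01)

    def test_kel_recovered_within_tenth_percent(self):
        indiv = IndividualPK(cl=9.713, v_central=300.0, n_compartments=1)
        dose = DoseEvent(Route.IV_INFUSION, 50.0, 1.25)
        times = np.arange(0.0, 145.0, 4.0)
        rng = np.random.default_rng(0)
        prof = simulate_subject_profile(NOISELESS, indiv, dose, times, rng)
        fit = estimate_terminal_phase(prof)
        assert fit.kel == pytest.approx(9.713 / 300.0, rel=1e-3)


class TestSubjectProfile:
    def test_noise_free_profile_equals_model(self):
        rng = np.random.default_rng(1)
        dose = DoseEvent(Route.ORAL, 100.0)
        times = np.array([0.5, 1.0, 2.0, 24.0])
        prof = simulate_subject_profile(NOISELESS, ONE_CPT, dose, times, rng)
        model = disposition_concentration(ONE_CPT, dose, times)
        np.testing.assert_allclose(prof.concentrations, model, rtol=1e-12)
        assert not any(p.blq for p in prof.points)

    def test_blq_values_flagged_and_zeroed(self):
        pop = PopulationModel()
        study = simulate_crossover_study(StudyTemplate(n_subjects=6, seed=4), pop)
        saw_blq = False
        for prof in study.profiles:
            for p in prof.points:
                if p.blq:
                    assert p.concentration == 0.0
                    saw_blq = True
                else:
                    assert p.concentration >= pop.lloq
        assert saw_blq  # pre-dose samples at minimum

    def test_blq_rate_monotone_in_lloq(self):
        def blq_fraction(lloq):
            pop = PopulationModel(lloq=lloq)
            study = simulate_crossover_study(
                StudyTemplate(n_subjects=6, seed=4), pop)
            flags = [p.blq for prof in study.profiles for p in prof.points]
            return np.mean(flags)

        fractions = [blq_fraction(l) for l in (0.5, 2.5, 10.0)]
        assert fractions[0] <= fractions[1] <= fractions[2]


class TestStudySimulation:
    def test_seed_determinism(self):
        a = simulate_crossover_study(StudyTemplate(n_subjects=4, seed=9),
                                     PopulationModel())
        b = simulate_crossover_study(StudyTemplate(n_subjects=4, seed=9),
                                     PopulationModel())
        assert a.profiles == b.profiles

    def test_adding_subject_preserves_existing(self):
        small = simulate_crossover_study(
            StudyTemplate(n_subjects=4, seed=9,
                          sequence_allocation=["IV_then_oral"] * 2
                          + ["oral_then_IV"] * 2),
            PopulationModel())
        big = simulate_crossover_study(
            StudyTemplate(n_subjects=5, seed=9,
                          sequence_allocation=["IV_then_oral"] * 2
                          + ["oral_then_IV"] * 3),
            PopulationModel())
        assert big.profiles[: len(small.profiles)] == small.profiles

    def test_balanced_allocation_and_periods(self):
        study = simulate_crossover_study(StudyTemplate(n_subjects=12, seed=0),
                                         PopulationModel())
        assert len(study.profiles) == 24
        iv_first = [p for p in study.profiles
                    if p.sequence.value == "IV_then_oral"]
        assert len(iv_first) == 12
        for p in study.profiles:
            assert p.treatment is p.sequence.treatment_in_period(p.period)

    def test_odd_n_requires_explicit_allocation(self):
        with pytest.raises(ValidationError):
            simulate_crossover_study(StudyTemplate(n_subjects=11, seed=0),
                                     PopulationModel())
        study = simulate_crossover_study(
            StudyTemplate(n_subjects=11, seed=0,
                          sequence_allocation=["IV_then_oral"] * 6
                          + ["oral_then_IV"] * 5),
            PopulationModel())
        assert len({p.subject_id for p in study.profiles}) == 11

    def test_period_effect_recovered(self):
        # inject a 10% period-2 exposure bump; the period coefficient of the
        # crossover fit should average near ln(1.1) over replicates
        from abspk.crossover import absolute_bioavailability
        from abspk.pipeline import nca_table

        pop = PopulationModel()
        effects = []
        for rep in range(20):
            tpl = StudyTemplate(n_subjects=12, seed=500 + rep,
                                period2_exposure_ratio=1.10)
            tab = nca_table(list(simulate_crossover_study(tpl, pop).profiles))
            res = absolute_bioavailability(tab)
            effects.append(res.fixed_effects["period"])
        assert np.mean(effects) == pytest.approx(math.log(1.10), abs=0.02)

    def test_washout_minimum_enforced(self):
        with pytest.raises(ValidationError):
            StudyTemplate(n_subjects=12, washout_days=5.0)


class TestMetabolite:
    def test_metabolite_profile_generated(self):
        study = simulate_crossover_study(StudyTemplate(n_subjects=2, seed=2),
                                         PopulationModel(),
                                         include_metabolite=True)
        analytes = {p.analyte for p in study.profiles}
        assert Analyte.METABOLITE in analytes
        assert len(study.profiles) == 8  # 2 subjects x 2 periods x 2 analytes

    def test_metabolite_auc_matches_mass_balance(self):
        # at steady mass balance: AUC_m = fm*CL*(MWm/MWp)*AUC_p/(km*Vm)
        pop = PopulationModel(n_compartments=1, cl_typ=9.713,
                              v_central_typ=300.0, omega_ln={},
                              sigma_prop=0.0, omega_iov_exposure=0.0, lloq=0.0)
        indiv = IndividualPK(cl=9.713, v_central=300.0, n_compartments=1)
        dose = DoseEvent(Route.IV_INFUSION, 50.0, 1.25)
        t = np.linspace(0.0, 600.0, 1200)
        cp = disposition_concentration(indiv, dose, t)
        cm = metabolite_concentration(indiv, dose, t, pop, grid_points=8000)
        auc_p = np.trapezoid(cp, t)
        auc_m = np.trapezoid(cm, t)
        expected = (pop.metabolite_fraction * 9.713
                    * (pop.mw_metabolite / pop.mw_parent)
                    / (pop.metabolite_k * pop.metabolite_v)) * auc_p
        assert auc_m == pytest.approx(expected, rel=0.02)


def test_draw_individual_respects_omegas():
    rng = np.random.default_rng(8)
    pop = PopulationModel()
    draws = [draw_individual(pop, rng).cl for _ in range(4000)]
    logs = np.log(draws)
    assert np.std(logs, ddof=1) == pytest.approx(0.30, rel=0.05)
    assert np.exp(np.mean(logs)) == pytest.approx(pop.cl_typ, rel=0.05)
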