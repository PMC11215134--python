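"""Compartmental PK: covariates, superposition, mass balance, half-lives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import opirescue as op
from opirescue.pk import DoseEvent, conc_function, disposition

SEC = 3600.0


class TestTypicalParameters:
    def test_reference_weight_gives_table_clearance(self, bundle):
        p = op.typical_parameters(bundle.pk_model("nalmefene"), 74.7, "intranasal")
        assert p.cl == pytest.approx(63.7)

    def test_allometric_scaling_of_clearance(self, bundle):
        m = bundle.pk_model("nalmefene")
        p = op.typical_parameters(m, 100.0, "intranasal")
        assert p.cl == pytest.approx(63.7 * (100.0 / 74.7) ** 0.572)

    def test_zero_exponent_removes_weight_dependence(self, bundle):
        m = bundle.pk_model("nalmefene").model_copy(update={"wt_exponent": 0.0})
        assert op.typical_parameters(m, 50.0).cl == op.typical_parameters(m, 120.0).cl

    def test_hypercapnic_study_shifts_intranasal_ka(self, bundle):
        m = bundle.pk_model("nalmefene")
        p = op.typical_parameters(m, 74.7, "intranasal", hypercapnic_study=True)
        assert p.ka == pytest.approx(0.497 * (1.0 - 0.349))

    def test_intranasal_carries_relative_bioavailability(self, bundle):
        m = bundle.pk_model("nalmefene")
        assert op.typical_parameters(m, route="intranasal").bioavail == pytest.approx(0.834)
        assert op.typical_parameters(m, route="intramuscular").bioavail == 1.0

    def test_unsupported_route_names_drug_and_route(self, bundle):
        with pytest.raises(ValueError, match="intravenous.*nalmefene|nalmefene.*intravenous"):
            op.typical_parameters(bundle.pk_model("nalmefene"), 74.7, "intravenous")


class TestPlasmaConcentration:
    def test_empty_dose_list_gives_zero_profile(self, nalmefene_typical, hour_grid):
        prof = op.plasma_concentration(nalmefene_typical, [], hour_grid)
        assert np.all(prof.conc_ng_ml == 0.0)

    def test_zero_before_first_dose(self, nalmefene_typical, hour_grid):
        dose = DoseEvent(time_s=1800.0, amount_mg=3.0, route="intranasal")
        prof = op.plasma_concentration(nalmefene_typical, [dose], hour_grid)
        assert np.all(prof.conc_ng_ml[hour_grid < 1800.0] == 0.0)
        assert prof.conc_ng_ml[hour_grid > 7200.0].max() > 0.0

    def test_simultaneous_doses_superpose_exactly(self, nalmefene_typical, hour_grid):
        one = op.plasma_concentration(
            nalmefene_typical,
            [DoseEvent(time_s=0.0, amount_mg=4.0, route="intranasal")],
            hour_grid,
        )
        two = op.plasma_concentration(
            nalmefene_typical,
            [DoseEvent(time_s=0.0, amount_mg=4.0, route="intranasal")] * 2,
            hour_grid,
        )
        np.testing.assert_allclose(two.conc_ng_ml, 2.0 * one.conc_ng_ml, rtol=1e-12)

    def test_superposition_of_separate_dose_lists(self, naloxone_typical, hour_grid):
        d1 = DoseEvent(time_s=0.0, amount_mg=4.0, route="intranasal")
        d2 = DoseEvent(time_s=3600.0, amount_mg=2.0, route="intranasal")
        a = op.plasma_concentration(naloxone_typical, [d1], hour_grid).conc_ng_ml
        b = op.plasma_concentration(naloxone_typical, [d2], hour_grid).conc_ng_ml
        ab = op.plasma_concentration(naloxone_typical, [d1, d2], hour_grid).conc_ng_ml
        np.testing.assert_allclose(ab, a + b, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("model_key,route,dose", [
        ("nalmefene", "intranasal", 3.0),
        ("nalmefene", "intramuscular", 1.0),
        ("naloxone_in", "intranasal", 4.0),
        ("fentanyl", "intravenous", 1.63),
    ])
    def test_closed_form_matches_ode(self, bundle, model_key, route, dose):
        params = op.typical_parameters(bundle.pk_model(model_key), 74.7, route)
        grid = np.arange(0.0, 6 * SEC + 1, 120.0)
        doses = [DoseEvent(time_s=0.0, amount_mg=dose, route=route)]
        cf = op.plasma_concentration(params, doses, grid, method="closed_form")
        ode = op.plasma_concentration(params, doses, grid, method="ode")
        scale = cf.conc_ng_ml.max()
        np.testing.assert_allclose(ode.conc_ng_ml, cf.conc_ng_ml, atol=1e-3 * scale,
                                   rtol=1e-3)

    def test_mass_balance_of_absorption_inputs(self, nalmefene_typical):
        """Integrated absorption input equals the bioavailable dose."""
        p = nalmefene_typical
        dose_mg = 3.0
        bio = dose_mg * p.bioavail
        # zero-order part: f0*bio over d2; first-order part integrates analytically
        t_end = 10 * op.terminal_half_life(p) * SEC
        ka_s = p.ka / SEC
        lag_s = p.t_lag * SEC
        first_order = (1 - p.f0) * bio * -math.expm1(-ka_s * (t_end - lag_s))
        total_in = p.f0 * bio + first_order
        assert total_in == pytest.approx(bio, rel=5e-3)

    def test_eliminated_mass_equals_bioavailable_dose(self, nalmefene_typical):
        """CL * AUC over 10 terminal half-lives recovers F * dose."""
        p = nalmefene_typical
        t_end = 10 * op.terminal_half_life(p) * SEC
        grid = np.linspace(0.0, t_end, 20001)
        prof = op.plasma_concentration(
            p, [DoseEvent(time_s=0.0, amount_mg=3.0, route="intranasal")], grid
        )
        auc_mg_s_per_l = np.trapezoid(prof.conc_ng_ml, grid) / 1000.0
        eliminated = p.cl / SEC * auc_mg_s_per_l
        assert eliminated == pytest.approx(3.0 * p.bioavail, rel=5e-3)

    def test_non_monotone_grid_rejected(self, nalmefene_typical):
        with pytest.raises(ValueError, match="strictly increasing"):
            op.plasma_concentration(nalmefene_typical, [], np.array([0.0, 2.0, 1.0]))

    def test_negative_dose_rejected(self):
        with pytest.raises(Exception):
            DoseEvent(time_s=0.0, amount_mg=-1.0, route="intranasal")


class TestTerminalHalfLife:
    def test_nalmefene_half_life_in_literature_range(self, nalmefene_typical):
        t_half = op.terminal_half_life(nalmefene_typical)
        assert 7.1 <= t_half <= 11.0
        assert t_half == pytest.approx(10.22, abs=0.05)

    def test_naloxone_half_life_matches_eigenvalue_formula(self, naloxone_typical):
        k10 = 396.0 / 65.7
        k12 = 284.0 / 65.7
        k21 = 284.0 / 102.0
        s = k10 + k12 + k21
        beta = 0.5 * (s - math.sqrt(s * s - 4 * k10 * k21))
        assert op.terminal_half_life(naloxone_typical) == pytest.approx(
            math.log(2) / beta
        )

    def test_one_compartment_limit(self, nalmefene_typical):
        p = nalmefene_typical.model_copy(update={"q": 1e-9})
        expected = math.log(2) * p.vc / p.cl
        assert op.terminal_half_life(p) == pytest.approx(expected, rel=1e-4)

    def test_half_life_matches_terminal_log_linear_slope(self, nalmefene_typical):
        """Simulated terminal phase decays at the closed-form beta rate."""
        p = nalmefene_typical
        t_half_s = op.terminal_half_life(p) * SEC
        grid = np.linspace(5 * t_half_s, 8 * t_half_s, 400)
        prof = op.plasma_concentration(
            p, [DoseEvent(time_s=0.0, amount_mg=3.0, route="intranasal")], grid
        )
        slope = np.polyfit(grid, np.log(prof.conc_ng_ml), 1)[0]
        assert math.log(2) / -slope / SEC == pytest.approx(
            op.terminal_half_life(p), rel=0.02
        )


class TestOpioidConcentration:
    def test_zero_dose_zero_profile(self, bundle, hour_grid):
        params = op.typical_parameters(bundle.pk_model("fentanyl"), 74.7, "intravenous")
        prof = op.opioid_concentration(
            "fentanyl",
            params,
            [DoseEvent(time_s=0.0, amount_mg=0.0, route="intravenous")],
            hour_grid,
        )
        assert np.all(prof.conc_ng_ml == 0.0)

    def test_missing_bundle_reported(self, hour_grid):
        with pytest.raises(ValueError, match="bundle not provided"):
            op.opioid_concentration("carfentanil", None, [], hour_grid)

    def test_unknown_opioid_rejected(self, hour_grid):
        with pytest.raises(ValueError, match="unknown opioid"):
            op.opioid_concentration("morphine", None, [], hour_grid)

    def test_carfentanil_concentration_halves_near_45_minutes(self, bundle):
        params = op.typical_parameters(bundle.pk_model("carfentanil"), 74.7, "intravenous")
        grid = np.arange(0.0, 2 * SEC, 10.0)
        prof = op.opioid_concentration(
            "carfentanil",
            params,
            [DoseEvent(time_s=0.0, amount_mg=0.022, route="intravenous")],
            grid,
        )
        c0 = prof.conc_ng_ml[0]
        t_half = grid[np.argmax(prof.conc_ng_ml <= c0 / 2)] / 60.0
        assert t_half == pytest.approx(45.0, abs=5.0)

    def test_dose_linearity(self, bundle, hour_grid):
        params = op.typical_parameters(bundle.pk_model("fentanyl"), 74.7, "intravenous")
        one = op.opioid_concentration(
            "fentanyl", params,
            [DoseEvent(time_s=0.0, amount_mg=1.63, route="intravenous")], hour_grid,
        ).conc_ng_ml
        two = op.opioid_concentration(
            "fentanyl", params,
            [DoseEvent(time_s=0.0, amount_mg=3.26, route="intravenous")], hour_grid,
        ).conc_ng_ml
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)


@settings(max_examples=25, deadline=None)
@given(
    cl=st.floats(10.0, 500.0),
    vc=st.floats(5.0, 200.0),
    q=st.floats(1.0, 300.0),
    vp=st.floats(10.0, 600.0),
    ka=st.floats(0.05, 10.0),
    f0=st.floats(0.0, 1.0),
)
def test_closed_form_and_ode_agree_for_random_parameters(cl, vc, q, vp, ka, f0):
    params = op.IndividualPKParameters(
        drug="x", route="intranasal", cl=cl, vc=vc, q=q, vp=vp, ka=ka, f0=f0,
        d2=0.5, t_lag=0.1, bioavail=0.9,
    )
    grid = np.linspace(0.0, 4 * SEC, 49)
    doses = [DoseEvent(time_s=0.0, amount_mg=5.0, route="intranasal")]
    cf = op.plasma_concentration(params, doses, grid, method="closed_form").conc_ng_ml
    ode = op.plasma_concentration(params, doses, grid, method="ode").conc_ng_ml
    np.testing.assert_allclose(ode, cf, rtol=1e-3, atol=1e-3 * max(cf.max(), 1e-9))
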