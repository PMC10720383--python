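"""PBK model assembly, integration, conservation and dose metrics."""

import numpy as np
import pytest

import fntqivive as fq
from fntqivive.errors import DomainError, ParameterValidationError, UsageError
from fntqivive.parameters import REACTIONS, SpeciesParameterSet
from fntqivive.pbk import N_STATES, SolverOptions


def _kin_zero(kinetics):
    return {r: k.model_copy(update={"vmax": 0.0, "scaling": "in_vivo"})
            for r, k in kinetics.items()}


def _species_with(sp, **overrides):
    d = sp.model_dump()
    d.update(overrides)
    return SpeciesParameterSet(**d)


class TestBuild:
    def test_state_dimension(self, rat_model):
        # 3 compounds × 8 state groups + 3 urine + 4 reaction accumulators
        assert rat_model.state_dimension == 3 * 8 + 3 + 4 == N_STATES

    def test_missing_reaction_rejected(self, rat_defaults):
        sp, compounds, kinetics = rat_defaults
        scaled = fq.scale_kinetics(kinetics, sp)
        scaled.pop("FNO_to_MNP_blood")
        with pytest.raises(ParameterValidationError, match="FNO_to_MNP_blood"):
            fq.build_model(sp, compounds, scaled)

    def test_unscaled_kinetics_rejected(self, rat_defaults):
        sp, compounds, kinetics = rat_defaults
        with pytest.raises(ParameterValidationError, match="in vivo"):
            fq.build_model(sp, compounds, kinetics)

    def test_missing_compound_rejected(self, rat_defaults):
        sp, compounds, kinetics = rat_defaults
        with pytest.raises(ParameterValidationError, match="MNP"):
            fq.build_model(sp, compounds[:2], fq.scale_kinetics(kinetics, sp))


class TestSimulate:
    def test_zero_dose_all_zero(self, rat_model):
        res = fq.simulate(rat_model, fq.DosingRegimen(route="oral", dose=0.0), 12.0)
        for arr in res.amounts.values():
            assert np.all(arr == 0.0)
        assert res.mass_balance_residual == 0.0

    def test_gi_transfer_closed_form(self, rat_model):
        """Stomach drains at ka_s + ks_i; closed-form exponential check."""
        sp = rat_model.species
        res = fq.simulate(rat_model, fq.DosingRegimen(route="oral", dose=5.0), 8.0)
        a0 = res.amounts[("FNT", "stomach")][0]
        expected = a0 * np.exp(-(sp.ka_s + sp.ks_i) * res.time)
        np.testing.assert_allclose(res.amounts[("FNT", "stomach")], expected, rtol=1e-6)

    def test_oral_initial_stomach_amount(self, rat_model):
        res = fq.simulate(rat_model, fq.DosingRegimen(route="oral", dose=5.0), 1.0)
        sp = rat_model.species
        mw = rat_model.compounds["FNT"].molecular_weight
        assert res.amounts[("FNT", "stomach")][0] == pytest.approx(
            sp.fa * 5.0 * sp.body_weight / mw * 1000.0)

    def test_iv_conservation_without_elimination(self, rat_defaults):
        """With all Vmax = 0 and vanishing GFR, iv body burden stays equal to
        the administered moles at every output time."""
        sp, compounds, kinetics = rat_defaults
        sp0 = _species_with(sp, gfr=1e-30)
        model = fq.build_model(sp0, compounds, _kin_zero(kinetics))
        res = fq.simulate(model, fq.DosingRegimen(route="iv", dose=1.0), 24.0)
        total = sum(res.amounts[("FNT", c)] for c in
                    ("stomach", "intestine", "liver", "kidney", "blood",
                     "fat", "rapidly_perfused", "slowly_perfused"))
        np.testing.assert_allclose(total, res.administered_umol, rtol=1e-7)

    @pytest.mark.parametrize("route,dose", [("oral", 0.1), ("oral", 15.0), ("iv", 0.94)])
    def test_mass_balance_audit(self, rat_model, route, dose):
        res = fq.simulate(rat_model, fq.DosingRegimen(route=route, dose=dose), 48.0)
        assert res.mass_balance_residual <= 1e-6 * res.administered_umol

    def test_multiple_oral_doses_refill_stomach(self, rat_model):
        reg = fq.DosingRegimen(route="oral", dose=1.0, n_doses=3, dose_interval=12.0)
        res = fq.simulate(rat_model, reg, 48.0)
        assert res.administered_umol == pytest.approx(
            3 * rat_model.species.fa * 1.0 * rat_model.species.body_weight
            / rat_model.compounds["FNT"].molecular_weight * 1000.0)
        st = res.amounts[("FNT", "stomach")]
        i12 = np.searchsorted(res.time, 12.0)
        assert st[i12] > st[i12 - 1]  # refill visible
        assert res.mass_balance_residual <= 1e-6 * res.administered_umol

    def test_duration_must_be_positive(self, rat_model):
        with pytest.raises(UsageError):
            fq.simulate(rat_model, fq.DosingRegimen(route="oral", dose=1.0), 0.0)

    def test_solver_tolerance_robustness(self, rat_defaults):
        """10× tighter tolerances move Cmax blood FNO by < 0.01%."""
        sp, compounds, kinetics = rat_defaults
        scaled = fq.scale_kinetics(kinetics, sp)
        reg = fq.DosingRegimen(route="oral", dose=5.0)
        m1 = fq.build_model(sp, compounds, scaled)
        m2 = fq.build_model(sp, compounds, scaled,
                            solver_options=SolverOptions(rtol=1e-9, atol=1e-11))
        c1 = fq.cmax(fq.simulate(m1, reg, 24.0), "FNO", "blood")[0]
        c2 = fq.cmax(fq.simulate(m2, reg, 24.0), "FNO", "blood")[0]
        assert abs(c1 - c2) / c2 < 1e-4

    def test_one_compartment_analytic_limit(self, rat_defaults):
        """Linear metabolism (Km ≫ C), unit partitioning and near-infinite
        perfusion collapse the model to one compartment with
        C(t) = C0·e^(−k·t); agreement < 1e-4 relative."""
        sp, compounds, kinetics = rat_defaults
        sp0 = _species_with(sp, cardiac_output=1e5, gfr=1e-30)
        unit_part = {t: 1.0 for t in
                     ("liver", "kidney", "fat", "rapidly_perfused", "slowly_perfused")}
        comps = [c.model_copy(update={"partition_blood": unit_part}) for c in compounds]
        kin = _kin_zero(kinetics)
        # single linear FNT loss: huge Km so rate = (Vmax/Km)·Cu
        kin["FNT_to_FNO"] = kin["FNT_to_FNO"].model_copy(
            update={"vmax": 1e7, "km": 1e9})
        model = fq.build_model(sp0, comps, kin,
                               solver_options=SolverOptions(rtol=1e-10, atol=1e-12))
        res = fq.simulate(model, fq.DosingRegimen(route="iv", dose=1.0), 24.0)
        v_tot = sum(sp0.tissue_volume(t) for t in unit_part) + sp0.blood_volume
        fnt = compounds[0]
        k_el = (1e7 / 1e9) * fnt.fup / fnt.bpr / v_tot
        c0 = res.administered_umol / v_tot
        expected = c0 * np.exp(-k_el * res.time)
        observed = res.concentrations[("FNT", "blood")]
        # skip t = 0: the bolus mixes across compartments within ~V/Q ≈ 1e-5 h
        mixed = res.time > 0.01
        assert np.max(np.abs(observed[mixed] - expected[mixed]) / expected[mixed]) < 1e-4


class TestCmax:
    def test_zero_dose(self, rat_model):
        res = fq.simulate(rat_model, fq.DosingRegimen(route="oral", dose=0.0), 6.0)
        assert fq.cmax(res, "FNO", "blood") == (0.0, 0.0)

    def test_monotone_decay_iv_peak_at_start(self, rat_defaults):
        sp, compounds, kinetics = rat_defaults
        model = fq.build_model(sp, compounds, _kin_zero(kinetics))
        res = fq.simulate(model, fq.DosingRegimen(route="iv", dose=1.0), 24.0)
        c, t = fq.cmax(res, "FNT", "blood")
        assert t == res.time[0]
        assert c == res.concentrations[("FNT", "blood")][0]

    def test_refinement_against_finer_grid(self, rat_defaults):
        """Quadratic refinement ≥ grid max and within 0.1% of a 10× grid."""
        sp, compounds, kinetics = rat_defaults
        scaled = fq.scale_kinetics(kinetics, sp)
        reg = fq.DosingRegimen(route="oral", dose=15.0)
        coarse = fq.build_model(sp, compounds, scaled,
                                solver_options=SolverOptions(points_per_24h=200))
        fine = fq.build_model(sp, compounds, scaled,
                              solver_options=SolverOptions(points_per_24h=2000))
        res_c = fq.simulate(coarse, reg, 24.0)
        res_f = fq.simulate(fine, reg, 24.0)
        c_ref, _ = fq.cmax(res_c, "FNO", "blood")
        c_fine, _ = fq.cmax(res_f, "FNO", "blood")
        assert c_ref >= res_c.concentrations[("FNO", "blood")].max()
        assert abs(c_ref - c_fine) / c_fine < 1e-3


class TestUrinary:
    def test_zero_at_t0_and_nondecreasing(self, rat_model, oral_regimen):
        res = fq.simulate(rat_model, oral_regimen, 24.0)
        assert fq.cumulative_urinary(res, "MNP", 0.0)[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(res.urinary["MNP"]) >= -1e-12)

    def test_out_of_range_rejected(self, rat_model, oral_regimen):
        res = fq.simulate(rat_model, oral_regimen, 24.0)
        with pytest.raises(DomainError):
            fq.cumulative_urinary(res, "MNP", 25.0)

    def test_quadrature_oracle(self, rat_model, oral_regimen):
        """Cumulative urine equals trapezoidal integration of the
        instantaneous renal rate GFR·C_kidney/P_kidney."""
        res = fq.simulate(rat_model, oral_regimen, 24.0)
        sp = rat_model.species
        p_k = rat_model.compounds["MNP"].partition_blood["kidney"]
        rate = sp.gfr_L_per_h * res.concentrations[("MNP", "kidney")] / p_k
        from scipy.integrate import cumulative_trapezoid
        expected = cumulative_trapezoid(rate, res.time, initial=0.0)
        observed = res.urinary["MNP"]
        assert np.max(np.abs(observed - expected)) < 2e-4 * max(observed.max(), 1e-12)

    def test_limiting_conservation_iv_all_to_urine(self, rat_defaults):
        """Without metabolism, everything eventually leaves in urine."""
        sp, compounds, kinetics = rat_defaults
        model = fq.build_model(sp, compounds, _kin_zero(kinetics))
        res = fq.simulate(model, fq.DosingRegimen(route="iv", dose=1.0), 3000.0)
        assert res.urinary["FNT"][-1] == pytest.approx(res.administered_umol, rel=1e-3)

    def test_mg_conversion(self, rat_model, oral_regimen):
        res = fq.simulate(rat_model, oral_regimen, 24.0)
        umol, mg = fq.cumulative_urinary(res, "MNP", 24.0)
        assert mg == pytest.approx(umol * 153.14 / 1000.0)
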