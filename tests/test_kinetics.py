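"""Michaelis–Menten fitting and IVIVE scaling."""

import numpy as np
import pytest

import fntqivive as fq
from fntqivive.errors import DegenerateDataError, ParameterValidationError, UsageError
from fntqivive.kinetics import IncubationDataset, michaelis_menten
from fntqivive.parameters import SpeciesParameterSet


def _species(**overrides):
    sp, _, _ = fq.load_defaults("rat")
    d = sp.model_dump()
    d.update(overrides)
    return SpeciesParameterSet(**d)


class TestFit:
    def test_noise_free_recovery(self):
        data = fq.gen_incubation(vmax=10.0, km=50.0,
                                 concentrations=[5, 10, 50, 100, 500, 1000, 5000],
                                 noise_sd=0.0)
        k, diag = fq.fit_michaelis_menten(data)
        assert k.vmax == pytest.approx(10.0, rel=1e-6)
        assert k.km == pytest.approx(50.0, rel=1e-6)
        assert diag.r_squared > 0.97

    def test_midpoint_identity(self):
        data = fq.gen_incubation(vmax=7.0, km=30.0, noise_sd=0.0)
        k, _ = fq.fit_michaelis_menten(data)
        assert michaelis_menten(k.km, k.vmax, k.km) == pytest.approx(k.vmax / 2)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        """The SSE minimizer agrees with a brute-force (Vmax, Km) lattice."""
        data = fq.gen_incubation(vmax=10.0, km=50.0, noise_sd=0.5, seed=42)
        k, diag = fq.fit_michaelis_menten(data)
        vg = np.linspace(8.0, 12.0, 161)
        kg = np.linspace(30.0, 70.0, 161)
        V, K = np.meshgrid(vg, kg, indexing="ij")
        pred = V[..., None] * data.substrate_conc / (K[..., None] + data.substrate_conc)
        sse = ((pred - data.velocity) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(k.vmax - vg[i]) <= vg[1] - vg[0]
        assert abs(k.km - kg[j]) <= kg[1] - kg[0]
        assert diag.sse <= sse[i, j] + 1e-9

    def test_invariant_to_row_order_and_replicate_duplication(self):
        data = fq.gen_incubation(vmax=5.0, km=100.0, noise_sd=0.2, seed=7)
        k0, _ = fq.fit_michaelis_menten(data)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(data.substrate_conc))
        shuffled = IncubationDataset(data.substrate_conc[order], data.velocity[order],
                                     data.matrix, data.species_label)
        ks, _ = fq.fit_michaelis_menten(shuffled)
        doubled = IncubationDataset(np.tile(data.substrate_conc, 2),
                                    np.tile(data.velocity, 2),
                                    data.matrix, data.species_label)
        kd, _ = fq.fit_michaelis_menten(doubled)
        assert ks.vmax == pytest.approx(k0.vmax, rel=1e-6)
        assert ks.km == pytest.approx(k0.km, rel=1e-6)
        assert kd.vmax == pytest.approx(k0.vmax, rel=1e-5)
        assert kd.km == pytest.approx(k0.km, rel=1e-5)

    def test_all_zero_velocity_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fq.fit_michaelis_menten(IncubationDataset(
                np.array([1.0, 10.0, 100.0, 1000.0]), np.zeros(4),
                "liver_microsomes", "rat"))

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ParameterValidationError, match="4 distinct"):
            IncubationDataset(np.array([1.0, 10.0, 100.0]), np.ones(3),
                              "liver_microsomes", "rat")

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        data = fq.gen_incubation(vmax=3.0, km=20.0, seed=3)
        df = pd.DataFrame({"concentration_uM": data.substrate_conc,
                           "velocity_nmol_min_mg": data.velocity})
        path = tmp_path / "inc.csv"
        df.to_csv(path, index=False)
        back = fq.read_incubation_csv(path, "liver_microsomes", "rat")
        np.testing.assert_allclose(back.velocity, data.velocity)


class TestCatalyticEfficiency:
    def test_arithmetic(self):
        k = fq.MMKinetics(vmax=10.0, km=50.0, matrix="liver_microsomes",
                          reaction_label="FNT_to_FNO")
        assert fq.catalytic_efficiency(k) == pytest.approx(0.2)

    def test_ratio_identity_under_joint_scaling(self):
        k = fq.MMKinetics(vmax=10.0, km=50.0, matrix="liver_microsomes",
                          reaction_label="FNT_to_FNO")
        k2 = k.model_copy(update={"vmax": 2 * k.vmax, "km": 2 * k.km})
        assert fq.catalytic_efficiency(k2) == pytest.approx(fq.catalytic_efficiency(k))

    def test_in_vivo_efficiency_dimensional_consistency(self, rat_defaults):
        """Scaled efficiency (L/h) = in vitro efficiency (mL/min/mg) × total
        microsomal protein (mg) × 0.06 (mL/min → L/h) — dimensional oracle."""
        sp, _, kinetics = rat_defaults
        k = kinetics["FNT_to_FNO"]
        scaled = fq.scale_vmax_liver(k, sp)
        total_protein_mg = sp.microsomal_yield * sp.liver_mass_g
        expected_L_per_h = fq.catalytic_efficiency(k) * total_protein_mg * 60.0 / 1000.0
        assert fq.catalytic_efficiency(scaled) == pytest.approx(expected_L_per_h)

    def test_species_bioactivation_efficiency_ratio(self, rat_defaults, human_defaults):
        """Rat CYP450 bioactivation is 6.4-fold more efficient than human."""
        _, _, kin_r = rat_defaults
        _, _, kin_h = human_defaults
        ratio = (fq.catalytic_efficiency(kin_r["FNT_to_FNO"])
                 / fq.catalytic_efficiency(kin_h["FNT_to_FNO"]))
        assert ratio == pytest.approx(6.4, rel=1e-9)


class TestScaling:
    def test_liver_scaling_arithmetic(self):
        # 1 nmol/min/mg × 35 mg/g × 10 g liver × 60/1000 = 21 μmol/h
        sp = _species(tissue_volume_fractions={
            "liver": 0.04, "kidney": 0.007, "fat": 0.07, "blood": 0.074,
            "rapidly_perfused": 0.05, "slowly_perfused": 0.676})
        assert sp.liver_mass_g == pytest.approx(10.0)
        k = fq.MMKinetics(vmax=1.0, km=50.0, matrix="liver_microsomes",
                          reaction_label="FNT_to_FNO")
        scaled = fq.scale_vmax_liver(k, sp)
        assert scaled.vmax == pytest.approx(21.0)
        assert scaled.km == k.km
        assert scaled.scaling == "in_vivo"

    def test_liver_scaling_zero_and_linearity(self, rat_defaults):
        sp, _, _ = rat_defaults
        k0 = fq.MMKinetics(vmax=0.0, km=50.0, matrix="liver_microsomes",
                           reaction_label="FNT_to_FNO")
        assert fq.scale_vmax_liver(k0, sp).vmax == 0.0
        big = _species(tissue_volume_fractions=dict(
            sp.tissue_volume_fractions,
            liver=2 * sp.tissue_volume_fractions["liver"]))
        k = fq.MMKinetics(vmax=1.5, km=50.0, matrix="liver_microsomes",
                          reaction_label="FNT_to_FNO")
        assert fq.scale_vmax_liver(k, big).vmax == pytest.approx(
            2 * fq.scale_vmax_liver(k, sp).vmax)

    def test_plasma_scaling_arithmetic(self):
        # 0.01 nmol/min/mg × 59 mg/mL × 10 mL plasma × 60/1000 = 0.354 μmol/h
        sp = _species(hematocrit=0.5, tissue_volume_fractions={
            "liver": 0.034, "kidney": 0.007, "fat": 0.07, "blood": 0.08,
            "rapidly_perfused": 0.05, "slowly_perfused": 0.676})
        assert sp.plasma_volume * 1000 == pytest.approx(10.0)
        k = fq.MMKinetics(vmax=0.01, km=1500.0, matrix="plasma",
                          reaction_label="FNO_to_MNP_blood")
        assert fq.scale_vmax_plasma(k, sp).vmax == pytest.approx(0.354)

    def test_wrong_matrix_usage_error(self, rat_defaults):
        sp, _, kinetics = rat_defaults
        with pytest.raises(UsageError):
            fq.scale_vmax_plasma(kinetics["FNT_to_FNO"], sp)
        with pytest.raises(UsageError):
            fq.scale_vmax_liver(kinetics["FNO_to_MNP_blood"], sp)

    def test_scaling_commutes_with_efficiency(self, rat_defaults):
        """Scaling Vmax then taking Vmax/Km equals scaling the efficiency."""
        sp, _, kinetics = rat_defaults
        k = kinetics["FNO_to_MNP_blood"]
        scaled = fq.scale_vmax_plasma(k, sp)
        factor = sp.plasma_protein_conc * sp.plasma_volume * 1000 * 60.0 / 1000.0
        assert fq.catalytic_efficiency(scaled) == pytest.approx(
            fq.catalytic_efficiency(k) * factor)
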