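"""qPCR → biomass → potential soil rate forward model."""

import pytest

from nitrotherm import (CellModel, KineticParams, SoilSample, allowed_models, averaged_inputs,
                        cells_per_g, enumerate_extremes, params_at_temperature,
                        predict_soil_rate, protein_per_g, soil_solution_conc)


def sample(**over):
    base = dict(
        name="s", gene_copies_per_g={"AOA_amoA": 1e8, "nxrA": 1e7},
        water_content=0.22, extractable_nh4=0.01, pH=8.5,
        amendment_nh4=5.0, accumulated_no2_uM={20.0: 700.0},
    )
    base.update(over)
    return SoilSample(**base)


class TestBiomassChain:
    @pytest.mark.parametrize("copies, per_genome, expected", [
        (1e8, 2, 5e7),
        (0.0, 4, 0.0),
        (7.5e7, 3, 2.5e7),
    ])
    def test_cells_per_g(self, copies, per_genome, expected):
        cm = CellModel("org", "AOA_amoA", per_genome, 100.0)
        assert cells_per_g(sample(gene_copies_per_g={"AOA_amoA": copies}), cm) == expected

    def test_missing_marker(self):
        cm = CellModel("org", "nxrB", 2, 100.0)
        with pytest.raises(KeyError, match="nxrB"):
            cells_per_g(sample(), cm)

    def test_protein_per_g_unit_arithmetic(self):
        cm = CellModel("org", "AOA_amoA", 1, 100.0)
        assert protein_per_g(5e7, cm) == pytest.approx(5e-3, rel=1e-12)
        assert protein_per_g(0.0, cm) == 0.0

    def test_protein_from_cell_volume(self):
        cm = CellModel.from_volume("org", "AOA_amoA", 1, cell_volume_um3=0.5,
                                   protein_density_pg_per_um3=0.1)
        assert cm.protein_per_cell == pytest.approx(50.0)


class TestSoilSolution:
    def test_amended_pool_dissolved_in_gravimetric_water(self):
        # 5 µmol g⁻¹ in 0.22 mL g⁻¹ → 22.7 mM
        assert soil_solution_conc(sample(), "nh4_amended") == pytest.approx(5 / 0.22 * 1000, rel=1e-12)
        assert soil_solution_conc(sample(water_content=0.72), "nh4_amended") == pytest.approx(
            5 / 0.72 * 1000, rel=1e-12)

    def test_native_pool(self):
        assert soil_solution_conc(sample(), "nh4_native") == pytest.approx(0.01 / 0.22 * 1000)
        assert soil_solution_conc(sample(extractable_nh4=0.0), "nh4_native") == 0.0

    def test_no2_assumed_without_amendment_is_oxidized_native_pool(self):
        s = sample(amendment_nh4=0.0)
        assert soil_solution_conc(s, "no2_assumed", 20.0) == pytest.approx(
            soil_solution_conc(s, "nh4_native"))

    def test_no2_assumed_with_amendment(self):
        s = sample()
        assert soil_solution_conc(s, "no2_assumed", 20.0) == 700.0
        # no accumulation measured at this temperature → detection limit
        assert soil_solution_conc(s, "no2_assumed", 10.0) == 2.0

    def test_detection_limit_branch_is_continuous(self):
        """Measured accumulation exactly at the detection limit gives the same
        concentration as the no-detection assumption."""
        at_limit = sample(accumulated_no2_uM={20.0: 2.0})
        below = sample(accumulated_no2_uM={})
        assert soil_solution_conc(at_limit, "no2_assumed", 20.0) == \
            soil_solution_conc(below, "no2_assumed", 20.0) == 2.0

    def test_water_content_validated(self):
        with pytest.raises(ValueError):
            sample(water_content=0.0)


class TestPredictSoilRate:
    p = KineticParams("org", "NH3_total", 30.0, 100.0, 500.0)

    def test_half_saturation_times_protein(self):
        pred = predict_soil_rate(self.p, protein=1e-3, s=500.0, model="MM")
        assert pred.rate == pytest.approx(0.05, rel=1e-12)

    def test_linearity_in_protein(self):
        one = predict_soil_rate(self.p, 1e-3, 250.0, "MM").rate
        two = predict_soil_rate(self.p, 2e-3, 250.0, "MM").rate
        assert two == pytest.approx(2 * one, rel=1e-14)

    def test_inhibition_lowers_rate(self):
        ph = KineticParams("org", "NH3_total", 30.0, 100.0, 500.0, 100.0)
        assert predict_soil_rate(ph, 1e-3, 5000.0, "Haldane").rate < \
            predict_soil_rate(ph, 1e-3, 5000.0, "MM").rate


class TestTemperatureLookup:
    series = [KineticParams("org", "NO2", t, 10.0 + t, 100.0 + 10 * t) for t in (10.0, 20.0, 30.0, 37.0, 42.0)]

    def test_exact_match(self):
        p, interp = params_at_temperature(self.series, 30.0)
        assert (p.vmax, interp) == (40.0, False)

    def test_linear_interpolation_at_40(self):
        p, interp = params_at_temperature(self.series, 40.0)
        assert interp
        assert p.vmax == pytest.approx(47.0 + 3 / 5 * 5.0)
        assert p.km == pytest.approx(470.0 + 3 / 5 * 50.0)

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="outside"):
            params_at_temperature(self.series, 5.0)

    def test_exact_mode_requires_match(self):
        with pytest.raises(ValueError, match="measured"):
            params_at_temperature(self.series, 40.0, mode="exact")


class TestHaldaneApplicationRules:
    def test_no_inhibition_without_amendment(self):
        assert allowed_models("AOA", amended=False, s=50.0, ki=500.0) == ("MM",)
        assert allowed_models("AOB", amended=False, s=50.0, ki=500.0) == ("MM",)
        assert allowed_models("AOA", amended=True, s=5000.0, ki=500.0) == ("MM", "Haldane")

    def test_haldane_dropped_when_no2_far_below_ki(self):
        assert allowed_models("NOB", amended=False, s=0.22, ki=900.0) == ("MM",)
        assert allowed_models("NOB", amended=True, s=700.0, ki=900.0) == ("MM", "Haldane")

    def test_no_ki_means_mm_only(self):
        assert allowed_models("NOB", amended=True, s=700.0, ki=None) == ("MM",)


class TestUncertainInputs:
    six = {k: (float(i), 0.1 * i) for i, k in enumerate(
        ["population", "protein_per_cell", "copies_per_genome", "vmax", "km", "ki"], start=1)}

    def test_means_returned(self):
        assert averaged_inputs(self.six) == {k: m for k, (m, _) in self.six.items()}

    def test_sixty_four_combinations(self):
        combos = enumerate_extremes(self.six)
        assert len(combos) == 64
        assert len({tuple(sorted(c.items())) for c in combos}) == 64

    def test_five_inputs_give_32(self):
        five = dict(list(self.six.items())[:5])
        assert len(enumerate_extremes(five)) == 32

    def test_zero_sd_collapses(self):
        flat = {k: (m, 0.0) for k, (m, _) in self.six.items()}
        combos = enumerate_extremes(flat)
        assert all(c == averaged_inputs(flat) for c in combos)
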