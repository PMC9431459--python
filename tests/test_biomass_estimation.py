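"""Bead calibration, the volume->carbon->nitrogen chain, and budgets."""

import math

import numpy as np
import pandas as pd
import pytest

from crococompete.biomass_estimation import (
    CARBON_MOLAR_MASS,
    DEFAULT_CONVERSIONS,
    BeadStandard,
    FcmObservation,
    GroupConversion,
    calibrate_size,
    carbon_per_cell,
    drawdown_vs_biomass,
    ethylene_to_fixed_n,
    fixation_fraction_of_demand,
    fls_to_volume,
    nitrogen_per_cell,
    population_biomass,
)
from crococompete.errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    ExtrapolationWarning,
)

BEADS_UM = (1.75, 2.0, 3.0, 6.0, 10.0)


def power_law_beads(scale=80.0, exponent=2.0, diameters=BEADS_UM):
    return [BeadStandard(d, scale * d**exponent) for d in diameters]


class TestSizeCalibration:
    def test_exact_power_law_recovers_inverse_exponent(self):
        cal = calibrate_size(power_law_beads(exponent=2.5))
        assert cal.slope == pytest.approx(1.0 / 2.5, rel=1e-12)
        for bead in power_law_beads(exponent=2.5):
            assert cal.diameter(bead.fls) == pytest.approx(bead.diameter, rel=1e-10)

    def test_two_standards_line_through_both(self):
        beads = [BeadStandard(2.0, 100.0), BeadStandard(6.0, 2000.0)]
        cal = calibrate_size(beads)
        for bead in beads:
            assert cal.diameter(bead.fls) == pytest.approx(bead.diameter, rel=1e-12)

    def test_noisy_standards_within_five_percent(self):
        rng = np.random.default_rng(3)
        beads = [
            BeadStandard(d, 80.0 * d**2 * rng.lognormal(0.0, 0.03)) for d in BEADS_UM
        ]
        cal = calibrate_size(beads)
        # closed-form OLS oracle on the log-log pairs
        x = np.log([b.fls for b in beads])
        y = np.log([b.diameter for b in beads])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert cal.slope == pytest.approx(slope, rel=1e-10)
        assert cal.intercept == pytest.approx(intercept, rel=1e-10)
        for bead in beads:
            assert cal.diameter(bead.fls) == pytest.approx(bead.diameter, rel=0.05)

    def test_single_diameter_degenerate(self):
        with pytest.raises(DegenerateFitError):
            calibrate_size([BeadStandard(2.0, 100.0), BeadStandard(2.0, 101.0)])


class TestVolumeAndCarbon:
    def test_sphere_formula(self):
        cal = calibrate_size(power_law_beads())
        fls_1um = 80.0  # FLS of a 1-um cell under the exact law
        with pytest.warns(ExtrapolationWarning):
            volume = fls_to_volume(cal, fls_1um)
        assert volume == pytest.approx(math.pi / 6.0, rel=1e-9)

    def test_cubic_scaling(self):
        cal = calibrate_size(power_law_beads())
        v1 = fls_to_volume(cal, 80.0 * 2.0**2)
        v2 = fls_to_volume(cal, 80.0 * 4.0**2)
        assert v2 == pytest.approx(8.0 * v1, rel=1e-9)

    def test_six_micron_bead_volume(self):
        cal = calibrate_size(power_law_beads())
        volume = fls_to_volume(cal, 80.0 * 6.0**2)
        assert volume == pytest.approx(math.pi / 6.0 * 216.0, rel=1e-9)  # 113.10 um3

    def test_volumetric_factor(self):
        assert carbon_per_cell(DEFAULT_CONVERSIONS["Cro"], 1.0) == pytest.approx(235.0)

    def test_volumetric_linearity(self):
        conv = DEFAULT_CONVERSIONS["Syn"]
        assert carbon_per_cell(conv, 2.7) == pytest.approx(2.0 * carbon_per_cell(conv, 1.35))

    def test_strathmann_at_unit_volume(self):
        # log10 C(pg) = -0.6 at V = 1 -> 0.2512 pg = 251.19 fg
        c = carbon_per_cell(DEFAULT_CONVERSIONS["PicoE"], 1.0)
        assert c == pytest.approx(10**-0.6 * 1000.0, rel=1e-9)

    def test_strathmann_power_law_slope(self):
        conv = DEFAULT_CONVERSIONS["PicoE"]
        volumes = np.logspace(-1, 2, 20)
        logc = np.log10([carbon_per_cell(conv, v) for v in volumes])
        slope = np.polyfit(np.log10(volumes), logc, 1)[0]
        assert slope == pytest.approx(0.94, abs=1e-9)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            carbon_per_cell(DEFAULT_CONVERSIONS["Cro"], 0.0)


class TestNitrogenConversion:
    @pytest.mark.parametrize("group,cn", [("Cro", 8.7), ("PicoE", 6.6)])
    def test_cn_ratio_units(self, group, cn):
        # carbon equivalent to `cn` fmol C converts to exactly 1 fmol N
        carbon_fg = cn * CARBON_MOLAR_MASS
        assert nitrogen_per_cell(DEFAULT_CONVERSIONS[group], carbon_fg) == pytest.approx(1.0)

    def test_zero_carbon(self):
        assert nitrogen_per_cell(DEFAULT_CONVERSIONS["Pro"], 0.0) == 0.0

    def test_bad_cn_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            GroupConversion(group="X", model="volumetric", cn_ratio=0.0)


@pytest.fixture(scope="module")
def cal():
    return calibrate_size(power_law_beads())


class TestPopulationBiomass:
    def test_dimensional_analysis_oracle(self, cal):
        """10^6 cells L^-1 at 1 fmol N cell^-1 is 1 nmol N L^-1."""
        import warnings as _warnings

        # pick the volume whose N content is exactly 1 fmol for Cro
        n_target_fg_c = 1.0 * 8.7 * CARBON_MOLAR_MASS
        volume = n_target_fg_c / 235.0
        diameter = (6.0 * volume / math.pi) ** (1.0 / 3.0)
        fls = 80.0 * diameter**2
        obs = FcmObservation(group="Cro", day=0.0, replicate="r1",
                             abundance=1000.0, median_fls=fls)  # 10^6 cells L^-1
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ExtrapolationWarning)
            n_pool, c_pool = population_biomass(obs, cal, DEFAULT_CONVERSIONS["Cro"])
        assert n_pool == pytest.approx(1.0, rel=1e-9)
        assert c_pool == pytest.approx(8.7, rel=1e-9)

    def test_zero_abundance(self, cal):
        obs = FcmObservation("Cro", 0.0, "r1", 0.0, 500.0)
        assert population_biomass(obs, cal, DEFAULT_CONVERSIONS["Cro"]) == (0.0, 0.0)

    def test_linearity_in_abundance(self, cal):
        a = FcmObservation("Syn", 0.0, "r1", 1000.0, 400.0)
        b = FcmObservation("Syn", 0.0, "r1", 2000.0, 400.0)
        n_a, _ = population_biomass(a, cal, DEFAULT_CONVERSIONS["Syn"])
        n_b, _ = population_biomass(b, cal, DEFAULT_CONVERSIONS["Syn"])
        assert n_b == pytest.approx(2.0 * n_a)


class TestFixation:
    def test_four_to_one_molar_ratio(self):
        assert ethylene_to_fixed_n(4.0, output="n2") == pytest.approx(1.0)
        assert ethylene_to_fixed_n(4.0, output="atoms") == pytest.approx(2.0)

    def test_zero_and_linearity(self):
        assert ethylene_to_fixed_n(0.0) == 0.0
        assert ethylene_to_fixed_n(3.0) + ethylene_to_fixed_n(5.0) == pytest.approx(
            ethylene_to_fixed_n(8.0)
        )

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            ethylene_to_fixed_n(-1.0)

    @pytest.mark.parametrize("increment,mortality,fixation,expected", [
        (5.0, 0.0, 5.0, 100.0),
        (5.0, 0.0, 0.0, 0.0),
        (9.0, 1.0, 1.0, 10.0),
    ])
    def test_percent_of_demand(self, increment, mortality, fixation, expected):
        pct = fixation_fraction_of_demand(increment, mortality, fixation)
        assert pct == pytest.approx(expected)

    def test_undefined_demand_flagged(self):
        assert fixation_fraction_of_demand(-2.0, 0.0, 1.0) is None


def _tiny_tables(day3_nutrient, day3_biomass):
    nutrients = pd.DataFrame(
        [
            {"day": d, "treatment": "control", "replicate": "r1", "nutrient": nut,
             "conc_nmol_l": conc, "below_detection": False}
            for d, nut, conc in [
                (0.0, "nh4", 100.0), (0.0, "no3", 20.0),
                (3.0, "nh4", day3_nutrient), (3.0, "no3", 20.0),
            ]
        ]
    )
    biomass = pd.DataFrame(
        [
            {"day": 0.0, "treatment": "control", "replicate": "r1", "group": "Cro",
             "c_nmol_l": 0.0, "n_nmol_l": 10.0},
            {"day": 3.0, "treatment": "control", "replicate": "r1", "group": "Cro",
             "c_nmol_l": 0.0, "n_nmol_l": day3_biomass},
        ]
    )
    return nutrients, biomass


class TestDrawdownVsBiomass:
    def test_closed_budget_ratio_one(self):
        nutrients, biomass = _tiny_tables(day3_nutrient=60.0, day3_biomass=50.0)
        budget = drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 3.0)
        assert budget.drawdown == pytest.approx(40.0)
        assert budget.ratio == pytest.approx(1.0)

    def test_half_explained(self):
        nutrients, biomass = _tiny_tables(day3_nutrient=60.0, day3_biomass=30.0)
        budget = drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 3.0)
        assert budget.ratio == pytest.approx(0.5)

    def test_zero_drawdown_flagged_not_nan(self):
        nutrients, biomass = _tiny_tables(day3_nutrient=100.0, day3_biomass=10.0)
        budget = drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 3.0)
        assert budget.ratio is None
        assert any("ratio-undefined" in f for f in budget.flags)

    def test_scale_invariance_of_ratio(self):
        nutrients, biomass = _tiny_tables(day3_nutrient=60.0, day3_biomass=30.0)
        scaled_n = nutrients.assign(conc_nmol_l=nutrients.conc_nmol_l * 7.0)
        scaled_b = biomass.assign(n_nmol_l=biomass.n_nmol_l * 7.0)
        a = drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 3.0)
        b = drawdown_vs_biomass(scaled_n, scaled_b, "control", 0.0, 3.0)
        assert a.ratio == pytest.approx(b.ratio)

    def test_missing_day_is_alignment_error(self):
        nutrients, biomass = _tiny_tables(60.0, 30.0)
        with pytest.raises(AlignmentError):
            drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 2.0)

    def test_censored_endpoint_substitution(self):
        nutrients, biomass = _tiny_tables(day3_nutrient=6.0, day3_biomass=30.0)
        nutrients.loc[
            (nutrients.day == 3.0) & (nutrients.nutrient == "nh4"), "below_detection"
        ] = True
        budget = drawdown_vs_biomass(nutrients, biomass, "control", 0.0, 3.0)
        assert budget.censored_endpoint
        # nh4 endpoint replaced by 6/2 = 3 -> drawdown 100-3 = 97
        assert budget.drawdown == pytest.approx(97.0)
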