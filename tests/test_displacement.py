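"""DWT → displacement conversion: coefficient interpolation, rule
evaluation, net-weight correction, and per-type dispatch."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vesselmass as vm
from vesselmass.displacement import (
    DeadweightCoefficientSpec,
    DwtConversionRule,
    MixedStrategy,
    strategy_displacement_kg,
)
from vesselmass.errors import ConfigurationError, EstimationError


class TestInterpolateCd:
    # every class ratio quoted alongside the conversion table, with the
    # endpoint range and evaluation LOA it was interpolated from
    @pytest.mark.parametrize(
        "spec_name,loa,expected",
        [
            ("large_passenger", 219.1, 0.243),
            ("ropax", 100.1, 0.233),
            ("stern_trawler", 48.6, 0.334),
            ("stern_trawler", 68.1, 0.478),
            ("stern_trawler", 93.4, 0.580),  # beyond range: clamped
            ("small_passenger", 62.2, 0.167),
            ("small_passenger", 56.3, 0.159),
            ("small_passenger", 53.2, 0.155),
            ("small_passenger", 68.1, 0.176),
            ("small_passenger", 93.4, 0.212),
        ],
    )
    def test_reproduces_quoted_class_ratios(self, strategy_table, spec_name, loa, expected):
        assert vm.interpolate_cd(strategy_table.cd_specs[spec_name], loa) == expected

    def test_lower_endpoint(self, strategy_table):
        spec = strategy_table.cd_specs["stern_trawler"]
        assert vm.interpolate_cd(spec, 44.0) == 0.300

    def test_nonpositive_loa_rejected(self, strategy_table):
        with pytest.raises(ValueError):
            vm.interpolate_cd(strategy_table.cd_specs["ropax"], 0.0)

    @given(loa=st.floats(min_value=1.0, max_value=500.0))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_and_clamped(self, strategy_table, loa):
        spec = strategy_table.cd_specs["stern_trawler"]
        cd = vm.interpolate_cd(spec, loa, decimals=None)
        assert spec.cd_lo <= cd <= spec.cd_hi
        # non-decreasing: a longer hull never has a smaller coefficient
        assert vm.interpolate_cd(spec, loa + 1.0, decimals=None) >= cd

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            DeadweightCoefficientSpec("bad", loa_lo_m=80, cd_lo=0.3, loa_hi_m=40, cd_hi=0.5)
        with pytest.raises(ConfigurationError):
            DeadweightCoefficientSpec("bad", loa_lo_m=40, cd_lo=1.3, loa_hi_m=80, cd_hi=0.5)


class TestApplyDwtRule:
    def test_ratio_rule_in_tonnes(self, strategy_table):
        rule = strategy_table.strategies[vm.VesselType.CRUISE]
        assert vm.apply_dwt_rule(rule, 10_000) == pytest.approx(41_152_000.0)

    def test_power_rule_at_unit_dwt(self, strategy_table):
        rule = strategy_table.strategies[vm.VesselType.TUG]
        assert vm.apply_dwt_rule(rule, 1.0) == pytest.approx(5230.1)

    def test_linear_rule_offset_in_us_tons(self, strategy_table):
        rule = strategy_table.strategies[vm.VesselType.TANKER]
        assert vm.apply_dwt_rule(rule, 0.0) == pytest.approx(4773.95 * 1016)

    def test_negative_dwt_rejected(self, strategy_table):
        with pytest.raises(ValueError):
            vm.apply_dwt_rule(strategy_table.strategies[vm.VesselType.TUG], -1.0)

    def test_malformed_rules_rejected(self):
        with pytest.raises(ConfigurationError):
            DwtConversionRule(form="power", scale=2.0, output_unit="tonnes")
        with pytest.raises(ConfigurationError):
            DwtConversionRule(form="ratio", scale=-1.0, output_unit="tonnes")
        with pytest.raises(ConfigurationError):
            DwtConversionRule(form="ratio", scale=1.0, output_unit="stone")


class TestNetWeightToDisplacement:
    @pytest.mark.parametrize(
        "net,capacity,expected",
        [
            (1000.0, 4, 1380.0),    # 1000 + 4*(75+20)
            (500.0, None, 595.0),   # capacity unknown: one person + luggage
            (0.0, 0, 0.0),
        ],
    )
    def test_capacity_correction(self, net, capacity, expected):
        assert vm.net_weight_to_displacement(net, capacity) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vm.net_weight_to_displacement(-1.0)


def _rec(vtype, **kw):
    kw.setdefault("loa_m", 50.0)
    return vm.VesselRecord(record_id="r", vessel_type=vtype, **kw)


class TestEstimateDisplacement:
    def test_reported_displacement_passes_through(self, strategy_table):
        rec = _rec("sailing", displacement_kg=23_733.0)
        assert vm.estimate_displacement(rec, strategy_table) == (23_733.0, "reported")

    def test_net_weight_route(self, strategy_table):
        rec = _rec("sailing", net_weight_kg=4000.0, capacity_persons=6)
        mass, method = vm.estimate_displacement(rec, strategy_table)
        assert (mass, method) == (4570.0, "net_weight")

    def test_cruise_ratio_route(self, strategy_table):
        rec = _rec("cruise", loa_m=219.1, dwt_tonnes=6059.0)
        mass, method = vm.estimate_displacement(rec, strategy_table)
        assert mass == pytest.approx(6059 * 4.1152 * 1000)
        assert method == "dwt_ratio"

    def test_mixed_category_averages_in_kg(self, strategy_table):
        # independent arithmetic: container equation (U.S. tons), then the
        # two coefficient ratios (tonnes), each converted to kg BEFORE the mean
        expected = (
            1.77955 * 1000**0.975578 * 1016
            + 1000 / 0.478 * 1000
            + 1000 / 0.176 * 1000
        ) / 3
        rec = _rec("government_research", loa_m=68.1, dwt_tonnes=1000.0)
        mass, method = vm.estimate_displacement(rec, strategy_table)
        assert mass == pytest.approx(expected, rel=1e-12)
        assert method == "dwt_mixed_mean"

    def test_no_usable_mass_field_names_record(self, strategy_table):
        rec = vm.VesselRecord.model_construct(
            record_id="ghost", vessel_type=vm.VesselType.TUG, loa_m=10.0,
            dwt_tonnes=None, displacement_kg=None, net_weight_kg=None,
            capacity_persons=None, source="ais",
        )
        with pytest.raises(EstimationError, match="ghost"):
            vm.estimate_displacement(rec, strategy_table)

    def test_per_record_cd_mode_uses_own_loa(self, strategy_table):
        # a 120 m ferry sits at the upper endpoint of its class range
        rec = _rec("ferry", loa_m=120.0, dwt_tonnes=1000.0)
        mass, _ = vm.estimate_displacement(rec, strategy_table, per_record_cd=True)
        assert mass == pytest.approx(1000 / 0.33 * 1000)

    def test_estimate_fleet_wrapper(self, strategy_table):
        recs = [_rec("cruise", loa_m=219.1, dwt_tonnes=100.0),
                _rec("sailing", displacement_kg=500.0)]
        masses, methods = vm.estimate_fleet(recs, strategy_table)
        assert methods == ["dwt_ratio", "reported"]
        assert masses[0] == pytest.approx(100 * 4.1152 * 1000)


class TestStrategyTableInvariants:
    RATIO_TYPES = {
        vm.VesselType.CRUISE: 4.1152,
        vm.VesselType.FERRY: 4.2918,
        vm.VesselType.FISHING: 2.9940,
        vm.VesselType.PASSENGER: 5.988,
        vm.VesselType.PLEASURE_CRAFT: 6.2893,
        vm.VesselType.SAILING: 6.4516,
    }

    def test_ratio_multipliers_are_reciprocal_coefficients(self, strategy_table):
        # each ratio multiplier must equal 1 / C_D to 4 decimals
        for vtype, multiplier in self.RATIO_TYPES.items():
            rule = strategy_table.strategies[vtype]
            assert rule.form == "ratio"
            assert rule.scale == multiplier
            assert round(1.0 / rule.cd, 4) == pytest.approx(multiplier, abs=5e-5)

    def test_ratio_bookkeeping_closes(self, strategy_table):
        # estimate * C_D returns the DWT in kg (tonne<->kg bookkeeping)
        for vtype in self.RATIO_TYPES:
            rule = strategy_table.strategies[vtype]
            est = vm.apply_dwt_rule(rule, 250.0)
            assert est * rule.cd == pytest.approx(250.0 * 1000, rel=1e-4)

    @pytest.mark.parametrize("dwt", [1.0, 10.0, 500.0])
    def test_ratio_strategies_homogeneous_degree_one(self, strategy_table, dwt):
        for vtype in self.RATIO_TYPES:
            rule = strategy_table.strategies[vtype]
            assert vm.apply_dwt_rule(rule, 2 * dwt) == pytest.approx(
                2 * vm.apply_dwt_rule(rule, dwt)
            )

    def test_all_twelve_types_covered(self, strategy_table):
        assert set(strategy_table.strategies) == set(vm.VesselType)

    def test_mixed_strategies_have_three_components(self, strategy_table):
        for vtype in (vm.VesselType.GOVERNMENT_RESEARCH, vm.VesselType.OTHER):
            strat = strategy_table.strategies[vtype]
            assert isinstance(strat, MixedStrategy)
            assert len(strat.components) == 3

    def test_mixed_strategy_monotone_in_dwt(self, strategy_table):
        strat = strategy_table.strategies[vm.VesselType.OTHER]
        vals = [strategy_displacement_kg(strat, d) for d in (1, 10, 100, 1000)]
        assert vals == sorted(vals)
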