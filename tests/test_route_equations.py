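"""The three route equations, aggregation, and weight-fraction rescaling."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tra_consumer import (
    CappedResultError,
    DomainError,
    ExposureScenario,
    Population,
    Substance,
    assess_scenario,
    dermal_daily_dose,
    inhalation_daily_dose,
    inhalation_event_concentration,
    oral_daily_dose,
    rescale_weight_fraction,
    saturated_vapor_concentration,
    total_exposure,
)
from tra_consumer.tra import ExposureResult


def scenario(**kw):
    base = dict(category_code="T", room_volume=20.0, event_duration=1.0)
    base.update(kw)
    return ExposureScenario(**base)


class TestInhalation:
    def test_forced_arithmetic(self, volatile_substance):
        s = scenario(product_amount=20.0, weight_fraction=1.0)
        conc = inhalation_event_concentration(s, volatile_substance)
        # 20000 mg / 20 m3 with f_rel=1 (2337 Pa, top band), below SVC
        assert conc.concentration == pytest.approx(1000.0)
        assert conc.caps_applied == ()

    def test_lowest_band_is_thousandth_of_highest(self):
        """A scenario whose top-band event average is 29700 mg/m3 drops to
        29.7 mg/m3 when the substance sits below 0.1 Pa."""
        s = scenario(product_amount=594.0, weight_fraction=1.0, event_duration=8.0)
        # MW high enough that the saturated-vapor cap stays above both values
        hi = Substance(name="hi", molecular_weight=1000.0, vapor_pressure=500.0)
        lo = Substance(name="lo", molecular_weight=1000.0, vapor_pressure=0.09)
        c_hi = inhalation_event_concentration(s, hi).concentration
        c_lo = inhalation_event_concentration(s, lo).concentration
        assert c_hi == pytest.approx(29700.0)
        assert c_lo == pytest.approx(29.7)

    def test_band_range_clothing_like(self):
        s = scenario(product_amount=37.0, weight_fraction=1.0)
        hi = Substance(name="hi", molecular_weight=166.0, vapor_pressure=200.0)
        lo = Substance(name="lo", molecular_weight=166.0, vapor_pressure=0.07)
        assert inhalation_event_concentration(s, hi).concentration == pytest.approx(1850.0)
        assert inhalation_event_concentration(s, lo).concentration == pytest.approx(1.85)

    def test_svc_cap_binds_and_is_recorded(self):
        s = scenario(product_amount=1000.0, weight_fraction=1.0)
        low_mw_low_vp = Substance(name="x", molecular_weight=100.0, vapor_pressure=8.0)
        conc = inhalation_event_concentration(s, low_mw_low_vp)
        svc = saturated_vapor_concentration(low_mw_low_vp)
        assert conc.caps_applied == ("svc_cap",)
        assert conc.concentration == pytest.approx(svc)

    def test_aerosol_ignores_vp_and_cap(self):
        s = scenario(product_amount=1000.0, weight_fraction=1.0, is_aerosol=True)
        for vp in (1e-4, 1.0, 1e4):
            sub = Substance(name="a", molecular_weight=100.0, vapor_pressure=vp)
            conc = inhalation_event_concentration(s, sub)
            assert conc.concentration == pytest.approx(5e4)  # 1e6 mg / 20 m3
            assert conc.caps_applied == ()

    def test_nonaerosol_concentration_never_exceeds_svc(self):
        s = scenario(product_amount=5000.0, weight_fraction=1.0)
        for vp in (1e-3, 0.05, 0.5, 5.0, 50.0, 5e3):
            sub = Substance(name="x", molecular_weight=120.0, vapor_pressure=vp)
            conc = inhalation_event_concentration(s, sub)
            assert conc.concentration <= saturated_vapor_concentration(sub) + 1e-9

    def test_dilution_fraction_multiplies_concentration(self, volatile_substance):
        full = scenario(product_amount=20.0)
        half = scenario(product_amount=20.0, dilution_fraction=0.5)
        assert inhalation_event_concentration(
            half, volatile_substance
        ).concentration == pytest.approx(
            0.5 * inhalation_event_concentration(full, volatile_substance).concentration
        )

    def test_daily_dose_arithmetic(self):
        s = scenario(event_duration=2.0)
        # C 632 mg/m3, IR 1 m3/h, t 2 h, n 1, BW 60 kg
        assert inhalation_daily_dose(632.0, s) == pytest.approx(21.07, abs=0.005)

    def test_daily_dose_zero_concentration(self):
        assert inhalation_daily_dose(0.0, scenario()) == 0.0

    def test_daily_dose_halving_body_weight_doubles(self):
        heavy = scenario(population=Population(body_weight=60.0))
        light = scenario(population=Population(body_weight=30.0))
        assert inhalation_daily_dose(10.0, light) == pytest.approx(
            2 * inhalation_daily_dose(10.0, heavy)
        )


class TestDermal:
    def test_areal_load_ten_mg_per_cm2(self):
        """A 0.01 cm layer at unit density carries 10 mg/cm2."""
        s = scenario(thickness_layer=0.01, contact_density=1.0, skin_contact_area=100.0)
        assert dermal_daily_dose(s).areal_load == pytest.approx(10.0)

    def test_flooring_dose(self, flooring):
        # 8750 mg/day over 60 kg -> 145.8, reported 146
        d = dermal_daily_dose(flooring)
        assert d.daily_dose * 60.0 == pytest.approx(8750.0)
        assert d.daily_dose == pytest.approx(145.8, abs=0.05)

    def test_zero_transfer_factor(self):
        s = scenario(skin_contact_area=100.0, transfer_factor=0.0)
        assert dermal_daily_dose(s).daily_dose == 0.0

    def test_nonstandard_thickness_layer_warns_not_errors(self):
        s = scenario(skin_contact_area=100.0, thickness_layer=0.005)
        d = dermal_daily_dose(s)
        assert d.daily_dose > 0
        assert any("thickness_layer" in w for w in d.warnings)


class TestOral:
    def test_arithmetic(self, child):
        s = scenario(ingested_amount=0.010, population=child)
        # 10 mg * 1 * 1 * 1 / 10 kg
        assert oral_daily_dose(s) == pytest.approx(1.0)

    def test_zero_weight_fraction(self):
        s = scenario(ingested_amount=0.010, weight_fraction=0.0)
        assert oral_daily_dose(s) == 0.0

    def test_linear_in_frequency(self):
        one = scenario(ingested_amount=0.010)
        two = scenario(ingested_amount=0.010, events_per_day=2.0)
        assert oral_daily_dose(two) == pytest.approx(2 * oral_daily_dose(one))


@st.composite
def uncapped_scenarios(draw):
    return dict(
        product_amount=draw(st.floats(0.1, 1e3)),
        weight_fraction=draw(st.floats(0.01, 1.0)),
        skin_contact_area=draw(st.floats(1.0, 2e4)),
        ingested_amount=draw(st.floats(1e-4, 0.1)),
        event_duration=draw(st.floats(0.1, 8.0)),
        events_per_day=draw(st.floats(0.5, 4.0)),
        body_weight=draw(st.floats(5.0, 100.0)),
    )


class TestLinearity:
    """Every route dose is exactly linear in WF, amounts, n and 1/BW while
    no cap binds (aerosol scenarios never cap)."""

    @given(params=uncapped_scenarios(), factor=st.floats(0.1, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_route_doses_scale_linearly(self, params, factor):
        sub = Substance(name="s", molecular_weight=150.0, vapor_pressure=100.0)

        def build(p):
            return scenario(
                is_aerosol=True,
                product_amount=p["product_amount"],
                weight_fraction=p["weight_fraction"],
                skin_contact_area=p["skin_contact_area"],
                ingested_amount=p["ingested_amount"],
                event_duration=p["event_duration"],
                events_per_day=p["events_per_day"],
                population=Population(body_weight=p["body_weight"]),
            )

        base = {r.route: r.daily_dose for r in assess_scenario(build(params), sub)}

        wf2 = dict(params, weight_fraction=min(params["weight_fraction"] * factor, 1.0))
        eff = wf2["weight_fraction"] / params["weight_fraction"]
        scaled = {r.route: r.daily_dose for r in assess_scenario(build(wf2), sub)}
        for route in base:
            assert scaled[route] == pytest.approx(eff * base[route], rel=1e-12)

        bw2 = dict(params, body_weight=params["body_weight"] * factor)
        scaled = {r.route: r.daily_dose for r in assess_scenario(build(bw2), sub)}
        for route in base:
            assert scaled[route] == pytest.approx(base[route] / factor, rel=1e-12)

        n2 = dict(params, events_per_day=params["events_per_day"] * factor)
        scaled = {r.route: r.daily_dose for r in assess_scenario(build(n2), sub)}
        for route in base:
            assert scaled[route] == pytest.approx(factor * base[route], rel=1e-12)


def bare(route, dose, **kw):
    return ExposureResult(route=route, daily_dose=dose, **kw)


class TestTotalExposure:
    def test_route_sum_dermal_plus_inhalation(self):
        total = total_exposure([bare("dermal", 46.0), bare("inhalation", 26.0)])
        assert total.daily_dose == pytest.approx(72.0)
        assert total.mass_balance_exceeded is None  # no mass bookkeeping

    def test_route_sum_with_fractional_doses(self):
        total = total_exposure([bare("inhalation", 1.4), bare("dermal", 30.0)])
        assert total.daily_dose == pytest.approx(31.4)

    def test_empty_list(self):
        assert total_exposure([]).daily_dose == 0.0

    def test_mixed_populations_rejected(self):
        with pytest.raises(DomainError):
            total_exposure(
                [
                    bare("dermal", 1.0, population_label="adult", body_weight=60.0),
                    bare("oral", 1.0, population_label="child", body_weight=10.0),
                ]
            )

    def test_mass_balance_flag_fires_for_full_release_plus_contact(self):
        """Full airborne release plus dermal and oral contact assigns more
        substance than the product contains; flagged, never corrected."""
        s = scenario(
            product_amount=20.0,
            weight_fraction=0.5,
            skin_contact_area=400.0,
            ingested_amount=0.001,
        )
        sub = Substance(name="v", molecular_weight=18.0, vapor_pressure=2337.0)
        results = assess_scenario(s, sub)
        assert {r.route for r in results} == {"inhalation", "dermal", "oral"}
        total = total_exposure(results)
        assert total.mass_balance_exceeded is True
        # the sum is still reported in full
        assert total.daily_dose == pytest.approx(sum(r.daily_dose for r in results))


class TestRescaleWeightFraction:
    def test_printed_spray_paint_rescale(self):
        """51.4 mg/kg/day at WF 0.5 rescales to 10.28 (reported 10.3) at 0.1."""
        r = bare("inhalation", 51.4, weight_fraction=0.5)
        out = rescale_weight_fraction(r, 0.5, 0.1)
        assert out.daily_dose == pytest.approx(10.28)
        assert round(out.daily_dose, 1) == 10.3

    def test_identity(self):
        r = bare("dermal", 12.0)
        assert rescale_weight_fraction(r, 0.2, 0.2).daily_dose == pytest.approx(12.0)

    def test_factor_five_reduction(self):
        """Dropping the flooring weight fraction 0.10 -> 0.02 cuts the dose
        by exactly a factor of five."""
        r = bare("dermal", 145.8, weight_fraction=0.10)
        out = rescale_weight_fraction(r, 0.10, 0.02)
        assert r.daily_dose / out.daily_dose == pytest.approx(5.0)

    def test_capped_result_refused(self):
        r = bare("inhalation", 5.0, caps_applied=("svc_cap",))
        with pytest.raises(CappedResultError):
            rescale_weight_fraction(r, 0.5, 0.1)

    def test_bad_old_wf(self):
        with pytest.raises(DomainError):
            rescale_weight_fraction(bare("oral", 1.0), 0.0, 0.1)
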