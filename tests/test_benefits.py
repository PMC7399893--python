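"""Benefit streams, their printed-table anchors, and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clts_cba as cba
from clts_cba import AgeBand, BANDS, SOURCES


def brute_force_total_benefits(p):
    """Independent double loop over years and bands, from first principles."""
    econ, epi, care, tu = p.econ, p.epi, p.care, p.timeuse
    r, g, T = econ.discount_rate, econ.income_growth, econ.horizon_years
    vsl0 = econ.vsl_override if econ.vsl_override is not None else \
        econ.vsl_reference * (econ.gni_local / econ.gni_reference) ** econ.vsl_elasticity
    trips = tu.female_fraction * tu.trips_per_day_female + \
        (1 - tu.female_fraction) * tu.trips_per_day_male
    total = 0.0
    for k in range(3):
        P = epi.population[k]
        cases = P * epi.days_averted_under5 * epi.band_ratio[k]
        if epi.deaths_averted_override is not None:
            cfr = epi.deaths_averted_override[k] / epi.deaths_override_case_basis[k]
        else:
            cfr = epi.case_fatality_rate[k]
        s = care.facility_fraction[k]
        ip, op = care.inpatient_fraction[k], care.outpatient_fraction[k]
        care_hours = s * (care.outpatient_hours_lost[k] + care.inpatient_hours_lost[k]) \
            + (1 - s) * care.nonseeking_hours_lost[k]
        care_frac = econ.caregiver_vot_fraction if k == 0 else econ.vot_fraction[k]
        for t in range(1, T + 1):
            disc = (1.0 + r) ** (-t)
            grow = (1.0 + g) ** t
            money = cases * (
                s * (care.inpatient_cost_per_case[k] * ip
                     + care.outpatient_cost_per_case[k] * op)
                + s * care.transport_cost_per_case[k]
                + s * care.meal_cost_per_case[k]
                + s * care.accommodation_cost_per_case[k] * ip
            )
            time_val = cases * care_hours * care_frac * econ.mean_hourly_income * grow
            hew = cases * s * care.hew_hours_per_case[k] \
                * econ.hew_vot_fraction * econ.hew_hourly_income * grow
            vsl = cases * cfr * vsl0 * grow
            acc = 0.0
            for src in SOURCES:
                hours = P * tu.switch_fraction[src][k] * trips \
                    * tu.minutes_per_roundtrip[src] / 60.0 * 365.0
                acc += hours * econ.vot_fraction[k] * econ.mean_hourly_income * grow
            total += disc * (money + time_val + hew + vsl + acc)
    return total


class TestQuantityStreams:
    def test_days_averted_ratios(self, params):
        assert cba.days_averted(AgeBand.UNDER5, params.epi) == pytest.approx(1.5660)
        assert cba.days_averted(AgeBand.AGE5TO14, params.epi) == \
            pytest.approx(1.5660 * 0.27)
        params.epi.days_averted_under5 = 0.0
        assert all(cba.days_averted(b, params.epi) == 0.0 for b in BANDS)

    def test_cases_reproduce_reported_totals(self, params):
        # 20,374 / 16,084 / 15,154 cases avoided over 10 years
        for band, expected in zip(BANDS, (20374, 16084, 15154)):
            total = cba.cases_averted_stream(band, params).total()
            assert round(total) == expected

    def test_stream_total_equals_per_year_loop(self, params):
        for band in BANDS:
            stream = cba.cases_averted_stream(band, params)
            per_year = params.epi.population[band.index] * cba.days_averted(band, params.epi)
            loop_total = sum(per_year for _ in range(params.econ.horizon_years))
            assert stream.total() == pytest.approx(loop_total)

    def test_deaths_from_cfr_and_override(self, params):
        cases = cba.cases_averted_stream(AgeBand.UNDER5, params)
        deaths = cba.deaths_averted(cases, 0.0007)
        assert round(deaths.total()) == 14
        assert cba.deaths_averted(cases, 0.0).total() == 0.0
        rescaled = cba.deaths_averted(cases, 0.0007, override_total=14.0)
        assert rescaled.total() == pytest.approx(14.0)

    @given(cfr=st.floats(0, 1))
    def test_deaths_bounded_by_cases(self, cfr):
        cases = cba.YearSeries(np.array([100.0, 50.0, 10.0]))
        assert cba.deaths_averted(cases, cfr).total() <= cases.total() + 1e-12

    def test_effective_cfr_matches_override_calibration(self, params):
        for band, override in zip(BANDS, (14, 3, 5)):
            cases = cba.cases_averted_stream(band, params)
            deaths = cba.deaths_averted(cases, cba.effective_cfr(band, params))
            assert deaths.total() == pytest.approx(override, rel=1e-4)


class TestValuationStreams:
    def test_zero_deaths_zero_value(self, params):
        zero = cba.YearSeries(np.zeros(10))
        assert cba.mortality_benefit_stream(zero, params.econ).total() == 0.0

    def test_mortality_growth_indexing(self, params):
        deaths = cba.YearSeries(np.ones(10))
        stream = cba.mortality_benefit_stream(deaths, params.econ)
        # one death per year: year-on-year values grow at g
        assert stream.values[9] / stream.values[0] == pytest.approx(1.02 ** 9)
        params.econ.income_growth = 0.0
        flat = cba.mortality_benefit_stream(deaths, params.econ)
        assert np.allclose(flat.values, 45194.0)

    def test_coi_zero_when_all_unit_inputs_zero(self, params):
        z = (0.0, 0.0, 0.0)
        for name in ("inpatient_cost_per_case", "outpatient_cost_per_case",
                     "transport_cost_per_case", "meal_cost_per_case",
                     "accommodation_cost_per_case", "outpatient_hours_lost",
                     "inpatient_hours_lost", "nonseeking_hours_lost",
                     "hew_hours_per_case"):
            setattr(params.care, name, z)
        items = cba.coi_per_case(AgeBand.AGE15PLUS, 1, params)
        assert all(v == 0.0 for v in items.values())

    def test_coi_single_pathway(self, params):
        params.care.facility_fraction = (1.0, 1.0, 1.0)
        params.care.inpatient_fraction = (0.0, 0.0, 0.0)
        params.care.outpatient_fraction = (1.0, 1.0, 1.0)
        params.care.outpatient_cost_per_case = (2.0, 2.0, 2.0)
        items = cba.coi_per_case(AgeBand.UNDER5, 1, params)
        assert items["treatment"] == pytest.approx(2.0)
        assert items["accommodation"] == 0.0

    def test_caregiver_item_is_one_working_day(self, params):
        # a case costs one 8-hour working day of (caregiver) time
        assert cba.care_hours_per_case(AgeBand.UNDER5, params) == pytest.approx(8.0)
        items = cba.coi_per_case(AgeBand.UNDER5, 1, params)
        expected = 8.0 * cba.care_value_of_time(AgeBand.UNDER5, 1, params.econ)
        assert items["caregiver_time"] == pytest.approx(expected)

    def test_morbidity_stream_equals_loop_oracle(self, params):
        r = params.econ.discount_rate
        streams = cba.morbidity_benefit_stream(AgeBand.UNDER5, params)
        cases = cba.cases_averted_stream(AgeBand.UNDER5, params)
        for item, series in streams.items():
            loop = sum(
                cases.values[t - 1] * cba.coi_per_case(AgeBand.UNDER5, t, params)[item]
                * (1 + r) ** (-t)
                for t in range(1, 11)
            )
            assert series.present_value(r) == pytest.approx(loop)

    def test_morbidity_subtotal_matches_reported(self, params):
        bd = cba.total_benefits_pv(params)
        under5 = sum(bd.cells[i][AgeBand.UNDER5] for i in cba.BENEFIT_ITEMS[:6])
        assert under5 == pytest.approx(122_692, rel=1e-3)
        assert bd.morbidity_total == pytest.approx(214_021, rel=1e-3)


class TestAccessibility:
    def test_zero_switch_zero_hours(self, params):
        params.timeuse.switch_fraction = {s: (0.0, 0.0, 0.0) for s in SOURCES}
        for band in BANDS:
            assert all(v == 0.0 for v in cba.accessibility_hours(band, params).values())

    def test_hand_computed_hours(self, params):
        # 100 switchers x 3.5 trips/day x 9 min x 365 d = 19,162.5 h/yr
        params.epi.population = (1301, 1000, 4608)
        params.timeuse.switch_fraction["open_defecation"] = (0.0, 0.1, 0.0)
        hours = cba.accessibility_hours(AgeBand.AGE5TO14, params)
        assert hours["open_defecation"] == pytest.approx(100 * 3.5 * 0.15 * 365)

    def test_under5_not_valued(self, params):
        stream = cba.accessibility_benefit_stream(AgeBand.UNDER5, params)
        assert all(s.total() == 0.0 for s in stream.values())

    def test_band_hours_match_reported_totals(self, params):
        # 1,101,556 h (5-14) and 963,346 h (15+) over 10 years
        for band, expected in ((AgeBand.AGE5TO14, 1_101_556),
                               (AgeBand.AGE15PLUS, 963_346)):
            per_year = sum(cba.accessibility_hours(band, params).values())
            assert per_year * 10 == pytest.approx(expected, rel=1e-3)

    def test_stream_equals_loop_oracle(self, params):
        r = params.econ.discount_rate
        hours = cba.accessibility_hours(AgeBand.AGE15PLUS, params)
        streams = cba.accessibility_benefit_stream(AgeBand.AGE15PLUS, params)
        for src in SOURCES:
            loop = sum(
                hours[src] * cba.value_of_time(AgeBand.AGE15PLUS, t, params.econ)
                * (1 + r) ** (-t)
                for t in range(1, 11)
            )
            assert streams[src].present_value(r) == pytest.approx(loop)


class TestAggregation:
    def test_degenerate_horizon_undiscounted(self, params):
        params.econ.discount_rate = 0.0
        params.econ.income_growth = 0.0
        params.econ.horizon_years = 1
        params.epi.deaths_override_case_basis = tuple(
            b / 10.0 for b in params.epi.deaths_override_case_basis
        )
        bd = cba.total_benefits_pv(params)
        # with T=1, r=g=0 the PV is exactly one year's flow: 10x smaller than
        # the 10-year undiscounted total
        params.econ.horizon_years = 10
        bd10 = cba.total_benefits_pv(params)
        assert bd10.grand_total == pytest.approx(10 * bd.grand_total)

    def test_grand_total_matches_reported(self, base_result):
        assert base_result.benefits.grand_total == pytest.approx(1_638_684, rel=2e-3)

    def test_equals_brute_force_double_loop(self, params):
        bd = cba.total_benefits_pv(params)
        assert bd.grand_total == pytest.approx(
            brute_force_total_benefits(params), rel=1e-10
        )

    def test_conservation_grand_total_is_sum_of_cells(self, base_result):
        bd = base_result.benefits
        cells = sum(bd.cells[item][b] for item in bd.cells for b in BANDS)
        assert bd.grand_total == pytest.approx(cells, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 13.7])
    def test_scale_equivariance_in_money(self, params, c):
        base = cba.total_benefits_pv(params).grand_total
        params.econ.vsl_override *= c
        params.econ.mean_hourly_income *= c
        params.econ.hew_hourly_income *= c
        for name in ("inpatient_cost_per_case", "outpatient_cost_per_case",
                     "transport_cost_per_case", "meal_cost_per_case",
                     "accommodation_cost_per_case"):
            setattr(params.care, name,
                    tuple(c * v for v in getattr(params.care, name)))
        assert cba.total_benefits_pv(params).grand_total == pytest.approx(c * base)

    def test_pv_nonincreasing_in_discount_rate(self, params):
        totals = []
        for r in (0.0, 0.02, 0.05, 0.08, 0.15):
            params.econ.discount_rate = r
            totals.append(cba.total_benefits_pv(params).grand_total)
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.08])
    def test_constant_stream_pv_is_annuity(self, r):
        stream = cba.YearSeries.constant(123.4, 10)
        loop = sum(123.4 * (1 + r) ** (-t) for t in range(1, 11))
        assert stream.present_value(r) == pytest.approx(loop)
        assert stream.present_value(r) == pytest.approx(123.4 * cba.annuity_factor(10, r))
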