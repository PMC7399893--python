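"""Benefit side of the model: mortality, morbidity, and accessibility.

Three benefit components are computed as year-indexed streams and then
discounted into a present-value breakdown by item and age band:

* averted premature deaths, valued by the value of a statistical life (VSL);
* averted diarrhoea cases, valued by the cost of illness (treatment,
  transport, meals, accommodation, caregiver time, health-professional time);
* time saved by households that switched from walking to an open defecation
  site, a communal latrine, or a neighbour's latrine to their own latrine.

A "case" is a diarrhoea-day. Quantity streams are constant in the base case;
scenarios pass per-year multipliers (behavioural slippage shrinks effects,
population growth scales the population).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    BANDS,
    SOURCES,
    AgeBand,
    EpiParams,
    ParameterSet,
    care_value_of_time,
    effective_vsl,
    growth_factor,
    hew_value_of_time,
    value_of_time,
)

#: Benefit items in Table layout order (rows of the benefit panel).
BENEFIT_ITEMS: tuple[str, ...] = (
    "treatment",
    "transport",
    "meals",
    "accommodation",
    "caregiver_time",
    "health_professional_time",
    "vsl",
    "switch_open_defecation",
    "switch_communal",
    "switch_neighbour",
)

MORBIDITY_ITEMS: tuple[str, ...] = BENEFIT_ITEMS[:6]


@dataclass
class YearSeries:
    """A money- or count-valued stream over years t = 1..T."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("YearSeries must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("YearSeries values must be finite")

    @classmethod
    def constant(cls, value: float, horizon: int) -> "YearSeries":
        return cls(np.full(horizon, float(value)))

    @property
    def horizon(self) -> int:
        return len(self.values)

    def total(self) -> float:
        return float(self.values.sum())

    def present_value(self, rate: float) -> float:
        """Discounted sum: sum_t v_t (1+rate)^-t."""
        t = np.arange(1, self.horizon + 1)
        return float(np.sum(self.values * (1.0 + rate) ** (-t)))

    def __mul__(self, other) -> "YearSeries":
        return YearSeries(self.values * np.asarray(other, dtype=float))

    __rmul__ = __mul__


@dataclass
class BenefitBreakdown:
    """Present-value benefits by item and age band (the benefit panel).

    ``cells[item][band]`` holds the discounted present value of one item for
    one band; subtotals and the grand total are sums of cells.
    """

    cells: dict[str, dict[AgeBand, float]] = field(default_factory=dict)

    def item_subtotal(self, item: str) -> float:
        return sum(self.cells[item].values())

    def band_subtotal(self, band: AgeBand) -> float:
        return sum(self.cells[item][band] for item in self.cells)

    @property
    def morbidity_total(self) -> float:
        return sum(self.item_subtotal(i) for i in MORBIDITY_ITEMS)

    @property
    def mortality_total(self) -> float:
        return self.item_subtotal("vsl")

    @property
    def accessibility_total(self) -> float:
        return sum(self.item_subtotal(i) for i in BENEFIT_ITEMS[7:])

    @property
    def grand_total(self) -> float:
        return sum(self.item_subtotal(item) for item in self.cells)

    def to_frame(self):
        """Benefit panel as a DataFrame (items x bands, with subtotal col)."""
        import pandas as pd

        rows = {}
        for item in BENEFIT_ITEMS:
            rows[item] = {b.value: self.cells[item][b] for b in BANDS}
            rows[item]["subtotal"] = self.item_subtotal(item)
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.loc["total"] = [
            self.band_subtotal(b) for b in BANDS
        ] + [self.grand_total]
        return frame


# ---------------------------------------------------------------------------
# quantity streams
# ---------------------------------------------------------------------------

def days_averted(band: AgeBand, epi: EpiParams) -> float:
    """Diarrhoea-days averted per person-year in ``band``."""
    return epi.days_averted_under5 * epi.band_ratio[band.index]


def _multipliers(p: ParameterSet, quantity_multiplier, population_multiplier):
    T = p.econ.horizon_years
    q = np.ones(T) if quantity_multiplier is None else np.asarray(quantity_multiplier, float)
    m = np.ones(T) if population_multiplier is None else np.asarray(population_multiplier, float)
    if len(q) != T or len(m) != T:
        raise ValueError("multiplier length must equal the horizon")
    return q * m


def cases_averted_stream(
    band: AgeBand,
    p: ParameterSet,
    quantity_multiplier=None,
    population_multiplier=None,
) -> YearSeries:
    """Cases (diarrhoea-days) averted per year: P_k x days averted."""
    base = p.epi.population[band.index] * days_averted(band, p.epi)
    mult = _multipliers(p, quantity_multiplier, population_multiplier)
    return YearSeries(base * mult)


def effective_cfr(band: AgeBand, p: ParameterSet) -> float:
    """Case-fatality rate actually applied to the cases-averted stream.

    A calibrated deaths override is converted into deaths-per-case against
    the fixed case basis it was calibrated on, so changing the horizon, the
    trial effect, or scenario multipliers scales deaths together with cases
    instead of pinning the calibrated totals.
    """
    k = band.index
    if p.epi.deaths_averted_override is None:
        return p.epi.case_fatality_rate[k]
    return p.epi.deaths_averted_override[k] / p.epi.deaths_override_case_basis[k]


def deaths_averted(
    cases: YearSeries, cfr: float, override_total: float | None = None
) -> YearSeries:
    """Deaths averted per year: cases x CFR, optionally rescaled.

    With ``override_total`` set, the stream is rescaled so its sum equals the
    override (calibration against a reported total).
    """
    if not 0.0 <= cfr <= 1.0:
        raise ValueError("cfr out of [0,1]")
    deaths = YearSeries(cases.values * cfr)
    if override_total is not None:
        total = deaths.total()
        if total > 0:
            deaths = YearSeries(deaths.values * (override_total / total))
        elif override_total > 0:
            # no CFR signal to distribute over: spread uniformly
            deaths = YearSeries.constant(override_total / cases.horizon, cases.horizon)
    return deaths


# ---------------------------------------------------------------------------
# valuation streams (undiscounted; discounting happens at aggregation)
# ---------------------------------------------------------------------------

def mortality_benefit_stream(deaths: YearSeries, econ) -> YearSeries:
    """Deaths valued at the year-t VSL: deaths_t x VSL_0 x (1+g)^t."""
    vsl0 = effective_vsl(econ)
    t = np.arange(1, deaths.horizon + 1)
    return YearSeries(deaths.values * vsl0 * (1.0 + econ.income_growth) ** t)


def coi_per_case(band: AgeBand, year: int, p: ParameterSet) -> dict[str, float]:
    """Cost of illness per case in ``band`` and ``year``, itemized.

    Facility-seekers (share SMT) incur treatment (inpatient/outpatient
    blend), transport, meals, accommodation (inpatient only), the carer's or
    sick person's lost working hours, and health-extension-worker time;
    non-seekers incur lost working hours only. Self-treatment is valued at
    zero.
    """
    k = band.index
    c = p.care
    s = c.facility_fraction[k]
    ip, op = c.inpatient_fraction[k], c.outpatient_fraction[k]
    vot = care_value_of_time(band, year, p.econ)
    hew = hew_value_of_time(year, p.econ)
    hours_seek = c.outpatient_hours_lost[k] + c.inpatient_hours_lost[k]
    return {
        "treatment": s * (c.inpatient_cost_per_case[k] * ip + c.outpatient_cost_per_case[k] * op),
        "transport": s * c.transport_cost_per_case[k],
        "meals": s * c.meal_cost_per_case[k],
        "accommodation": s * c.accommodation_cost_per_case[k] * ip,
        "caregiver_time": (s * hours_seek + (1 - s) * c.nonseeking_hours_lost[k]) * vot,
        "health_professional_time": s * c.hew_hours_per_case[k] * hew,
    }


def care_hours_per_case(band: AgeBand, p: ParameterSet) -> float:
    """Expected caregiver/sick-person hours lost per case (care pathway mix)."""
    k = band.index
    c = p.care
    s = c.facility_fraction[k]
    return s * (c.outpatient_hours_lost[k] + c.inpatient_hours_lost[k]) + (
        1 - s
    ) * c.nonseeking_hours_lost[k]


def morbidity_benefit_stream(
    band: AgeBand,
    p: ParameterSet,
    quantity_multiplier=None,
    population_multiplier=None,
) -> dict[str, YearSeries]:
    """Cost-of-illness benefit per year, itemized: cases x per-case COI."""
    cases = cases_averted_stream(band, p, quantity_multiplier, population_multiplier)
    T = p.econ.horizon_years
    items: dict[str, list[float]] = {item: [] for item in MORBIDITY_ITEMS[:6]}
    for t in range(1, T + 1):
        per_case = coi_per_case(band, t, p)
        for item, v in per_case.items():
            items[item].append(cases.values[t - 1] * v)
    return {item: YearSeries(np.array(vals)) for item, vals in items.items()}


def accessibility_hours(band: AgeBand, p: ParameterSet) -> dict[str, float]:
    """Hours saved per year, by source, from switching to a household latrine.

    P_k x switch fraction x round trips/day (sex-averaged) x minutes/60 x 365.
    Zero for under-5s.
    """
    if band is AgeBand.UNDER5:
        return {src: 0.0 for src in SOURCES}
    k = band.index
    tu = p.timeuse
    pop = p.epi.population[k]
    trips = tu.trips_per_day_average
    out = {}
    for src in SOURCES:
        frac = tu.switch_fraction[src][k]
        minutes = tu.minutes_per_roundtrip[src]
        out[src] = pop * frac * trips * (minutes / 60.0) * 365.0
    return out


def accessibility_benefit_stream(
    band: AgeBand,
    p: ParameterSet,
    quantity_multiplier=None,
    population_multiplier=None,
) -> dict[str, YearSeries]:
    """Accessibility hours valued at the band's own value of time, by source."""
    hours = accessibility_hours(band, p)
    T = p.econ.horizon_years
    mult = _multipliers(p, quantity_multiplier, population_multiplier)
    out = {}
    for src in SOURCES:
        if band is AgeBand.UNDER5:
            vals = np.zeros(T)
        else:
            vot = np.array([value_of_time(band, t, p.econ) for t in range(1, T + 1)])
            vals = hours[src] * vot * mult
        out[src] = YearSeries(vals)
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def total_benefits_pv(
    p: ParameterSet,
    quantity_multiplier=None,
    population_multiplier=None,
) -> BenefitBreakdown:
    """Discount every benefit stream and assemble the item x band panel."""
    p.require_valid()
    r = p.econ.discount_rate
    cells: dict[str, dict[AgeBand, float]] = {item: {} for item in BENEFIT_ITEMS}

    for band in BANDS:
        cases = cases_averted_stream(band, p, quantity_multiplier, population_multiplier)
        deaths = deaths_averted(cases, effective_cfr(band, p))
        cells["vsl"][band] = mortality_benefit_stream(deaths, p.econ).present_value(r)

        morb = morbidity_benefit_stream(band, p, quantity_multiplier, population_multiplier)
        for item, series in morb.items():
            cells[item][band] = series.present_value(r)

        acc = accessibility_benefit_stream(band, p, quantity_multiplier, population_multiplier)
        for src in SOURCES:
            cells[f"switch_{src}"][band] = acc[src].present_value(r)

    return BenefitBreakdown(cells=cells)
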