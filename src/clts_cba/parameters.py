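"""Parameter set for the sanitation cost-benefit model.

Every symbol of the model lives here: populations and epidemiology, care
seeking and cost-of-illness inputs, latrine-access time use, and the economic
constants (discount rate, income growth, value-of-statistical-life transfer).
Parameters load from a TOML config with explicit units in key names; unknown
keys are rejected so a typo cannot silently fall back to a default.

Monetary values are constant 2016 international dollars throughout. Incomes
and the VSL are survey values at time 0; year-t flows are valued at
``base * (1+g)**t`` and discounted at ``(1+r)**-t`` (end-of-year flows).
"""

from __future__ import annotations

import dataclasses
import enum
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any


class ParameterError(ValueError):
    """Raised for config parse failures, unknown keys, or domain errors."""


class AgeBand(enum.Enum):
    """The three age strata of the model: <5, 5-14, and 15+ years."""

    UNDER5 = "under5"
    AGE5TO14 = "age5to14"
    AGE15PLUS = "age15plus"

    @property
    def index(self) -> int:
        return BANDS.index(self)


BANDS: tuple[AgeBand, ...] = (AgeBand.UNDER5, AgeBand.AGE5TO14, AgeBand.AGE15PLUS)

#: Walking-destination sources a household can switch away from.
SOURCES: tuple[str, ...] = ("open_defecation", "communal", "neighbour")

Triple = tuple[float, float, float]


def _triple(x: Any, name: str) -> Triple:
    try:
        vals = tuple(float(v) for v in x)
    except TypeError as exc:
        raise ParameterError(f"{name}: expected a 3-element list") from exc
    if len(vals) != 3:
        raise ParameterError(f"{name}: expected exactly 3 values (one per age band)")
    return vals  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EpiParams:
    """Population sizes and diarrhoea burden reduction.

    ``days_averted_under5`` is the trial effect: diarrhoea-days averted per
    under-5 child per year. Other bands scale by ``band_ratio``. A "case"
    is a diarrhoea-day throughout the model. ``deaths_averted_override``
    optionally pins the total deaths averted per band over the horizon
    (a calibration; implemented as an effective case-fatality rate so that
    scenarios scaling cases scale deaths with them).
    """

    population: Triple = (1301, 3804, 4608)
    days_averted_under5: float = 1.5660
    band_ratio: Triple = (1.0, 0.27, 0.21)
    case_fatality_rate: Triple = (0.0007, 0.0005, 0.0003)
    deaths_averted_override: Triple | None = None
    deaths_override_case_basis: Triple | None = None

    def validate(self) -> list[str]:
        errs = []
        for i, p in enumerate(self.population):
            if p < 0 or p != int(p):
                errs.append(f"epi.population[{i}]: must be a non-negative integer")
        for i, c in enumerate(self.case_fatality_rate):
            if not 0.0 <= c <= 1.0:
                errs.append(f"epi.case_fatality_rate[{i}]: cfr out of [0,1]")
        if self.days_averted_under5 < 0:
            errs.append("epi.days_averted_under5: must be >= 0")
        if self.band_ratio[0] != 1.0:
            errs.append("epi.band_ratio[0]: under-5 ratio must be 1")
        if any(r < 0 for r in self.band_ratio):
            errs.append("epi.band_ratio: ratios must be >= 0")
        if self.deaths_averted_override is not None:
            if any(d < 0 for d in self.deaths_averted_override):
                errs.append("epi.deaths_averted_override: deaths must be >= 0")
            if self.deaths_override_case_basis is None:
                errs.append(
                    "epi.deaths_averted_override: needs deaths_override_case_basis "
                    "(total cases the override totals were calibrated against)"
                )
            elif any(b <= 0 for b in self.deaths_override_case_basis):
                errs.append("epi.deaths_override_case_basis: must be > 0")
        return errs


@dataclass
class CareSeekingParams:
    """Cost-of-illness inputs, one value per age band.

    Fractions: ``facility_fraction`` (SMT) is the share of cases taken to a
    health facility; ``inpatient_fraction``/``outpatient_fraction`` split the
    facility-seekers. Unit costs are money per case on the relevant pathway.
    Hours are working hours lost per case; ``hew_hours_per_case`` is the
    health-extension-worker time absorbed per facility-seeking case.
    """

    facility_fraction: Triple = (0.56, 0.56, 0.56)
    inpatient_fraction: Triple = (0.089286, 0.089286, 0.089286)
    outpatient_fraction: Triple = (0.910714, 0.910714, 0.910714)
    inpatient_cost_per_case: Triple = (0.0, 0.0, 0.0)
    outpatient_cost_per_case: Triple = (0.0, 0.0, 0.0)
    transport_cost_per_case: Triple = (0.0, 0.0, 0.0)
    meal_cost_per_case: Triple = (0.0, 0.0, 0.0)
    accommodation_cost_per_case: Triple = (0.0, 0.0, 0.0)
    outpatient_hours_lost: Triple = (7.285714, 7.285714, 7.285714)
    inpatient_hours_lost: Triple = (0.714286, 0.714286, 0.714286)
    nonseeking_hours_lost: Triple = (8.0, 8.0, 8.0)
    hew_hours_per_case: Triple = (0.0, 0.0, 0.0)
    care_days_per_case: float = 1.0

    def validate(self) -> list[str]:
        errs = []
        for name in ("facility_fraction", "inpatient_fraction", "outpatient_fraction"):
            for i, v in enumerate(getattr(self, name)):
                if not 0.0 <= v <= 1.0:
                    errs.append(f"care.{name}[{i}]: fraction out of [0,1]")
        for i, (ip, op) in enumerate(
            zip(self.inpatient_fraction, self.outpatient_fraction)
        ):
            if ip + op > 1.0 + 1e-9:
                errs.append(f"care: inpatient_fraction[{i}] + outpatient_fraction[{i}] > 1")
        for name in (
            "inpatient_cost_per_case", "outpatient_cost_per_case",
            "transport_cost_per_case", "meal_cost_per_case",
            "accommodation_cost_per_case", "outpatient_hours_lost",
            "inpatient_hours_lost", "nonseeking_hours_lost", "hew_hours_per_case",
        ):
            for i, v in enumerate(getattr(self, name)):
                if v < 0:
                    errs.append(f"care.{name}[{i}]: must be >= 0")
        if self.care_days_per_case < 0:
            errs.append("care.care_days_per_case: must be >= 0")
        return errs


@dataclass
class TimeUseParams:
    """Latrine-accessibility time use.

    ``switch_fraction[source]`` gives, per band, the fraction of the band that
    switched from walking to *source* (open defecation site, communal latrine,
    neighbour's latrine) to a household latrine. Trip frequency is sex
    specific (community report: six round trips/day for women, one for men).
    """

    switch_fraction: dict[str, Triple] = field(
        default_factory=lambda: {s: (0.0, 0.0, 0.0) for s in SOURCES}
    )
    minutes_per_roundtrip: dict[str, float] = field(
        default_factory=lambda: {"open_defecation": 9.0, "communal": 7.0, "neighbour": 5.0}
    )
    trips_per_day_female: float = 6.0
    trips_per_day_male: float = 1.0
    female_fraction: float = 0.5

    @property
    def trips_per_day_average(self) -> float:
        f = self.female_fraction
        return f * self.trips_per_day_female + (1 - f) * self.trips_per_day_male

    def validate(self) -> list[str]:
        errs = []
        for src in SOURCES:
            if src not in self.switch_fraction:
                errs.append(f"timeuse.switch_fraction: missing source '{src}'")
                continue
            for i, v in enumerate(self.switch_fraction[src]):
                if not 0.0 <= v <= 1.0:
                    errs.append(f"timeuse.switch_fraction.{src}[{i}]: fraction out of [0,1]")
        for src, v in self.minutes_per_roundtrip.items():
            if v < 0:
                errs.append(f"timeuse.minutes_per_roundtrip.{src}: must be >= 0")
        if self.trips_per_day_female < 0 or self.trips_per_day_male < 0:
            errs.append("timeuse: trips per day must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            errs.append("timeuse.female_fraction: fraction out of [0,1]")
        return errs


@dataclass
class EconParams:
    """Economic constants.

    ``vot_fraction`` is the fraction of the mean hourly income at which an
    hour of a band member's own time is valued (0 for under-5s, whose time is
    not valued; their sickness time is carried by an adult caregiver at
    ``caregiver_vot_fraction``). ``vsl_override``, when set, replaces the
    benefit-transfer VSL with a pinned value.
    """

    discount_rate: float = 0.03
    horizon_years: int = 10
    income_growth: float = 0.02
    vsl_reference: float = 8.9e6
    gni_reference: float = 58700.0
    gni_local: float = 1730.0
    vsl_elasticity: float = 1.5
    vsl_override: float | None = None
    mean_hourly_income: float = 0.67
    vot_fraction: Triple = (0.0, 0.25, 0.5)
    caregiver_vot_fraction: float = 0.5
    hew_hourly_income: float = 1.79
    hew_vot_fraction: float = 1.0
    working_hours_per_year: float = 1920.0
    households: int = 1737
    communities: int = 24

    def validate(self) -> list[str]:
        errs = []
        if self.horizon_years < 1 or self.horizon_years != int(self.horizon_years):
            errs.append("econ.horizon_years: must be an integer >= 1")
        if self.discount_rate < 0:
            errs.append("econ.discount_rate: must be >= 0")
        if self.income_growth < 0:
            errs.append("econ.income_growth: must be >= 0")
        for i, v in enumerate(self.vot_fraction):
            if not 0.0 <= v <= 1.0:
                errs.append(f"econ.vot_fraction[{i}]: fraction out of [0,1]")
        if not 0.0 <= self.caregiver_vot_fraction <= 1.0:
            errs.append("econ.caregiver_vot_fraction: fraction out of [0,1]")
        if not 0.0 <= self.hew_vot_fraction <= 1.0:
            errs.append("econ.hew_vot_fraction: fraction out of [0,1]")
        if self.working_hours_per_year <= 0:
            errs.append("econ.working_hours_per_year: must be > 0")
        for name in ("vsl_reference", "gni_reference", "gni_local"):
            if getattr(self, name) <= 0:
                errs.append(f"econ.{name}: must be > 0")
        if self.households <= 0:
            errs.append("econ.households: must be > 0")
        if self.communities <= 0:
            errs.append("econ.communities: must be > 0")
        return errs


@dataclass
class ParameterSet:
    """The full, validated input of a model run."""

    epi: EpiParams = field(default_factory=EpiParams)
    care: CareSeekingParams = field(default_factory=CareSeekingParams)
    timeuse: TimeUseParams = field(default_factory=TimeUseParams)
    econ: EconParams = field(default_factory=EconParams)
    om_fraction: float = 0.10
    education_fraction: float = 0.10
    program_ledger_path: Path | None = None
    local_ledger_path: Path | None = None

    def validate(self) -> list[str]:
        errs = (
            self.epi.validate()
            + self.care.validate()
            + self.timeuse.validate()
            + self.econ.validate()
        )
        for name in ("om_fraction", "education_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errs.append(f"{name}: fraction out of [0,1]")
        return errs

    def require_valid(self) -> "ParameterSet":
        errs = self.validate()
        if errs:
            raise ParameterError("invalid parameter set:\n" + "\n".join(errs))
        return self


def validate(p: ParameterSet) -> list[str]:
    """Return every invariant violation in ``p`` (empty list = valid)."""
    return p.validate()


# ---------------------------------------------------------------------------
# derived economic quantities
# ---------------------------------------------------------------------------

def benefit_transfer_vsl(
    vsl_ref: float, gni_ref: float, gni_local: float, elasticity: float
) -> float:
    """Transfer a reference VSL across countries by income scaling.

    Returns ``vsl_ref * (gni_local / gni_ref) ** elasticity``.
    """
    if vsl_ref <= 0 or gni_ref <= 0 or gni_local <= 0:
        raise ParameterError("benefit_transfer_vsl: all inputs must be > 0")
    return vsl_ref * (gni_local / gni_ref) ** elasticity


def effective_vsl(econ: EconParams) -> float:
    """Base-year VSL: the override if pinned, else the benefit transfer."""
    if econ.vsl_override is not None:
        return econ.vsl_override
    return benefit_transfer_vsl(
        econ.vsl_reference, econ.gni_reference, econ.gni_local, econ.vsl_elasticity
    )


def hourly_income(annual_income: float, working_hours: float) -> float:
    """Convert annual income to an hourly wage (default 1920 h/year)."""
    if working_hours <= 0:
        raise ParameterError("hourly_income: working_hours must be > 0")
    return annual_income / working_hours


def growth_factor(econ: EconParams, year: int) -> float:
    """Income growth multiplier for year t: (1+g)**t (base values at t=0)."""
    return (1.0 + econ.income_growth) ** year


def value_of_time(band: AgeBand, year: int, econ: EconParams) -> float:
    """Value of one hour of a band member's own time in year t (money/h).

    Zero for under-5 children, whose time is not valued.
    """
    if not isinstance(band, AgeBand):
        raise ParameterError(f"value_of_time: unknown band {band!r}")
    if not 1 <= year <= econ.horizon_years:
        raise ParameterError(f"value_of_time: year {year} outside 1..{econ.horizon_years}")
    frac = econ.vot_fraction[band.index]
    return frac * econ.mean_hourly_income * growth_factor(econ, year)


def care_value_of_time(band: AgeBand, year: int, econ: EconParams) -> float:
    """Hourly value applied to sickness/care time for a case in ``band``.

    An under-5 case costs an adult caregiver's time (valued at
    ``caregiver_vot_fraction``); older cases cost the sick person's own time.
    """
    if band is AgeBand.UNDER5:
        return econ.caregiver_vot_fraction * econ.mean_hourly_income * growth_factor(econ, year)
    return value_of_time(band, year, econ)


def hew_value_of_time(year: int, econ: EconParams) -> float:
    """Hourly value of health-extension-worker time in year t."""
    return econ.hew_vot_fraction * econ.hew_hourly_income * growth_factor(econ, year)


# ---------------------------------------------------------------------------
# config I/O (TOML)
# ---------------------------------------------------------------------------

_SECTION_TYPES: dict[str, type] = {
    "epi": EpiParams,
    "care": CareSeekingParams,
    "timeuse": TimeUseParams,
    "econ": EconParams,
}

_TRIPLE_FIELDS = {
    "population", "band_ratio", "case_fatality_rate", "deaths_averted_override",
    "deaths_override_case_basis",
    "facility_fraction", "inpatient_fraction", "outpatient_fraction",
    "inpatient_cost_per_case", "outpatient_cost_per_case",
    "transport_cost_per_case", "meal_cost_per_case", "accommodation_cost_per_case",
    "outpatient_hours_lost", "inpatient_hours_lost", "nonseeking_hours_lost",
    "hew_hours_per_case", "vot_fraction",
}

_COSTS_KEYS = {"om_fraction", "education_fraction", "program_ledger", "local_ledger"}


def _build_section(cls: type, data: dict, section: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, val in data.items():
        if key not in known:
            raise ParameterError(f"[{section}] unknown key '{key}'")
        if key in _TRIPLE_FIELDS:
            kwargs[key] = _triple(val, f"{section}.{key}")
        elif key == "switch_fraction":
            if not isinstance(val, dict):
                raise ParameterError("timeuse.switch_fraction must be a table")
            out = {}
            for src, fracs in val.items():
                if src not in SOURCES:
                    raise ParameterError(f"timeuse.switch_fraction: unknown source '{src}'")
                out[src] = _triple(fracs, f"timeuse.switch_fraction.{src}")
            kwargs[key] = out
        elif key == "minutes_per_roundtrip":
            if not isinstance(val, dict):
                raise ParameterError("timeuse.minutes_per_roundtrip must be a table")
            for src in val:
                if src not in SOURCES:
                    raise ParameterError(
                        f"timeuse.minutes_per_roundtrip: unknown source '{src}'"
                    )
            kwargs[key] = {src: float(v) for src, v in val.items()}
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a TOML config file.

    Missing optional keys take the documented defaults; unknown keys and
    invariant violations raise :class:`ParameterError`.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ParameterError(f"config file not found: {path}")
    except tomllib.TOMLDecodeError as exc:
        raise ParameterError(f"config parse failure in {path}: {exc}")

    kwargs: dict[str, Any] = {}
    for section, data in raw.items():
        if section in _SECTION_TYPES:
            kwargs[section] = _build_section(_SECTION_TYPES[section], data, section)
        elif section == "costs":
            for key, val in data.items():
                if key not in _COSTS_KEYS:
                    raise ParameterError(f"[costs] unknown key '{key}'")
                if key in ("om_fraction", "education_fraction"):
                    kwargs[key] = float(val)
                else:
                    target = "program_ledger_path" if key == "program_ledger" else "local_ledger_path"
                    kwargs[target] = (path.parent / val).resolve()
        else:
            raise ParameterError(f"unknown config section '{section}'")

    p = ParameterSet(**kwargs)
    errs = p.validate()
    if errs:
        raise ParameterError(
            f"validation errors in {path}:\n" + "\n".join(errs)
        )
    return p


def _toml_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        if isinstance(v, float) and (math.isnan(v) or math.isinf(v)):
            raise ParameterError("cannot serialize non-finite value")
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def _toml_value(v: Any) -> str:
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    return _toml_scalar(v)


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write ``p`` as a TOML config; ``load_parameters`` round-trips it."""
    path = Path(path)
    lines: list[str] = []
    for section, obj in (("epi", p.epi), ("care", p.care), ("econ", p.econ)):
        lines.append(f"[{section}]")
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            if val is None:
                continue
            lines.append(f"{f.name} = {_toml_value(val)}")
        lines.append("")
    tu = p.timeuse
    lines.append("[timeuse]")
    for name in ("trips_per_day_female", "trips_per_day_male", "female_fraction"):
        lines.append(f"{name} = {_toml_value(getattr(tu, name))}")
    lines.append("")
    lines.append("[timeuse.minutes_per_roundtrip]")
    for src in SOURCES:
        if src in tu.minutes_per_roundtrip:
            lines.append(f"{src} = {_toml_value(tu.minutes_per_roundtrip[src])}")
    lines.append("")
    lines.append("[timeuse.switch_fraction]")
    for src in SOURCES:
        if src in tu.switch_fraction:
            lines.append(f"{src} = {_toml_value(tu.switch_fraction[src])}")
    lines.append("")
    lines.append("[costs]")
    lines.append(f"om_fraction = {_toml_value(p.om_fraction)}")
    lines.append(f"education_fraction = {_toml_value(p.education_fraction)}")
    if p.program_ledger_path is not None:
        lines.append(f'program_ledger = "{p.program_ledger_path}"')
    if p.local_ledger_path is not None:
        lines.append(f'local_ledger = "{p.local_ledger_path}"')
    path.write_text("\n".join(lines) + "\n")


def default_config_path() -> Path:
    """Path of the packaged base-case config."""
    return Path(str(resources.files("clts_cba").joinpath("data/base_case.toml")))


def load_default_parameters() -> ParameterSet:
    """The packaged base-case calibration (24 intervention villages, 2016)."""
    return load_parameters(default_config_path())
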