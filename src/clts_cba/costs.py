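"""Cost side of the model: ledgers, annualization, and present-value totals.

Costs are line items in CSV ledgers, tagged program/local and
capital/recurrent, valued in exactly one of three ways: a direct money
amount (top-down, from financial records), people x hours x hourly rate
(bottom-up time), or units x unit price (materials). Initial costs are lump
sums; operation & maintenance and hygiene education recur each year at a
fraction of the *annualized* initial capital, which makes their present
value equal to fraction x capital independently of the discount rate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import ParameterSet

LEDGER_COLUMNS = (
    "label", "actor", "category", "kind",
    "people", "hours_per_person", "hourly_rate",
    "units", "unit_price", "amount", "lifespan_years",
)


class LedgerError(ValueError):
    """Raised for malformed ledger rows."""


@dataclass
class CostItem:
    """One cost-ledger line; exactly one valuation form must be set."""

    label: str
    actor: str
    category: str              # "program" | "local"
    kind: str                  # "capital" | "recurrent"
    people: float | None = None
    hours_per_person: float | None = None
    hourly_rate: float | None = None
    units: float | None = None
    unit_price: float | None = None
    amount: float | None = None
    lifespan_years: float | None = None

    @property
    def valuation_form(self) -> str:
        forms = []
        if self.amount is not None:
            forms.append("money")
        if self.people is not None or self.hours_per_person is not None:
            forms.append("time")
        if self.units is not None or self.unit_price is not None:
            forms.append("material")
        if len(forms) != 1:
            raise LedgerError(
                f"item '{self.label}': exactly one valuation form required, got {forms or 'none'}"
            )
        return forms[0]

    def value(self, default_hourly_rate: float | None = None) -> float:
        """Money value of the item; time rows without a rate use the default."""
        form = self.valuation_form
        if form == "money":
            return float(self.amount)
        if form == "time":
            if self.people is None or self.hours_per_person is None:
                raise LedgerError(f"item '{self.label}': time valuation needs people and hours")
            rate = self.hourly_rate if self.hourly_rate is not None else default_hourly_rate
            if rate is None:
                raise LedgerError(f"item '{self.label}': no hourly rate available")
            return time_cost(self.people, self.hours_per_person, rate)
        if self.units is None or self.unit_price is None:
            raise LedgerError(f"item '{self.label}': material valuation needs units and unit_price")
        return float(self.units) * float(self.unit_price)

    def validate(self) -> list[str]:
        errs = []
        if self.category not in ("program", "local"):
            errs.append(f"item '{self.label}': unknown category '{self.category}'")
        if self.kind not in ("capital", "recurrent"):
            errs.append(f"item '{self.label}': unknown kind '{self.kind}'")
        try:
            self.valuation_form
        except LedgerError as exc:
            errs.append(str(exc))
        for name in ("people", "hours_per_person", "hourly_rate", "units",
                     "unit_price", "amount"):
            v = getattr(self, name)
            if v is not None and v < 0:
                errs.append(f"item '{self.label}': {name} must be >= 0")
        if self.kind == "capital" and (self.lifespan_years is None or self.lifespan_years < 1):
            errs.append(f"item '{self.label}': capital items need a lifespan >= 1 year")
        return errs


@dataclass
class CostSummary:
    """Present-value cost panel: initial costs plus recurring O&M/education."""

    program_capital: float
    program_recurrent: float
    local_capital: float
    local_recurrent: float
    om_pv: float
    education_pv: float

    @property
    def program_initial(self) -> float:
        return self.program_capital + self.program_recurrent

    @property
    def local_initial(self) -> float:
        return self.local_capital + self.local_recurrent

    @property
    def initial_total(self) -> float:
        return self.program_initial + self.local_initial

    @property
    def total_pv(self) -> float:
        return self.initial_total + self.om_pv + self.education_pv

    def to_dict(self) -> dict[str, float]:
        return {
            "program_capital": self.program_capital,
            "program_recurrent": self.program_recurrent,
            "local_capital": self.local_capital,
            "local_recurrent": self.local_recurrent,
            "om_pv": self.om_pv,
            "education_pv": self.education_pv,
            "total_pv": self.total_pv,
        }


# ---------------------------------------------------------------------------
# ledger I/O and bottom-up valuation
# ---------------------------------------------------------------------------

def read_ledger(path: str | Path) -> list[CostItem]:
    """Read a cost ledger CSV into CostItems, in file order.

    Malformed rows raise :class:`LedgerError` naming the row number
    (1-based, excluding the header). Results are cached per (path, mtime)
    so repeated model runs (e.g. Monte Carlo) do not re-read the file.
    """
    path = Path(path)
    key = (str(path), path.stat().st_mtime_ns)
    cached = _LEDGER_CACHE.get(key)
    if cached is None:
        cached = _read_ledger_uncached(path)
        _LEDGER_CACHE[key] = cached
    return [dataclasses.replace(item) for item in cached]


_LEDGER_CACHE: dict[tuple[str, int], list[CostItem]] = {}


def _read_ledger_uncached(path: Path) -> list[CostItem]:
    frame = pd.read_csv(path, dtype={"label": str, "actor": str,
                                     "category": str, "kind": str})
    unknown = set(frame.columns) - set(LEDGER_COLUMNS)
    if unknown:
        raise LedgerError(f"{path}: unknown ledger columns {sorted(unknown)}")
    missing = {"label", "category", "kind"} - set(frame.columns)
    if missing:
        raise LedgerError(f"{path}: missing required columns {sorted(missing)}")

    items: list[CostItem] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        def num(name):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        item = CostItem(
            label=str(row.label),
            actor=str(getattr(row, "actor", "") or ""),
            category=str(row.category),
            kind=str(row.kind),
            people=num("people"),
            hours_per_person=num("hours_per_person"),
            hourly_rate=num("hourly_rate"),
            units=num("units"),
            unit_price=num("unit_price"),
            amount=num("amount"),
            lifespan_years=num("lifespan_years"),
        )
        errs = item.validate()
        if errs:
            raise LedgerError(f"{path}, row {i}: " + "; ".join(errs))
        items.append(item)
    return items


def time_cost(people: float, hours: float, rate: float) -> float:
    """Bottom-up time valuation: people x hours/person x money/hour."""
    if people < 0 or hours < 0 or rate < 0:
        raise ValueError("time_cost inputs must be >= 0")
    return float(people) * float(hours) * float(rate)


def latrine_capital(items: list[CostItem], hi_0: float) -> float:
    """Capital cost of latrine construction from local/capital ledger items.

    Material purchases are units x unit price; construction time is
    households x hours x the adult hourly income ``hi_0`` (used when the row
    carries no explicit rate).
    """
    total = 0.0
    for item in items:
        if item.category == "local" and item.kind == "capital":
            total += item.value(default_hourly_rate=hi_0)
    return total


# ---------------------------------------------------------------------------
# annualization
# ---------------------------------------------------------------------------

def annuity_factor(n: int, r: float) -> float:
    """A(n, r) = (1 - (1+r)^-n) / r, with the r -> 0 limit equal to n."""
    if n < 1:
        raise ValueError("annuity_factor: n must be >= 1")
    if r < 0:
        raise ValueError("annuity_factor: r must be >= 0")
    if r < 1e-12:  # limit as r -> 0; avoids 0/0 underflow at tiny rates
        return float(n)
    return -math.expm1(-n * math.log1p(r)) / r


def annualize_capital(K: float, S: float, n: int, r: float) -> float:
    """Equivalent annual cost of capital K with resale S after n years."""
    if not K >= S >= 0:
        raise ValueError("annualize_capital requires K >= S >= 0")
    return (K - S * (1.0 + r) ** (-n)) / annuity_factor(n, r)


def om_education_pv(capital_total: float, fraction: float, n: int, r: float) -> float:
    """PV of paying fraction x annualized capital each year for n years.

    Algebraically equal to ``fraction * capital_total`` for every discount
    rate (the annuity factors cancel); computed as the explicit discounted
    sum so the identity is emergent, not assumed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("om_education_pv: fraction out of [0,1]")
    annual = fraction * annualize_capital(capital_total, 0.0, n, r)
    return sum(annual * (1.0 + r) ** (-t) for t in range(1, n + 1))


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def total_costs_pv(
    p: ParameterSet,
    program_items: list[CostItem] | None = None,
    local_items: list[CostItem] | None = None,
) -> CostSummary:
    """Assemble the cost panel from the ledgers referenced by ``p``.

    Program capital amounts (vehicles, motorcycles) are stored already
    prorated to the project duration, so they enter as-is. O&M and education
    recur at their configured fractions of annualized total initial capital
    over the horizon.
    """
    p.require_valid()
    if program_items is None:
        program_items = read_ledger(p.program_ledger_path) if p.program_ledger_path else []
    if local_items is None:
        local_items = read_ledger(p.local_ledger_path) if p.local_ledger_path else []

    hi0 = p.econ.mean_hourly_income
    prog_cap = sum(i.value(hi0) for i in program_items
                   if i.category == "program" and i.kind == "capital")
    prog_rec = sum(i.value(hi0) for i in program_items
                   if i.category == "program" and i.kind == "recurrent")
    local_rec = sum(i.value(hi0) for i in local_items
                    if i.category == "local" and i.kind == "recurrent")
    local_cap = latrine_capital(local_items, hi0)

    capital_total = prog_cap + local_cap
    T, r = p.econ.horizon_years, p.econ.discount_rate
    if capital_total > 0:
        om = om_education_pv(capital_total, p.om_fraction, T, r)
        edu = om_education_pv(capital_total, p.education_fraction, T, r)
    else:
        om = edu = 0.0

    return CostSummary(
        program_capital=prog_cap,
        program_recurrent=prog_rec,
        local_capital=local_cap,
        local_recurrent=local_rec,
        om_pv=om,
        education_pv=edu,
    )
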