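"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

One-way analysis re-runs the base scenario at the low and high bound of one
parameter at a time and records the NPV/BCR span. The probabilistic analysis
draws every listed parameter independently from its distribution and
propagates each joint draw through the model; draws are consumed in declared
parameter order from a single seeded generator, so appending a parameter to
the list does not perturb earlier columns.
"""

from __future__ import annotations

import copy
import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import Scenario, run_scenario
from .parameters import ParameterSet

_INDEXED = re.compile(r"^(\w+)\[(\d+)\]$")


class SensitivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def _set_adult_vot(p: ParameterSet, v: float) -> None:
    # adult hours are valued both as own time (band 3) and as caregiver time
    f = list(p.econ.vot_fraction)
    f[2] = v
    p.econ.vot_fraction = tuple(f)
    p.econ.caregiver_vot_fraction = v


def _set_child_vot(p: ParameterSet, v: float) -> None:
    f = list(p.econ.vot_fraction)
    f[1] = v
    p.econ.vot_fraction = tuple(f)


def _set_elasticity(p: ParameterSet, v: float) -> None:
    # varying the transfer elasticity only has effect if the VSL is not pinned
    p.econ.vsl_elasticity = v
    p.econ.vsl_override = None


def _set_horizon(p: ParameterSet, v: float) -> None:
    p.econ.horizon_years = max(1, int(round(v)))


#: Named setters for parameters that touch more than one raw field.
PATH_ALIASES = {
    "adult_vot_fraction": _set_adult_vot,
    "child_vot_fraction": _set_child_vot,
    "vsl_elasticity": _set_elasticity,
    "latrine_lifespan_years": _set_horizon,
    "discount_rate": lambda p, v: setattr(p.econ, "discount_rate", v),
    "effect_days_under5": lambda p, v: setattr(p.epi, "days_averted_under5", v),
}


def _apply_parameter(q: ParameterSet, path: str, value: float) -> None:
    """Set the parameter at ``path`` on ``q`` in place."""
    if path in PATH_ALIASES:
        PATH_ALIASES[path](q, value)
        return
    parts = path.split(".")
    obj = q
    try:
        for part in parts[:-1]:
            obj = getattr(obj, part)
        last = parts[-1]
        m = _INDEXED.match(last)
        if m:
            name, idx = m.group(1), int(m.group(2))
            seq = list(getattr(obj, name))
            seq[idx] = value
            setattr(obj, name, tuple(seq))
        else:
            if not hasattr(obj, last):
                raise AttributeError(last)
            if last == "horizon_years":
                value = int(round(value))
            setattr(obj, last, value)
    except (AttributeError, IndexError) as exc:
        raise SensitivityError(f"cannot resolve parameter path '{path}'") from exc


def set_parameter(p: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with the parameter at ``path`` replaced.

    ``path`` is either a named alias (e.g. ``adult_vot_fraction``) or a
    dotted attribute path, optionally indexed: ``econ.discount_rate``,
    ``care.facility_fraction[0]``.
    """
    q = copy.deepcopy(p)
    _apply_parameter(q, path, value)
    return q


# ---------------------------------------------------------------------------
# one-way analysis
# ---------------------------------------------------------------------------

@dataclass
class OneWaySpec:
    parameter: str
    low: float
    high: float

    def validate(self) -> list[str]:
        if self.low > self.high:
            return [f"{self.parameter}: low > high"]
        return []


def default_one_way_specs() -> list[OneWaySpec]:
    """The packaged one-way set: latrine lifespan, value-of-time fractions,
    discount rate, trial-effect confidence bounds, and VSL elasticity."""
    return [
        OneWaySpec("latrine_lifespan_years", 5, 15),
        OneWaySpec("adult_vot_fraction", 0.25, 0.75),
        OneWaySpec("child_vot_fraction", 0.0, 0.50),
        OneWaySpec("discount_rate", 0.0, 0.08),
        OneWaySpec("effect_days_under5", 0.2, 2.6),
        OneWaySpec("vsl_elasticity", 1.0, 2.0),
    ]


def one_way(p: ParameterSet, specs: list[OneWaySpec]) -> pd.DataFrame:
    """Tornado records, sorted by BCR span (descending).

    Columns: parameter, low_value, high_value, bcr_low, bcr_high,
    npv_low, npv_high; *_low is the result at the parameter's low bound.
    """
    rows = []
    for spec in specs:
        errs = spec.validate()
        if errs:
            raise SensitivityError("; ".join(errs))
        res_low = run_scenario(set_parameter(p, spec.parameter, spec.low))
        res_high = run_scenario(set_parameter(p, spec.parameter, spec.high))
        rows.append({
            "parameter": spec.parameter,
            "low_value": spec.low,
            "high_value": spec.high,
            "bcr_low": res_low.bcr,
            "bcr_high": res_high.bcr,
            "npv_low": res_low.npv,
            "npv_high": res_high.npv,
        })
    frame = pd.DataFrame(rows)
    frame["bcr_span"] = (frame["bcr_high"] - frame["bcr_low"]).abs()
    frame = frame.sort_values("bcr_span", ascending=False, kind="stable")
    return frame.drop(columns="bcr_span").reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic analysis
# ---------------------------------------------------------------------------

DIST_FAMILIES = ("normal_truncated", "uniform", "triangular", "beta", "gamma", "point")


@dataclass
class DistSpec:
    """A sampling distribution attached to one parameter path.

    params by family: normal_truncated(mean, sd, low, high), uniform(low,
    high), triangular(low, mode, high), beta(a, b[, low, high]),
    gamma(shape, scale), point(value).
    """

    parameter: str
    family: str
    params: dict[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        errs = []
        need = {
            "normal_truncated": {"mean", "sd"},
            "uniform": {"low", "high"},
            "triangular": {"low", "mode", "high"},
            "beta": {"a", "b"},
            "gamma": {"shape", "scale"},
            "point": {"value"},
        }
        if self.family not in DIST_FAMILIES:
            return [f"{self.parameter}: unknown family '{self.family}'"]
        missing = need[self.family] - set(self.params)
        if missing:
            errs.append(f"{self.parameter}: missing {sorted(missing)} for {self.family}")
            return errs
        pr = self.params
        if self.family == "normal_truncated" and pr["sd"] <= 0:
            errs.append(f"{self.parameter}: sd must be > 0")
        if self.family == "uniform" and pr["low"] > pr["high"]:
            errs.append(f"{self.parameter}: low > high")
        if self.family == "triangular" and not pr["low"] <= pr["mode"] <= pr["high"]:
            errs.append(f"{self.parameter}: requires low <= mode <= high")
        if self.family == "beta" and (pr["a"] <= 0 or pr["b"] <= 0):
            errs.append(f"{self.parameter}: beta shapes must be > 0")
        if self.family == "gamma" and (pr["shape"] <= 0 or pr["scale"] <= 0):
            errs.append(f"{self.parameter}: gamma parameters must be > 0")
        return errs

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pr = self.params
        if self.family == "point":
            return np.full(n, pr["value"])
        if self.family == "uniform":
            return rng.uniform(pr["low"], pr["high"], n)
        if self.family == "triangular":
            if pr["low"] == pr["high"]:
                return np.full(n, pr["low"])
            return rng.triangular(pr["low"], pr["mode"], pr["high"], n)
        if self.family == "normal_truncated":
            lo = pr.get("low", -np.inf)
            hi = pr.get("high", np.inf)
            a = (lo - pr["mean"]) / pr["sd"]
            b = (hi - pr["mean"]) / pr["sd"]
            return stats.truncnorm.rvs(a, b, loc=pr["mean"], scale=pr["sd"],
                                       size=n, random_state=rng)
        if self.family == "beta":
            lo, hi = pr.get("low", 0.0), pr.get("high", 1.0)
            return lo + (hi - lo) * rng.beta(pr["a"], pr["b"], n)
        return rng.gamma(pr["shape"], pr["scale"], n)


def default_psa_dists() -> list[DistSpec]:
    """Packaged default distributions for the Monte Carlo analysis.

    Trial effect ~ truncated normal (mean 1.566, sd from the reported 95% CI
    0.2-2.6, truncated at 0); latrine lifespan ~ triangular(5, 10, 15);
    value-of-time fractions ~ uniform over their one-way ranges; discount
    rate ~ uniform(0, 0.08); VSL elasticity ~ uniform(1, 2).
    """
    sd = (2.6 - 0.2) / (2 * 1.959964)
    return [
        DistSpec("effect_days_under5", "normal_truncated",
                 {"mean": 1.566, "sd": sd, "low": 0.0}),
        DistSpec("latrine_lifespan_years", "triangular",
                 {"low": 5, "mode": 10, "high": 15}),
        DistSpec("adult_vot_fraction", "uniform", {"low": 0.25, "high": 0.75}),
        DistSpec("child_vot_fraction", "uniform", {"low": 0.0, "high": 0.50}),
        DistSpec("discount_rate", "uniform", {"low": 0.0, "high": 0.08}),
        DistSpec("vsl_elasticity", "uniform", {"low": 1.0, "high": 2.0}),
    ]


@dataclass
class PSAResult:
    npv: np.ndarray
    bcr: np.ndarray
    seed: int
    n_draws: int
    draws: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"npv": self.npv, "bcr": self.bcr})
        if self.draws is not None:
            frame = pd.concat([self.draws.reset_index(drop=True), frame], axis=1)
        return frame


def psa(p: ParameterSet, dists: list[DistSpec], n: int, seed: int) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through the model."""
    if n < 1:
        raise SensitivityError("psa: n must be >= 1")
    all_errs = [e for d in dists for e in d.validate()]
    if all_errs:
        raise SensitivityError("; ".join(all_errs))
    rng = np.random.default_rng(seed)
    columns = {d.parameter: d.draw(n, rng) for d in dists}

    npv = np.empty(n)
    bcr = np.empty(n)
    for i in range(n):
        q = copy.deepcopy(p)
        for name, col in columns.items():
            _apply_parameter(q, name, float(col[i]))
        res = run_scenario(q)
        npv[i], bcr[i] = res.npv, res.bcr
    return PSAResult(npv=npv, bcr=bcr, seed=seed, n_draws=n,
                     draws=pd.DataFrame(columns))


def percentiles(res: PSAResult, q: list[float]) -> dict[str, np.ndarray]:
    """Empirical quantiles of the NPV and BCR draws.

    Uses linear interpolation between order statistics (numpy's default
    'linear' definition).
    """
    if res.n_draws == 0:
        raise SensitivityError("percentiles: empty PSA result")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise SensitivityError("percentiles: q must lie in [0,1]")
    return {
        "npv": np.quantile(res.npv, q),
        "bcr": np.quantile(res.bcr, q),
    }


def cdf_export(res: PSAResult, path: str | Path) -> Path:
    """Write empirical CDFs of BCR and NPV as CSV.

    Columns: cumulative_fraction, bcr, npv — each value column sorted
    ascending, so all three columns are monotone non-decreasing.
    """
    if res.n_draws == 0:
        raise SensitivityError("cdf_export: empty PSA result")
    path = Path(path)
    n = res.n_draws
    fractions = np.arange(1, n + 1) / n
    bcr_sorted = np.sort(res.bcr)
    npv_sorted = np.sort(res.npv)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cumulative_fraction", "bcr", "npv"])
        for f, b, v in zip(fractions, bcr_sorted, npv_sorted):
            writer.writerow([f"{f:.10g}", f"{b:.10g}", f"{v:.10g}"])
    return path
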