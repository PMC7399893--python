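"""Synthetic cluster-randomized trial data with the structure the CBA assumes.

The generator emulates a two-arm, 24+24-village trial: village rosters of
households and people in three age bands; a 140-day caregiver diary of daily
diarrhoea indicators for a subsample of under-5 children, with village-level
multiplicative (mean-one lognormal) frailty creating cluster correlation;
care-seeking episodes attached to positive diary runs; household latrine
source states before/after the intervention; round-trip walking times; and
household incomes. Estimators recover the model's parameters back from the
micro-data — the longitudinal-prevalence effect ratio by a cluster-summary
estimator with a village-resampling bootstrap, and care-seeking, income,
time-use and switching parameters as sample proportions and means.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import SOURCES, ParameterSet

_BEFORE_SOURCES = ("own",) + SOURCES


class SyntheticError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generating conditions for one synthetic trial.

    Defaults mirror the study conditions: 24 villages per arm, ~72 households
    per village of mean size 5.6, 140-day diaries for ~18 under-5 children
    per village, a control longitudinal prevalence of 773/52,467
    diarrhoea-days per person-day (5.4 days/child-year), and an intervention
    to control prevalence ratio of 0.71.
    """

    n_villages_per_arm: int = 24
    households_per_village: int = 72
    mean_household_size: float = 5.6
    band_mix: tuple[float, float, float] = (0.134, 0.392, 0.474)
    diary_days: int = 140
    diary_children_per_village: int = 18
    diary_completion_min: float = 0.75
    control_daily_prev: float = 773.0 / 52467.0
    effect_ratio: float = 0.71
    village_frailty_sd: float = 0.35
    care_facility_prob: float = 0.56
    care_drugstore_prob: float = 0.03
    care_home_prob: float = 0.04
    hospitalization_prob: float = 0.05          # of all cases (episodes)
    hospital_stay_days_mean: float = 5.0
    before_source_probs: dict[str, float] = field(default_factory=lambda: {
        "own": 0.73, "open_defecation": 0.08, "communal": 0.06, "neighbour": 0.13,
    })
    switch_prob: dict[str, float] = field(default_factory=lambda: {
        "open_defecation": 0.5, "communal": 0.6, "neighbour": 0.5,
    })
    trip_minutes_mean: dict[str, float] = field(default_factory=lambda: {
        "open_defecation": 9.0, "communal": 7.0, "neighbour": 5.0,
    })
    trip_minutes_sd: float = 2.0
    hourly_income_mean: float = 0.67
    income_log_sd: float = 0.8
    working_hours_per_year: float = 1920.0
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        for nm in ("n_villages_per_arm", "households_per_village",
                   "diary_days", "diary_children_per_village"):
            if getattr(self, nm) < 1:
                errs.append(f"{nm}: must be >= 1")
        probs = (self.care_facility_prob, self.care_drugstore_prob, self.care_home_prob)
        if any(not 0 <= x <= 1 for x in probs):
            errs.append("care probabilities must lie in [0,1]")
        if sum(probs) > 1.0 + 1e-9:
            errs.append("care probabilities must sum to <= 1")
        if not 0 <= self.control_daily_prev <= 1:
            errs.append("control_daily_prev: probability out of [0,1]")
        if self.effect_ratio < 0:
            errs.append("effect_ratio: must be >= 0")
        if self.control_daily_prev * self.effect_ratio > 1:
            errs.append("intervention prevalence exceeds 1")
        if not 0 <= self.hospitalization_prob <= min(1.0, self.care_facility_prob + 1e-9):
            errs.append("hospitalization_prob must be <= care_facility_prob")
        if abs(sum(self.before_source_probs.get(s, 0) for s in _BEFORE_SOURCES) - 1) > 1e-6:
            errs.append("before_source_probs must sum to 1")
        for s in SOURCES:
            if not 0 <= self.switch_prob.get(s, 0) <= 1:
                errs.append(f"switch_prob.{s}: out of [0,1]")
        if not 0 < self.diary_completion_min <= 1:
            errs.append("diary_completion_min: out of (0,1]")
        return errs


@dataclass
class SyntheticTrialData:
    """Micro-data tables of one synthetic trial."""

    villages: pd.DataFrame       # village_id, arm
    households: pd.DataFrame     # household_id, village_id, arm, hourly_income
    persons: pd.DataFrame        # person_id, household_id, village_id, arm, band, sex
    diary_index: pd.DataFrame    # person_id, village_id, arm, days_observed
    diary: np.ndarray            # children x diary_days; 0/1 observed, -1 unobserved
    episodes: pd.DataFrame       # person_id, village_id, arm, start_day, duration_days,
                                 # care_type, hospitalized, stay_days
    latrines: pd.DataFrame       # household_id, village_id, arm, before_source, after_own
    trips: pd.DataFrame          # household_id, source, minutes_per_roundtrip
    config: SynthConfig
    seed: int


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_trial(c: SynthConfig, seed: int | None = None) -> SyntheticTrialData:
    """Generate one trial; fully reproducible from the seed."""
    errs = c.validate()
    if errs:
        raise SyntheticError("invalid synthetic config: " + "; ".join(errs))
    seed = c.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_vil = 2 * c.n_villages_per_arm
    arms = np.array(["intervention"] * c.n_villages_per_arm + ["control"] * c.n_villages_per_arm)
    villages = pd.DataFrame({"village_id": np.arange(n_vil), "arm": arms})

    # households and people
    hh_rows, person_rows = [], []
    hh_id = 0
    pid = 0
    bands = np.array(["under5", "age5to14", "age15plus"])
    for v in range(n_vil):
        for _ in range(c.households_per_village):
            size = max(1, rng.poisson(c.mean_household_size))
            income = rng.lognormal(
                np.log(c.hourly_income_mean) - c.income_log_sd**2 / 2.0,
                c.income_log_sd,
            )
            hh_rows.append((hh_id, v, arms[v], income))
            band_idx = rng.choice(3, size=size, p=np.asarray(c.band_mix) / sum(c.band_mix))
            sexes = rng.choice(np.array(["female", "male"]), size=size)
            for b, s in zip(band_idx, sexes):
                person_rows.append((pid, hh_id, v, arms[v], bands[b], s))
                pid += 1
            hh_id += 1
    households = pd.DataFrame(
        hh_rows, columns=["household_id", "village_id", "arm", "hourly_income"]
    )
    persons = pd.DataFrame(
        person_rows, columns=["person_id", "household_id", "village_id", "arm", "band", "sex"]
    )

    # village frailty: mean-one lognormal multiplier on daily prevalence
    frailty = rng.lognormal(-c.village_frailty_sd**2 / 2.0, c.village_frailty_sd, n_vil)
    arm_prev = np.where(
        arms == "intervention",
        c.control_daily_prev * c.effect_ratio,
        c.control_daily_prev,
    )

    # diary subsample: under-5 children per village
    diary_rows = []
    diary_mat = []
    under5 = persons[persons["band"] == "under5"]
    for v in range(n_vil):
        pool = under5[under5["village_id"] == v]["person_id"].to_numpy()
        take = min(c.diary_children_per_village, len(pool))
        chosen = rng.choice(pool, size=take, replace=False) if take else np.array([], int)
        p_village = min(arm_prev[v] * frailty[v], 0.95)
        for child in chosen:
            days_obs = int(round(
                c.diary_days * rng.uniform(c.diary_completion_min, 1.0)
            ))
            row = np.full(c.diary_days, -1, dtype=np.int8)
            row[:days_obs] = (rng.random(days_obs) < p_village).astype(np.int8)
            diary_mat.append(row)
            diary_rows.append((int(child), v, arms[v], days_obs))
    diary_index = pd.DataFrame(
        diary_rows, columns=["person_id", "village_id", "arm", "days_observed"]
    )
    diary = np.vstack(diary_mat) if diary_mat else np.empty((0, c.diary_days), np.int8)

    episodes = _draw_episodes(diary, diary_index, c, rng)
    latrines, trips = _draw_latrines(households, c, rng)

    return SyntheticTrialData(
        villages=villages, households=households, persons=persons,
        diary_index=diary_index, diary=diary, episodes=episodes,
        latrines=latrines, trips=trips, config=copy.deepcopy(c), seed=seed,
    )


def _draw_episodes(diary, diary_index, c: SynthConfig, rng) -> pd.DataFrame:
    """Care episodes: one per run of consecutive positive diary days."""
    rows = []
    p_none = 1.0 - c.care_facility_prob - c.care_drugstore_prob - c.care_home_prob
    types = np.array(["facility", "drugstore_or_traditional", "home", "none"])
    type_p = np.array([c.care_facility_prob, c.care_drugstore_prob, c.care_home_prob, p_none])
    hosp_given_facility = (
        c.hospitalization_prob / c.care_facility_prob if c.care_facility_prob > 0 else 0.0
    )
    for i in range(diary.shape[0]):
        row = diary[i]
        pos = (row == 1).astype(np.int8)
        # run starts: positive day not preceded by a positive day
        starts = np.flatnonzero(np.diff(np.concatenate(([0], pos))) == 1)
        ends = np.flatnonzero(np.diff(np.concatenate((pos, [0]))) == -1)
        meta = diary_index.iloc[i]
        for s, e in zip(starts, ends):
            care = rng.choice(types, p=type_p)
            hospitalized = bool(care == "facility" and rng.random() < hosp_given_facility)
            stay = int(1 + rng.poisson(max(c.hospital_stay_days_mean - 1.0, 0.0))) if hospitalized else 0
            rows.append((
                int(meta["person_id"]), int(meta["village_id"]), meta["arm"],
                int(s), int(e - s + 1), care, hospitalized, stay,
            ))
    return pd.DataFrame(rows, columns=[
        "person_id", "village_id", "arm", "start_day", "duration_days",
        "care_type", "hospitalized", "stay_days",
    ])


def _draw_latrines(households, c: SynthConfig, rng):
    """Latrine source before the intervention and switching, plus trip times."""
    n = len(households)
    sources = np.array(_BEFORE_SOURCES)
    probs = np.array([c.before_source_probs[s] for s in _BEFORE_SOURCES])
    before = rng.choice(sources, size=n, p=probs / probs.sum())
    switch_p = np.array([
        0.0 if b == "own" else c.switch_prob[b] for b in before
    ])
    is_intervention = (households["arm"] == "intervention").to_numpy()
    switched = (rng.random(n) < switch_p) & is_intervention
    after_own = (before == "own") | switched
    latrines = pd.DataFrame({
        "household_id": households["household_id"],
        "village_id": households["village_id"],
        "arm": households["arm"],
        "before_source": before,
        "after_own": after_own,
    })

    trip_rows = []
    for hh, b in zip(households["household_id"], before):
        if b == "own":
            continue
        minutes = max(0.5, rng.normal(c.trip_minutes_mean[b], c.trip_minutes_sd))
        trip_rows.append((hh, b, minutes))
    trips = pd.DataFrame(trip_rows, columns=["household_id", "source", "minutes_per_roundtrip"])
    return latrines, trips


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def village_prevalences(d: SyntheticTrialData) -> pd.DataFrame:
    """Longitudinal prevalence (diarrhoea-days / person-days) per village."""
    days = np.where(d.diary == 1, 1, 0).sum(axis=1)
    obs = (d.diary >= 0).sum(axis=1)
    frame = d.diary_index.copy()
    frame["diarrhoea_days"] = days
    frame["person_days"] = obs
    agg = frame.groupby(["village_id", "arm"], as_index=False)[
        ["diarrhoea_days", "person_days"]
    ].sum()
    agg["prevalence"] = agg["diarrhoea_days"] / agg["person_days"]
    return agg


def estimate_effect(
    d: SyntheticTrialData, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Intervention/control prevalence ratio with a cluster bootstrap CI.

    The estimator is the ratio of unweighted village means of longitudinal
    prevalence (a cluster-summary approximation of the trial's adjusted
    analysis); the CI is the percentile interval over ``n_boot``
    within-arm village resamples.
    """
    vp = village_prevalences(d)
    prev_i = vp.loc[vp["arm"] == "intervention", "prevalence"].to_numpy()
    prev_c = vp.loc[vp["arm"] == "control", "prevalence"].to_numpy()
    if len(prev_i) == 0 or len(prev_c) == 0 or vp["person_days"].min() <= 0:
        raise SyntheticError("estimate_effect: each arm needs villages with person-days")
    if prev_c.mean() == 0:
        raise SyntheticError("estimate_effect: zero prevalence in control arm")
    ratio = prev_i.mean() / prev_c.mean()

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = rng.choice(prev_i, size=len(prev_i), replace=True).mean()
        bc = rng.choice(prev_c, size=len(prev_c), replace=True).mean()
        boots[b] = bi / bc if bc > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(ratio), (float(lo), float(hi))


#: Estimate keys that map one-to-one onto generator truths.
#: ``switch_<s>`` is the probability of switching among prior users of the
#: source; ``switch_share_<s>`` is the population share that switched (prior
#: use x switching), which is what the CBA's switch fractions mean.
RECOVERED_PARAMETERS = (
    "effect_ratio",
    "facility_fraction", "drugstore_fraction", "home_fraction",
    "hospitalized_fraction", "hospital_stay_days",
    "mean_hourly_income",
    "trip_minutes_open_defecation", "trip_minutes_communal", "trip_minutes_neighbour",
    "switch_open_defecation", "switch_communal", "switch_neighbour",
    "switch_share_open_defecation", "switch_share_communal", "switch_share_neighbour",
)


def truth_values(c: SynthConfig) -> dict[str, float]:
    """Generator truths aligned with :func:`estimate_parameters` keys."""
    out = {
        "effect_ratio": c.effect_ratio,
        "facility_fraction": c.care_facility_prob,
        "drugstore_fraction": c.care_drugstore_prob,
        "home_fraction": c.care_home_prob,
        "hospitalized_fraction": c.hospitalization_prob,
        "hospital_stay_days": c.hospital_stay_days_mean,
        "mean_hourly_income": c.hourly_income_mean,
    }
    for s in SOURCES:
        out[f"trip_minutes_{s}"] = c.trip_minutes_mean[s]
        out[f"switch_{s}"] = c.switch_prob[s]
        out[f"switch_share_{s}"] = c.before_source_probs[s] * c.switch_prob[s]
    return out


def estimate_parameters(
    d: SyntheticTrialData, priors: SynthConfig | None = None
) -> tuple[dict[str, float], list[str]]:
    """Sample proportions/means of the CBA parameters, from micro-data.

    Returns ``(estimates, missing)``: strata with no observations fall back
    to the prior (the generating config by default) and are listed in
    ``missing``.
    """
    if len(d.persons) == 0:
        raise SyntheticError("estimate_parameters: empty trial data")
    priors = priors or d.config
    prior = truth_values(priors)
    est: dict[str, float] = {}
    missing: list[str] = []

    try:
        ratio, _ = estimate_effect(d, n_boot=10, seed=0)
        est["effect_ratio"] = ratio
    except SyntheticError:
        est["effect_ratio"] = prior["effect_ratio"]
        missing.append("effect_ratio")

    ep = d.episodes
    if len(ep):
        est["facility_fraction"] = float((ep["care_type"] == "facility").mean())
        est["drugstore_fraction"] = float((ep["care_type"] == "drugstore_or_traditional").mean())
        est["home_fraction"] = float((ep["care_type"] == "home").mean())
        est["hospitalized_fraction"] = float(ep["hospitalized"].mean())
        stays = ep.loc[ep["hospitalized"], "stay_days"]
        if len(stays):
            est["hospital_stay_days"] = float(stays.mean())
        else:
            est["hospital_stay_days"] = prior["hospital_stay_days"]
            missing.append("hospital_stay_days")
    else:
        for key in ("facility_fraction", "drugstore_fraction", "home_fraction",
                    "hospitalized_fraction", "hospital_stay_days"):
            est[key] = prior[key]
            missing.append(key)

    est["mean_hourly_income"] = float(d.households["hourly_income"].mean())

    for s in SOURCES:
        sub = d.trips[d.trips["source"] == s]
        if len(sub):
            est[f"trip_minutes_{s}"] = float(sub["minutes_per_roundtrip"].mean())
        else:
            est[f"trip_minutes_{s}"] = prior[f"trip_minutes_{s}"]
            missing.append(f"trip_minutes_{s}")
        lat = d.latrines
        interv = lat[lat["arm"] == "intervention"]
        users = interv[interv["before_source"] == s]
        if len(users):
            est[f"switch_{s}"] = float(users["after_own"].mean())
            est[f"switch_share_{s}"] = float(users["after_own"].sum() / len(interv))
        else:
            est[f"switch_{s}"] = prior[f"switch_{s}"]
            est[f"switch_share_{s}"] = prior[f"switch_share_{s}"]
            missing.append(f"switch_{s}")

    return est, missing


def apply_overlay(p: ParameterSet, estimates: dict[str, float]) -> ParameterSet:
    """Write recovered parameters into a copy of a ParameterSet.

    Facility and inpatient fractions broadcast across age bands (the diary
    observes under-5s only); the population-share switch estimates
    (``switch_share_<s>``) apply to the over-5 bands.
    """
    q = copy.deepcopy(p)
    f = estimates.get("facility_fraction")
    if f is not None:
        q.care.facility_fraction = (f, f, f)
    hosp = estimates.get("hospitalized_fraction")
    if hosp is not None and f:
        ip = min(1.0, hosp / f)
        q.care.inpatient_fraction = (ip, ip, ip)
        q.care.outpatient_fraction = (1 - ip, 1 - ip, 1 - ip)
    income = estimates.get("mean_hourly_income")
    if income is not None:
        q.econ.mean_hourly_income = income
    for s in SOURCES:
        minutes = estimates.get(f"trip_minutes_{s}")
        if minutes is not None:
            q.timeuse.minutes_per_roundtrip[s] = minutes
        sw = estimates.get(f"switch_share_{s}")
        if sw is not None:
            old = q.timeuse.switch_fraction[s]
            q.timeuse.switch_fraction[s] = (old[0], sw, sw)
    return q.require_valid()


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------

def recovery_report(
    truth: SynthConfig,
    estimates: list[dict[str, float]],
    effect_cis: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-parameter bias, relative error, and CI coverage over replicates.

    ``estimates`` is one dict per replicate (keys as in
    :func:`estimate_parameters`); ``effect_cis`` optionally carries the
    bootstrap CI of the effect ratio per replicate, from which coverage of
    the true ratio is computed.
    """
    if not estimates:
        raise SyntheticError("recovery_report: no estimates")
    tv = truth_values(truth)
    rows = []
    for name in RECOVERED_PARAMETERS:
        vals = np.array([e[name] for e in estimates if name in e], dtype=float)
        if len(vals) == 0:
            continue
        t = tv[name]
        bias = float(vals.mean() - t)
        rel = float(bias / t) if t != 0 else np.nan
        coverage = np.nan
        if name == "effect_ratio" and effect_cis:
            hits = [lo <= t <= hi for lo, hi in effect_cis]
            coverage = float(np.mean(hits))
        rows.append({
            "parameter": name, "truth": t, "mean_estimate": float(vals.mean()),
            "bias": bias, "relative_error": rel, "ci_coverage": coverage,
            "n_replicates": len(vals),
        })
    return pd.DataFrame(rows)


def run_recovery(
    c: SynthConfig, n_replicates: int, n_boot: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Generate-estimate ``n_replicates`` trials and tabulate recovery."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    ests, cis = [], []
    for s in seeds:
        d = generate_trial(c, seed=int(s))
        ratio, ci = estimate_effect(d, n_boot=n_boot, seed=int(s) + 1)
        est, _ = estimate_parameters(d)
        est["effect_ratio"] = ratio
        ests.append(est)
        cis.append(ci)
    return recovery_report(c, ests, effect_cis=cis)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_trial(d: SyntheticTrialData, out_dir: str | Path) -> Path:
    """Write the trial as a directory of CSV tables plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d.villages.to_csv(out / "villages.csv", index=False)
    d.households.to_csv(out / "households.csv", index=False)
    d.persons.to_csv(out / "persons.csv", index=False)
    d.diary_index.to_csv(out / "diary_index.csv", index=False)
    pd.DataFrame(d.diary).to_csv(out / "diary.csv", index=False)
    d.episodes.to_csv(out / "episodes.csv", index=False)
    d.latrines.to_csv(out / "latrines.csv", index=False)
    d.trips.to_csv(out / "trips.csv", index=False)
    manifest = {
        "seed": d.seed,
        "config": dataclasses.asdict(d.config),
        "tables": ["villages", "households", "persons", "diary_index",
                   "diary", "episodes", "latrines", "trips"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_trial(in_dir: str | Path) -> SyntheticTrialData:
    """Read a trial directory written by :func:`write_trial`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_raw = manifest["config"]
    for key in ("band_mix",):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = SynthConfig(**cfg_raw)
    return SyntheticTrialData(
        villages=pd.read_csv(src / "villages.csv"),
        households=pd.read_csv(src / "households.csv"),
        persons=pd.read_csv(src / "persons.csv"),
        diary_index=pd.read_csv(src / "diary_index.csv"),
        diary=pd.read_csv(src / "diary.csv").to_numpy(dtype=np.int8),
        episodes=pd.read_csv(src / "episodes.csv"),
        latrines=pd.read_csv(src / "latrines.csv"),
        trips=pd.read_csv(src / "trips.csv"),
        config=config,
        seed=manifest["seed"],
    )
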