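"""Synthetic trial generation, estimators, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import clts_cba as cba
from clts_cba.synthetic import (
    RECOVERED_PARAMETERS, SyntheticError, SyntheticTrialData, truth_values,
    village_prevalences,
)


def _small_config(**kw):
    defaults = dict(n_villages_per_arm=6, households_per_village=18,
                    diary_children_per_village=8, seed=0)
    defaults.update(kw)
    return cba.SynthConfig(**defaults)


def _diary_only_trial(matrices, arms):
    """Hand-built trial: one diary matrix per village, no roster tables."""
    rows, mats = [], []
    pid = 0
    for v, (mat, arm) in enumerate(zip(matrices, arms)):
        for child in mat:
            rows.append((pid, v, arm, int((child >= 0).sum())))
            mats.append(child)
            pid += 1
    index = pd.DataFrame(rows, columns=["person_id", "village_id", "arm", "days_observed"])
    empty = pd.DataFrame()
    return SyntheticTrialData(
        villages=pd.DataFrame({"village_id": range(len(arms)), "arm": arms}),
        households=empty, persons=index, diary_index=index,
        diary=np.vstack(mats), episodes=empty, latrines=empty, trips=empty,
        config=cba.SynthConfig(), seed=0,
    )


def _block_diary(positives, person_days, width=140):
    """Children x days matrix with exactly the given totals."""
    full, rem = divmod(person_days, width)
    rows = np.zeros((full + (1 if rem else 0), width), dtype=np.int8)
    if rem:
        rows[-1, rem:] = -1
    flat = rows.reshape(-1)
    observed = np.flatnonzero(flat == 0)
    flat[observed[:positives]] = 1
    return rows


class TestGeneration:
    def test_seed_determinism_end_to_end(self):
        c = _small_config(seed=5)
        a, b = cba.generate_trial(c), cba.generate_trial(c)
        assert np.array_equal(a.diary, b.diary)
        assert a.episodes.equals(b.episodes)
        assert a.latrines.equals(b.latrines)
        ra, _ = cba.estimate_effect(a, n_boot=50, seed=2)
        rb, _ = cba.estimate_effect(b, n_boot=50, seed=2)
        assert ra == rb

    def test_diary_only_for_under5(self):
        d = cba.generate_trial(_small_config())
        under5 = set(d.persons.loc[d.persons["band"] == "under5", "person_id"])
        assert set(d.diary_index["person_id"]).issubset(under5)

    def test_arms_balanced(self):
        d = cba.generate_trial(_small_config())
        counts = d.villages["arm"].value_counts()
        assert counts["intervention"] == counts["control"] == 6

    def test_zero_prevalence_no_episodes(self):
        d = cba.generate_trial(_small_config(control_daily_prev=0.0))
        assert len(d.episodes) == 0

    def test_every_episode_starts_on_positive_day(self):
        d = cba.generate_trial(_small_config(seed=9))
        pid_to_row = {p: i for i, p in enumerate(d.diary_index["person_id"])}
        for ep in d.episodes.itertuples():
            assert d.diary[pid_to_row[ep.person_id], ep.start_day] == 1

    def test_control_burden_matches_configured_rate(self):
        # configured control prevalence corresponds to 5.4 days/child-year
        days, obs = 0, 0
        for seed in range(4):
            d = cba.generate_trial(cba.SynthConfig(seed=seed))
            ctrl = (d.diary_index["arm"] == "control").to_numpy()
            days += np.where(d.diary[ctrl] == 1, 1, 0).sum()
            obs += (d.diary[ctrl] >= 0).sum()
        assert days / obs * 365 == pytest.approx(5.4, rel=0.08)

    def test_infeasible_config_rejected(self):
        with pytest.raises(SyntheticError):
            cba.generate_trial(_small_config(control_daily_prev=1.5))


class TestEffectEstimator:
    def test_self_comparison_is_exactly_one(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((5, 140)) < 0.02).astype(np.int8)
        d = _diary_only_trial([mat, mat], ["intervention", "control"])
        ratio, _ = cba.estimate_effect(d, n_boot=20, seed=0)
        assert ratio == 1.0

    def test_pooled_ratio_matches_hand_arithmetic(self):
        # one village per arm makes the cluster-summary ratio equal the
        # pooled ratio of longitudinal prevalences
        mat_i = _block_diary(481, 49_571)
        mat_c = _block_diary(773, 52_467)
        d = _diary_only_trial([mat_i, mat_c], ["intervention", "control"])
        ratio, _ = cba.estimate_effect(d, n_boot=20, seed=0)
        assert ratio == pytest.approx((481 / 49_571) / (773 / 52_467))

    def test_empty_arm_rejected(self):
        mat = np.ones((2, 140), dtype=np.int8)
        d = _diary_only_trial([mat], ["intervention"])
        with pytest.raises(SyntheticError):
            cba.estimate_effect(d, n_boot=10, seed=0)

    def test_village_prevalences_sum_consistency(self):
        d = cba.generate_trial(_small_config(seed=2))
        vp = village_prevalences(d)
        assert vp["person_days"].sum() == (d.diary >= 0).sum()
        assert vp["diarrhoea_days"].sum() == np.where(d.diary == 1, 1, 0).sum()

    def test_error_shrinks_with_trial_size(self):
        errs_small, errs_large = [], []
        for seed in range(8):
            small = cba.generate_trial(_small_config(seed=seed))
            large = cba.generate_trial(cba.SynthConfig(seed=seed))
            r_s, _ = cba.estimate_effect(small, n_boot=10, seed=seed)
            r_l, _ = cba.estimate_effect(large, n_boot=10, seed=seed)
            errs_small.append(abs(r_s - 0.71))
            errs_large.append(abs(r_l - 0.71))
        assert np.mean(errs_large) < np.mean(errs_small)


class TestParameterRecovery:
    def test_proportions_recovered_within_sampling_error(self):
        d = cba.generate_trial(cba.SynthConfig(seed=4))
        est, missing = cba.estimate_parameters(d)
        assert missing == []
        n_ep = len(d.episodes)
        half_width = 1.96 * np.sqrt(0.56 * 0.44 / n_ep)
        assert est["facility_fraction"] == pytest.approx(0.56, abs=2 * half_width)
        assert est["trip_minutes_open_defecation"] == pytest.approx(9.0, abs=0.5)
        assert est["mean_hourly_income"] == pytest.approx(0.67, rel=0.15)

    def test_degenerate_spread_recovered_exactly(self):
        c = _small_config(trip_minutes_sd=0.0, income_log_sd=0.0)
        d = cba.generate_trial(c)
        est, _ = cba.estimate_parameters(d)
        assert est["trip_minutes_neighbour"] == pytest.approx(5.0)
        assert est["mean_hourly_income"] == pytest.approx(0.67)

    def test_missing_strata_fall_back_to_priors(self):
        c = _small_config(control_daily_prev=0.0, effect_ratio=1.0)
        d = cba.generate_trial(c)
        est, missing = cba.estimate_parameters(d)
        assert "facility_fraction" in missing
        assert est["facility_fraction"] == c.care_facility_prob

    def test_overlay_feeds_scenario_engine(self, params):
        d = cba.generate_trial(cba.SynthConfig(seed=6))
        est, _ = cba.estimate_parameters(d)
        q = cba.apply_overlay(params, est)
        res = cba.run_scenario(q)
        assert res.costs.total_pv > 0 and np.isfinite(res.bcr)

    def test_recovery_report_shape_and_bias(self):
        c = _small_config(trip_minutes_sd=0.0, seed=1)
        report = cba.run_recovery(c, n_replicates=3, n_boot=20, seed=1)
        assert len(report) == len(RECOVERED_PARAMETERS)
        frozen = report.set_index("parameter")
        assert frozen.loc["trip_minutes_communal", "bias"] == pytest.approx(0.0)
        assert 0 <= frozen.loc["effect_ratio", "ci_coverage"] <= 1

    def test_truth_values_cover_all_tracked_parameters(self):
        assert set(truth_values(cba.SynthConfig())) == set(RECOVERED_PARAMETERS)


class TestPersistence:
    def test_write_read_roundtrip(self, tmp_path):
        d = cba.generate_trial(_small_config(seed=3))
        out = cba.write_trial(d, tmp_path / "trial")
        d2 = cba.read_trial(out)
        assert np.array_equal(d.diary, d2.diary)
        pd.testing.assert_frame_equal(d.episodes, d2.episodes)
        assert d2.config == d.config
        assert d2.seed == d.seed
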