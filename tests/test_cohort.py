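"""Synthetic cohort generator: determinism, calibration, trial structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fepbias import (
    SimulationConfig,
    expected_lq1,
    generate_cohort_trials,
    generate_participants,
    generate_trials,
    inject_contaminants,
    score_participants,
)
from fepbias.cohort import ConfigurationError, sample_lq1


def zero_effect_config(**kw) -> SimulationConfig:
    base = dict(
        effect_map={"choice_bias": {"intercept": 0.0}, "rt_bias": {"intercept": 0.0}},
        noise_sd_choice=0.0,
        noise_sd_rt=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestParticipants:
    def test_seed_determinism(self, small_config):
        a = generate_participants(small_config)
        b = generate_participants(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_sex_counts_near_configured_proportions(self):
        cfg = SimulationConfig(n_participants=427, seed=11)
        counts = generate_participants(cfg)["sex"].value_counts()
        for sex, expected in [("female", 214), ("male", 210), ("undisclosed", 3)]:
            p = expected / 427
            se = np.sqrt(427 * p * (1 - p))
            assert abs(counts.get(sex, 0) - expected) <= 3 * se + 3

    def test_degenerate_age_distribution(self):
        cfg = SimulationConfig(n_participants=20, age_sd=0.0, age_mean=30.0, seed=1)
        assert (generate_participants(cfg)["age"] == 30.0).all()

    def test_zero_noise_traits_equal_intercept(self):
        cfg = zero_effect_config(n_participants=15, seed=2)
        cfg.effect_map["choice_bias"]["intercept"] = 0.37
        p = generate_participants(cfg)
        assert np.allclose(p["truth_choice_bias"], 0.37)

    def test_age_moments_match_targets(self):
        cfg = SimulationConfig(n_participants=20000, seed=5)
        age = generate_participants(cfg)["age"]
        assert age.min() >= cfg.age_min and age.max() <= cfg.age_max
        assert age.mean() == pytest.approx(cfg.age_mean, abs=0.2)
        assert age.std() == pytest.approx(cfg.age_sd, abs=0.2)

    def test_instrument_moments_match_targets(self):
        cfg = SimulationConfig(n_participants=20000, seed=5)
        sc = score_participants(generate_participants(cfg))
        assert sc["ehi_score"].mean() == pytest.approx(77.83, abs=2.0)
        assert sc["ehi_score"].std() == pytest.approx(55.17, abs=2.5)
        for sub, mean in cfg.aq_subscale_means.items():
            assert sc[sub].mean() == pytest.approx(mean, abs=0.3)
            assert sc[sub].std() == pytest.approx(cfg.aq_subscale_sds[sub], abs=0.3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sex_proportions={"female": 0.9, "male": 0.2, "undisclosed": 0.0})
        with pytest.raises(ValueError):
            SimulationConfig(age_min=10)
        bad_corr = np.full((5, 5), 0.99)
        np.fill_diagonal(bad_corr, 0.5)
        with pytest.raises(ValueError):
            SimulationConfig(aq_subscale_corr=bad_corr.tolist())


class TestTrials:
    def test_session_structure(self, small_config, small_cohort):
        participants, _ = small_cohort
        log = generate_trials(participants.iloc[0], small_config)
        task = log[~log["is_attention_check"]]
        assert len(task) == 192
        assert task["emotion"].value_counts().eq(64).all()
        n_checks = int(log["is_attention_check"].sum())
        assert 2 <= n_checks <= 4 or (participants.iloc[0]["pilot_flag"] and n_checks == 4)
        # top/bottom counterbalance within each emotion
        for _, grp in task.groupby("emotion"):
            assert grp["left_vf_on_top"].sum() == 32

    def test_trial_count_must_divide_by_three(self, small_cohort):
        participants, _ = small_cohort
        cfg = SimulationConfig(n_trials=100)
        with pytest.raises(ConfigurationError):
            generate_trials(participants.iloc[0], cfg)

    def test_unbiased_choice_is_symmetric(self):
        cfg = zero_effect_config(n_participants=1, n_trials=300000, seed=3)
        p = generate_participants(cfg)
        log = generate_trials(p.iloc[0], cfg)
        task = log[~log["is_attention_check"]]
        responded = task[task["chosen_side"] != "none"]
        frac_left = (responded["chosen_side"] == "left_vf").mean()
        se = 0.5 / np.sqrt(len(responded))
        assert abs(frac_left - 0.5) <= 3 * se

    def test_strong_bias_matches_logistic_expectation(self):
        cfg = zero_effect_config(n_participants=1, n_trials=300000, seed=4)
        cfg.effect_map["choice_bias"]["intercept"] = 4.0
        p = generate_participants(cfg)
        log = generate_trials(p.iloc[0], cfg)
        responded = log[(~log["is_attention_check"]) & (log["chosen_side"] != "none")]
        n_l = (responded["chosen_side"] == "left_vf").sum()
        n = len(responded)
        lq1 = (2 * n_l - n) / n
        target = expected_lq1(4.0)  # 2*logistic(4) - 1 ~ 0.964
        assert target == pytest.approx(0.9640, abs=5e-4)
        p_hit = expit(4.0)
        se = 2 * np.sqrt(p_hit * (1 - p_hit) / n)
        assert abs(lq1 - target) <= 4 * se

    def test_rt_bias_shifts_side_conditional_means(self):
        cfg = zero_effect_config(n_participants=1, n_trials=30000, seed=6)
        cfg.effect_map["rt_bias"]["intercept"] = 0.2
        p = generate_participants(cfg)
        log = generate_trials(p.iloc[0], cfg)
        responded = log[(~log["is_attention_check"]) & (log["chosen_side"] != "none")]
        rt_r = responded.loc[responded["chosen_side"] == "right_vf", "rt_ms"].mean()
        rt_l = responded.loc[responded["chosen_side"] == "left_vf", "rt_ms"].mean()
        assert rt_r > rt_l
        # lognormal location shift of +-0.1 => ratio ~ exp(0.2)
        assert rt_r / rt_l == pytest.approx(np.exp(0.2), rel=0.05)

    def test_single_and_cohort_generation_agree(self, small_config, small_cohort):
        participants, _ = small_cohort
        cohort_trials = generate_cohort_trials(participants.head(5), small_config)
        row = participants.iloc[3]
        single = generate_trials(row, small_config)
        subset = (
            cohort_trials[cohort_trials["participant_id"] == row["participant_id"]]
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(single, subset)

    def test_mean_lq1_converges_to_logistic_transform(self):
        cfg = zero_effect_config(n_participants=400, seed=8)
        cfg.effect_map["choice_bias"]["intercept"] = 0.5
        p = generate_participants(cfg)
        trials = generate_cohort_trials(p, cfg)
        from fepbias import score_laterality

        lat = score_laterality(trials)
        target = expected_lq1(0.5)
        se = lat["lq1"].std() / np.sqrt(len(lat))
        assert abs(lat["lq1"].mean() - target) <= 4 * se


class TestContaminants:
    def test_zero_rates_identity(self, small_config, small_cohort):
        participants, trials = small_cohort
        p2, t2 = inject_contaminants(participants, trials, small_config)
        pd.testing.assert_frame_equal(participants, p2)
        pd.testing.assert_frame_equal(trials, t2)

    def test_fast_guessers_fall_below_completion(self, contaminated_cohort):
        participants, trials = contaminated_cohort
        guessers = participants[participants["truth_fast_guesser"]]
        assert len(guessers) > 0
        for pid in guessers["participant_id"]:
            own = trials[
                (trials["participant_id"] == pid) & (~trials["is_attention_check"])
            ]
            fast = (own["rt_ms"] < 200).sum()
            valid = ((own["chosen_side"] != "none") & (own["rt_ms"] >= 200)).sum()
            assert fast >= 11
            assert valid / 192 < 0.95

    def test_inattentive_sit_at_exclusion_threshold(self, contaminated_cohort):
        participants, _ = contaminated_cohort
        flagged = participants[participants["truth_inattentive"]]
        assert len(flagged) > 0
        standard = flagged[~flagged["pilot_flag"]]
        if len(standard):
            assert (standard["attention_checks_failed"] == 2).all()
        pilots = flagged[flagged["pilot_flag"]]
        if len(pilots):
            assert (pilots["attention_checks_failed"] == 3).all()

    def test_bots_marked(self, contaminated_cohort):
        participants, _ = contaminated_cohort
        bots = participants[participants["truth_bot"]]
        assert len(bots) > 0
        assert (~bots["bot_response_valid"]).all()


def test_sample_lq1_matches_trial_generation_distribution():
    """The binomial shortcut and the full trial log share their first moments."""
    cfg = zero_effect_config(n_participants=300, seed=13)
    cfg.effect_map["choice_bias"]["intercept"] = 0.8
    p = generate_participants(cfg)
    short = sample_lq1(p, cfg, np.random.default_rng(99))
    trials = generate_cohort_trials(p, cfg)
    from fepbias import score_laterality

    full = score_laterality(trials)["lq1"]
    se = np.sqrt(short.var() / len(short) + full.var() / len(full))
    assert abs(short.mean() - full.mean()) <= 4 * se
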