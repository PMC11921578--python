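"""Synthetic participant cohorts and chimeric-faces-task trial logs.

The generator emulates, at the response level, an online general-population
study of hemispheric bias in facial emotion processing:

* demographics — biological sex drawn from configured proportions (with a
  small undisclosed fraction), age from a truncated normal on [18, 67];
* handedness — a latent Edinburgh Handedness Inventory score from a
  right-skewed three-component mixture on [-100, 100], then mapped to ten
  valid 5-level item responses whose scored value is unbiased for the latent;
* autistic traits — five AQ subscale scores from a discretised Gaussian
  copula matched to configured means/SDs/correlations, spread over keyed
  1-4 item responses (exact item-level realism is out of scope);
* task behaviour — two latent traits per participant: a choice bias (the
  log-odds of picking the face whose emotive hemiface sits in the left
  visual field) and a reaction-time bias (a log-scale RT shift between
  right- and left-visual-field-emotion choices), each a linear function of
  covariates via ``effect_map`` plus Gaussian noise;
* trials — a fixed number of task trials with the three emotions (happy,
  angry, fearful) equally represented and top/bottom placement
  counterbalanced; choices Bernoulli(logistic(choice_bias)); RTs lognormal
  with the location shifted by +-rt_bias/2 by chosen side and truncated at
  the 4.5 s response window (exceedance becomes a non-response trial);
  2-4 in-task attention checks (4 under the pilot protocol) interleaved at
  random positions.

All randomness fans out deterministically from the single config seed, one
stream per participant, so subsetting a cohort never reshuffles the others.
``inject_contaminants`` then creates the data-quality failures the cleaning
stage must catch, keeping ground-truth labels in ``truth_*`` columns.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import fsolve
from scipy.special import expit

from .config import AQ_SUBSCALES, SimulationConfig
from .instruments import load_aq_key

__all__ = [
    "generate_participants",
    "generate_trials",
    "generate_cohort_trials",
    "inject_contaminants",
    "simulate_cohort",
    "expected_lq1",
    "sample_lq1",
]

EMOTIONS = ("happy", "angry", "fearful")

#: Number of sub-200 ms / blanked trials given to a marked fast-guesser or
#: non-responder: 192 - 11 = 181 valid trials, i.e. 94.3% completion,
#: just under the 95% gate.
N_CONTAMINATED_TRIALS = 11


class ConfigurationError(ValueError):
    """Raised when a simulation request is internally impossible."""


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def expected_lq1(choice_bias: np.ndarray | float) -> np.ndarray | float:
    """Closed-form expectation of the choice quotient: 2*logistic(b) - 1."""
    return 2.0 * expit(choice_bias) - 1.0


@lru_cache(maxsize=64)
def _truncnorm_moment_params(
    mean: float, sd: float, lo: float, hi: float
) -> Tuple[float, float]:
    """Location/scale of a truncated normal on [lo, hi] with the given moments."""
    def gap(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = st.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ok, msg = fsolve(gap, [mean, np.log(sd)], full_output=True)
    if ok != 1 or max(abs(np.asarray(gap(sol)))) > 1e-6:
        raise ConfigurationError(
            f"no truncated normal on [{lo}, {hi}] has mean {mean}, sd {sd}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_age(
    rng: np.random.Generator, config: SimulationConfig, size: int
) -> np.ndarray:
    if config.age_sd == 0:
        return np.full(size, np.clip(config.age_mean, config.age_min, config.age_max))
    loc, scale = _truncnorm_moment_params(
        config.age_mean, config.age_sd, config.age_min, config.age_max
    )
    a = (config.age_min - loc) / scale
    b = (config.age_max - loc) / scale
    return st.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _ehi_items_from_latent(
    rng: np.random.Generator, latent: np.ndarray
) -> np.ndarray:
    """Map latent handedness in [-100, 100] to 10 item codes in {-2..2}.

    Each item is a one-check (weak) item with probability 0.25, else a
    two-check item; checks fall on the right with p = (latent+100)/200.
    The scored laterality quotient of the items is unbiased for the latent.
    """
    n = len(latent)
    p = ((latent + 100.0) / 200.0)[:, None]
    one_check = rng.random((n, 10)) < 0.25
    r1 = rng.random((n, 10)) < p  # the single check of weak items
    r2 = rng.binomial(2, np.broadcast_to(p, (n, 10)))  # two-check items
    items = np.where(one_check, np.where(r1, 1, -1), r2 - 1 + np.sign(r2 - 1))
    # r2-1+sign(r2-1): 0 checks -> -2, 1 -> 0, 2 -> +2
    return items.astype(int)


def _aq_items_from_copula(
    rng: np.random.Generator, config: SimulationConfig, n: int, key: pd.DataFrame
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Raw 1-4 responses for all 50 items plus the keyed subscale sums.

    A Gaussian copula correlates the five subscale scores; each target score
    is then spread uniformly at random over the subscale's 10 items (each
    contributing a keyed 1-4 value), and keyed values are converted to raw
    responses through the instrument key.
    """
    corr = config.aq_corr_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 5)) @ chol.T
    means = np.array([config.aq_subscale_means[s] for s in AQ_SUBSCALES])
    sds = np.array([config.aq_subscale_sds[s] for s in AQ_SUBSCALES])
    scores = np.clip(np.rint(means + sds * z), 10, 40).astype(int)

    raw = np.empty((n, 50), dtype=int)
    subscale_sums: Dict[str, np.ndarray] = {}
    reverse = key["reverse_keyed"].to_numpy()
    for j, sub in enumerate(AQ_SUBSCALES):
        item_idx = np.flatnonzero((key["subscale"] == sub).to_numpy())
        extras = scores[:, j] - 10  # 0..30 points beyond the all-1 floor
        alloc = np.empty((n, 10), dtype=int)
        for i in range(n):
            alloc[i] = rng.multivariate_hypergeometric([3] * 10, extras[i])
        keyed = 1 + alloc
        rev = reverse[item_idx]
        raw[:, item_idx] = np.where(rev, 5 - keyed, keyed)
        subscale_sums[sub] = keyed.sum(axis=1)
    return raw, subscale_sums


def _linear_trait(
    coeffs: Dict[str, float], covariates: Dict[str, np.ndarray], n: int
) -> np.ndarray:
    out = np.full(n, float(coeffs.get("intercept", 0.0)))
    for name, beta in coeffs.items():
        if name == "intercept" or beta == 0:
            continue
        if ":" in name:
            a, b = name.split(":", 1)
            value = covariates[a] * covariates[b]
        else:
            value = covariates[name]
        out = out + beta * value
    return out


def generate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the participant table: demographics, items, latent traits.

    Deterministic under a fixed ``config.seed``. Truth columns (``truth_*``)
    carry the generative latents and contamination labels for test oracles;
    they are never consumed by the analysis stages.
    """
    rng = _rng_for(config.seed, 0)
    n = config.n_participants
    key = load_aq_key()

    sexes = np.array(["female", "male", "undisclosed"])
    probs = np.array([config.sex_proportions[s] for s in sexes])
    sex = sexes[rng.choice(3, size=n, p=probs)]

    age = _draw_age(rng, config, n)

    weights = np.array([c.weight for c in config.ehi_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    comp_mean = np.array([c.mean for c in config.ehi_mixture])[comp]
    comp_sd = np.array([c.sd for c in config.ehi_mixture])[comp]
    # censored, not truncated: mass piles up at the +-100 scale ends
    ehi_latent = np.clip(rng.normal(comp_mean, comp_sd), -100.0, 100.0)
    self_handedness = np.array([c.label for c in config.ehi_mixture])[comp]
    ehi_items = _ehi_items_from_latent(rng, ehi_latent)

    aq_raw, subscale_sums = _aq_items_from_copula(rng, config, n, key)

    pilot = rng.random(n) < config.pilot_fraction
    n_checks_in_task = np.where(pilot, 4, rng.integers(2, 5, size=n))

    # checks = (R - L) accumulated with strong=2/weak=1/equal=1-each weighting
    right = np.zeros(n)
    left = np.zeros(n)
    for code, (l_ch, r_ch) in {(-2): (2, 0), -1: (1, 0), 0: (1, 1), 1: (0, 1), 2: (0, 2)}.items():
        cnt = (ehi_items == code).sum(axis=1)
        left += cnt * l_ch
        right += cnt * r_ch
    ehi_score = 100.0 * (right - left) / (right + left)

    covariates: Dict[str, np.ndarray] = {
        "age": age,
        "sex_male": (sex == "male").astype(float),
        "ehi_score": ehi_score,
        **{s: subscale_sums[s].astype(float) for s in AQ_SUBSCALES},
    }
    choice_bias = _linear_trait(config.effect_map.get("choice_bias", {}), covariates, n)
    rt_bias = _linear_trait(config.effect_map.get("rt_bias", {}), covariates, n)
    if config.noise_sd_choice > 0:
        choice_bias = choice_bias + rng.normal(0, config.noise_sd_choice, n)
    if config.noise_sd_rt > 0:
        rt_bias = rt_bias + rng.normal(0, config.noise_sd_rt, n)

    table: Dict[str, np.ndarray] = {
        "participant_id": np.array([f"P{i:05d}" for i in range(n)]),
        "age": age,
        "sex": sex,
        "self_handedness": self_handedness,
    }
    for i in range(10):
        table[f"ehi_item_{i + 1}"] = ehi_items[:, i]
    for i in range(50):
        table[f"aq_item_{i + 1}"] = aq_raw[:, i]
    table.update(
        {
            "pilot_flag": pilot,
            "bot_response_valid": np.ones(n, dtype=bool),
            "attention_checks_failed": np.zeros(n, dtype=int),
            "attention_checks_total": n_checks_in_task + 2,
            "n_attention_trials": n_checks_in_task,
            "truth_choice_bias": choice_bias,
            "truth_rt_bias": rt_bias,
            "truth_ehi_latent": ehi_latent,
            "truth_bot": np.zeros(n, dtype=bool),
            "truth_inattentive": np.zeros(n, dtype=bool),
            "truth_fast_guesser": np.zeros(n, dtype=bool),
            "truth_nonresponder": np.zeros(n, dtype=bool),
        }
    )
    return pd.DataFrame(table)


def _participant_trial_arrays(
    rng: np.random.Generator,
    choice_bias: float,
    rt_bias: float,
    n_checks: int,
    config: SimulationConfig,
) -> Dict[str, np.ndarray]:
    nt = config.n_trials
    if nt % 3 != 0:
        raise ConfigurationError(
            f"n_trials={nt} not divisible by 3; equal emotion distribution impossible"
        )
    per = nt // 3
    emotion = np.repeat(np.arange(3), per)
    top = np.zeros(nt, dtype=bool)
    for e in range(3):
        idx = np.flatnonzero(emotion == e)
        n_top = per // 2 + (per % 2 and rng.random() < 0.5)
        top[idx[:n_top]] = True
    order = rng.permutation(nt)
    emotion, top = emotion[order], top[order]

    chose_left = rng.random(nt) < expit(choice_bias)
    shift = np.where(chose_left, -rt_bias / 2.0, rt_bias / 2.0)
    rt = np.exp(
        np.log(config.rt_base_ms) + shift + config.rt_sigma_log * rng.standard_normal(nt)
    )
    timeout = rt > config.response_window_ms
    side = np.where(chose_left, "left_vf", "right_vf").astype(object)
    side[timeout] = "none"
    rt[timeout] = np.nan

    total = nt + n_checks
    check_pos = np.sort(rng.choice(total, size=n_checks, replace=False))
    is_check = np.zeros(total, dtype=bool)
    is_check[check_pos] = True
    task_pos = np.flatnonzero(~is_check)

    emotions_all = np.empty(total, dtype=object)
    emotions_all[task_pos] = np.array(EMOTIONS, dtype=object)[emotion]
    emotions_all[check_pos] = "check"
    top_all = np.zeros(total, dtype=bool)
    top_all[task_pos] = top
    side_all = np.full(total, "none", dtype=object)
    side_all[task_pos] = side
    rt_all = np.full(total, np.nan)
    rt_all[task_pos] = rt
    rt_all[check_pos] = np.minimum(
        np.exp(np.log(config.rt_base_ms) + config.rt_sigma_log * rng.standard_normal(n_checks)),
        config.response_window_ms,
    )
    return {
        "trial_index": np.arange(total),
        "emotion": emotions_all,
        "left_vf_on_top": top_all,
        "is_attention_check": is_check,
        "check_passed": np.ones(total, dtype=bool),
        "chosen_side": side_all,
        "rt_ms": rt_all,
    }


def generate_trials(
    participant: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """One participant's full task log (task trials + attention checks)."""
    idx = int(str(participant["participant_id"]).lstrip("P"))
    rng = _rng_for(config.seed, 1, idx)
    arrays = _participant_trial_arrays(
        rng,
        float(participant["truth_choice_bias"]),
        float(participant["truth_rt_bias"]),
        int(participant["n_attention_trials"]),
        config,
    )
    df = pd.DataFrame(arrays)
    df.insert(0, "participant_id", participant["participant_id"])
    return df


def generate_cohort_trials(
    participants: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Task logs for a whole cohort, one deterministic RNG stream each."""
    pieces: List[Dict[str, np.ndarray]] = []
    ids: List[np.ndarray] = []
    for _, row in participants.iterrows():
        idx = int(str(row["participant_id"]).lstrip("P"))
        rng = _rng_for(config.seed, 1, idx)
        arrays = _participant_trial_arrays(
            rng,
            float(row["truth_choice_bias"]),
            float(row["truth_rt_bias"]),
            int(row["n_attention_trials"]),
            config,
        )
        pieces.append(arrays)
        ids.append(np.repeat(row["participant_id"], len(arrays["trial_index"])))
    cols = {"participant_id": np.concatenate(ids)}
    for name in pieces[0]:
        cols[name] = np.concatenate([p[name] for p in pieces])
    return pd.DataFrame(cols)


def inject_contaminants(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Create bot, attention, fast-guess and non-response failures.

    Marked participants receive, respectively: an invalid bot-check response;
    exactly threshold-many failed attention checks (2 standard / 3 pilot,
    with one extra near-threshold passer for boundary coverage); 11 of their
    task trials pushed under 200 ms; or 11 task trials blanked to
    non-responses — both of the latter leaving 181/192 valid trials, below
    the 95% completion gate. Ground truth lands in the ``truth_*`` columns.
    With all rates zero the cohort is returned unchanged.
    """
    c = config.contamination
    if (c.bot_rate, c.inattentive_rate, c.fast_guess_rate, c.nonresponse_rate) == (
        0.0,
        0.0,
        0.0,
        0.0,
    ):
        return participants, trials

    participants = participants.copy()
    trials = trials.copy()
    rng = _rng_for(config.seed, 2)
    pool = rng.permutation(participants["participant_id"].to_numpy())
    cursor = 0

    def take(rate: float) -> np.ndarray:
        nonlocal cursor
        k = int(round(rate * len(participants)))
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    p = participants.set_index("participant_id", drop=False)

    for pid in take(c.bot_rate):
        p.loc[pid, "bot_response_valid"] = False
        p.loc[pid, "truth_bot"] = True

    inattentive = take(c.inattentive_rate)
    for pid in inattentive:
        k_fail = 3 if p.loc[pid, "pilot_flag"] else 2
        p.loc[pid, "attention_checks_failed"] = k_fail
        p.loc[pid, "truth_inattentive"] = True
        mask = (trials["participant_id"] == pid) & trials["is_attention_check"]
        flip = trials.index[mask][: k_fail]
        trials.loc[flip, "check_passed"] = False
    if len(inattentive) and cursor < len(pool):
        # boundary passer: one failure below the threshold, not excludable
        pid = pool[cursor]
        cursor += 1
        p.loc[pid, "attention_checks_failed"] = (
            2 if p.loc[pid, "pilot_flag"] else 1
        )

    responded = trials["chosen_side"].isin(["left_vf", "right_vf"]) & ~trials[
        "is_attention_check"
    ].astype(bool)
    for pid in take(c.fast_guess_rate):
        cand = trials.index[responded & (trials["participant_id"] == pid)]
        hit = rng.choice(cand, size=min(N_CONTAMINATED_TRIALS, len(cand)), replace=False)
        trials.loc[hit, "rt_ms"] = rng.uniform(50.0, 199.0, size=len(hit))
        p.loc[pid, "truth_fast_guesser"] = True

    for pid in take(c.nonresponse_rate):
        cand = trials.index[responded & (trials["participant_id"] == pid)]
        hit = rng.choice(cand, size=min(N_CONTAMINATED_TRIALS, len(cand)), replace=False)
        trials.loc[hit, "chosen_side"] = "none"
        trials.loc[hit, "rt_ms"] = np.nan
        p.loc[pid, "truth_nonresponder"] = True

    return p.reset_index(drop=True), trials


def simulate_cohort(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Participants plus trial logs, contaminants included per the config."""
    participants = generate_participants(config)
    trials = generate_cohort_trials(participants, config)
    return inject_contaminants(participants, trials, config)


def sample_lq1(
    participants: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw each participant's choice quotient from its exact trial marginal.

    N_L ~ Binomial(n_trials, logistic(choice_bias)) is the distribution the
    full trial log induces when no trials are lost to cleaning, so replicate
    studies can skip the per-trial bookkeeping.
    """
    p_left = expit(participants["truth_choice_bias"].to_numpy())
    n_left = rng.binomial(config.n_trials, p_left)
    return (2.0 * n_left - config.n_trials) / config.n_trials
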