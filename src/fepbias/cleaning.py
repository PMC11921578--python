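"""Participant- and trial-level exclusion rules with an auditable report.

Rule order (logged in the report):

1. completeness — any missing questionnaire item or an incomplete task log
   excludes the participant outright (no imputation);
2. attention gate — >= 2 failed attention checks exclude (>= 3 under the
   pilot protocol, which administered extra checks);
3. bot gate — failed free-text bot check excludes;
4. response-pattern flag — a deterministic proxy for manual review:
   over-long runs of one response key or near-zero key entropy;
5. fast-trial filter — responded trials under 200 ms are removed
   (strict 'below': 199 ms goes, 200 ms stays);
6. completion gate — after the fast filter, participants with fewer than
   95% valid responded task trials are excluded.

Undisclosed-sex participants survive cleaning but are removed from any
model-bound table by :func:`sex_analysis_filter`; they stay in sex-free
descriptives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CleaningConfig

__all__ = [
    "CleaningReport",
    "filter_fast_trials",
    "attention_gate",
    "completion_gate",
    "pattern_flag",
    "sex_analysis_filter",
    "clean_cohort",
]

RULE_ORDER = (
    "incomplete",
    "attention_fail",
    "bot_fail",
    "pattern_flag",
    "completion_below_95",
)


@dataclass
class CleaningReport:
    """Counts and per-participant audit trail of the applied exclusion rules."""

    n_input: int = 0
    n_retained: int = 0
    exclusions: Dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in RULE_ORDER}
    )
    trail: Dict[str, List[str]] = field(default_factory=dict)
    n_trials_removed_fast: int = 0
    rule_order: Tuple[str, ...] = RULE_ORDER

    def record(self, participant_id: str, reason: str) -> None:
        self.exclusions[reason] += 1
        self.trail.setdefault(str(participant_id), []).append(reason)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
            "n_trials_removed_fast": self.n_trials_removed_fast,
            "rule_order": list(self.rule_order),
            "excluded_participants": {k: list(v) for k, v in self.trail.items()},
        }

    def validate(self) -> None:
        n_excluded = len(self.trail)
        if self.n_input != self.n_retained + n_excluded:
            raise AssertionError("cleaning bookkeeping does not balance")
        if any(len(v) == 0 for v in self.trail.values()):
            raise AssertionError("excluded participant without a recorded reason")


def filter_fast_trials(
    trials: pd.DataFrame, rt_min_ms: float = 200.0
) -> Tuple[pd.DataFrame, int]:
    """Drop responded task trials with reaction time strictly below the floor.

    Attention-check trials and non-response trials (no RT) are never removed
    here. Negative RTs indicate corrupt input and raise.
    """
    rt = trials["rt_ms"]
    if (rt.dropna() < 0).any():
        raise ValueError("negative reaction time encountered")
    responded = trials["chosen_side"].isin(["left_vf", "right_vf"]) & ~trials[
        "is_attention_check"
    ].astype(bool)
    fast = responded & (rt < rt_min_ms)
    return trials[~fast].copy(), int(fast.sum())


def attention_gate(
    failures: int,
    pilot: bool = False,
    threshold_standard: int = 2,
    threshold_pilot: int = 3,
) -> bool:
    """True (pass) unless the failure count reaches the protocol's threshold."""
    if failures < 0:
        raise ValueError("negative failure count")
    return failures < (threshold_pilot if pilot else threshold_standard)


def completion_gate(valid_trials: int, total_trials: int, min_rate: float = 0.95) -> bool:
    """True (pass) iff valid_trials / total_trials >= min_rate."""
    if total_trials <= 0:
        raise ValueError("total_trials must be positive")
    return valid_trials / total_trials >= min_rate


def _longest_run(seq: np.ndarray) -> int:
    if len(seq) == 0:
        return 0
    change = np.nonzero(seq[1:] != seq[:-1])[0]
    bounds = np.concatenate(([-1], change, [len(seq) - 1]))
    return int(np.diff(bounds).max())


def pattern_flag(
    keys: Sequence[str] | np.ndarray,
    max_run: int = 25,
    min_entropy: float = 0.10,
) -> bool:
    """Flag over-repetitive responding from the ordered response-key sequence.

    True when the longest run of one key exceeds ``max_run`` or the binary
    key entropy (bits) falls below ``min_entropy``. An empty sequence is not
    flagged (completeness is handled elsewhere).
    """
    arr = np.asarray(keys)
    if arr.size == 0:
        return False
    if _longest_run(arr) > max_run:
        return True
    _, counts = np.unique(arr, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return entropy < min_entropy


def sex_analysis_filter(participants: pd.DataFrame) -> pd.DataFrame:
    """Restrict a table to disclosed-sex rows for any analysis involving sex."""
    out = participants[participants["sex"].isin(["female", "male"])].copy()
    if out.empty:
        warnings.warn("no disclosed-sex participants remain; model table is empty")
    return out


def _response_keys(trials: pd.DataFrame) -> np.ndarray:
    """Top/bottom key presses reconstructed from chosen side and image layout."""
    chose_left = trials["chosen_side"].to_numpy() == "left_vf"
    left_on_top = trials["left_vf_on_top"].to_numpy().astype(bool)
    return np.where(chose_left == left_on_top, "top", "bottom")


def clean_cohort(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    config: CleaningConfig | None = None,
    n_task_trials: int | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Apply every exclusion rule in order; return retained tables and report.

    ``n_task_trials`` is the completion-gate denominator per participant
    (the task's nominal non-check trial count); inferred from the modal
    per-participant task-trial count when omitted.
    """
    cfg = config or CleaningConfig()
    report = CleaningReport(n_input=len(participants))

    task = trials[~trials["is_attention_check"].astype(bool)]
    per_p_trials = task.groupby("participant_id").size()
    if n_task_trials is None:
        if per_p_trials.empty:
            raise ValueError("no task trials supplied")
        n_task_trials = int(per_p_trials.mode().iloc[0])

    item_cols = [f"ehi_item_{i}" for i in range(1, 11)] + [
        f"aq_item_{i}" for i in range(1, 51)
    ]
    excluded: set = set()

    for _, row in participants.iterrows():
        pid = row["participant_id"]
        n_logged = int(per_p_trials.get(pid, 0))
        if row[item_cols].isna().any() or n_logged < n_task_trials:
            report.record(pid, "incomplete")
            excluded.add(pid)

    pilot = participants.set_index("participant_id")["pilot_flag"].astype(bool)
    fails = participants.set_index("participant_id")["attention_checks_failed"]
    for pid in participants["participant_id"]:
        if pid in excluded:
            continue
        if not attention_gate(
            int(fails[pid]),
            pilot=bool(pilot[pid]),
            threshold_standard=cfg.attention_fail_threshold,
            threshold_pilot=cfg.attention_fail_threshold_pilot,
        ):
            report.record(pid, "attention_fail")
            excluded.add(pid)

    bot_ok = participants.set_index("participant_id")["bot_response_valid"].astype(bool)
    for pid in participants["participant_id"]:
        if pid not in excluded and not bot_ok[pid]:
            report.record(pid, "bot_fail")
            excluded.add(pid)

    responded = task[task["chosen_side"].isin(["left_vf", "right_vf"])]
    for pid, grp in responded.groupby("participant_id"):
        if pid in excluded:
            continue
        ordered = grp.sort_values("trial_index")
        if pattern_flag(
            _response_keys(ordered),
            max_run=cfg.pattern_max_run,
            min_entropy=cfg.pattern_min_entropy,
        ):
            report.record(pid, "pattern_flag")
            excluded.add(pid)

    kept_trials, n_fast = filter_fast_trials(trials, rt_min_ms=cfg.rt_min_ms)
    report.n_trials_removed_fast = n_fast

    kept_task = kept_trials[~kept_trials["is_attention_check"].astype(bool)]
    valid_counts = (
        kept_task[kept_task["chosen_side"].isin(["left_vf", "right_vf"])]
        .groupby("participant_id")
        .size()
    )
    for pid in participants["participant_id"]:
        if pid in excluded:
            continue
        if not completion_gate(
            int(valid_counts.get(pid, 0)), n_task_trials, min_rate=cfg.completion_min
        ):
            report.record(pid, "completion_below_95")
            excluded.add(pid)

    retained = participants[~participants["participant_id"].isin(excluded)].copy()
    retained_trials = kept_trials[
        kept_trials["participant_id"].isin(retained["participant_id"])
    ].copy()
    report.n_retained = len(retained)
    report.validate()
    return retained, retained_trials, report
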