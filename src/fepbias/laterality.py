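"""Laterality quotients for hemispheric bias in facial emotion processing.

Two indices per participant, both in [-1, 1] with positive values indicating
a left-visual-field / right-hemisphere advantage:

* LQ1 (choice bias):   (N_L - N_R) / N_total, where N_L / N_R count valid
  trials on which the face with the emotion in the left / right visual field
  was chosen.
* LQ2 (reaction-time bias): (RT_R - RT_L) / RT_Total, with RT_L / RT_R the
  mean reaction times of left- / right-visual-field-emotion choices and
  RT_Total the mean over all valid trials. Slower right-side choices
  (RT_R > RT_L) therefore push LQ2 positive.

LQ2 is undefined when a participant never chose one of the two sides.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["compute_lq1", "compute_lq2", "score_laterality"]


def compute_lq1(n_left: int, n_right: int, n_total: int) -> float:
    """Choice-based laterality quotient (N_L - N_R) / N_total."""
    if n_total <= 0:
        raise ZeroDivisionError("LQ1 undefined: no valid trials")
    if n_left < 0 or n_right < 0 or n_left + n_right > n_total:
        raise ValueError("need 0 <= n_left + n_right <= n_total")
    return (n_left - n_right) / n_total


def compute_lq2(rt_right_mean: float, rt_left_mean: float, rt_total_mean: float) -> float:
    """Reaction-time laterality quotient (RT_R - RT_L) / RT_Total.

    Returns NaN when either side-conditional mean is missing (no choices on
    that side), which excludes the participant from the RT-bias model only.
    """
    if math.isnan(rt_right_mean) or math.isnan(rt_left_mean):
        return float("nan")
    if not rt_total_mean > 0:
        raise ZeroDivisionError("LQ2 undefined: non-positive mean reaction time")
    return (rt_right_mean - rt_left_mean) / rt_total_mean


def score_laterality(
    trials: pd.DataFrame,
    denominator: str = "valid",
    n_nominal: int | None = None,
) -> pd.DataFrame:
    """Per-participant laterality summary from a (cleaned) trial log.

    Parameters
    ----------
    trials
        Long table with participant_id, is_attention_check, chosen_side
        ({'left_vf', 'right_vf', 'none'}) and rt_ms.
    denominator
        'valid' (default): N_total in LQ1 is the participant's valid responded
        trial count. 'nominal': the task's nominal trial count ``n_nominal``.
    n_nominal
        Required when denominator='nominal'.

    Returns
    -------
    One row per participant: n_left, n_right, n_total, rt_left_mean,
    rt_right_mean, rt_total_mean, lq1, lq2. Participants with zero valid
    trials are dropped (LQ1 undefined); lq2 is NaN where one side is empty.
    """
    if denominator not in ("valid", "nominal"):
        raise ValueError("denominator must be 'valid' or 'nominal'")
    if denominator == "nominal" and not n_nominal:
        raise ValueError("n_nominal required for the nominal denominator")

    task = trials[~trials["is_attention_check"].astype(bool)]
    valid = task[task["chosen_side"].isin(["left_vf", "right_vf"])]

    pid = valid["participant_id"]
    is_left = (valid["chosen_side"] == "left_vf").astype(int)
    grp_rt = valid["rt_ms"].groupby(pid)
    out = pd.DataFrame(
        {
            "n_left": is_left.groupby(pid).sum(),
            "n_total": pid.groupby(pid).size(),
            "rt_total_mean": grp_rt.mean(),
        }
    )
    out["n_right"] = out["n_total"] - out["n_left"]
    side_rt = valid.pivot_table(
        index="participant_id", columns="chosen_side", values="rt_ms", aggfunc="mean"
    )
    out["rt_left_mean"] = side_rt.get("left_vf", np.nan)
    out["rt_right_mean"] = side_rt.get("right_vf", np.nan)

    denom = out["n_total"] if denominator == "valid" else n_nominal
    out["lq1"] = (out["n_left"] - out["n_right"]) / denom
    out["lq2"] = (out["rt_right_mean"] - out["rt_left_mean"]) / out["rt_total_mean"]
    out.loc[(out["n_left"] == 0) | (out["n_right"] == 0), "lq2"] = np.nan

    cols = [
        "n_left",
        "n_right",
        "n_total",
        "rt_left_mean",
        "rt_right_mean",
        "rt_total_mean",
        "lq1",
        "lq2",
    ]
    return out[cols].reset_index()
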