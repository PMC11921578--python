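"""Questionnaire scoring: Edinburgh Handedness Inventory and Autism-spectrum Quotient.

The EHI is a 10-item hand-preference inventory on a 5-level scale from strong
left to strong right; its score is the classic laterality quotient
100*(R - L)/(R + L) in [-100, 100], where R and L are preference "checks"
accumulated with the two-column convention (strong preference = 2 checks on
one side, weak = 1, no preference = 1 check each side).

The AQ is a 50-item trait questionnaire with five 10-item subscales
(social skills, attention switching, attention to detail, communication,
imagination). Scoring here uses the alternative 4-point method: each item
contributes its keyed 1-4 response (reverse-keyed items flipped as 5 - r),
giving subscale scores in [10, 40] and totals in [50, 200].

The item -> subscale / keying map ships as an editable CSV
(``fepbias/data/aq_key.csv``) rather than hard-coded constants.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AQ_SUBSCALES

__all__ = [
    "EHI_LEVELS",
    "load_aq_key",
    "score_ehi",
    "score_aq",
    "cronbach_alpha",
    "score_participants",
    "subscale_alphas",
]

#: Valid EHI item codes: -2 strong left, -1 weak left, 0 no preference,
#: +1 weak right, +2 strong right.
EHI_LEVELS = (-2, -1, 0, 1, 2)

# (left checks, right checks) per item code under the two-column convention
_EHI_CHECKS = {-2: (2, 0), -1: (1, 0), 0: (1, 1), 1: (0, 1), 2: (0, 2)}


class ScoringError(ValueError):
    """Raised for incomplete or out-of-range questionnaire responses."""


def load_aq_key() -> pd.DataFrame:
    """Load the AQ item key: columns item (1-50), subscale, reverse_keyed."""
    with resources.files("fepbias.data").joinpath("aq_key.csv").open() as fh:
        key = pd.read_csv(fh)
    key["reverse_keyed"] = key["reverse_keyed"].astype(bool)
    return key.set_index("item").sort_index()


def score_ehi(items: Sequence[float]) -> float:
    """Score a complete 10-item EHI response; returns a value in [-100, 100]."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (10,):
        raise ScoringError(f"EHI requires exactly 10 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ScoringError("EHI response incomplete: missing items are not imputed")
    if not np.isin(arr, EHI_LEVELS).all():
        raise ScoringError(f"EHI item codes must be in {EHI_LEVELS}")
    left = sum(_EHI_CHECKS[int(v)][0] for v in arr)
    right = sum(_EHI_CHECKS[int(v)][1] for v in arr)
    return 100.0 * (right - left) / (right + left)


def score_aq(items: Sequence[float], key: pd.DataFrame | None = None) -> dict:
    """Score a complete 50-item AQ response under the 4-point alternative method.

    Parameters
    ----------
    items
        Raw responses in order of item number, each in 1..4 on the agreement
        scale (1 = definitely disagree ... 4 = definitely agree).
    key
        Item key as returned by :func:`load_aq_key`; loaded if omitted.

    Returns
    -------
    dict with ``total`` (50-200), ``subscales`` (each 10-40) and the per-item
    ``keyed`` values.
    """
    if key is None:
        key = load_aq_key()
    arr = np.asarray(items, dtype=float)
    if arr.shape != (50,):
        raise ScoringError(f"AQ requires exactly 50 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ScoringError("AQ response incomplete: missing items are not imputed")
    if not np.isin(arr, (1, 2, 3, 4)).all():
        raise ScoringError("AQ responses must be integers in 1..4")
    reverse = key["reverse_keyed"].to_numpy()
    keyed = np.where(reverse, 5 - arr, arr).astype(int)
    subscales = {
        sub: int(keyed[(key["subscale"] == sub).to_numpy()].sum())
        for sub in AQ_SUBSCALES
    }
    return {"total": int(keyed.sum()), "subscales": subscales, "keyed": keyed}


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a participants x items matrix of one scale.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (ddof=1) variances. Requires >=2 items, >=3 participants and
    a nonzero variance of the item sums.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("variance of item sums is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def _item_columns(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def score_participants(participants: pd.DataFrame) -> pd.DataFrame:
    """Add ehi_score, aq_total and the five AQ subscale columns to a cohort table.

    Expects columns ehi_item_1..10 (codes -2..2) and aq_item_1..50 (raw 1..4).
    Rows with any missing item raise; completeness is handled upstream by the
    cleaning stage.
    """
    key = load_aq_key()
    ehi_cols = _item_columns("ehi_item_", 10)
    aq_cols = _item_columns("aq_item_", 50)
    missing = [c for c in ehi_cols + aq_cols if c not in participants.columns]
    if missing:
        raise ScoringError(f"cohort table lacks item columns: {missing[:5]} ...")

    out = participants.copy()
    ehi = out[ehi_cols].to_numpy(dtype=float)
    aq = out[aq_cols].to_numpy(dtype=float)
    if np.isnan(ehi).any() or np.isnan(aq).any():
        raise ScoringError("missing questionnaire items; exclude incomplete rows first")

    left = np.zeros(len(out))
    right = np.zeros(len(out))
    for code, (l_ch, r_ch) in _EHI_CHECKS.items():
        n_code = (ehi == code).sum(axis=1)
        left += n_code * l_ch
        right += n_code * r_ch
    out["ehi_score"] = 100.0 * (right - left) / (right + left)

    reverse = key["reverse_keyed"].to_numpy()
    keyed = np.where(reverse, 5 - aq, aq)
    for sub in AQ_SUBSCALES:
        mask = (key["subscale"] == sub).to_numpy()
        out[sub] = keyed[:, mask].sum(axis=1).astype(int)
    out["aq_total"] = keyed.sum(axis=1).astype(int)
    return out


def subscale_alphas(participants: pd.DataFrame) -> dict[str, float]:
    """Cronbach's alpha of each AQ subscale from keyed item responses."""
    key = load_aq_key()
    aq = participants[_item_columns("aq_item_", 50)].to_numpy(dtype=float)
    keyed = np.where(key["reverse_keyed"].to_numpy(), 5 - aq, aq)
    return {
        sub: cronbach_alpha(keyed[:, (key["subscale"] == sub).to_numpy()])
        for sub in AQ_SUBSCALES
    }
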