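"""OLS interaction models, semipartial effect sizes, diagnostics, correlations.

Both published-style models regress a laterality quotient on 13 predictor
terms: eight main effects (EHI handedness score, age, sex with female as the
reference level, and the five AQ subscales) plus the five AQ-subscale-by-sex
interactions. Predictors enter raw (uncentred, unstandardised); the male
indicator is 0/1 and interactions are plain products. Model 1 uses the
choice-based quotient (lq1) as outcome, model 2 the reaction-time quotient
(lq2).

Per coefficient the table reports the unstandardised estimate, SE, t-based
95% CI, two-sided p, and the squared semipartial correlation
sr^2 = t^2 * (1 - R^2) / df_resid — the share of outcome variance the term
explains uniquely. Diagnostics: Durbin-Watson, studentised (Koenker)
Breusch-Pagan, Shapiro-Wilk on residuals. No multiple-testing correction is
applied across coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

from .config import AQ_SUBSCALES

__all__ = [
    "MAIN_TERMS",
    "INTERACTION_TERMS",
    "ALL_TERMS",
    "RegressionResult",
    "build_design",
    "fit_model",
    "semipartial_r2",
    "diagnostics",
    "correlation_matrix",
    "prepare_model_frame",
]

#: Main-effect order of the published models.
MAIN_TERMS: Tuple[str, ...] = (
    "ehi_score",
    "age",
    "sex_male",
) + AQ_SUBSCALES

#: One interaction per AQ subscale with the male indicator.
INTERACTION_TERMS: Tuple[str, ...] = tuple(f"{s}:sex_male" for s in AQ_SUBSCALES)

ALL_TERMS: Tuple[str, ...] = MAIN_TERMS + INTERACTION_TERMS


@dataclass
class RegressionResult:
    """A fitted linear model: coefficient table, fit statistics, diagnostics."""

    outcome: str
    terms: Tuple[str, ...]
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, t, p, sr2
    r2: float
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    p_model: float
    diagnostics: Dict[str, float]
    residuals: np.ndarray
    fitted: np.ndarray
    n: int

    def fit_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f": self.f_stat,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "p_model": self.p_model,
        }


def prepare_model_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Add the male indicator and product interaction columns to a scored table.

    Requires disclosed sex on every row (apply the sex filter first).
    """
    out = data.copy()
    if not out["sex"].isin(["female", "male"]).all():
        raise ValueError("undisclosed-sex rows present; apply sex_analysis_filter first")
    out["sex_male"] = (out["sex"] == "male").astype(float)
    for sub in AQ_SUBSCALES:
        out[f"{sub}:sex_male"] = out[sub] * out["sex_male"]
    return out


def build_design(
    data: pd.DataFrame, terms: Sequence[str] = ALL_TERMS
) -> pd.DataFrame:
    """Design matrix with an explicit intercept column, in term order."""
    x = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        x[t] = pd.to_numeric(data[t], errors="raise").astype(float)
    return x


def _check_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via pivoted QR
        _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [x.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [x.columns[j] for j in piv[len(diag):]]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")


def fit_model(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str] = ALL_TERMS,
) -> RegressionResult:
    """Ordinary least squares with t-based CIs, sr^2 and assumption checks.

    Complete cases only: rows missing the outcome (e.g. participants with an
    undefined reaction-time quotient) are dropped before fitting.
    """
    terms = tuple(terms)
    cols = [outcome, *terms]
    frame = data[cols].dropna()
    y = frame[outcome].to_numpy(dtype=float)
    x = build_design(frame, terms)
    _check_rank(x)

    model = sm.OLS(y, x.to_numpy(dtype=float))
    res = model.fit()
    names = list(x.columns)
    ci = res.conf_int(alpha=0.05)

    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    sr2 = res.tvalues**2 * (1.0 - res.rsquared) / res.df_resid
    coef["sr2"] = sr2
    coef.loc[coef["term"] == "intercept", "sr2"] = np.nan

    diag = diagnostics_from_fit(res.resid, x.to_numpy(dtype=float))
    return RegressionResult(
        outcome=outcome,
        terms=terms,
        coefficients=coef.reset_index(drop=True),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_model=float(res.f_pvalue),
        diagnostics=diag,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=len(frame),
    )


def semipartial_r2(result: RegressionResult, term: str) -> float:
    """sr^2 of one term: t^2 (1 - R^2_full) / df_resid.

    Identical (to numerical precision) to the R^2 drop from refitting the
    model without the term.
    """
    row = result.coefficients.loc[result.coefficients["term"] == term]
    if row.empty or term == "intercept":
        raise KeyError(f"term {term!r} not among the model's predictors")
    t = float(row["t"].iloc[0])
    return t * t * (1.0 - result.r2) / result.df_resid


def diagnostics_from_fit(resid: np.ndarray, exog: np.ndarray) -> Dict[str, float]:
    resid = np.asarray(resid, dtype=float)
    out: Dict[str, float] = {"durbin_watson": float(durbin_watson(resid))}
    try:
        _, bp_p, _, _ = het_breuschpagan(resid, exog, robust=True)
        out["breusch_pagan_p"] = float(bp_p)
    except (ValueError, np.linalg.LinAlgError):
        out["breusch_pagan_p"] = float("nan")
    if len(resid) >= 3:
        out["shapiro_wilk_p"] = float(st.shapiro(resid).pvalue)
    else:
        out["shapiro_wilk_p"] = float("nan")
    return out


def diagnostics(result: RegressionResult) -> Dict[str, float]:
    """Durbin-Watson, studentised Breusch-Pagan p, Shapiro-Wilk p."""
    return dict(result.diagnostics)


def correlation_matrix(
    data: pd.DataFrame, columns: Sequence[str], group: str = "all"
) -> Dict[str, Dict[str, pd.DataFrame]]:
    """Pairwise Pearson r and p matrices, overall or split by biological sex.

    p-values come from the t transform t = r sqrt((n-2)/(1-r^2)). Pairs with
    a constant column get NaN r (flagged by a warning column in r itself).
    """
    def one(frame: pd.DataFrame) -> Dict[str, pd.DataFrame]:
        k = len(columns)
        r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
        p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
        np.fill_diagonal(p.values, np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                pair = frame[[columns[i], columns[j]]].dropna()
                if len(pair) < 3:
                    rij, pij = np.nan, np.nan
                elif pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                    rij, pij = np.nan, np.nan
                else:
                    rij, pij = st.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                r.iloc[i, j] = r.iloc[j, i] = rij
                p.iloc[i, j] = p.iloc[j, i] = pij
        return {"r": r, "p": p}

    if group == "all":
        return {"all": one(data)}
    if group == "by_sex":
        return {
            sex: one(data[data["sex"] == sex]) for sex in ("female", "male")
        }
    raise ValueError("group must be 'all' or 'by_sex'")
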