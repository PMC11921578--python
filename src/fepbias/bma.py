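"""BIC-approximate Bayesian model averaging with inclusion Bayes factors.

The model space mirrors the published design: an intercept-only null model,
one single-predictor model per main effect, and one full model carrying all
main effects plus the sex interactions — with 8 mains and 5 interactions
that is exactly 10 models, each with prior probability 1/10 (uniform-equal
prior odds). Interactions therefore appear only in the full model, giving
prior inclusion probabilities of 0.20 for every main effect and 0.10 for
every interaction.

Each model's evidence is approximated through its BIC,

    BIC = k * ln(n) - 2 * ln(L_hat),

with the Gaussian OLS profile likelihood
ln(L_hat) = -(n/2) * (ln(2*pi) + ln(RSS/n) + 1) and k counting the intercept,
the slopes and the residual-variance parameter. The Bayes factor of a model
against the null is exp((BIC_null - BIC_model)/2); only BIC differences
matter, so the k convention is a frozen offset. All arithmetic stays on the
log scale, keeping results finite for |delta BIC| well beyond 1400.

For a term T, with posterior model probabilities p_m proportional to
prior_m * BF_m, the inclusion Bayes factor compares posterior to prior
inclusion odds marginalised over the whole space ("comparison = all models"):

    BF_incl(T) = [P(T|D) / (1 - P(T|D))] / [P(T) / (1 - P(T))].

Evidence strength follows the conventional Bayes-factor bands
(weak 1-3, moderate 3-20, strong 20-150, very strong > 150; upper edges
inclusive), with BF < 1 reported on the reciprocal band as evidence against
inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ModelSpace",
    "BMAResult",
    "EvidenceLabel",
    "enumerate_space",
    "model_bic",
    "log_bf_vs_null",
    "bf_vs_null",
    "inclusion_stats",
    "label_evidence",
    "run_bma",
]


@dataclass(frozen=True)
class ModelSpace:
    """An ordered set of nested OLS models with prior model probabilities."""

    models: Tuple[Tuple[str, ...], ...]
    prior_probs: Tuple[float, ...]
    terms: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.models)

    def prior_inclusion(self, term: str) -> float:
        return sum(
            p for m, p in zip(self.models, self.prior_probs) if term in m
        )


@dataclass(frozen=True)
class EvidenceLabel:
    """Kass-Raftery-style strength band plus direction of the evidence."""

    strength: str  # none | weak | moderate | strong | very strong
    direction: str  # for | against | equivocal

    def __str__(self) -> str:
        if self.direction == "equivocal":
            return "no evidence either way"
        return f"{self.strength}, {self.direction} inclusion"


def enumerate_space(
    mains: Sequence[str], interactions: Sequence[str] = ()
) -> ModelSpace:
    """Null + one model per main effect + one full model, uniform priors."""
    mains = tuple(mains)
    interactions = tuple(interactions)
    all_terms = mains + interactions
    if len(set(all_terms)) != len(all_terms):
        raise ValueError("duplicate terms in model space")
    models: list[Tuple[str, ...]] = [()]
    models.extend((m,) for m in mains)
    models.append(all_terms)
    n = len(models)
    return ModelSpace(
        models=tuple(models),
        prior_probs=tuple(1.0 / n for _ in models),
        terms=all_terms,
    )


def _ols_rss(y: np.ndarray, x: np.ndarray) -> float:
    coef, rss, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design in model space")
    if rss.size == 0:  # perfect fit or n <= p
        rss = np.array([float(np.sum((y - x @ coef) ** 2))])
    return float(rss[0])


def model_bic(terms: Sequence[str], data: pd.DataFrame, outcome: str) -> float:
    """BIC of the OLS model ``outcome ~ intercept + terms`` on complete cases.

    k includes the intercept, the slopes and the residual variance.
    """
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    cols = [data[t].to_numpy(dtype=float) for t in terms]
    x = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    rss = _ols_rss(y, x)
    if rss <= 0:
        raise ValueError("zero residual sum of squares; BIC undefined")
    k = x.shape[1] + 1
    loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    return k * np.log(n) - 2.0 * loglik


def log_bf_vs_null(bic_model: float, bic_null: float) -> float:
    """log Bayes factor of a model against the null from their BICs."""
    return (bic_null - bic_model) / 2.0


def bf_vs_null(bic_model: float, bic_null: float) -> float:
    return float(np.exp(log_bf_vs_null(bic_model, bic_null)))


def inclusion_stats(space: ModelSpace, log_bfs: Sequence[float]) -> pd.DataFrame:
    """Posterior model probabilities and per-term inclusion Bayes factors.

    Parameters
    ----------
    space
        The model space (the null model's log BF must be 0).
    log_bfs
        One log Bayes factor per model, versus the null, in model order.

    Returns
    -------
    Per-term table: prior_incl, posterior_incl, bf_inclusion,
    log_bf_inclusion, evidence.
    """
    log_bfs = np.asarray(log_bfs, dtype=float)
    if log_bfs.shape != (len(space),):
        raise ValueError("need one log BF per model")
    if not np.isfinite(log_bfs).all():
        raise ValueError("non-finite log Bayes factor")
    log_prior = np.log(np.asarray(space.prior_probs))
    log_unnorm = log_prior + log_bfs
    log_post = log_unnorm - logsumexp(log_unnorm)

    rows = []
    for term in space.terms:
        member = np.array([term in m for m in space.models])
        if member.all() or not member.any():
            raise ValueError(f"term {term!r} must split the model space")
        prior_incl = space.prior_inclusion(term)
        log_odds_post = logsumexp(log_post[member]) - logsumexp(log_post[~member])
        log_odds_prior = np.log(prior_incl) - np.log1p(-prior_incl)
        log_bf_incl = log_odds_post - log_odds_prior
        rows.append(
            {
                "term": term,
                "prior_incl": prior_incl,
                "posterior_incl": float(np.exp(logsumexp(log_post[member]))),
                "bf_inclusion": float(np.exp(log_bf_incl)),
                "log_bf_inclusion": float(log_bf_incl),
                "evidence": str(label_evidence_log(log_bf_incl)),
            }
        )
    return pd.DataFrame(rows)


_BANDS = ((np.log(3.0), "weak"), (np.log(20.0), "moderate"), (np.log(150.0), "strong"))


def label_evidence_log(log_bf: float) -> EvidenceLabel:
    """Evidence band from a log inclusion Bayes factor (overflow-safe)."""
    if not np.isfinite(log_bf):
        raise ValueError("log BF must be finite")
    if log_bf == 0.0:
        return EvidenceLabel("none", "equivocal")
    direction = "for" if log_bf > 0 else "against"
    mag = abs(log_bf)
    for edge, name in _BANDS:
        if mag <= edge:
            return EvidenceLabel(name, direction)
    return EvidenceLabel("very strong", direction)


def label_evidence(bf: float) -> EvidenceLabel:
    """Evidence band from an inclusion Bayes factor (> 0)."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    return label_evidence_log(float(np.log(bf)))


def run_bma(
    data: pd.DataFrame,
    outcome: str,
    mains: Sequence[str],
    interactions: Sequence[str],
) -> "BMAResult":
    """Fit the whole model space on one outcome and summarise it."""
    space = enumerate_space(mains, interactions)
    bics = [model_bic(m, data, outcome) for m in space.models]
    bic_null = bics[0]
    log_bfs = [log_bf_vs_null(b, bic_null) for b in bics]
    log_prior = np.log(np.asarray(space.prior_probs))
    log_unnorm = log_prior + np.asarray(log_bfs)
    log_post = log_unnorm - logsumexp(log_unnorm)
    models = pd.DataFrame(
        {
            "terms": [" + ".join(m) if m else "(intercept only)" for m in space.models],
            "n_terms": [len(m) for m in space.models],
            "bic": bics,
            "log_bf_vs_null": log_bfs,
            "posterior_prob": np.exp(log_post),
        }
    )
    terms = inclusion_stats(space, log_bfs)
    return BMAResult(space=space, models=models, terms=terms, n=len(data))


@dataclass
class BMAResult:
    """Per-model and per-term summaries of one model-averaging run."""

    space: ModelSpace
    models: pd.DataFrame
    terms: pd.DataFrame
    n: int
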