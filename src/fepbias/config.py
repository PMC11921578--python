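"""Configuration models for the cohort simulator and the analysis pipeline.

All tunables carry defaults that emulate the recruitment the analysis assumes:
a general-population adult online cohort of 427 (214 female, 210 male,
3 undisclosed), ages 18-67, predominantly right-handed, performing a
192-trial chimeric faces task with a 4.5 s response window.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

#: Canonical AQ subscale order used throughout the package.
AQ_SUBSCALES: Tuple[str, ...] = (
    "social_skills",
    "attention_switching",
    "attention_to_detail",
    "communication",
    "imagination",
)


class MixtureComponent(BaseModel):
    """One truncated-normal component of the handedness mixture on [-100, 100]."""

    weight: float = Field(gt=0, le=1)
    mean: float
    sd: float = Field(gt=0)
    label: str = "right"


class ContaminationConfig(BaseModel):
    """Rates of injected data-quality problems, each a cohort fraction in [0, 1]."""

    bot_rate: float = Field(default=0.0, ge=0, le=1)
    inattentive_rate: float = Field(default=0.0, ge=0, le=1)
    fast_guess_rate: float = Field(default=0.0, ge=0, le=1)
    nonresponse_rate: float = Field(default=0.0, ge=0, le=1)


def _default_ehi_mixture() -> List[MixtureComponent]:
    # Weights follow the self-reported handedness split 378/10/39 of 427.
    # Components are censored at [-100, 100], so locations beyond the scale
    # ends pile mass at the extremes (many respondents score exactly +-100);
    # these values put the scored instrument near mean 77.8, sd 55.2.
    return [
        MixtureComponent(weight=378 / 427, mean=128.0, sd=32.0, label="right"),
        MixtureComponent(weight=10 / 427, mean=10.0, sd=30.0, label="ambidextrous"),
        MixtureComponent(weight=39 / 427, mean=-100.0, sd=38.0, label="left"),
    ]


def _default_aq_means() -> Dict[str, float]:
    return {
        "social_skills": 22.84,
        "attention_switching": 25.20,
        "attention_to_detail": 25.24,
        "communication": 20.88,
        "imagination": 20.12,
    }


def _default_aq_sds() -> Dict[str, float]:
    return {
        "social_skills": 5.07,
        "attention_switching": 4.26,
        "attention_to_detail": 5.05,
        "communication": 4.90,
        "imagination": 3.89,
    }


def _default_aq_corr() -> List[List[float]]:
    # Modest positive correlations among the socially loaded subscales;
    # attention to detail is near-orthogonal to the rest.
    r, d = 0.30, 0.10
    order = AQ_SUBSCALES
    m = np.full((5, 5), r)
    np.fill_diagonal(m, 1.0)
    i_det = order.index("attention_to_detail")
    m[i_det, :] = d
    m[:, i_det] = d
    m[i_det, i_det] = 1.0
    return m.tolist()


def _default_effect_map() -> Dict[str, Dict[str, float]]:
    # Latent-trait regressions on raw covariates. Keys are covariate names;
    # "a:b" denotes a product term. Calibrated so LQ1 has mean ~0.17, sd ~0.32
    # and LQ2 mean ~0.02, sd ~0.09 on the default cohort.
    return {
        "choice_bias": {"intercept": 0.22, "ehi_score": 0.002},
        "rt_bias": {
            "intercept": -0.0808,
            "attention_switching": 0.004,
            "sex_male": -0.141,
            "imagination:sex_male": 0.007,
        },
    }


class SimulationConfig(BaseModel):
    """Full parameterisation of the synthetic cohort and task-log generator."""

    n_participants: int = Field(default=427, gt=0)
    sex_proportions: Dict[str, float] = Field(
        default_factory=lambda: {
            "female": 214 / 427,
            "male": 210 / 427,
            "undisclosed": 3 / 427,
        }
    )
    # age_mean/age_sd are the target cohort moments; the generator solves for
    # the truncated-normal location/scale that realises them on [age_min, age_max]
    age_mean: float = 27.23
    age_sd: float = Field(default=8.43, ge=0)
    age_min: float = 18.0
    age_max: float = 67.0

    ehi_mixture: List[MixtureComponent] = Field(default_factory=_default_ehi_mixture)

    aq_subscale_means: Dict[str, float] = Field(default_factory=_default_aq_means)
    aq_subscale_sds: Dict[str, float] = Field(default_factory=_default_aq_sds)
    aq_subscale_corr: List[List[float]] = Field(default_factory=_default_aq_corr)

    effect_map: Dict[str, Dict[str, float]] = Field(default_factory=_default_effect_map)
    noise_sd_choice: float = Field(default=0.72, ge=0)
    noise_sd_rt: float = Field(default=0.06, ge=0)

    n_trials: int = Field(default=192, gt=0)
    rt_base_ms: float = Field(default=1000.0, gt=0)
    rt_sigma_log: float = Field(default=0.40, gt=0)
    response_window_ms: float = Field(default=4500.0, gt=0)

    contamination: ContaminationConfig = Field(default_factory=ContaminationConfig)
    pilot_fraction: float = Field(default=0.05, ge=0, le=1)
    seed: int = 0

    @field_validator("sex_proportions")
    @classmethod
    def _check_sex_proportions(cls, v: Dict[str, float]) -> Dict[str, float]:
        if set(v) != {"female", "male", "undisclosed"}:
            raise ValueError("sex_proportions must have keys female, male, undisclosed")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("sex_proportions must be non-negative and sum to 1")
        return v

    @field_validator("ehi_mixture")
    @classmethod
    def _check_mixture(cls, v: List[MixtureComponent]) -> List[MixtureComponent]:
        if abs(sum(c.weight for c in v) - 1.0) > 1e-9:
            raise ValueError("ehi_mixture weights must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimulationConfig":
        if self.age_min < 18:
            raise ValueError("age_min must be >= 18 (adult recruitment)")
        if self.age_max < self.age_min:
            raise ValueError("age_max must be >= age_min")
        for d in (self.aq_subscale_means, self.aq_subscale_sds):
            if set(d) != set(AQ_SUBSCALES):
                raise ValueError(f"AQ subscale parameters must cover {AQ_SUBSCALES}")
        corr = np.asarray(self.aq_subscale_corr, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ValueError("aq_subscale_corr must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("aq_subscale_corr must be positive definite")
        return self

    def aq_corr_matrix(self) -> np.ndarray:
        return np.asarray(self.aq_subscale_corr, dtype=float)


class CleaningConfig(BaseModel):
    """Thresholds of the participant- and trial-level exclusion rules."""

    rt_min_ms: float = Field(default=200.0, gt=0)
    completion_min: float = Field(default=0.95, gt=0, le=1)
    attention_fail_threshold: int = Field(default=2, ge=1)
    attention_fail_threshold_pilot: int = Field(default=3, ge=1)
    pattern_max_run: int = Field(default=25, ge=1)
    pattern_min_entropy: float = Field(default=0.10, ge=0)


class PipelineConfig(BaseModel):
    """End-to-end run configuration: simulation, cleaning and reporting options."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    cleaning: CleaningConfig = Field(default_factory=CleaningConfig)
    lq1_denominator: str = Field(default="valid", pattern="^(valid|nominal)$")
    verbose: bool = False
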