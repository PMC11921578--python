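"""BIC-approximate Bayesian model averaging with inclusion Bayes factors.

Builds the 10-model space (intercept-only, eight single-predictor models,
one full model), converts each model's BIC into a Bayes factor against the
null, and reports per-term posterior inclusion probabilities and
BF_Inclusion — the change from prior to posterior inclusion odds.
"""

from fepbias import (
    MAIN_TERMS,
    INTERACTION_TERMS,
    SimulationConfig,
    run_bma,
    score_laterality,
    score_participants,
    sex_analysis_filter,
    simulate_cohort,
)
from fepbias.regression import prepare_model_frame

config = SimulationConfig(n_participants=427, seed=1)
participants, trials = simulate_cohort(config)
merged = score_participants(participants).merge(
    score_laterality(trials), on="participant_id"
)
frame = prepare_model_frame(sex_analysis_filter(merged))

for outcome in ("lq1", "lq2"):
    data = frame.dropna(subset=[outcome])
    result = run_bma(data, outcome, MAIN_TERMS, INTERACTION_TERMS)
    print(f"\n=== outcome {outcome} (n = {result.n}) ===")
    print(result.models[["terms", "bic", "posterior_prob"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nper-term inclusion statistics:")
    print(result.terms[["term", "prior_incl", "posterior_incl", "bf_inclusion", "evidence"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

print("\nBF_Inclusion > 1 favours including a term; < 1 favours leaving it out "
      "(bands: weak 1-3, moderate 3-20, strong 20-150, very strong > 150).")
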