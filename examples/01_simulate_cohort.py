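"""Simulate a chimeric-faces-task cohort and inspect its structure.

Generates 427 participants with demographics, questionnaire item responses
and latent task-behaviour traits, plus each participant's full trial log,
then prints the headline descriptives the generator is calibrated to.
"""

from fepbias import SimulationConfig, score_participants, simulate_cohort

config = SimulationConfig(n_participants=427, seed=1)
participants, trials = simulate_cohort(config)
scored = score_participants(participants)

print(f"participants: {len(participants)}")
print(f"sex counts:   {participants['sex'].value_counts().to_dict()}")
print(f"age:          mean {participants['age'].mean():.1f}, "
      f"sd {participants['age'].std():.1f} (target 27.2 / 8.4)")
print(f"EHI score:    mean {scored['ehi_score'].mean():.1f}, "
      f"sd {scored['ehi_score'].std():.1f} (target 77.8 / 55.2)")
print(f"AQ total:     mean {scored['aq_total'].mean():.1f}, "
      f"sd {scored['aq_total'].std():.1f} (target 114.4 / 14.7)")

one = trials[trials["participant_id"] == participants["participant_id"].iloc[0]]
task = one[~one["is_attention_check"]]
print(f"\none session: {len(task)} task trials "
      f"({task['emotion'].value_counts().to_dict()}), "
      f"{int(one['is_attention_check'].sum())} in-task attention checks")
print("Each task trial records which mirrored chimeric face was chosen "
      "(emotion in the left or right visual field) and the reaction time in ms.")
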