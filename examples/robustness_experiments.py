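"""Run the four robustness studies on a small synthetic cohort.

Uses the two linear models on three subjects to keep the demonstration
quick; the full study runs all six models on eleven subjects (see the
acceptance script). Patterns to look for: dropping channels costs
accuracy, more training data helps, and cross-session or posture
transfer degrades sharply.
"""

from semgtorque.experiments import (
    ExperimentPlan,
    channel_subset_experiment,
    cross_session_experiment,
    posture_experiment,
    training_fraction_experiment,
)
from semgtorque.synthetic import generate_cohort

cohort = generate_cohort(n_subjects=3, master_seed=0)
plan = ExperimentPlan(models=("ols", "rls"), seed=1)

print("=== channel subsets (mean Ra2) ===")
res = channel_subset_experiment(cohort, plan)
print(res.summary()[("ra2", "mean")].round(3).to_string())
print("best 2-channel pair per subject/model:",
      sorted(set(res.extras["best_pairs"].values())))

print("\n=== training-set size (mean Ra2) ===")
res = training_fraction_experiment(cohort, plan)
print(res.summary()[("ra2", "mean")].round(3).to_string())

print("\n=== cross-session transfer (mean Ra2) ===")
res = cross_session_experiment(cohort, plan)
print(res.summary()[("ra2", "mean")].round(3).to_string())
print("percent change of mean Ra2, session 1 -> 2:",
      res.relative_changes("s1", "s2", "ra2", "percent"))

print("\n=== arm posture (mean NRMSE) ===")
res = posture_experiment(cohort, plan)
print(res.summary()[("nrmse", "mean")].round(4).to_string())
print("fold increase, pronated -> supinated:",
      {m: round(res.mean(m, "supinated", "nrmse")
                / res.mean(m, "pronated", "nrmse"), 2)
       for m in plan.models})
print("\ntraining in one condition and testing in another degrades every "
      "model: retraining after electrode or posture changes is essential")
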