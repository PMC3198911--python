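"""Fit all six torque estimators on one subject and compare accuracy.

Trains on a random 75% of the decimated samples of a session-1 recording
and evaluates NRMSE / R^2 / adjusted R^2 on the held-out 25%.
"""

from semgtorque import MODEL_KINDS
from semgtorque.experiments import block_split_indices, fit_and_evaluate
from semgtorque.pbm import GAConfig
from semgtorque.processing import process_recording
from semgtorque.synthetic import draw_subject, generate_recording

subject = draw_subject("compare-demo", seed=3)
recording = process_recording(generate_recording(subject, seed=5))
train_idx, test_idx = block_split_indices(
    recording.n_samples, 0.75, 100, contiguous=False, seed=1
)
print(f"train {len(train_idx)} / test {len(test_idx)} decimated samples\n")
print(f"{'model':<6} {'NRMSE %':>8} {'R2':>7} {'Ra2':>7}")
for model in MODEL_KINDS:
    ev = fit_and_evaluate(
        recording, model, recording.channel_names, train_idx,
        {"test": (recording, test_idx)},
        seed=0, ga=GAConfig(population=30, generations=40),
    )["test"]
    print(f"{model:<6} {100 * ev.nrmse:>8.2f} {ev.r2:>7.3f} {ev.ra2:>7.3f}")
print("\nNRMSE is the RMS torque error over the measured range "
      "(max flexion + |max extension|); adjusted R2 penalizes R2 for the "
      "eight SEMG channels used. All six models land in the same few-"
      "percent band on same-session data.")
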