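"""Generate one synthetic recording and run the SEMG conditioning chain.

Builds a full-length protocol execution (33,520 samples at 1 kHz: one
maximal flexion and extension, then gradual ramps to 50% and 25% MVC),
conditions the eight channels into normalized activation envelopes, and
decimates to every 100th sample.
"""

import numpy as np

from semgtorque import process_recording, resample_every
from semgtorque.synthetic import draw_subject, generate_recording

subject = draw_subject("demo", seed=42)
recording = generate_recording(subject, seed=7)
print(f"raw recording: {recording.n_samples} samples, "
      f"{recording.n_channels} channels at {recording.sample_rate_hz:g} Hz")
print(f"torque range: {recording.torque.min():.2f} .. "
      f"{recording.torque.max():.2f} N·m  (flexion positive)")

processed = process_recording(recording)
print("processing steps:", " -> ".join(processed.provenance))
print("envelope range per channel: "
      f"min {processed.envelopes.min():.3f}, "
      f"max {processed.envelopes.max():.3f} (each channel peaks at 1)")

decimated = resample_every(processed, 100)
print(f"decimated training set: {decimated.n_samples} samples "
      "(every 100th sample)")

# mean envelope per channel during the opening maximal flexion
mvc = slice(500, 2000)
means = processed.envelopes[mvc].mean(axis=0)
for name, m in zip(processed.channel_names, means):
    role = "flexor" if name in ("FCR", "PL", "FDS", "FCU") else "extensor"
    print(f"  {name:<5} ({role:<8}) mean envelope during flexion MVC: {m:.2f}")
print("flexor channels are high and extensor channels near the "
      "co-activation floor, as expected during maximal flexion")
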