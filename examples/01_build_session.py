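"""Build a temporal-bisection session and inspect the conflict geometry.

A session holds 150 trials: 30 visual-only, 30 audio-only, then 90 bimodal
trials with the three conflict levels randomly interleaved.  A conflict of
delta = +50 ms offsets the probe by +50 ms (audio later) and the anchors by
-50 ms between the modalities, a 100-ms net conflict.
"""

import numpy as np

from tempobind import SessionConfig, build_session, build_trial, session_to_frame

slots = build_session(SessionConfig(seed=1))
print(f"session slots: {len(slots)}")
conditions = {}
for s in slots:
    conditions[s.condition.value] = conditions.get(s.condition.value, 0) + 1
print(f"trials per condition: {conditions}")
print(f"easy-trial fraction: {np.mean([s.is_easy for s in slots]):.2f}")

trial = build_trial("AV_pos", 50, 500)
print(f"\ndelta=+50 trial at nominal probe 500 ms:")
print(f"  audio  events (ms): {trial.audio_times}")
print(f"  visual events (ms): {trial.visual_times}")
net = (trial.audio_times[1] - trial.visual_times[1]) - (
    trial.audio_times[0] - trial.visual_times[0])
print(f"  net probe-vs-anchor audio-visual conflict: {net:.0f} ms")

print("\nfirst rows of the serialized session:")
print(session_to_frame(slots).head(3).to_string(index=False))
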