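"""Post-processing: mode voting, debouncing and proportional control.

Window predictions arrive ~10 per second.  A rolling queue of 10 takes
the modal label when it fills >= 75 % of the buffer (else 'Unknown'), a
debouncer emits a command only on state changes, and — while a gesture is
held — the arm's roll angle relative to the onset setpoint drives a
proportional controller (here in discrete three-state mode, like an LED
strip switching colour on lateral/medial rotation).
"""

import numpy as np

from fmgkit import PredictionQueue, SpatialState, debounce, spatial_update

# a scripted prediction stream: hold Fist, wobble, then switch to Wave Out
script = (["Fist"] * 14
          + ["Fist", "Pinch", "Fist", "Pinch", "Fist", "Pinch"]  # noisy patch
          + ["Wave Out"] * 14)
roll = np.concatenate([np.zeros(14), np.zeros(6), np.linspace(0, 24, 14)])

queue = PredictionQueue(capacity=10, confidence=0.75)
state = SpatialState(default_axis="roll", mode="discrete", threshold_deg=10.0)
previous = None

for i, (label, angle) in enumerate(zip(script, roll)):
    final = queue.push_and_decide(label)
    out = spatial_update(state, final, np.array([0.0, 0.0, angle]))
    emitted = debounce(previous, final)
    note = []
    if emitted:
        note.append("EMIT " + final)
    if out is not None and out.discrete_state != "neutral":
        note.append(f"discrete state: {out.discrete_state} ({out.delta_deg:+.0f} deg)")
    print(f"{i:2d}  predicted {label:9s} -> final {final:9s} {' | '.join(note)}")
    if final != "pending":
        previous = final

# Expected behaviour: one EMIT when Fist first becomes confident, an
# 'Unknown' stretch during the noisy patch (no emission), one EMIT for
# Wave Out, and a 'lateral' discrete state once the roll passes +10 deg.
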