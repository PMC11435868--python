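import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmgkit import (
    PENDING,
    UNKNOWN,
    GestureProfile,
    PredictionQueue,
    SpatialState,
    build_frames,
    debounce,
    generate_session,
    spatial_update,
    stream_decisions,
    wrap_angle,
)
from conftest import noiseless_spec


def feed(queue, labels):
    return [queue.push_and_decide(lab) for lab in labels]


def test_unanimous_queue_emits_its_label():
    q = PredictionQueue()
    decisions = feed(q, ["Fist"] * 10)
    assert decisions[:9] == [PENDING] * 9
    assert decisions[9] == "Fist"


def test_seven_of_ten_is_too_random():
    q = PredictionQueue()
    assert feed(q, ["Fist"] * 7 + ["Pinch"] * 3)[-1] == UNKNOWN


def test_eight_of_ten_emits_the_mode():
    q = PredictionQueue()
    assert feed(q, ["Fist"] * 8 + ["Pinch"] * 2)[-1] == "Fist"


def test_hold_last_confident_bridges_unknown_periods():
    q = PredictionQueue(hold_last_confident=True)
    feed(q, ["Fist"] * 10)
    # dilute the buffer below 75% confidence
    decisions = feed(q, ["Pinch", "Wave In", "Pinch"])
    assert decisions[-1] == "Fist"
    q2 = PredictionQueue(hold_last_confident=False)
    feed(q2, ["Fist"] * 10)
    assert feed(q2, ["Pinch", "Wave In", "Pinch"])[-1] == UNKNOWN


def test_queue_slides_and_eventually_tracks_constant_input():
    q = PredictionQueue()
    feed(q, ["Fist"] * 10)
    decisions = feed(q, ["Wave In"] * 30)
    assert decisions[-1] == "Wave In"
    # one decision per pushed prediction once warmed up: rate never exceeds input
    assert len(decisions) == 30


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=10, max_size=60))
def test_queue_decision_is_mode_or_unknown(labels):
    q = PredictionQueue()
    for lab in labels[:9]:
        assert q.push_and_decide(lab) == PENDING
    buffer = list(labels[:9])
    for lab in labels[9:]:
        buffer.append(lab)
        window = buffer[-10:]
        decision = q.push_and_decide(lab)
        counts = {w: window.count(w) for w in set(window)}
        top = max(counts.values())
        if top >= 8:  # ceil(0.75 * 10)
            assert counts.get(decision) == top
        else:
            assert decision == UNKNOWN


@pytest.mark.parametrize("prev,cur,expected", [
    ("Fist", "Fist", False),
    (None, "Fist", True),
    ("Fist", UNKNOWN, False),
    ("Fist", "Pinch", True),
    (UNKNOWN, UNKNOWN, False),
    ("Fist", PENDING, False),
])
def test_debounce_contract(prev, cur, expected):
    assert debounce(prev, cur) is expected


def test_debounce_emits_once_per_state_change_on_scripted_stream():
    script = ["Fist"] * 12 + [UNKNOWN] * 3 + ["Fist"] * 5 + ["Pinch"] * 4
    previous = None
    emissions = []
    for cur in script:
        if debounce(previous, cur):
            emissions.append(cur)
        previous = cur
    assert emissions == ["Fist", "Fist", "Pinch"]


def test_spatial_onset_latches_setpoint_with_zero_output():
    state = SpatialState(default_axis="yaw")
    out = spatial_update(state, "Fist", np.array([30.0, 0.0, 0.0]))
    assert out.delta_deg == 0.0
    assert out.value == 0.0
    again = spatial_update(state, "Fist", np.array([30.0, 0.0, 0.0]))
    assert again.value == 0.0


def test_discrete_mode_thresholds():
    state = SpatialState(default_axis="roll", mode="discrete", gain=1.0,
                         threshold_deg=10.0)
    spatial_update(state, "Fist", np.array([0.0, 0.0, 0.0]))
    lateral = spatial_update(state, "Fist", np.array([0.0, 0.0, 20.0]))
    assert lateral.discrete_state == "lateral"
    medial = spatial_update(state, "Fist", np.array([0.0, 0.0, -20.0]))
    assert medial.discrete_state == "medial"
    neutral = spatial_update(state, "Fist", np.array([0.0, 0.0, 5.0]))
    assert neutral.discrete_state == "neutral"


def test_wraparound_uses_shortest_arc():
    state = SpatialState(default_axis="yaw")
    spatial_update(state, "Fist", np.array([170.0, 0.0, 0.0]))
    out = spatial_update(state, "Fist", np.array([-170.0, 0.0, 0.0]))
    assert out.delta_deg == pytest.approx(20.0)
    assert abs(out.delta_deg) < 340.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(-1000, 1000))
def test_wrap_angle_range_and_identity(d):
    wrapped = wrap_angle(d)
    assert -180.0 <= wrapped < 180.0
    assert (wrapped - d) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
           (wrapped - d) % 360.0 == pytest.approx(360.0, abs=1e-6)


def test_no_gesture_means_no_lock_on():
    state = SpatialState(default_axis="roll")
    assert spatial_update(state, UNKNOWN, np.array([0.0, 0.0, 50.0])) is None
    assert spatial_update(state, PENDING, np.array([0.0, 0.0, 50.0])) is None
    assert state.active is None and state.setpoint is None


def test_proportional_output_exactly_linear_in_sweep():
    """Noiseless sweep: controller output is linear in the angle, residual 0."""
    state = SpatialState(default_axis="roll", mode="repeat_rate", gain=2.0)
    angles = np.linspace(0.0, 90.0, 181)
    outputs = []
    for a in angles:
        out = spatial_update(state, "Wave Out", np.array([0.0, 0.0, a]))
        outputs.append(out.value)
    coeffs = np.polyfit(angles, outputs, 1)
    residual = np.max(np.abs(np.polyval(coeffs, angles) - outputs))
    assert residual <= 1e-9
    assert coeffs[0] == pytest.approx(2.0)


def test_index_increment_mode_steps():
    state = SpatialState(default_axis="roll", mode="index_increment",
                         gain=1.0, step_deg=10.0)
    spatial_update(state, "Fist", np.array([0.0, 0.0, 0.0]))
    for angle, expected in [(5.0, 0), (12.0, 1), (25.0, 2), (-1.0, -1)]:
        out = spatial_update(state, "Fist", np.array([0.0, 0.0, angle]))
        assert out.code_index == expected


def test_spatial_requires_euler():
    state = SpatialState()
    with pytest.raises(ValueError):
        spatial_update(state, "Fist", None)


def test_quasi_dynamic_classifies_like_its_static_counterpart():
    """Orientation sweeps never touch the features: frames are identical."""
    static = GestureProfile("Fist", (4.0, 1.0, 2.5, 3.0, 1.5), onset_ramp_s=0.0)
    sweeping = dataclasses.replace(static, euler_sweep=("roll", 0.0, 60.0))
    spec_a = noiseless_spec(gestures=(static,), n_trials=1)
    spec_b = noiseless_spec(gestures=(sweeping,), n_trials=1)
    (sa,) = generate_session(spec_a)
    (sb,) = generate_session(spec_b)
    fa = build_frames(sa)
    fb = build_frames(sb)
    for a, b in zip(fa, fb):
        np.testing.assert_array_equal(a.values, b.values)


def test_stream_decisions_toggles_spatial_seamlessly():
    events = [(0.1 * i, "Fist", np.array([0.0, 0.0, float(i)])) for i in range(20)]
    plain = list(stream_decisions(iter(events)))
    augmented = list(stream_decisions(iter(events), spatial=SpatialState()))
    assert [d for _, d, _ in plain] == [d for _, d, _ in augmented]
    assert all(o is None for _, _, o in plain)
    assert any(o is not None for _, _, o in augmented)
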