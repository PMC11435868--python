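"""Post-processing: prediction voting, debouncing and spatial augmentation.

The classifier emits roughly ten window-level predictions per second.
Three layers turn that stream into stable device commands:

1. **Prediction queue** — a rolling buffer (default capacity 10).  Once
   full, the modal label becomes the final prediction *if* it fills at
   least a confidence fraction θ (default 75 %) of the buffer; otherwise
   the predictions are deemed too random and the decision is ``Unknown``
   (optionally replaced by the last confident gesture, useful when a
   fatigued user slackens a held gesture).  Until the buffer first fills,
   the decision is ``pending`` rather than a guess.  The buffer slides by
   one after each decision.

2. **Debouncing** — a command is emitted only when the final decision
   *changes* to a real gesture; repeats of the same gesture and
   ``Unknown`` periods transmit nothing.

3. **Spatial augmentation** — orientation never enters featurisation or
   classification (a quasi-dynamic gesture classifies exactly like its
   static counterpart).  Instead, when a gesture becomes active, the
   current Euler triplet is latched as the *setpoint*; while the gesture
   is held, the controller output is ``gain`` times the shortest signed
   angular difference between the current and setpoint angle on the
   gesture's configured axis.  With no active gesture the device is not
   locked on and orientation does nothing.  The proportional output can
   drive a repeat rate (codes/second), an incremental code index, or a
   discrete three-way state.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

UNKNOWN = "Unknown"
PENDING = "pending"

AXES = {"yaw": 0, "pitch": 1, "roll": 2}


class PredictionQueue:
    """Rolling mode-vote buffer over streaming window predictions."""

    def __init__(
        self,
        capacity: int = 10,
        confidence: float = 0.75,
        hold_last_confident: bool = False,
    ) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if not 0 < confidence <= 1:
            raise ValueError("confidence must be in (0, 1]")
        self.capacity = capacity
        self.confidence = confidence
        self.hold_last_confident = hold_last_confident
        self._buffer: deque[str] = deque(maxlen=capacity)
        self.last_confident: Optional[str] = None

    def push_and_decide(self, label: str) -> str:
        """Push one prediction; return the final decision.

        ``pending`` while warming up; afterwards the modal label when its
        count reaches ``confidence * capacity``, else ``Unknown`` (or the
        last confident gesture when ``hold_last_confident`` is set).
        """
        self._buffer.append(label)
        if len(self._buffer) < self.capacity:
            return PENDING
        counts = Counter(self._buffer)
        # deterministic mode: highest count, alphabetical tie-break
        mode, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if count / self.capacity >= self.confidence:
            self.last_confident = mode
            return mode
        if self.hold_last_confident and self.last_confident is not None:
            return self.last_confident
        return UNKNOWN

    def reset(self) -> None:
        self._buffer.clear()
        self.last_confident = None


def is_gesture(decision: Optional[str]) -> bool:
    return decision is not None and decision not in (UNKNOWN, PENDING)


def debounce(previous: Optional[str], current: Optional[str]) -> bool:
    """Emit only on a state change to a real gesture.

    Repeats of the same gesture, ``Unknown`` and warm-up decisions never
    transmit.
    """
    return is_gesture(current) and current != previous


def wrap_angle(delta_deg: float) -> float:
    """Shortest signed arc equivalent of an angle difference, in [-180, 180)."""
    return float((delta_deg + 180.0) % 360.0 - 180.0)


@dataclass
class ControllerOutput:
    """Proportional-control output for one held gesture at one instant."""

    gesture: str
    axis: str
    delta_deg: float            # shortest signed angle from the setpoint
    value: float                # gain * delta_deg
    mode: str
    repeat_hz: Optional[float] = None
    code_index: Optional[int] = None
    discrete_state: Optional[str] = None


@dataclass
class SpatialState:
    """Configuration and latched state for spatial augmentation.

    ``axis_for`` maps each gesture to the single anatomical axis
    considered while that gesture is held (default ``roll`` — rolling
    motions keep the IR transmitter's line of sight steadier than pitch
    or yaw).  ``mode`` selects how the proportional value is consumed:

    * ``repeat_rate`` — codes per second, ``max(0, value) * rate_scale``;
    * ``index_increment`` — ``floor(value / step_deg)`` selects a stored
      code index;
    * ``discrete`` — three-way state: ``lateral`` above ``+threshold_deg``,
      ``medial`` below ``-threshold_deg``, else ``neutral``.
    """

    axis_for: dict[str, str] = field(default_factory=dict)
    default_axis: str = "roll"
    gain: float = 1.0
    mode: str = "discrete"
    step_deg: float = 10.0
    threshold_deg: float = 10.0
    rate_scale: float = 0.1  # codes/s per unit of proportional output

    active: Optional[str] = None
    setpoint: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("repeat_rate", "index_increment", "discrete"):
            raise ValueError(f"unknown spatial mode {self.mode!r}")
        for axis in list(self.axis_for.values()) + [self.default_axis]:
            if axis not in AXES:
                raise ValueError(f"unknown axis {axis!r}")

    def axis_of(self, gesture: str) -> str:
        return self.axis_for.get(gesture, self.default_axis)


def spatial_update(
    state: SpatialState,
    decision: Optional[str],
    euler: Optional[np.ndarray],
) -> Optional[ControllerOutput]:
    """Advance the spatial controller by one decision step.

    On gesture onset the setpoint orientation is latched and the output is
    zero.  While the gesture is held, the output is proportional to the
    shortest signed angular difference from the setpoint on the gesture's
    configured axis.  On ``Unknown``/``pending``/no gesture the state is
    released and ``None`` is returned — orientation does nothing when no
    gesture is locked on.
    """
    if not is_gesture(decision):
        state.active = None
        state.setpoint = None
        return None
    if euler is None:
        raise ValueError("spatial mode requires Euler orientation data")
    euler = np.asarray(euler, dtype=float)
    if euler.shape != (3,):
        raise ValueError("euler must be a (yaw, pitch, roll) triplet")

    if decision != state.active:
        state.active = decision
        state.setpoint = euler.copy()

    axis = state.axis_of(decision)
    idx = AXES[axis]
    delta = wrap_angle(euler[idx] - state.setpoint[idx])
    value = state.gain * delta
    out = ControllerOutput(
        gesture=decision, axis=axis, delta_deg=delta, value=value, mode=state.mode
    )
    if state.mode == "repeat_rate":
        out.repeat_hz = max(0.0, value) * state.rate_scale
    elif state.mode == "index_increment":
        out.code_index = int(np.floor(value / state.step_deg))
    else:  # discrete
        if value > state.threshold_deg:
            out.discrete_state = "lateral"
        elif value < -state.threshold_deg:
            out.discrete_state = "medial"
        else:
            out.discrete_state = "neutral"
    return out


def stream_decisions(
    events: Iterable[tuple[float, str, Optional[np.ndarray]]],
    queue: Optional[PredictionQueue] = None,
    spatial: Optional[SpatialState] = None,
) -> Iterator[tuple[float, str, Optional[ControllerOutput]]]:
    """Run the post-processing chain over a prediction stream.

    ``events`` yields ``(timestamp, window_prediction, euler_or_None)``;
    the generator yields ``(timestamp, final_decision, controller_output)``.
    Passing ``spatial=None`` disables augmentation (the toggle is
    seamless: the decision path is identical either way).
    """
    queue = queue or PredictionQueue()
    for t, label, euler in events:
        decision = queue.push_and_decide(label)
        output = None
        if spatial is not None:
            output = spatial_update(spatial, decision, euler)
        yield t, decision, output
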