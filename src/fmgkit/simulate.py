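"""Synthetic pFMG armband session generator.

A pneumatic force-myography (pFMG) armband carries five soft
pressure-sensitive chambers wrapped around the upper forearm.  Holding a
static hand gesture deforms the chambers and shifts each chamber's internal
pressure to a gesture-specific plateau.  This module emulates that signal:
per-gesture chamber offsets (relative to the resting baseline), a sigmoid
onset ramp from rest to the held plateau, a per-trial execution offset
(users re-seat the gesture slightly on every repetition), slow linear
drift, additive sensor noise, and — for quasi-dynamic gestures — a slow
Euler-angle sweep about one anatomical axis recorded by an on-board IMU.

All pressures are *relative*: the resting baseline is subtracted at
acquisition time, so a stream at rest sits at zero on every channel.

Everything is reproducible from ``SessionSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

N_CHAMBERS = 5

EULER_AXES = ("yaw", "pitch", "roll")

#: Default sampling period of the armband's pressure sensors (seconds).
DEFAULT_SAMPLING_PERIOD = 0.00135  # 740 Hz

#: Default samples per gesture recording (~2.7 s at 740 Hz).
DEFAULT_SAMPLES = 2000


@dataclass(frozen=True)
class GestureProfile:
    """Ground-truth signal parameters for one static gesture.

    Parameters
    ----------
    label:
        Gesture name (e.g. ``"Fist"``).
    chamber_means:
        Relative-pressure plateau of each of the five chambers while the
        gesture is held (arbitrary kPa-equivalent units, rest = 0).
    onset_ramp_s:
        Duration of the sigmoid ramp from rest to the held plateau, in
        seconds.  Recordings default to ``0`` — a training recording
        captures an already-established hold, as in the standard
        acquisition protocol where the user forms the gesture before the
        2.7 s capture begins.  Non-zero ramps model gesture formation in
        online streams.
    euler_sweep:
        Optional ``(axis, start_deg, end_deg)`` describing a slow linear
        orientation sweep over the recording (a quasi-dynamic gesture).
        ``axis`` is one of ``"yaw"``, ``"pitch"``, ``"roll"``.
    """

    label: str
    chamber_means: tuple[float, ...]
    onset_ramp_s: float = 0.0
    euler_sweep: Optional[tuple[str, float, float]] = None

    def __post_init__(self) -> None:
        if len(self.chamber_means) != N_CHAMBERS:
            raise ValueError(
                f"{self.label}: expected {N_CHAMBERS} chamber means, "
                f"got {len(self.chamber_means)}"
            )
        if self.onset_ramp_s < 0:
            raise ValueError("onset_ramp_s must be >= 0")
        if self.euler_sweep is not None:
            axis, start, end = self.euler_sweep
            if axis not in EULER_AXES:
                raise ValueError(f"unknown Euler axis {axis!r}")
            for angle in (start, end):
                if not -180.0 <= angle <= 180.0:
                    raise ValueError("sweep angles must lie in [-180, 180]")


def default_gestures() -> list[GestureProfile]:
    """The five benchmark gestures with invented chamber plateaus.

    The paper-style characterisation plots show stable plateaus but print
    no numeric pressures, so these values are honest inventions chosen to
    mimic the qualitative structure of a real recording: chamber 1
    separates Fist from Spread Fingers strongly, while chamber 2 (over the
    pronator teres, unused by all five gestures) stays near one common
    level for every gesture and is therefore nearly uninformative.
    """
    return [
        GestureProfile("Fist", (4.0, 1.0, 2.5, 3.0, 1.5)),
        GestureProfile("Pinch", (1.5, 1.1, 1.0, 2.0, 3.0)),
        GestureProfile("Spread Fingers", (0.8, 1.0, 3.5, 1.2, 2.2)),
        GestureProfile("Wave In", (2.5, 0.9, 1.5, 0.8, 0.9)),
        GestureProfile("Wave Out", (1.2, 1.05, 3.0, 2.6, 0.6)),
    ]


@dataclass(frozen=True)
class SessionSpec:
    """Everything needed to generate one recording session.

    Defaults mirror the acquisition protocol the toolkit assumes: 2000
    samples per gesture recording at a 1.35 ms sampling period (≈2.7 s),
    three trials per session, five gestures.  Noise and variability scales
    are small relative to the inter-gesture plateau separation: the
    per-sample noise default (0.01 units) reflects the noise floor of
    amplified board-mount pressure sensors (~0.05 % of full scale)
    against kPa-scale gesture deltas, while trial-to-trial variability is
    dominated by the re-execution offset (0.05 units).
    """

    gestures: tuple[GestureProfile, ...] = field(
        default_factory=lambda: tuple(default_gestures())
    )
    n_trials: int = 3
    samples_per_recording: int = DEFAULT_SAMPLES
    sampling_period: float = DEFAULT_SAMPLING_PERIOD
    noise_sd: float = 0.01
    trial_offset_sd: float = 0.05
    drift_slope: float = 0.01  # units per second
    include_euler: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.samples_per_recording < 2:
            raise ValueError("samples_per_recording must be >= 2")
        if self.noise_sd < 0 or self.trial_offset_sd < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def recording_duration_s(self) -> float:
        return self.samples_per_recording * self.sampling_period


@dataclass
class SampleStream:
    """One gesture recording: time-aligned 5-channel relative pressures.

    ``euler`` (degrees, columns yaw/pitch/roll) is present when the
    session was generated with IMU support, otherwise ``None``.
    """

    label: str
    session_id: int
    trial_id: int
    pressures: np.ndarray  # (n_samples, 5)
    sampling_period: float
    euler: Optional[np.ndarray] = None  # (n_samples, 3)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2 or self.pressures.shape[1] != N_CHAMBERS:
            raise ValueError("pressures must be (n_samples, 5)")
        if not np.isfinite(self.pressures).all():
            raise ValueError("pressures contain non-finite values")
        if self.euler is not None:
            self.euler = np.asarray(self.euler, dtype=float)
            if self.euler.shape != (self.n_samples, 3):
                raise ValueError("euler must be (n_samples, 3)")
            if not np.isfinite(self.euler).all():
                raise ValueError("euler contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.pressures.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_period

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_period

    @property
    def trial_key(self) -> tuple[int, int]:
        """(session, trial) pair identifying the trial this stream belongs to."""
        return (self.session_id, self.trial_id)


def _onset_ramp(t: np.ndarray, ramp_s: float) -> np.ndarray:
    """Sigmoid rise from ~0 at t=0 to ~1 at t=ramp_s; 1 everywhere if ramp_s=0."""
    if ramp_s <= 0:
        return np.ones_like(t)
    # expit(±4) ≈ 0.018 / 0.982 at the ramp endpoints
    return expit((t - ramp_s / 2.0) / (ramp_s / 8.0))


def generate_session(spec: SessionSpec, session_id: int = 0) -> list[SampleStream]:
    """Generate ``spec.n_trials`` trials of every gesture in ``spec``.

    Each stream is built as::

        pressure = ramp(t) * chamber_mean
                 + trial_offset            (one draw per trial & chamber)
                 + drift_slope * t
                 + noise_sd * N(0, 1)      (i.i.d. per sample)

    The Euler trace is constant at zero unless the gesture declares a
    sweep, in which case the configured axis is interpolated linearly from
    the start to the end angle over the recording (the user rotates the
    arm slowly while holding the gesture).

    Returns the streams ordered trial-major (trial 0 gestures, trial 1
    gestures, ...).  Identical ``(spec, session_id)`` always produces
    bit-identical output.
    """
    rng = np.random.default_rng([int(spec.seed), int(session_id)])
    n = spec.samples_per_recording
    t = np.arange(n) * spec.sampling_period
    streams: list[SampleStream] = []
    for trial in range(spec.n_trials):
        for profile in spec.gestures:
            ramp = _onset_ramp(t, profile.onset_ramp_s)
            means = np.asarray(profile.chamber_means, dtype=float)
            offsets = spec.trial_offset_sd * rng.standard_normal(N_CHAMBERS)
            noise = spec.noise_sd * rng.standard_normal((n, N_CHAMBERS))
            pressures = (
                ramp[:, None] * means[None, :]
                + offsets[None, :]
                + (spec.drift_slope * t)[:, None]
                + noise
            )
            euler = None
            if spec.include_euler:
                euler = np.zeros((n, 3))
                if profile.euler_sweep is not None:
                    axis, start, end = profile.euler_sweep
                    euler[:, EULER_AXES.index(axis)] = np.linspace(start, end, n)
            streams.append(
                SampleStream(
                    label=profile.label,
                    session_id=session_id,
                    trial_id=trial,
                    pressures=pressures,
                    sampling_period=spec.sampling_period,
                    euler=euler,
                )
            )
    return streams


def generate_sessions(spec: SessionSpec, n_sessions: int) -> list[SampleStream]:
    """Generate several sessions; session ``i`` uses the seed pair (seed, i)."""
    streams: list[SampleStream] = []
    for sid in range(n_sessions):
        streams.extend(generate_session(spec, session_id=sid))
    return streams


def make_redundant_chamber(spec: SessionSpec, chamber_index: int) -> SessionSpec:
    """Return a spec where one chamber is uninformative across all gestures.

    The designated chamber's plateau is replaced, in every gesture, by the
    across-gesture mean of that chamber — emulating a chamber that sits
    over a muscle none of the gestures engages.  Useful for checking that
    feature selection and classification degrade gracefully.
    """
    if not 0 <= chamber_index < N_CHAMBERS:
        raise IndexError(f"chamber_index must be in 0..{N_CHAMBERS - 1}")
    common = float(
        np.mean([g.chamber_means[chamber_index] for g in spec.gestures])
    )
    new_gestures = []
    for g in spec.gestures:
        means = list(g.chamber_means)
        means[chamber_index] = common
        new_gestures.append(replace(g, chamber_means=tuple(means)))
    return replace(spec, gestures=tuple(new_gestures))


# ---------------------------------------------------------------------------
# Delimited-text persistence: <prefix>.csv holds one row per sample
# (t, p1..p5[, yaw, pitch, roll]); <prefix>.json is the sidecar manifest.

_PRESSURE_COLS = [f"p{i + 1}" for i in range(N_CHAMBERS)]


def write_stream(stream: SampleStream, prefix: str | Path) -> tuple[Path, Path]:
    """Write a stream as CSV + JSON manifest; lossless at full float precision."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    manifest_path = prefix.with_suffix(".json")
    cols = ["t"] + _PRESSURE_COLS
    data = [stream.times, *stream.pressures.T]
    if stream.euler is not None:
        cols += list(EULER_AXES)
        data += list(stream.euler.T)
    matrix = np.column_stack(data)
    header = ",".join(cols)
    np.savetxt(csv_path, matrix, delimiter=",", header=header, comments="",
               fmt="%.17g")
    manifest = {
        "label": stream.label,
        "session_id": stream.session_id,
        "trial_id": stream.trial_id,
        "sampling_period": stream.sampling_period,
        "n_samples": stream.n_samples,
        "has_euler": stream.euler is not None,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return csv_path, manifest_path


def read_stream(prefix: str | Path) -> SampleStream:
    """Read a stream written by :func:`write_stream`."""
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    matrix = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1,
                        ndmin=2)
    pressures = matrix[:, 1 : 1 + N_CHAMBERS]
    euler = matrix[:, 1 + N_CHAMBERS :] if manifest["has_euler"] else None
    return SampleStream(
        label=manifest["label"],
        session_id=manifest["session_id"],
        trial_id=manifest["trial_id"],
        pressures=pressures,
        sampling_period=manifest["sampling_period"],
        euler=euler,
    )


def write_session(streams: Sequence[SampleStream], directory: str | Path) -> list[Path]:
    """Write a collection of streams into ``directory`` with systematic names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefixes = []
    for s in streams:
        safe = s.label.replace(" ", "_")
        prefix = directory / f"s{s.session_id}_t{s.trial_id}_{safe}"
        write_stream(s, prefix)
        prefixes.append(prefix)
    return prefixes


def read_session(directory: str | Path) -> list[SampleStream]:
    """Read every stream under ``directory`` (sorted by filename)."""
    directory = Path(directory)
    return [read_stream(p.with_suffix("")) for p in sorted(directory.glob("*.json"))]
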