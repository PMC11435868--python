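"""Sliding-window segmentation and signal-integrity checks.

Gesture recordings are segmented into overlapping fixed-length windows
(default: 100 samples ≈ 135 ms with a 50-sample stride, i.e. 50 % overlap)
before featurisation.  Two integrity checks accompany segmentation:

* :func:`spike_alert` flags abnormal pressure spikes — a relative change
  above a threshold (default 20 %) within less than a configurable horizon
  (default 1 s).  Clean static-gesture recordings raise no alerts.
* :func:`validity_filter` applies a band-pass filter and raises a flag
  when a significant fraction of (detrended) signal energy lies outside
  the pass band.  The classification path consumes unfiltered data; the
  filter exists purely as a fail-safe diagnostic, since stable pFMG
  plateaus need no rectification or smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .simulate import N_CHAMBERS, SampleStream


@dataclass(frozen=True)
class WindowingConfig:
    """Window length and stride, both in samples."""

    length: int = 100
    stride: int = 50

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if not 1 <= self.stride <= self.length:
            raise ValueError("stride must satisfy 1 <= stride <= length")


@dataclass
class Window:
    """One window of a parent stream (rows = samples, cols = chambers)."""

    pressures: np.ndarray  # (length, 5)
    start: int
    label: str
    session_id: int
    trial_id: int


def n_windows(n_samples: int, cfg: WindowingConfig) -> int:
    """Number of full windows: floor((N - W) / S) + 1.

    For the canonical 50 %-overlap setup (W = 2S, S | N) this reduces to
    N/S - 1, e.g. 2000 samples → 39 windows.
    """
    if n_samples < cfg.length:
        return 0
    return (n_samples - cfg.length) // cfg.stride + 1


def segment(stream: SampleStream, cfg: WindowingConfig | None = None) -> list[Window]:
    """Cut a stream into overlapping windows starting at 0, S, 2S, ...

    Trailing samples that do not fill a whole window are dropped.  Raises
    ``ValueError`` when the stream is shorter than one window.
    """
    cfg = cfg or WindowingConfig()
    count = n_windows(stream.n_samples, cfg)
    if count == 0:
        raise ValueError(
            f"stream of {stream.n_samples} samples is shorter than one "
            f"window ({cfg.length})"
        )
    windows = []
    for i in range(count):
        start = i * cfg.stride
        windows.append(
            Window(
                pressures=stream.pressures[start : start + cfg.length].copy(),
                start=start,
                label=stream.label,
                session_id=stream.session_id,
                trial_id=stream.trial_id,
            )
        )
    return windows


def spike_alert(
    stream: SampleStream,
    rel_threshold: float = 0.20,
    horizon_s: float = 1.0,
    denominator_floor: float | None = None,
) -> list[tuple[int, int]]:
    """Flag abrupt relative pressure changes.

    A sample ``t`` on channel ``c`` is flagged when, for some lag
    ``tau`` shorter than ``horizon_s``,

        |p(t) - p(t - tau)| / max(|p(t - tau)|, floor)  >  rel_threshold.

    ``floor`` guards against division blow-ups near zero relative pressure
    and defaults to 1 % of the stream's overall dynamic range.

    Returns ``(channel, sample_index)`` pairs, sorted; empty on clean
    static-gesture data.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be positive")
    if horizon_s <= 0:
        raise ValueError("horizon_s must be positive")
    p = stream.pressures
    n = p.shape[0]
    if denominator_floor is None:
        dyn = float(p.max() - p.min())
        denominator_floor = max(0.01 * dyn, 1e-12)
    max_lag = int(np.ceil(horizon_s / stream.sampling_period))  # tau*dt < horizon
    flagged = np.zeros_like(p, dtype=bool)
    for tau in range(1, min(max_lag, n)):
        prev = p[:-tau]
        cur = p[tau:]
        ratio = np.abs(cur - prev) / np.maximum(np.abs(prev), denominator_floor)
        flagged[tau:] |= ratio > rel_threshold
    chans, idx = np.nonzero(flagged.T)
    return sorted(zip(chans.tolist(), idx.tolist()))


def validity_filter(
    stream: SampleStream,
    order: int = 5,
    band: tuple[float, float] = (0.5, 330.0),
    energy_fraction: float = 0.25,
) -> tuple[SampleStream, bool]:
    """Band-pass the stream and flag excessive out-of-band energy.

    ``band`` is (low, high) in Hz and must satisfy 0 < low < high < fs/2.
    Each channel is detrended (mean removed) and its spectrum inspected;
    the alert flag is raised when any channel carries more than
    ``energy_fraction`` of its total energy outside the pass band.  The
    returned stream holds the zero-phase filtered pressures for
    inspection — the classification path keeps using the raw stream.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    fs = 1.0 / stream.sampling_period
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band must satisfy 0 < lo < hi < fs/2 = {fs / 2:.1f} Hz")

    p = stream.pressures
    # Linear detrend: the plateau offset and slow sensor drift are expected
    # signal content, not out-of-band contamination.
    centred = sps.detrend(p, axis=0, type="linear")
    freqs = np.fft.rfftfreq(p.shape[0], d=stream.sampling_period)
    spectrum = np.fft.rfft(centred, axis=0)
    power = np.abs(spectrum) ** 2
    total = power.sum(axis=0)
    out_of_band = power[(freqs < lo) | (freqs > hi)].sum(axis=0)
    # Detrend residuals of near-constant channels are pure rounding noise;
    # don't let their "spectrum" raise the flag.
    negligible = total <= 1e-18 * np.maximum((p ** 2).sum(axis=0), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(negligible, 0.0, out_of_band / np.maximum(total, 1e-300))
    flag = bool((frac > energy_fraction).any())

    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, p, axis=0)
    filtered_stream = SampleStream(
        label=stream.label,
        session_id=stream.session_id,
        trial_id=stream.trial_id,
        pressures=filtered,
        sampling_period=stream.sampling_period,
        euler=None if stream.euler is None else stream.euler.copy(),
    )
    return filtered_stream, flag
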