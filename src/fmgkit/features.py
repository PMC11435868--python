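"""Time-domain featurisation of windowed pFMG signals.

Each window of a single channel is reduced to a vector of classical
time-domain myoelectric features.  The candidate registry has 17 members:

======  ==========================================================
IAV     integrated absolute value, sum |x_i|
WL      waveform length, sum |x_{i+1} - x_i|
AAC     average amplitude change, WL / W
SSC     slope sign changes above a deadband threshold
SSI     simple square integral, sum x_i^2
RMS     root mean square, sqrt(SSI / W)
VAR     sample variance, sum (x_i - mean)^2 / (W - 1)
MAV     mean absolute value, IAV / W
MAV1    MAV with 0.5 weights outside the central half of the window
MAV2    MAV with linear tapered weights outside the central half
ZC      zero crossings whose amplitude step exceeds a threshold
TM3-5   absolute 3rd/4th/5th temporal moments, |mean(x^k)|
WAMP    Willison amplitude: steps |x_{i+1} - x_i| above a threshold
DASDV   difference absolute standard deviation, sqrt(sum dx^2/(W-1))
MYOP    myopulse percentage rate: fraction of |x_i| above a threshold
======  ==========================================================

A *featured window* is this vector for one channel; a *featured frame*
concatenates the five channels' featured windows in fixed channel order
and is the classifier's input row (5 x 17 = 85 values for the full set).

Thresholded features (ZC, SSC, WAMP, MYOP) default their deadband to 1 %
of the window's per-channel dynamic range when no explicit value is set.

SSC uses the deadband on the neighbouring amplitude steps (a slope
reversal counts only when at least one adjacent step exceeds the
threshold), which keeps the count invariant when window and threshold are
scaled together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import Window, WindowingConfig, segment
from .simulate import N_CHAMBERS, SampleStream

#: Canonical ordering of the 17-member candidate registry.
ALL_FEATURES: tuple[str, ...] = (
    "IAV", "WL", "AAC", "SSC", "SSI", "RMS", "VAR", "MAV", "MAV1", "MAV2",
    "ZC", "TM3", "TM4", "TM5", "WAMP", "DASDV", "MYOP",
)

#: Accepted aliases: "MAV3" is occasionally used for plain MAV as the third
#: member of the MAV family.
FEATURE_ALIASES = {"MAV3": "MAV"}


@dataclass(frozen=True)
class FeatureSet:
    """An ordered selection of feature names plus deadband thresholds.

    ``None`` thresholds resolve, per window and channel, to 1 % of that
    window's dynamic range.
    """

    names: tuple[str, ...] = ALL_FEATURES
    eps_zc: Optional[float] = None
    eps_ssc: Optional[float] = None
    eps_wamp: Optional[float] = None
    eps_myop: Optional[float] = None

    def __post_init__(self) -> None:
        resolved = tuple(FEATURE_ALIASES.get(n, n) for n in self.names)
        object.__setattr__(self, "names", resolved)
        unknown = set(resolved) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if len(set(resolved)) != len(resolved):
            raise ValueError("feature names must be unique")
        for eps in (self.eps_zc, self.eps_ssc, self.eps_wamp, self.eps_myop):
            if eps is not None and eps < 0:
                raise ValueError("thresholds must be >= 0")

    def __len__(self) -> int:
        return len(self.names)


def _default_eps(x: np.ndarray) -> float:
    return 0.01 * float(x.max() - x.min())


def _mav1_weights(w: int) -> np.ndarray:
    i = np.arange(1, w + 1)
    weights = np.full(w, 0.5)
    weights[(i >= 0.25 * w) & (i <= 0.75 * w)] = 1.0
    return weights


def _mav2_weights(w: int) -> np.ndarray:
    i = np.arange(1, w + 1, dtype=float)
    weights = np.ones(w)
    low = i < 0.25 * w
    high = i > 0.75 * w
    weights[low] = 4.0 * i[low] / w
    weights[high] = 4.0 * (w - i[high]) / w
    return weights


def compute_features(x: Sequence[float] | np.ndarray, fs: FeatureSet | None = None) -> np.ndarray:
    """Featurise one channel of one window.

    Returns the feature values aligned to ``fs.names``.  Deterministic;
    raises on empty or non-finite input and on windows shorter than 2.
    """
    fs = fs or FeatureSet()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D sequence of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("window contains non-finite samples")
    w = x.size
    dx = np.diff(x)
    abs_x = np.abs(x)

    eps_zc = fs.eps_zc if fs.eps_zc is not None else _default_eps(x)
    eps_ssc = fs.eps_ssc if fs.eps_ssc is not None else _default_eps(x)
    eps_wamp = fs.eps_wamp if fs.eps_wamp is not None else _default_eps(x)
    eps_myop = fs.eps_myop if fs.eps_myop is not None else _default_eps(x)

    values: dict[str, float] = {}
    need = set(fs.names)

    iav = float(abs_x.sum())
    wl = float(np.abs(dx).sum())
    ssi = float((x ** 2).sum())
    if "IAV" in need:
        values["IAV"] = iav
    if "WL" in need:
        values["WL"] = wl
    if "AAC" in need:
        values["AAC"] = wl / w
    if "SSC" in need:
        d1 = x[1:-1] - x[:-2]   # x_i - x_{i-1}
        d2 = x[1:-1] - x[2:]    # x_i - x_{i+1}
        reversal = d1 * d2 > 0
        big_enough = np.maximum(np.abs(d1), np.abs(d2)) >= max(eps_ssc, 1e-300)
        values["SSC"] = float(np.count_nonzero(reversal & big_enough))
    if "SSI" in need:
        values["SSI"] = ssi
    if "RMS" in need:
        values["RMS"] = float(np.sqrt(ssi / w))
    if "VAR" in need:
        values["VAR"] = float(((x - x.mean()) ** 2).sum() / (w - 1))
    if "MAV" in need:
        values["MAV"] = iav / w
    if "MAV1" in need:
        values["MAV1"] = float((_mav1_weights(w) * abs_x).sum() / w)
    if "MAV2" in need:
        values["MAV2"] = float((_mav2_weights(w) * abs_x).sum() / w)
    if "ZC" in need:
        sign_change = x[:-1] * x[1:] < 0
        values["ZC"] = float(
            np.count_nonzero(sign_change & (np.abs(dx) >= eps_zc))
        )
    for k, name in ((3, "TM3"), (4, "TM4"), (5, "TM5")):
        if name in need:
            values[name] = float(abs(np.mean(x ** k)))
    if "WAMP" in need:
        values["WAMP"] = float(np.count_nonzero(np.abs(dx) > eps_wamp))
    if "DASDV" in need:
        values["DASDV"] = float(np.sqrt((dx ** 2).sum() / (w - 1)))
    if "MYOP" in need:
        values["MYOP"] = float(np.count_nonzero(abs_x > eps_myop)) / w

    return np.array([values[name] for name in fs.names])


@dataclass
class FeaturedFrame:
    """Concatenated per-channel feature vectors for one window."""

    label: str
    session_id: int
    trial_id: int
    window_start: int
    values: np.ndarray  # (n_channels * n_features,)
    feature_names: tuple[str, ...]  # e.g. ("ch1_RMS", ..., "ch5_MYOP")

    @property
    def trial_key(self) -> tuple[int, int]:
        return (self.session_id, self.trial_id)


def frame_column_names(fs: FeatureSet, n_channels: int = N_CHAMBERS) -> tuple[str, ...]:
    return tuple(
        f"ch{c + 1}_{name}" for c in range(n_channels) for name in fs.names
    )


def featurise_window(window: Window, fs: FeatureSet | None = None) -> FeaturedFrame:
    """Build one featured frame from one multi-channel window."""
    fs = fs or FeatureSet()
    vectors = [
        compute_features(window.pressures[:, c], fs)
        for c in range(window.pressures.shape[1])
    ]
    return FeaturedFrame(
        label=window.label,
        session_id=window.session_id,
        trial_id=window.trial_id,
        window_start=window.start,
        values=np.concatenate(vectors),
        feature_names=frame_column_names(fs, window.pressures.shape[1]),
    )


def build_frames(
    stream: SampleStream,
    cfg: WindowingConfig | None = None,
    fs: FeatureSet | None = None,
) -> list[FeaturedFrame]:
    """Segment a stream and featurise every window, in order."""
    cfg = cfg or WindowingConfig()
    fs = fs or FeatureSet()
    return [featurise_window(w, fs) for w in segment(stream, cfg)]


def build_all_frames(
    streams: Sequence[SampleStream],
    cfg: WindowingConfig | None = None,
    fs: FeatureSet | None = None,
) -> list[FeaturedFrame]:
    frames: list[FeaturedFrame] = []
    for s in streams:
        frames.extend(build_frames(s, cfg, fs))
    return frames


# ---------------------------------------------------------------------------
# Tabular persistence

META_COLS = ("label", "session", "trial", "window_start")


def frames_to_dataframe(frames: Sequence[FeaturedFrame]) -> pd.DataFrame:
    """Wide table: label, session, trial, window_start, ch<k>_<feature>..."""
    if not frames:
        raise ValueError("no frames")
    names = frames[0].feature_names
    for f in frames:
        if f.feature_names != names:
            raise ValueError("frames have inconsistent feature layouts")
    meta = pd.DataFrame(
        {
            "label": [f.label for f in frames],
            "session": [f.session_id for f in frames],
            "trial": [f.trial_id for f in frames],
            "window_start": [f.window_start for f in frames],
        }
    )
    data = pd.DataFrame(np.vstack([f.values for f in frames]), columns=list(names))
    return pd.concat([meta, data], axis=1)


def dataframe_to_frames(df: pd.DataFrame) -> list[FeaturedFrame]:
    feature_cols = tuple(c for c in df.columns if c not in META_COLS)
    frames = []
    for _, row in df.iterrows():
        frames.append(
            FeaturedFrame(
                label=row["label"],
                session_id=int(row["session"]),
                trial_id=int(row["trial"]),
                window_start=int(row["window_start"]),
                values=row[list(feature_cols)].to_numpy(dtype=float),
                feature_names=feature_cols,
            )
        )
    return frames


def write_frames(frames: Sequence[FeaturedFrame], path: str | Path) -> Path:
    path = Path(path)
    frames_to_dataframe(frames).to_csv(path, index=False)
    return path


def read_frames(path: str | Path) -> list[FeaturedFrame]:
    return dataframe_to_frames(pd.read_csv(path))
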