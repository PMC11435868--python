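"""Filter-based feature selection via coefficients of variation.

A feature is useful when it is *stable within* a gesture (low intra-gesture
coefficient of variation across that gesture's frames) and *different
between* gestures (high inter-gesture coefficient of variation across the
per-gesture means).  Features are ranked on these two criteria — channel-
averaged, with the inter-gesture criterion weighted more heavily — and the
top fraction (default half) is retained.

This is a pure filter approach: no classifier is consulted at any point,
which avoids wrapper-style overfitting and keeps selection fast.

An earlier-style hard mask (intra CV < 10 % AND inter CV > 20 %) is kept
as a diagnostic view only (:func:`threshold_mask`); it tends to accept a
feature on one chamber and reject it on another, which is why ranking is
the production path.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureSet, FeaturedFrame, frames_to_dataframe

_COL_RE = re.compile(r"^ch(\d+)_(.+)$")


def _cv(values: np.ndarray, eps: float) -> tuple[float, bool]:
    """Sample-sd coefficient of variation; flags near-zero-mean instability."""
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    unstable = abs(mean) < eps
    return sd / max(abs(mean), eps), unstable


@dataclass
class VarianceReport:
    """Per-(feature, channel, gesture) CV table plus per-feature scores.

    Attributes
    ----------
    table:
        Tidy frame with columns feature, channel, gesture, intra_mean,
        intra_cv, unstable.
    inter:
        Tidy frame with columns feature, channel, inter_cv, unstable.
    per_feature:
        One row per feature: channel-averaged ``intra_score`` (lower is
        better) and ``inter_score`` (higher is better).
    """

    table: pd.DataFrame
    inter: pd.DataFrame
    per_feature: pd.DataFrame
    eps: float

    @property
    def features(self) -> list[str]:
        return self.per_feature["feature"].tolist()

    def write(self, path: str | Path) -> Path:
        """Serialise the tidy per-(feature, channel, gesture) table as CSV."""
        path = Path(path)
        merged = self.table.merge(self.inter, on=["feature", "channel"],
                                  suffixes=("", "_inter"))
        merged.to_csv(path, index=False)
        return path


def variance_report(frames: Sequence[FeaturedFrame], eps: float = 1e-12) -> VarianceReport:
    """Compute intra- and inter-gesture coefficients of variation.

    For feature ``f`` on channel ``c``:

    * ``intra_cv(g, f, c)`` = sd / |mean| of the feature over gesture
      ``g``'s frames (sample sd, ddof=1);
    * ``inter_cv(f, c)`` = sd / |mean| across gestures of those
      per-gesture means.

    Means whose magnitude falls below ``eps`` are flagged ``unstable`` and
    the CV denominator is floored at ``eps``.  Requires at least two
    gestures with at least two frames each.
    """
    # Canonical row order makes the report exactly invariant to the order
    # frames are supplied in (float summation is order-sensitive).
    df = (
        frames_to_dataframe(frames)
        .sort_values(["label", "session", "trial", "window_start"], kind="mergesort")
        .reset_index(drop=True)
    )
    gestures = sorted(df["label"].unique())
    if len(gestures) < 2:
        raise ValueError("variance report needs at least 2 gestures")
    counts = df.groupby("label").size()
    if (counts < 2).any():
        raise ValueError("every gesture needs at least 2 frames")

    feature_cols = [c for c in df.columns if _COL_RE.match(c)]
    rows = []
    inter_rows = []
    for col in feature_cols:
        m = _COL_RE.match(col)
        channel, feat = int(m.group(1)), m.group(2)
        intra_means = []
        for g in gestures:
            vals = df.loc[df["label"] == g, col].to_numpy(dtype=float)
            cv, unstable = _cv(vals, eps)
            mean = float(vals.mean())
            intra_means.append(mean)
            rows.append(
                {
                    "feature": feat,
                    "channel": channel,
                    "gesture": g,
                    "intra_mean": mean,
                    "intra_cv": cv,
                    "unstable": unstable,
                }
            )
        inter_cv, unstable = _cv(np.asarray(intra_means), eps)
        inter_rows.append(
            {
                "feature": feat,
                "channel": channel,
                "inter_cv": inter_cv,
                "unstable": unstable,
            }
        )

    table = pd.DataFrame(rows)
    inter = pd.DataFrame(inter_rows)
    per_feature = (
        table.groupby("feature")["intra_cv"].mean().rename("intra_score").reset_index()
        .merge(
            inter.groupby("feature")["inter_cv"].mean().rename("inter_score").reset_index(),
            on="feature",
        )
        .sort_values("feature")
        .reset_index(drop=True)
    )
    return VarianceReport(table=table, inter=inter, per_feature=per_feature, eps=eps)


def rank_features(
    report: VarianceReport,
    w_inter: float = 2.0,
    w_intra: float = 1.0,
) -> list[str]:
    """Rank features by composite rank score; best first.

    Each feature receives a rank on the inter-gesture score (descending:
    rank 1 = most separated) and on the intra-gesture score (ascending:
    rank 1 = most stable).  The composite is
    ``w_inter * inter_rank + w_intra * intra_rank`` with ``w_inter >
    w_intra`` by default, encoding that separation between gestures
    outweighs within-gesture stability in borderline cases.  Ties break
    alphabetically, so the order is a deterministic total order.
    """
    if w_inter <= 0 or w_intra < 0:
        raise ValueError("weights must be positive (w_inter) / non-negative (w_intra)")
    pf = report.per_feature.copy()
    if pf.empty:
        raise ValueError("empty variance report")
    pf["inter_rank"] = pf["inter_score"].rank(ascending=False, method="min")
    pf["intra_rank"] = pf["intra_score"].rank(ascending=True, method="min")
    pf["composite"] = w_inter * pf["inter_rank"] + w_intra * pf["intra_rank"]
    pf = pf.sort_values(["composite", "feature"], kind="mergesort")
    return pf["feature"].tolist()


def select_top(
    ranked: Sequence[str],
    fraction: float = 0.5,
    rounding: str = "floor",
    **featureset_kwargs,
) -> FeatureSet:
    """Keep the top ``fraction`` of a ranked feature list.

    Odd counts are resolved by ``rounding`` ("floor", the default, or
    "ceil"); at least one feature is always kept.  14 features at 0.5 →
    7 kept; 17 at 0.5 → 8 under the floor convention.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rounder = math.floor if rounding == "floor" else math.ceil
    if rounding not in ("floor", "ceil"):
        raise ValueError("rounding must be 'floor' or 'ceil'")
    k = max(1, rounder(fraction * len(ranked)))
    return FeatureSet(names=tuple(ranked[:k]), **featureset_kwargs)


def threshold_mask(
    report: VarianceReport,
    intra_max: float = 0.10,
    inter_min: float = 0.20,
) -> pd.DataFrame:
    """Diagnostic hard-threshold view: per (feature, channel), does the
    feature pass intra CV < ``intra_max`` on every gesture AND inter CV >
    ``inter_min``?  Kept for inspection only; the production path ranks.
    """
    intra_ok = (
        report.table.groupby(["feature", "channel"])["intra_cv"]
        .max()
        .lt(intra_max)
        .rename("intra_ok")
    )
    inter_ok = (
        report.inter.set_index(["feature", "channel"])["inter_cv"]
        .gt(inter_min)
        .rename("inter_ok")
    )
    mask = pd.concat([intra_ok, inter_ok], axis=1).reset_index()
    mask["passes"] = mask["intra_ok"] & mask["inter_ok"]
    return mask
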