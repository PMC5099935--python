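"""Sliding-window mean / average-slope features with leakage-safe scaling.

Per trial, channel and chromophore, two features are computed inside each
3 s window: the sample mean and the ordinary-least-squares slope of value
against time (units per second).  Windows are anchored by their *right end*
on integer seconds from -5 to 25 s relative to task onset (31 windows for
the default grid, stepping 1 s), which requires epoch support back to -8 s.

Feature z-scoring is fitted on training data only and applied to held-out
data with the training statistics, so cross-validation stays leakage-free.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import ConfigurationError, EpochSet

__all__ = [
    "WindowGrid",
    "FeatureMatrix",
    "Normalization",
    "window_anchors",
    "extract",
    "extract_all",
    "normalize_fit",
    "normalize_apply",
]


@dataclass(frozen=True)
class WindowGrid:
    """Right-end anchors of sliding windows."""

    anchors: Tuple[float, ...]
    width: float = 3.0
    step: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors)
        if a.size == 0:
            raise ConfigurationError("grid has no anchors")
        if a.size > 1 and not np.allclose(np.diff(a), self.step):
            raise ConfigurationError("anchors must be evenly spaced by step")

    @property
    def n_windows(self) -> int:
        return len(self.anchors)

    def window(self, anchor: float) -> Tuple[float, float]:
        return (anchor - self.width, anchor)


def window_anchors(
    analysis_range: Tuple[float, float] = (-5.0, 25.0),
    width: float = 3.0,
    step: float = 1.0,
) -> WindowGrid:
    """Anchors at every ``step`` across ``analysis_range`` inclusive.

    The default configuration (range [-5, 25] s, 3 s windows, 1 s step)
    yields 31 anchors; each window [anchor - width, anchor] needs epoch
    support from ``analysis_range[0] - width`` onward.
    """
    lo, hi = analysis_range
    if hi < lo:
        raise ConfigurationError("analysis range must satisfy lo <= hi")
    if width <= 0 or step <= 0:
        raise ConfigurationError("width and step must be positive")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    anchors = tuple(lo + i * step for i in range(n))
    return WindowGrid(anchors=anchors, width=width, step=step)


@dataclass
class FeatureMatrix:
    """Trials x (channels x stats x chromophores) feature block at one anchor."""

    X: np.ndarray                     # (n_trials, n_features)
    labels: np.ndarray
    anchor: float
    columns: Tuple[str, ...]          # "<ch>_<chromo>_<mean|slope>"

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _ols_slope(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """OLS slope of y against t along the last axis (closed form)."""
    tc = t - t.mean()
    denom = np.sum(tc**2)
    return (y * tc).sum(axis=-1) / denom


def extract(
    epochs: EpochSet,
    anchor: float,
    width: float = 3.0,
    chromophores: Sequence[str] = ("hbo", "hbr"),
    slope_kind: str = "ols",
) -> FeatureMatrix:
    """Mean and slope features in the window [anchor - width, anchor].

    ``slope_kind`` selects the within-window slope estimator: ``"ols"``
    (default) or ``"endpoint"`` (last minus first sample over the window
    span).
    """
    if len(chromophores) == 0:
        raise ConfigurationError("at least one chromophore is required")
    lo, hi = anchor - width, anchor
    if lo < epochs.window[0] - 1e-9 or hi > epochs.window[1] + 1e-9:
        raise ConfigurationError(
            f"window [{lo}, {hi}] s outside epoch window {epochs.window}"
        )
    t = epochs.times
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    tw = t[mask]
    blocks: List[np.ndarray] = []
    names: List[str] = []
    for chromo in chromophores:
        data = epochs.chromophore(chromo)[:, :, mask]   # (trials, ch, samples)
        mean = data.mean(axis=2)
        if slope_kind == "ols":
            slope = _ols_slope(data, tw)
        elif slope_kind == "endpoint":
            slope = (data[:, :, -1] - data[:, :, 0]) / (tw[-1] - tw[0])
        else:
            raise ConfigurationError(f"unknown slope_kind {slope_kind!r}")
        blocks.extend([mean, slope])
        for stat in ("mean", "slope"):
            names.extend(f"{ch}_{chromo}_{stat}" for ch in epochs.channel_names)
    # column order: [chromo x stat] blocks of channels
    X = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        X=X, labels=epochs.labels.copy(), anchor=anchor, columns=tuple(names)
    )


def extract_all(
    epochs: EpochSet,
    grid: Optional[WindowGrid] = None,
    chromophores: Sequence[str] = ("hbo", "hbr"),
    slope_kind: str = "ols",
) -> Dict[float, FeatureMatrix]:
    """One FeatureMatrix per grid anchor (31 for the default grid)."""
    grid = grid or window_anchors()
    return {
        a: extract(epochs, a, grid.width, chromophores, slope_kind)
        for a in grid.anchors
    }


@dataclass
class Normalization:
    """Per-column centering/scaling statistics fitted on training data."""

    center: np.ndarray
    scale: np.ndarray
    constant_columns: np.ndarray      # flags: zero-variance columns (scale 1)


def normalize_fit(train: FeatureMatrix) -> Normalization:
    """Fit zero-mean / unit-variance column statistics on training rows."""
    if train.X.shape[0] < 2:
        raise ConfigurationError("need >= 2 training rows to fit normalization")
    center = train.X.mean(axis=0)
    scale = train.X.std(axis=0, ddof=1)
    constant = scale == 0
    scale = np.where(constant, 1.0, scale)
    return Normalization(center=center, scale=scale, constant_columns=constant)


def normalize_apply(norm: Normalization, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply training statistics to any feature matrix (train or held-out)."""
    X = (fm.X - norm.center) / norm.scale
    return FeatureMatrix(X=X, labels=fm.labels, anchor=fm.anchor, columns=fm.columns)
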