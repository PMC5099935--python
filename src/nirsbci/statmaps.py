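"""Point-biserial separability maps over channels x time.

The separability of the two task conditions at a channel and time point is
measured with the point-biserial correlation

    r = sqrt(N1*N2) / (N1 + N2) * (E[x1] - E[x2]) / sigma,

where x1/x2 are the trial values of class 1 (MA) and class 2 (BL), N1/N2
the trial counts and sigma the population standard deviation over the
pooled trials of both classes.  With this convention r is identical to the
Pearson correlation between the trial values and a binary class indicator,
and perfectly separated equal-sized classes give exactly |r| = 1.

p-values follow from the exact t transform t = r*sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom; multiple comparisons are Bonferroni-corrected and
maps are rendered as signed log10 p (positive where MA > BL).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .containers import BL, MA, ConfigurationError, EpochSet

__all__ = [
    "SeparabilityMap",
    "rvalue",
    "rvalue_map",
    "r_to_p",
    "bonferroni",
    "signed_logp",
    "period_map",
]

_TINY_P = np.finfo(float).tiny


def rvalue(x1: np.ndarray, x2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Point-biserial r between class-1 and class-2 samples.

    Broadcasts over leading axes: ``x1``/``x2`` have trials on axis 0 and r
    is computed element-wise over the remaining axes.  Returns ``(r,
    degenerate)`` where ``degenerate`` flags points with zero pooled
    variance (r set to 0 there).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("both classes must be non-empty")
    pooled = np.concatenate([x1, x2], axis=0)
    sigma = pooled.std(axis=0)        # population (N-denominator) SD
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    degenerate = sigma == 0
    safe = np.where(degenerate, 1.0, sigma)
    r = np.sqrt(n1 * n2) / (n1 + n2) * diff / safe
    r = np.where(degenerate, 0.0, r)
    return np.clip(r, -1.0, 1.0), degenerate


def r_to_p(r: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided p-value from r via the exact t transform on n1+n2-2 dof."""
    if n1 + n2 <= 2:
        raise ConfigurationError("need n1 + n2 > 2 for the t transform")
    r = np.asarray(r, dtype=float)
    dof = n1 + n2 - 2
    saturated = np.abs(r) >= 1.0
    rs = np.where(saturated, 0.0, r)
    t = rs * np.sqrt(dof / (1.0 - rs**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    p = np.where(saturated, _TINY_P, p)
    return np.minimum(p, 1.0)


def bonferroni(p: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m*p); m defaults to p.size."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


@dataclass
class SeparabilityMap:
    """r, p and signed log10(p) per channel x time (or channel x period)."""

    r: np.ndarray                     # (channels, points) in [-1, 1]
    p: np.ndarray                     # raw two-sided p
    p_adj: np.ndarray                 # Bonferroni-adjusted
    times: np.ndarray                 # seconds (or period midpoints)
    channel_names: Tuple[str, ...]
    n1: int
    n2: int
    m_comparisons: int
    degenerate: np.ndarray = field(default_factory=lambda: np.array([]))
    class_order: Tuple[str, str] = (MA, BL)

    @property
    def signed_logp(self) -> np.ndarray:
        return signed_logp(self.r, self.p_adj)


def signed_logp(r: np.ndarray, p_adj: np.ndarray) -> np.ndarray:
    """sign(r) * -log10(p_adj); positive where MA responds more than BL."""
    return np.sign(r) * (-np.log10(np.maximum(p_adj, _TINY_P)))


def rvalue_map(
    epochs: EpochSet,
    chromophore: str,
    m_comparisons: Optional[int] = None,
) -> SeparabilityMap:
    """Point-biserial map over channels x time samples for one chromophore.

    Bonferroni multiplicity defaults to the number of time samples (the
    display axis of a per-channel time course); pass ``m_comparisons`` to
    correct over a different family.
    """
    ma_mask, bl_mask = epochs.class_masks()
    n1, n2 = int(ma_mask.sum()), int(bl_mask.sum())
    if n1 == 0 or n2 == 0:
        raise ConfigurationError("both MA and BL trials are required")
    data = epochs.chromophore(chromophore)    # (trials, channels, samples)
    r, degenerate = rvalue(data[ma_mask], data[bl_mask])
    p = r_to_p(r, n1, n2)
    m = m_comparisons if m_comparisons is not None else r.shape[1]
    p_adj = bonferroni(p, m)
    return SeparabilityMap(
        r=r, p=p, p_adj=p_adj,
        times=epochs.times,
        channel_names=epochs.channel_names,
        n1=n1, n2=n2, m_comparisons=m, degenerate=degenerate,
    )


def period_map(
    epochs: EpochSet,
    chromophore: str,
    periods: Sequence[Tuple[float, float]],
    m_comparisons: Optional[int] = None,
) -> SeparabilityMap:
    """Topography-style map: r over per-trial means within time periods.

    For each period the trial values are averaged over the period's samples
    first, then r is computed per channel; multiplicity defaults to
    channels x periods.
    """
    ma_mask, bl_mask = epochs.class_masks()
    n1, n2 = int(ma_mask.sum()), int(bl_mask.sum())
    if n1 == 0 or n2 == 0:
        raise ConfigurationError("both MA and BL trials are required")
    t = epochs.times
    data = epochs.chromophore(chromophore)
    cols_r, cols_deg = [], []
    for lo, hi in periods:
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ConfigurationError(f"period [{lo}, {hi}] s has no samples")
        vals = data[:, :, mask].mean(axis=2)
        r, deg = rvalue(vals[ma_mask], vals[bl_mask])
        cols_r.append(r)
        cols_deg.append(deg)
    r = np.stack(cols_r, axis=1)
    degenerate = np.stack(cols_deg, axis=1)
    p = r_to_p(r, n1, n2)
    m = m_comparisons if m_comparisons is not None else r.size
    p_adj = bonferroni(p, m)
    mids = np.array([(lo + hi) / 2 for lo, hi in periods])
    return SeparabilityMap(
        r=r, p=p, p_adj=p_adj, times=mids,
        channel_names=epochs.channel_names,
        n1=n1, n2=n2, m_comparisons=m, degenerate=degenerate,
    )
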