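"""Geometric RSE / RMI-violation measures on CDFs, mean-RT RSE, Vincentising.

Effect sizes are horizontal (time-axis) quantile differences in ms, matching
how the field reports distributional facilitation: the redundant signals
effect (RSE) is the mean quantile gap between the faster-signal reference
(the pointwise maximum of the unisensory CDFs) and the multisensory CDF, and
the race-model-inequality (RMI) violation is the mean positive quantile gap
relative to Miller's bound min(1, F_A + F_V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ig import DistCurve

__all__ = [
    "QuantileSet",
    "DEFAULT_PROBS",
    "TEN_QUANTILES",
    "rse_geometric",
    "rmi_violation_geometric",
    "rse_mean",
    "vincent_average",
]

DEFAULT_PROBS = (np.arange(200) + 0.5) / 200
"""200 evenly spaced probability levels for whole-distribution measures."""

TEN_QUANTILES = (np.arange(10) + 0.5) / 10
"""The ten quantile levels (i - 0.5)/10 of block-Vincentised ten-trial data."""


@dataclass(frozen=True)
class QuantileSet:
    """Empirical quantile summary: probabilities and the matching RTs (ms)."""

    probs: np.ndarray
    rts: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        rts = np.asarray(self.rts, dtype=float)
        if probs.shape != rts.shape or probs.ndim != 1:
            raise ValueError("probs and rts must be 1-d arrays of equal length")
        if np.any(probs <= 0) or np.any(probs >= 1):
            raise ValueError("quantile probabilities must lie in (0, 1)")
        if np.any(np.diff(probs) <= 0):
            raise ValueError("quantile probabilities must be strictly increasing")
        if np.any(np.diff(rts) < 0):
            raise ValueError("quantile RTs must be non-decreasing")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "rts", rts)


def _on_common_grid(f_a: DistCurve, f_v: DistCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = f_a.t
    if f_v.t.shape == t.shape and np.array_equal(f_v.t, t):
        return t, f_a.cdf, f_v.cdf
    fv = np.interp(t, f_v.t, f_v.cdf)
    return t, f_a.cdf, fv


def rse_geometric(f_av: DistCurve, f_a: DistCurve, f_v: DistCurve, probs=DEFAULT_PROBS) -> float:
    """Geometric RSE in ms: mean quantile gap to the faster-signal reference.

    The reference is the pointwise max of the unisensory CDFs, whose quantile
    at level p is the smaller of the two unisensory quantiles.  Negative if
    the multisensory condition is slower than the faster signal.
    """
    probs = np.asarray(probs, dtype=float)
    q_ref = np.minimum(f_a.quantile(probs), f_v.quantile(probs))
    return float(np.mean(q_ref - f_av.quantile(probs)))


def rmi_violation_geometric(
    f_av: DistCurve, f_a: DistCurve, f_v: DistCurve, probs=DEFAULT_PROBS
) -> float:
    """Geometric RMI violation in ms: mean positive quantile gap to the bound.

    The bound CDF is min(1, F_A + F_V); only quantile levels where the
    multisensory curve beats the bound contribute, so the measure is >= 0 and
    exactly 0 for probability summation.
    """
    probs = np.asarray(probs, dtype=float)
    t, fa, fv = _on_common_grid(f_a, f_v)
    bound = DistCurve(t, np.minimum(1.0, fa + fv))
    d = bound.quantile(probs) - f_av.quantile(probs)
    return float(np.mean(np.maximum(0.0, d)))


def _mean_rt(x, probs=DEFAULT_PROBS) -> float:
    """Mean RT of a sample or of a DistCurve discretised at ``probs``."""
    if isinstance(x, DistCurve):
        return float(np.mean(x.quantile(np.asarray(probs, dtype=float))))
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty RT sample")
    return float(np.mean(x))


def rse_mean(rt_av, rt_a, rt_v, soa: float = 0.0, probs=DEFAULT_PROBS) -> float:
    """Mean-RT RSE in ms with SOA-adjusted unisensory references.

    The lagging modality's onset delay is added to its unisensory RTs before
    taking the faster reference (positive soa = auditory lags, so the soa is
    added to the auditory mean; negative soa adds |soa| to the visual mean).
    """
    mean_av = _mean_rt(rt_av, probs)
    mean_a = _mean_rt(rt_a, probs) + max(soa, 0.0)
    mean_v = _mean_rt(rt_v, probs) + max(-soa, 0.0)
    return min(mean_a, mean_v) - mean_av


def vincent_average(blocks) -> QuantileSet:
    """Vincentise equal-length RT blocks: rank-order each, average rank-wise.

    Returns the quantile set at levels (i - 0.5)/n for block length n.
    """
    arrays = [np.sort(np.asarray(b, dtype=float)) for b in blocks]
    if not arrays:
        raise ValueError("no blocks given")
    n = arrays[0].size
    if n == 0 or any(a.size != n for a in arrays):
        raise ValueError("all blocks must have the same non-zero length")
    rts = np.mean(np.vstack(arrays), axis=0)
    probs = (np.arange(n) + 0.5) / n
    return QuantileSet(probs, rts)
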