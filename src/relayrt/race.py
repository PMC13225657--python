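"""Single-stage benchmark models of the redundant signals effect.

Raab's race model explains multisensory speed-up by statistical facilitation:
with independent parallel channels, the response is triggered by the faster,
so ``F_AV = F_A + F_V - F_A*F_V`` (probability summation).  Miller's race
model inequality caps any race account at ``F_AV <= F_A + F_V``; empirical
exceedance of that bound falsifies single-stage independent races.  The
shifted race translates the race prediction earlier by a free constant delta,
an ad-hoc one-parameter account of such violations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .ig import DistCurve, IGParams, ig_cdf, ig_pdf, ig_survival

__all__ = [
    "ModalityPair",
    "default_grid",
    "race_cdf",
    "rmi_bound",
    "stage_race",
    "shifted_race_cdf",
]

GRID_STEP = 0.25
"""Default time-grid spacing in ms: fine enough to resolve the fast tail
where RMI violations live while keeping convolutions cheap."""


@dataclass(frozen=True)
class ModalityPair:
    """Unisensory IG parameters for the auditory and visual channels."""

    aud: IGParams
    vis: IGParams


def default_grid(params: Iterable[IGParams], step: float = GRID_STEP, pad: float = 0.0) -> np.ndarray:
    """Uniform grid from 0 to the slowest channel's mean + 8 SD (+ pad), in ms."""
    params = list(params)
    if not params:
        raise ValueError("need at least one parameter set to size the grid")
    tmax = max(p.mu + 8.0 * p.sd for p in params) + pad
    return np.arange(0.0, tmax + step, step)


def _check_probs(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must be probabilities in [0, 1]")
    return arr


def race_cdf(fa, fv):
    """Probability summation for two independent racers: fa + fv - fa*fv."""
    fa = _check_probs(fa, "fa")
    fv = _check_probs(fv, "fv")
    return fa + fv - fa * fv


def rmi_bound(fa, fv):
    """Miller's bound min(1, fa + fv) on any race-architecture CDF."""
    fa = _check_probs(fa, "fa")
    fv = _check_probs(fv, "fv")
    return np.minimum(1.0, fa + fv)


def stage_race(stage_a: Optional[IGParams], stage_v: Optional[IGParams], grid: np.ndarray) -> DistCurve:
    """CDF and PDF of the minimum of two independent IG stage times.

    ``F(t) = 1 - S_A(t) S_V(t)`` and ``f(t) = f_A S_V + f_V S_A``.  A ``None``
    stage is degenerate (zero duration or absent racer): the race collapses to
    the other modality's own distribution.  Both stages degenerate is a
    zero-duration stage altogether and is rejected here.
    """
    grid = np.asarray(grid, dtype=float)
    if stage_a is None and stage_v is None:
        raise ValueError("at least one racer must be non-degenerate")
    if stage_a is None:
        return DistCurve(grid, ig_cdf(grid, stage_v), ig_pdf(grid, stage_v))
    if stage_v is None:
        return DistCurve(grid, ig_cdf(grid, stage_a), ig_pdf(grid, stage_a))
    sa = ig_survival(grid, stage_a)
    sv = ig_survival(grid, stage_v)
    cdf = 1.0 - sa * sv
    pdf = ig_pdf(grid, stage_a) * sv + ig_pdf(grid, stage_v) * sa
    return DistCurve(grid, cdf, pdf)


def shifted_race_cdf(pair: ModalityPair, delta: float, grid: np.ndarray) -> DistCurve:
    """Race CDF evaluated at shifted times: ``1 - S_A(t+delta) S_V(t+delta)``.

    ``delta > 0`` translates the prediction toward faster responses.  The
    shift must keep every evaluated time non-negative.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] + delta < 0:
        raise ValueError(
            f"shift delta={delta} drives evaluation to negative times "
            f"(grid starts at {grid[0]})"
        )
    ts = grid + delta
    cdf = 1.0 - ig_survival(ts, pair.aud) * ig_survival(ts, pair.vis)
    pdf = ig_pdf(ts, pair.aud) * ig_survival(ts, pair.vis) + ig_pdf(ts, pair.vis) * ig_survival(
        ts, pair.aud
    )
    return DistCurve(grid, cdf, pdf)
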