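"""Inverse-Gaussian (Wald) distribution machinery and RT-share stage partitioning.

The inverse Gaussian with mean ``mu`` and shape ``lam`` (variance ``mu**3/lam``)
is the first-passage-time law of a drift-to-bound process and the standard
parametric model for positively skewed response-time distributions.  Its key
property for staged architectures is closure under addition when the ratio
``lam/mu**2`` is shared: a fitted unisensory RT distribution can therefore be
decomposed exactly into sequential latent stages.  A stage receiving an RT
share ``w`` of the total is distributed ``IG(mu*w, lam*w**2)`` — the stage
means and variances then add back to the parent's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats

__all__ = [
    "IGParams",
    "StagePartition",
    "DistCurve",
    "ig_pdf",
    "ig_cdf",
    "ig_survival",
    "ig_quantile",
    "ig_moments",
    "ig_sample",
    "partition",
    "recombine",
]


@dataclass(frozen=True)
class IGParams:
    """Inverse-Gaussian parameter pair: mean ``mu`` (ms) and shape ``lam`` (ms)."""

    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"IG mean mu must be positive and finite, got {self.mu}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"IG shape lam must be positive and finite, got {self.lam}")

    @property
    def sd(self) -> float:
        """Standard deviation sqrt(mu**3 / lam) in ms."""
        return float(np.sqrt(self.mu**3 / self.lam))

    def frozen(self) -> stats.rv_continuous:
        """The equivalent ``scipy.stats.invgauss`` frozen distribution."""
        return stats.invgauss(self.mu / self.lam, scale=self.lam)


@dataclass(frozen=True)
class StagePartition:
    """Normalised RT-share weights splitting one IG into sequential stages.

    ``weights[i]`` is the proportion of the total RT (mean and variance alike)
    attributed to stage ``i``; weights must be non-negative and sum to one.
    """

    weights: tuple

    def __init__(self, weights: Sequence[float]) -> None:
        w = tuple(float(x) for x in weights)
        if len(w) < 1:
            raise ValueError("partition needs at least one stage")
        if any(x < 0 for x in w):
            raise ValueError(f"negative RT share in {w}")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError(f"RT shares must sum to 1, got sum {sum(w)!r}")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def two_stage(cls, share: float) -> "StagePartition":
        """Two-stage partition with first-stage RT share ``share``."""
        return cls((share, 1.0 - share))

    @classmethod
    def equal(cls, n: int) -> "StagePartition":
        """``n`` stages of equal share 1/n."""
        return cls((1.0 / n,) * n)


@dataclass(frozen=True)
class DistCurve:
    """A distribution tabulated on a time grid: CDF values and optional PDF."""

    t: np.ndarray
    cdf: np.ndarray
    pdf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        cdf = np.asarray(self.cdf, dtype=float)
        if t.ndim != 1 or t.shape != cdf.shape:
            raise ValueError("t and cdf must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if cdf.min() < -1e-9 or cdf.max() > 1 + 1e-9:
            raise ValueError("cdf values must lie in [0, 1]")
        if np.any(np.diff(cdf) < -1e-9):
            raise ValueError("cdf must be non-decreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "cdf", np.clip(cdf, 0.0, 1.0))
        if self.pdf is not None:
            pdf = np.asarray(self.pdf, dtype=float)
            if pdf.shape != t.shape:
                raise ValueError("pdf must match the time grid")
            object.__setattr__(self, "pdf", pdf)

    def quantile(self, probs) -> np.ndarray:
        """Invert the tabulated CDF by linear interpolation.

        Raises a coverage error for probabilities the curve does not span.
        """
        probs = np.atleast_1d(np.asarray(probs, dtype=float))
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("quantile levels must lie in [0, 1]")
        top = self.cdf[-1]
        if np.any(probs > top + 1e-12):
            raise ValueError(
                f"curve reaches cdf {top:.6f} but quantile {probs.max():.6f} requested "
                "(grid does not cover the support)"
            )
        return np.interp(probs, self.cdf, self.t)


def _validate_t(t) -> np.ndarray:
    return np.asarray(t, dtype=float)


def ig_pdf(t, p: IGParams) -> np.ndarray:
    """IG density (1/ms); zero on t <= 0."""
    t = _validate_t(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.sqrt(p.lam / (2 * np.pi * tp**3)) * np.exp(
        -p.lam * (tp - p.mu) ** 2 / (2 * p.mu**2 * tp)
    )
    return out[0] if scalar else out


def ig_cdf(t, p: IGParams) -> np.ndarray:
    """IG cumulative distribution function."""
    t = _validate_t(t)
    return p.frozen().cdf(t)


def ig_survival(t, p: IGParams) -> np.ndarray:
    """IG survival function 1 - F(t)."""
    t = _validate_t(t)
    return p.frozen().sf(t)


def ig_quantile(q, p: IGParams) -> np.ndarray:
    """Inverse CDF by bracketed root finding (relative tolerance 1e-8).

    Robust at extreme quantiles; consistent with :func:`ig_cdf` by construction.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr <= 0) or np.any(q_arr >= 1):
        raise ValueError("quantile levels must lie strictly inside (0, 1)")
    frozen = p.frozen()

    def solve(qi: float) -> float:
        lo, hi = 1e-9, p.mu
        while frozen.cdf(hi) < qi:
            hi *= 2.0
        return optimize.brentq(lambda t: frozen.cdf(t) - qi, lo, hi, rtol=1e-10)

    out = np.array([solve(qi) for qi in q_arr])
    return out[0] if np.isscalar(q) or np.asarray(q).ndim == 0 else out


def ig_moments(p: IGParams) -> tuple[float, float]:
    """(mean, sd) in ms: mean = mu, sd = sqrt(mu**3/lam)."""
    return p.mu, p.sd


def ig_sample(p: IGParams, n: int, rng) -> np.ndarray:
    """Draw ``n`` IG variates with the Michael-Schucany-Haas transform.

    ``rng`` is a seed or a ``numpy.random.Generator`` passed by value; no
    global state is touched.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    y = rng.standard_normal(n) ** 2
    x = p.mu + (p.mu**2 * y) / (2 * p.lam) - (p.mu / (2 * p.lam)) * np.sqrt(
        4 * p.mu * p.lam * y + p.mu**2 * y**2
    )
    u = rng.uniform(size=n)
    accept = u <= p.mu / (p.mu + x)
    return np.where(accept, x, p.mu**2 / x)


def partition(p: IGParams, w: StagePartition) -> list[Optional[IGParams]]:
    """Split ``p`` into sequential stage parameters per the RT-share rule.

    Stage ``i`` is ``IG(mu*w_i, lam*w_i**2)``.  A zero-weight stage is a
    degenerate zero-duration stage and is returned as ``None`` (an explicit
    marker): with a zero first-stage share the relay reduces to the race model.
    """
    stages: list[Optional[IGParams]] = []
    for wi in w.weights:
        if wi == 0.0:
            stages.append(None)
        else:
            stages.append(IGParams(p.mu * wi, p.lam * wi**2))
    return stages


def recombine(stages: Sequence[Optional[IGParams]]) -> IGParams:
    """Sum of IG stages sharing a common lam/mu**2 ratio, as one IGParams.

    The IG family is closed under addition only when all components share the
    ratio ``lam/mu**2``; a mismatch (relative tolerance 1e-9) is rejected.
    """
    real = [s for s in stages if s is not None]
    if not real:
        raise ValueError("no non-degenerate stages to recombine")
    ratios = np.array([s.lam / s.mu**2 for s in real])
    c = ratios[0]
    if np.any(np.abs(ratios - c) > 1e-9 * c):
        raise ValueError(
            f"stages do not share a common lam/mu^2 ratio (got {ratios.tolist()}); "
            "IG additivity does not hold"
        )
    mu = sum(s.mu for s in real)
    return IGParams(mu, c * mu**2)
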