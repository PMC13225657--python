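"""The relay model: sequential races with cross-modal initiation.

The relay model decomposes each unisensory response time into sequential
IG-distributed stages via the RT-share partition.  In the multisensory
condition each stage is a race between modalities, and the winner of a stage
initiates the next stage in *both* modalities (cross-modal initiation).  The
total RT is the sum of the stage-race times,

    RT_AV = min(T_A1, T_V1) + min(T_A2, T_V2),

assuming independence between stages.  The multisensory CDF follows by
convolving the stage-1 race CDF with the stage-2 race PDF, and iteratively so
for more stages.  With a first-stage share of zero (or one) the model reduces
to the classical race model; between those limits it amplifies the redundant
signals effect and produces race-model-inequality violations.

For asynchronous onsets the lagging modality's stage-1 clock starts at its
own onset (lag tau), and if stage 2 is initiated before that onset the
lagging modality enters stage 2 with the residual lag:

    T_AV1 = min(T_L1, T_G1 + tau)
    T_AV2 = min(T_L2, T_G2 + max(0, tau - T_AV1))

(L = leading, G = lagging).  The analytic CDF splits into an early-initiation
part (stage 2 starts before the lagging onset) and a late-initiation part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ig import DistCurve, IGParams, StagePartition, ig_sample, ig_survival, partition
from .race import ModalityPair, default_grid, stage_race

__all__ = [
    "RelaySpec",
    "relay_cdf",
    "multistage_relay_cdf",
    "relay_soa_cdf",
    "relay_predict",
    "relay_simulate",
]

COVERAGE_CDF = 0.999


@dataclass(frozen=True)
class RelaySpec:
    """A relay-model configuration.

    soa: signed onset lag in ms; positive means the auditory signal lags the
    visual onset (and negative the reverse).  The partition (shared across
    modalities) must have a single stage for the classical race limit or two
    stages when soa != 0.
    """

    pair: ModalityPair
    partition: StagePartition
    soa: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.soa):
            raise ValueError("soa must be finite")
        if self.soa != 0.0 and len(self.partition) != 2:
            raise ValueError("asynchronous onsets are implemented for two-stage relays")

    @classmethod
    def two_stage(cls, pair: ModalityPair, share: float, soa: float = 0.0) -> "RelaySpec":
        return cls(pair, StagePartition.two_stage(share), soa)


def _stieltjes_conv(values: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Trapezoid Lebesgue-Stieltjes convolution on a shared uniform grid.

    ``int values(t - x) dM(x)`` where ``masses[j]`` is the measure of cell
    ``[t_j, t_{j+1})``.  Convolving with exact CDF increments rather than
    sampled densities preserves probability mass even when a stage
    distribution is much narrower than the grid step.
    """
    n = len(values)
    a = np.convolve(values, masses)[:n]
    return 0.5 * (a + np.concatenate(([0.0], a[:-1])))


def _cell_masses(cdf_vals: np.ndarray) -> np.ndarray:
    return np.diff(cdf_vals)


def _check_coverage(cdf: np.ndarray) -> None:
    if cdf[-1] < COVERAGE_CDF:
        raise ValueError(
            f"time grid too short: cdf reaches only {cdf[-1]:.4f} < {COVERAGE_CDF} at the end"
        )


def multistage_relay_cdf(pair: ModalityPair, parts: StagePartition, grid: np.ndarray) -> DistCurve:
    """Relay CDF for an N-stage partition by iterated convolution.

    The stage-1 race CDF is successively convolved with the distributions of
    the later stage races (Stieltjes form, using exact stage-race CDF
    increments, so narrow stages lose no mass).  Degenerate (zero-share)
    stages contribute a Dirac at zero and are skipped; a single effective
    stage is the classical race model.
    """
    grid = np.asarray(grid, dtype=float)
    stages_a = partition(pair.aud, parts)
    stages_v = partition(pair.vis, parts)
    live = [(a, v) for a, v in zip(stages_a, stages_v) if a is not None]
    if not live:
        raise ValueError("all stages are degenerate")
    cdf = stage_race(*live[0], grid).cdf
    for sa, sv in live[1:]:
        cdf_i = stage_race(sa, sv, grid).cdf
        cdf = np.clip(_stieltjes_conv(cdf, _cell_masses(cdf_i)), 0.0, 1.0)
        cdf = np.maximum.accumulate(cdf)
    _check_coverage(cdf)
    return DistCurve(grid, cdf)


def _auto_grid(spec: RelaySpec, step: float | None = None) -> np.ndarray:
    """Grid sized for the asynchronous case too: under a large lag the relay
    CDF tends to the leading unisensory CDF, which needs ~2 extra SDs beyond
    the default mu + 8 SD extent to reach coverage."""
    params = [spec.pair.aud, spec.pair.vis]
    pad = abs(spec.soa) + 2.0 * max(p.sd for p in params)
    kw = {} if step is None else {"step": step}
    return default_grid(params, pad=pad, **kw)


def relay_cdf(spec: RelaySpec, grid: np.ndarray | None = None) -> DistCurve:
    """Synchronous-onset relay CDF (dispatches to the SOA form when soa != 0)."""
    if grid is None:
        grid = _auto_grid(spec)
    if spec.soa != 0.0:
        return relay_soa_cdf(spec, grid)
    return multistage_relay_cdf(spec.pair, spec.partition, grid)


def _roles(spec: RelaySpec) -> tuple[IGParams, IGParams, float]:
    """(leading, lagging, tau>0) unisensory params per the sign convention."""
    if spec.soa > 0:  # auditory lags visual onset
        return spec.pair.vis, spec.pair.aud, spec.soa
    return spec.pair.aud, spec.pair.vis, -spec.soa


def relay_soa_cdf(spec: RelaySpec, grid: np.ndarray | None = None) -> DistCurve:
    """Two-stage relay CDF under an onset lag tau, t = 0 at the leading onset.

    F(t) = Phi_early(t) + Phi_late(t) with

      Phi_early(t) = int_0^min(t,tau) f_L1(u) [1 - S_L2(t-u) S_G2(t-tau)] du
      Phi_late(t)  = int_tau^t g(u) [1 - S_L2(t-u) S_G2(t-u)] du
      g(u) = f_L1(u) S_G1(u-tau) + f_G1(u-tau) S_L1(u)

    At tau = 0 this coincides with the synchronous relay; for lags beyond the
    leading modality's total RT it converges to the leading unisensory CDF.
    The split at u = tau uses half-open subintervals so nothing is counted
    twice.
    """
    if grid is None:
        grid = _auto_grid(spec)
    grid = np.asarray(grid, dtype=float)
    if spec.soa == 0.0:
        return multistage_relay_cdf(spec.pair, spec.partition, grid)
    dt = grid[1] - grid[0]
    lead, lag, tau = _roles(spec)
    w1, w2 = spec.partition.weights
    L1, L2 = partition(lead, spec.partition)
    G1, G2 = partition(lag, spec.partition)
    if L1 is None:
        # zero first-stage share: stage 2 starts at t = 0 for both, the
        # lagging modality carrying the full residual lag tau
        t_lag = np.maximum(grid - tau, 0.0)
        cdf = 1.0 - ig_survival(grid, L2) * np.where(
            grid > tau, ig_survival(t_lag, G2), 1.0
        )
        _check_coverage(cdf)
        return DistCurve(grid, cdf)

    t_lag = grid - tau  # lagging modality's own clock
    SL1 = ig_survival(grid, L1)
    FL1 = 1.0 - SL1
    SL2 = ig_survival(grid, L2)
    SG1_lag = np.where(t_lag > 0, ig_survival(np.maximum(t_lag, 0.0), G1), 1.0)
    SG2_lag = np.where(t_lag > 0, ig_survival(np.maximum(t_lag, 0.0), G2), 1.0)
    SG2 = ig_survival(grid, G2)

    # split the stage-1 completion-time measure at u = tau with half-open
    # cells; a cell straddling tau is apportioned linearly so nothing is
    # counted twice.  Below tau only the leading modality can finish, so the
    # lagged race CDF M(u) = 1 - S_L1(u) S_G1(u - tau) coincides with F_L1.
    frac_early = np.clip((tau - grid[:-1]) / dt, 0.0, 1.0)
    dm_L1 = _cell_masses(FL1)
    dm_early = dm_L1 * frac_early
    M = 1.0 - SL1 * SG1_lag
    dm_late = _cell_masses(M) * (1.0 - frac_early)

    # early initiation: stage 2 starts before the lagging onset, the lagging
    # modality enters with the residual lag tau - u rolled into S_G2(t - tau)
    conv_early = _stieltjes_conv(SL2, dm_early)
    FL1_cap = np.concatenate(([0.0], np.cumsum(dm_early)))
    phi_early = FL1_cap - SG2_lag * conv_early

    # late initiation: both signals present at u, plain stage-2 race
    G_mass = np.concatenate(([0.0], np.cumsum(dm_late)))
    h = SL2 * SG2
    phi_late = G_mass - _stieltjes_conv(h, dm_late)

    cdf = np.clip(phi_early + phi_late, 0.0, 1.0)
    cdf = np.maximum.accumulate(cdf)
    _check_coverage(cdf)
    return DistCurve(grid, cdf)


def relay_predict(spec: RelaySpec, grid: np.ndarray | None = None) -> DistCurve:
    """Unified entry point: race (1 stage), relay (N stages), with or without SOA."""
    return relay_cdf(spec, grid)


def relay_simulate(spec: RelaySpec, n: int, rng) -> np.ndarray:
    """Draw ``n`` trial-level multisensory RTs from the generative relay model.

    All stage times are drawn independently (inter-stage independence); the
    lag logic applies the residual stage-2 delay to the lagging modality.
    Zero-share stages contribute zero duration.
    """
    if n < 1:
        raise ValueError(f"trial count must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    if spec.soa == 0.0:
        total = np.zeros(n)
        for sa, sv in zip(partition(spec.pair.aud, spec.partition), partition(spec.pair.vis, spec.partition)):
            if sa is None:
                continue
            total += np.minimum(ig_sample(sa, n, rng), ig_sample(sv, n, rng))
        return total
    lead, lag, tau = _roles(spec)
    L1, L2 = partition(lead, spec.partition)
    G1, G2 = partition(lag, spec.partition)
    tl1 = ig_sample(L1, n, rng)
    tg1 = ig_sample(G1, n, rng)
    tl2 = ig_sample(L2, n, rng)
    tg2 = ig_sample(G2, n, rng)
    t1 = np.minimum(tl1, tg1 + tau)
    residual = np.maximum(0.0, tau - t1)
    t2 = np.minimum(tl2, tg2 + residual)
    return t1 + t2
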