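"""Synthetic redundant-signals studies with the structure the analyses assume.

Each preset emulates one of four benchmark designs: a 74-participant group
study with Vincentised ten-quantile output (miller1982), a single-subject
11-SOA design (miller1986_soa), a ten-participant 5-SOA design (otto_soa),
and a twenty-participant 3x2 signal-strength design (otto_intensity).
Unisensory trials are drawn from the fitted IG distributions; multisensory
trials from the generative relay sampler.  Participant heterogeneity is
modelled as independent multiplicative lognormal jitter on mu and lam
(default 10%), emulating per-participant fits scattered around the group
values.  Catch trials, misses and outliers are not simulated: the modelling
framework assumes ceiling performance on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ig import IGParams, ig_sample
from .race import ModalityPair
from .relay import RelaySpec, relay_simulate
from .fitting import BinnedData, fit_ig_qmpe, fit_rt_share

__all__ = [
    "TABLE1",
    "Condition",
    "StudyDesign",
    "preset",
    "PRESETS",
    "generate_study",
    "refit_study_share",
    "recovery_experiment",
]

TABLE1 = {
    "miller1982": {"A": IGParams(399, 3272), "V": IGParams(402, 7309)},
    "miller1986": {"A": IGParams(231, 3931), "V": IGParams(348, 4979)},
    "otto_soa": {"A": IGParams(376, 8619), "V": IGParams(404, 14225)},
    "otto_intensity": {
        "A_S": IGParams(412, 13925),
        "A_M": IGParams(457, 11711),
        "A_W": IGParams(508, 7888),
        "V_S": IGParams(431, 15486),
        "V_M": IGParams(515, 9534),
    },
}
"""Best-fitting unisensory IG parameters of the four benchmark datasets."""


@dataclass(frozen=True)
class Condition:
    """One stimulus condition: unisensory (one side None) or redundant."""

    label: str
    aud: Optional[IGParams] = None
    vis: Optional[IGParams] = None
    soa: float = 0.0

    def __post_init__(self) -> None:
        if self.aud is None and self.vis is None:
            raise ValueError(f"condition {self.label!r} has no modality")

    @property
    def multisensory(self) -> bool:
        return self.aud is not None and self.vis is not None


@dataclass(frozen=True)
class StudyDesign:
    """A complete synthetic study.

    trials_per_condition counts trials per condition within each block of
    each participant, so totals match the benchmark designs (e.g. 74
    participants x 2 blocks x 10 trials = 1480).
    """

    participants: int
    blocks: int
    trials_per_condition: int
    conditions: tuple
    share: float = 0.2
    seed: int = 0
    jitter_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.participants < 1 or self.blocks < 1 or self.trials_per_condition < 1:
            raise ValueError("participants, blocks and trial counts must be >= 1")
        if not 0 <= self.share <= 0.5:
            raise ValueError("RT share must lie in [0, 0.5]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        object.__setattr__(self, "conditions", tuple(self.conditions))


def _soa_conditions(a: IGParams, v: IGParams, soas: Sequence[float]) -> list[Condition]:
    conds = [Condition("A", aud=a), Condition("V", vis=v)]
    for soa in soas:
        conds.append(Condition(f"AV{soa:+.0f}", aud=a, vis=v, soa=soa))
    return conds


def preset(name: str) -> StudyDesign:
    """A benchmark study design by name.

    miller1982: 74 participants, 2 blocks x 10 trials, A/V/AV synchronous.
    miller1986_soa: 1 participant, 40 blocks x 10 trials, 11 SOAs (33 ms steps).
    otto_soa: 10 participants, 4 blocks x 40 trials, SOAs -60..60 (30 ms steps).
    otto_intensity: 20 participants, 2 blocks x 50 trials, 5 unisensory
        intensity levels crossed into 6 multisensory conditions (3 auditory x
        2 visual).
    """
    if name == "miller1982":
        t = TABLE1["miller1982"]
        return StudyDesign(74, 2, 10, _soa_conditions(t["A"], t["V"], [0.0]), share=0.226, seed=1982)
    if name == "miller1986_soa":
        t = TABLE1["miller1986"]
        soas = [s * sign for s in (33, 67, 100, 133, 167) for sign in (-1, 1)] + [0.0]
        return StudyDesign(
            1, 40, 10, _soa_conditions(t["A"], t["V"], sorted(soas)), share=0.135, seed=1986, jitter_sd=0.0
        )
    if name == "otto_soa":
        t = TABLE1["otto_soa"]
        return StudyDesign(
            10, 4, 40, _soa_conditions(t["A"], t["V"], [-60, -30, 0, 30, 60]), share=0.107, seed=2013
        )
    if name == "otto_intensity":
        t = TABLE1["otto_intensity"]
        conds = [Condition(k, aud=v) if k.startswith("A") else Condition(k, vis=v) for k, v in t.items()]
        for ak in ("A_S", "A_M", "A_W"):
            for vk in ("V_S", "V_M"):
                conds.append(Condition(f"{ak}{vk}", aud=t[ak], vis=t[vk]))
        return StudyDesign(20, 2, 50, conds, share=0.129, seed=2014)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("miller1982", "miller1986_soa", "otto_soa", "otto_intensity")


def _jitter(p: IGParams, rng: np.random.Generator, sd: float) -> IGParams:
    if sd == 0:
        return p
    f = np.exp(rng.normal(0.0, sd, size=2))
    return IGParams(p.mu * f[0], p.lam * f[1])


def generate_study(design: StudyDesign, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate a full study as a tidy trial table.

    Columns: participant, block, condition, soa_ms, rt_ms.  One master seed
    (the design's, unless overridden) fixes the whole table.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.trials_per_condition
    rows = []
    for pid in range(1, design.participants + 1):
        # per-participant parameter heterogeneity, shared across conditions
        jmap = {}
        for cond in design.conditions:
            for p in (cond.aud, cond.vis):
                if p is not None and p not in jmap:
                    jmap[p] = _jitter(p, rng, design.jitter_sd)
        for block in range(1, design.blocks + 1):
            for cond in design.conditions:
                if cond.multisensory:
                    spec = RelaySpec.two_stage(
                        ModalityPair(jmap[cond.aud], jmap[cond.vis]), design.share, cond.soa
                    )
                    rt = relay_simulate(spec, n, rng)
                else:
                    p = jmap[cond.aud if cond.aud is not None else cond.vis]
                    rt = ig_sample(p, n, rng)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "block": block,
                            "condition": cond.label,
                            "soa_ms": cond.soa,
                            "rt_ms": rt,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def refit_study_share(df: pd.DataFrame, design: StudyDesign) -> tuple[float, float]:
    """Refit a generated study at the group level: pooled QMPE unisensory
    fits, then a joint-NLL share fit over all multisensory conditions.

    Pooling across participants follows the fixed-unisensory protocol at the
    trial counts the benchmark designs provide (e.g. 1600 per condition for
    the SOA design); the share signal is too shallow to pin down from a
    single participant's 160 trials.
    """
    uni = {}
    for cond in design.conditions:
        if not cond.multisensory:
            rts = df.loc[df["condition"] == cond.label, "rt_ms"].to_numpy()
            uni[cond.label] = fit_ig_qmpe(rts).params
    a = next(v for k, v in uni.items() if k.startswith("A"))
    v = next(v for k, v in uni.items() if k.startswith("V"))
    pair = ModalityPair(a, v)
    multis = [c for c in design.conditions if c.multisensory]
    binned = [
        BinnedData.from_sample(df.loc[df["condition"] == c.label, "rt_ms"].to_numpy())
        for c in multis
    ]
    res = fit_rt_share(pair, binned, objective="qmpe_nll_joint", soas=[c.soa for c in multis])
    return float(res.params), float(res.objective)


def recovery_experiment(
    design: StudyDesign, true_share: float, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Simulate-and-refit the RT share; one row per replicate.

    Each replicate regenerates the whole study at ``true_share`` and refits
    it with :func:`refit_study_share`.  Fit failures are recorded per
    replicate rather than aborting the experiment.  The summary bias and
    RMSE of the estimator are attached as ``DataFrame.attrs``.
    """
    design = replace(design, share=true_share)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for rep, s in enumerate(seeds):
        try:
            share, obj = refit_study_share(generate_study(design, seed=int(s)), design)
            rows.append({"replicate": rep, "fitted_share": share, "objective": obj, "error": ""})
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            rows.append({"replicate": rep, "fitted_share": np.nan, "objective": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows)
    ok = out["fitted_share"].dropna()
    out.attrs["bias"] = float(ok.mean() - true_share) if len(ok) else np.nan
    out.attrs["rmse"] = float(np.sqrt(np.mean((ok - true_share) ** 2))) if len(ok) else np.nan
    return out
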