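"""Temporal asynchrony: the RSE as a function of stimulus onset asynchrony.

Uses the single-subject SOA-study fits (A: mu=231, lam=3931; V: mu=348,
lam=4979).  Positive SOA = auditory lags visual onset.  Prints the mean-RT
RSE (against SOA-adjusted unisensory references) for the race model and for
the relay at the study's best-fitting 13.5% share: both peak where the SOA
offsets the ~117 ms auditory advantage, but only the relay reaches
empirically realistic magnitudes.
"""

import numpy as np

from relayrt import IGParams, ModalityPair, RelaySpec, StagePartition, relay_cdf, rse_mean

pair = ModalityPair(aud=IGParams(231, 3931), vis=IGParams(348, 4979))
soas = [s * x for s in (167, 133, 100, 67, 33) for x in (-1,)] + [0] + [33, 67, 100, 133, 167]

print("SOA (ms)   race RSE (ms)   relay RSE (ms, share 13.5%)")
for soa in soas:
    curves = {}
    for name, share in (("race", (0.0, 1.0)), ("relay", (0.135, 0.865))):
        spec = RelaySpec(pair, StagePartition(share), soa)
        curves[name] = rse_mean(relay_cdf(spec), np.array([pair.aud.mu]), np.array([pair.vis.mu]), soa)
    print(f"{soa:7.0f}    {curves['race']:8.1f}        {curves['relay']:8.1f}")

print("\nAs the lag grows the lagging signal is progressively excluded and"
      "\nboth models converge to the leading unisensory condition (RSE -> 0);"
      "\nthe relay transitions between regimes with no extra parameters.")
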