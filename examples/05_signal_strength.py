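"""Signal-strength manipulation: fit one condition, predict the rest.

Simulates the 3 (auditory) x 2 (visual) intensity design, fits the RT share
only in the medium-medium condition, then predicts the RSE of all six
multisensory conditions with no further free parameters and correlates
predicted with observed RSEs — the out-of-sample test of the relay
mechanism's invariance across signal strengths.
"""

import numpy as np

from relayrt import (
    BinnedData,
    ModalityPair,
    RelaySpec,
    corr_perm_test,
    fit_ig_qmpe,
    fit_rt_share,
    generate_study,
    preset,
    relay_cdf,
    rse_mean,
)

design = preset("otto_intensity")  # true share 0.129
df = generate_study(design, seed=7)

uni = {
    c.label: fit_ig_qmpe(df[df.condition == c.label].rt_ms.to_numpy()).params
    for c in design.conditions
    if not c.multisensory
}
pair_mm = ModalityPair(uni["A_M"], uni["V_M"])
target = BinnedData.from_sample(df[df.condition == "A_MV_M"].rt_ms.to_numpy())
fit = fit_rt_share(pair_mm, [target], objective="qmpe_nll_joint", soas=[0.0])
print(f"share fitted on A_M V_M only: {fit.params:.3f} (true {design.share})")

observed, predicted = [], []
print("\ncondition   observed RSE   predicted RSE (ms)")
for cond in design.conditions:
    if not cond.multisensory:
        continue
    ak, vk = cond.label.split("V_")
    pair = ModalityPair(uni[ak.rstrip("_")], uni["V_" + vk])
    rts = df[df.condition == cond.label].rt_ms.to_numpy()
    obs = min(uni[ak.rstrip("_")].mu, uni["V_" + vk].mu) - rts.mean()
    pred = rse_mean(relay_cdf(RelaySpec.two_stage(pair, fit.params)), pair.aud.mu, pair.vis.mu)
    observed.append(obs)
    predicted.append(pred)
    print(f"{cond.label:9s}   {obs:8.1f}      {pred:8.1f}")

r, p = corr_perm_test(observed, predicted, n_iter=10_000, rng=1)
print(f"\nPearson r = {r:.2f}, permutation p = {p:.3f}")
print("A single invariant relay share transfers across signal strengths:"
      "\nweaker, more variable signals yield larger facilitation, as the"
      "\nvariability rule predicts.")
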