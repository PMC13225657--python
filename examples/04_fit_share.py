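"""Simulate a full SOA study and recover its RT share from the trial table.

Generates the ten-participant, five-SOA synthetic design at a known
first-stage RT share (10.7%), refits the unisensory inverse-Gaussian
parameters by QMPE from the pooled unisensory trials, then fits the share by
joint negative log-likelihood across the five multisensory conditions —
the full fixed-unisensory protocol, end to end.
"""

from relayrt import generate_study, preset, refit_study_share

design = preset("otto_soa")  # true share 0.107 baked into the preset
df = generate_study(design, seed=42)
print(f"simulated {len(df)} trials: {design.participants} participants, "
      f"conditions {sorted(df.condition.unique())}")

share, nll = refit_study_share(df, design)
print(f"true RT share  {design.share:.3f}")
print(f"fitted RT share {share:.3f}   joint NLL {nll:.1f}")
print("\nThe fitted share is the single free multisensory parameter; the"
      "\nunisensory parameters were refit from the data and held fixed, so"
      "\nrecovery near the true value validates the whole pipeline.")
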