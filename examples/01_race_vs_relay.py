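"""Race vs relay predictions on the classic group-level detection fits.

Builds the probability-summation (race) prediction and two-stage relay
predictions from published unisensory inverse-Gaussian fits (A: mu=399,
lam=3272; V: mu=402, lam=7309) and prints the geometric redundant-signals
effect (RSE) and race-model-inequality (RMI) violation for each.
"""

from relayrt import (
    IGParams,
    ModalityPair,
    RelaySpec,
    StagePartition,
    default_grid,
    multistage_relay_cdf,
    relay_cdf,
    rmi_violation_geometric,
    rse_geometric,
    stage_race,
)

pair = ModalityPair(aud=IGParams(399, 3272), vis=IGParams(402, 7309))
grid = default_grid([pair.aud, pair.vis])
f_a = stage_race(pair.aud, None, grid)
f_v = stage_race(None, pair.vis, grid)

race = multistage_relay_cdf(pair, StagePartition((1.0,)), grid)
print(f"race model        RSE {rse_geometric(race, f_a, f_v):5.1f} ms   "
      f"RMI violation {rmi_violation_geometric(race, f_a, f_v):4.1f} ms")

for share in (0.1, 0.226, 0.5):
    relay = relay_cdf(RelaySpec.two_stage(pair, share), grid)
    print(f"relay share {share:4.0%}  RSE {rse_geometric(relay, f_a, f_v):5.1f} ms   "
          f"RMI violation {rmi_violation_geometric(relay, f_a, f_v):4.1f} ms")

print("\nThe race model predicts facilitation from statistical summation alone"
      "\nand can never violate the Miller bound; cross-modal initiation in the"
      "\nrelay amplifies the RSE and produces bound violations, growing with"
      "\nthe first-stage RT share up to its symmetric maximum at 50%.")
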