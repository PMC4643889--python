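"""Classify the ESS structure of a pair of 2x2 games.

Builds the bistable-bistable pair A = [[1,0],[0,1]] (patch 1) and
B = [[2,0],[0,1]] (patch 2), prints each game's ESS report and the regime
label of the pair. "bistable" means both pure strategies are ESSs and the
interior rest point (p* or q*) is an unstable mixing threshold.
"""

import json

import patchgame as pg

sys = pg.TwoPatchSystem(
    pg.Game2x2(1, 0, 0, 1),
    pg.Game2x2(2, 0, 0, 1),
    pg.PatchEnv(alpha=1.75, beta=0.05, c_out=0.014),
    pg.PatchEnv(alpha=2.0, beta=0.01, c_out=0.014),
)
pair = pg.classify_pair(sys)
print(json.dumps(pair.to_dict(), indent=2))
print(
    f"\nRegime {pair.label}: both patches are coordination games; the mixing "
    f"thresholds are p* = {pair.essA.interior_candidate:.4f} and "
    f"q* = {pair.essB.interior_candidate:.4f}. Neither mixed point is an ESS, "
    "so each isolated patch tips to all-R1 or all-R2 depending on its start."
)
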