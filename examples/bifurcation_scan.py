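"""Sweep the common migration rate and tabulate the equilibrium census.

On the bifurcation template the number of attractors shrinks as migration
strengthens: four below c ~ 0.0155, three up to c ~ 0.021, then only the
two monomorphic symmetric states. Thresholds are reported as bracketing
intervals between grid points where a count changes.
"""

import numpy as np

import patchgame as pg

sys = pg.get_scenario("fig4").sys
rows = pg.scan(sys, c_values=np.arange(0.0, 0.051, 0.005), densify_step=1e-3)

print(f"{'c':>8} {'total':>6} {'stable':>7} {'unstable':>9} {'interior':>9}")
for r in rows:
    print(f"{r.c:8.4f} {r.n_total:6d} {r.n_stable:7d} {r.n_unstable:9d} {r.n_interior:9d}")

print("\ncensus changes:")
for t in pg.detect_thresholds(rows):
    changes = ", ".join(f"{k}: {a}->{b}" for k, (a, b) in t["changes"].items())
    print(f"  c in ({t['c_low']:.4f}, {t['c_high']:.4f}): {changes}")
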