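"""Backward-bifurcation diagram: endemic infective level versus R0.

Sweeps the recruitment rate A through the case3 family so that R0 crosses 1,
printing the endemic branch structure. Below the turning point R0c the
disease always dies out; between R0c and 1 two endemic states exist (upper
branch stable, lower unstable); above 1 a single endemic branch remains.
The turning point is located by bisecting the discriminant of the
endemic-equilibrium quadratic.
"""

import numpy as np

from seirsat import bifurcation_scan, get_preset

p = get_preset("case3").parameters
grid = np.linspace(4.0, 14.0, 41)
branch = bifurcation_scan(p, "A", grid)

value, R0_turn, I_turn = branch.turning_point
print(f"turning point: A = {value:.10g}, R0c = {R0_turn:.10g}, I = {I_turn:.10g}\n")
print(f"{'A':>8} {'R0':>10}  endemic I-roots (u=upper/stable side, l=lower)")
for A, R0 in zip(branch.grid, branch.R0):
    roots = [
        f"{pt.I_root:.4f}{'u' if pt.stable_side else 'l'}"
        for pt in branch.points
        if pt.param_value == A
    ]
    print(f"{A:8.3f} {R0:10.6f}  {' '.join(roots) if roots else '-'}")
print("\nTwo roots appear for R0c < R0 < 1: reducing R0 below 1 does not")
print("remove the endemic state until R0 drops below the turning point R0c.")
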