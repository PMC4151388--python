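"""Thresholds, equilibria and stability for the three shipped scenarios.

For each scenario this prints the basic reproduction number R0, the
backward-bifurcation threshold k0, the endemic-stability threshold k1, every
equilibrium with its coordinates, and the local stability verdicts. Case 1
has R0 < 1 and no endemic point (disease dies out); case 2 has R0 > 1 and a
unique stable endemic point (disease persists); case 3 has R0 < 1 yet two
endemic points — the backward-bifurcation regime where pushing R0 below 1
is not enough to eradicate the disease.
"""

from seirsat import (
    PRESETS,
    dfe_stability,
    endemic_equilibria,
    endemic_stability,
    thresholds,
)

for name, scenario in PRESETS.items():
    p = scenario.parameters
    thr = thresholds(p)
    rep = endemic_equilibria(p)
    print(f"\n=== {name} ===")
    print(f"R0 = {thr.R0:.10g}   (k0 = {thr.k0:.10g}, k1 = {thr.k1:.10g}, k = {p.k})")
    print(f"disease-free point (S, E, I) = ({rep.dfe[0]:.10g}, 0, 0): "
          f"{dfe_stability(p).verdict}")
    print(f"existence case: {rep.case_label}, backward bifurcation: "
          f"{rep.backward_bifurcation}")
    for i, pt in enumerate(rep.endemic, 1):
        S, E, I = pt.state
        verdict = endemic_stability(pt.state, p).verdict
        print(f"endemic-{i}: (S, E, I) = ({S:.10g}, {E:.10g}, {I:.10g}) -> {verdict}")
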