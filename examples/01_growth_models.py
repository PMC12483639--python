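"""Deterministic growth models and the step-like threshold pathology.

Builds the three growth models at matched thresholds, prints their
equilibria and asymmetry ratios, and times the threshold model's rise: the
classical threshold extension crawls above the threshold for years and then
jumps to the carrying capacity almost instantaneously, unlike any real
tumour.
"""

import numpy as np

import oncodyn as od

# ERM1 with nu=1, decay rate r=0.12/unit, threshold A=1 cell, capacity K=1e4
p_erm1 = od.GrowthParams.erm1_from_thresholds(1.0, 0.12, 1.0, 1e4)
rep = od.equilibria(p_erm1)
print("ERM1 equilibria (cells):", [f"{e:g}" for e in rep.equilibria])
print(f"ERM1 asymmetry |l_grow/l_sat| = {rep.defining_feature:.4f}  (< 1: too slow to grow)")

t_1pct = od.first_passage_time(p_erm1, 2.0, 100.0, 50.0)
t_99pct = od.first_passage_time(p_erm1, 2.0, 9900.0, 50.0)
print(f"time from 2 cells to 1% of K : {t_1pct:.2f} time units")
print(f"time from 1% to 99% of K     : {t_99pct - t_1pct:.3f} time units  (the 'step')")

# ERM2: immune clearance s produces the threshold instead; asymmetry >= 1
p_erm2 = od.GrowthParams.erm2_from_thresholds(1.0, 0.12, 1.0, 1e4)
rep2 = od.equilibria(p_erm2)
print(f"\nERM2 equilibria: {[f'{e:g}' for e in rep2.equilibria]}, "
      f"asymmetry = {rep2.defining_feature:.3f} (>= 1: cancer-like)")

# asymmetry-versus-shape curves at fixed A=1, K=100
grid = np.logspace(-0.5, 2, 6)
print("\nnu grid:          ", np.round(grid, 2))
print("Richards ratio:   ", np.round(od.asymmetry_curve("richards", grid, 1.0), 3))
print("ERM1 ratio (< 1): ", np.round(od.asymmetry_curve("erm1", grid, 1.0, A=1, K=100), 3))
print("ERM2 ratio:       ", np.round(od.asymmetry_curve("erm2", grid, 1.0, A=1, K=100), 3))
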