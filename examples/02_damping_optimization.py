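"""Second-loop damping: scan the IκBε delay and feedback strength.

Scores each (tau2, eps) grid point by the largest nuclear NF-κB
peak-trough difference after six hours of persistent stimulation — small
values mean the second loop has quenched the late oscillations.
"""

import numpy as np

from nfkbloop import reference_params
from nfkbloop.pipelines import damping_scan

params = reference_params()
tau2_grid = np.arange(0.0, 90.1, 15.0)
eps_grid = [0.0, 0.3, params.eps]
res = damping_scan(params, 1.0, tau2_grid, eps_grid, t_end=600.0)

print("late-oscillation metric (nM), rows = eps, cols = tau2 (min):")
print("tau2: " + "  ".join(f"{t:6.1f}" for t in tau2_grid))
for eps, row in zip(eps_grid, res.metric):
    print(f"eps={eps:4.2f} " + "  ".join(f"{m:6.1f}" for m in row))
print(f"\nminimum at tau2 = {res.argmin[0]:.1f} min, eps = {res.argmin[1]:.2f}")

# The eps = 0 row is flat (no second loop, tau2 irrelevant and the primary
# oscillation persists); with the loop active the metric collapses when the
# extra IκBε delay is ~45 min — half an oscillation period — so the ε wave
# arrives in antiphase and fills the inhibitor troughs.
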