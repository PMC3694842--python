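"""Synthetic observables: half-maximal delay estimation and calibration.

Generates noisy mRNA induction time courses, reads the synthesis delay
off the 50%-activation crossing, and demonstrates anchor-based
calibration recovering a known delay from simulated observables.
"""

import numpy as np

from nfkbloop import reference_params
from nfkbloop.synth import (
    ANCHOR_EVALUATORS,
    Anchor,
    calibrate_parameters,
    estimate_half_max_delay,
    gen_mrna_course,
)

true_delay = 45.0
estimates = [
    estimate_half_max_delay(gen_mrna_course(true_delay, noise_cv=0.1, seed=s))
    for s in range(10)
]
print(f"true half-max delay : {true_delay:.1f} min")
print(f"replicate estimates : {np.round(estimates, 1)}")
print(f"mean of N=10        : {np.mean(estimates):.1f} min")

ref = reference_params()
period = ANCHOR_EVALUATORS["single_period"](ref, 1.0)
peak = ANCHOR_EVALUATORS["single_peak_x"](ref, 1.0)
res = calibrate_parameters(
    [Anchor("single_period", period, 0.02), Anchor("single_peak_x", peak, 0.02)],
    {"tau1": (30.0, 70.0)},
    ref.with_(tau1=55.0),  # deliberately wrong start
)
print(f"\ncalibration: started tau1 = 55.0, recovered {res.params.tau1:.2f} "
      f"(truth {ref.tau1:.1f}); success = {res.success}")

# The estimator is unbiased to within a sampling-grid fraction at 10%
# multiplicative noise, and the bounded local search pulls the synthesis
# delay back to the value that generated the anchors.
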