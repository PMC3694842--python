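"""Temporal dose response: how stimulus duration maps to response duration.

The response duration is the total time nuclear NF-κB spends above a
50 nM threshold. The oscillating single-loop module quantizes this map
(several input durations give the same output), while the damped dual
module grades it.
"""

import numpy as np

from nfkbloop import reference_params
from nfkbloop.pipelines import duration_response

params = reference_params()
pulses = np.array([15.0, 30.0, 60.0, 120.0, 150.0, 180.0, 240.0, 300.0])
single = duration_response("single", params, 1.0, pulses, t_end=520.0)
dual = duration_response("dual", params, 1.0, pulses, t_end=520.0)

print("input (min)   single (min)   dual (min)")
for d, s_out, d_out in zip(pulses, single.response_durations, dual.response_durations):
    print(f"{d:8.0f}   {s_out:10.1f}   {d_out:9.1f}")

# Short pulses hit a common floor set by the IκBα synthesis delay; for
# longer inputs the dual response grows roughly one-for-one with the
# stimulus, whereas the single-loop output clusters on oscillation-locked
# plateaus.
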