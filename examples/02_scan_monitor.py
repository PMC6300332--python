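"""Monitor an aggregated sequence with the moving-window scan.

Simulates a shifted run, aggregates it at level 5, scans it, and prints
the standardized maxima at the decision points around the shift together
with the signal times in original units.
"""

import numpy as np

from netsurv import (
    AggregationSpec,
    CommunityStructure,
    ScanConfig,
    ShiftSpec,
    build_block_matrix,
    draw_degree_propensities,
    generate_sequence,
    scan_sequence,
)

rng = np.random.default_rng(11)
structure = CommunityStructure((10, 10))
theta = draw_degree_propensities(structure, rng=rng)
P = build_block_matrix(1.0, 2.0, 2)
seq = generate_sequence(structure, theta, P,
                        ShiftSpec(shift_fraction=1.5, shift_time=842),
                        860, rng)

agg = AggregationSpec(level=5).apply(seq)      # 172 matrices of width 5
res = scan_sequence(agg, ScanConfig())         # window 20, threshold 4

print("time  M*_deg  M*_nbr1  M*_nbr2  signal")
for idx in range(165, 172):
    t = (idx + 1) * 5
    m = res.standardized_max_stats[idx]
    print(f"{t:4d}  {m[0]:6.2f}  {m[1]:7.2f}  {m[2]:7.2f}  "
          f"{'<-- signal' if res.signal_flags[idx] else ''}")
print("signal times (original units):", res.signal_times.tolist())
# The shift starts in period 843; the first aggregated block that is mostly
# anomalous ends at 845, where the standardized maxima jump above the
# signaling threshold of 4.
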