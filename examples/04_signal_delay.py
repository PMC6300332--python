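"""Conditional signal delay and the late-shift penalty.

Shows (a) the delay distribution at aggregation levels 1 and 20 for a
strong shift, and (b) how the detection rate degrades when the shift
arrives late inside a level-20 aggregation period.
"""

from netsurv import ScenarioConfig, conditional_delay_distribution, shift_offset_profile

for level in (1, 20):
    cfg = ScenarioConfig(baseline_diag=1.0, shift_fraction=1.5,
                         level=level, seed=8)
    res = conditional_delay_distribution(cfg, 60)
    print(f"W={level:2d}: detected {res['n_detected']}/{res['replications']}, "
          f"mean delay {res['mean']:.1f}, median {res['median']:.1f}, "
          f"histogram {res['histogram']}")
# At W = 1 a detected shift is flagged almost immediately (delay ~0-2);
# at W = 20 the monitor must wait for the end of the aggregation period,
# so delays spread across 0..19 original periods.

cfg = ScenarioConfig(baseline_diag=1.0, shift_fraction=1.5, level=20, seed=8)
profile = shift_offset_profile(cfg, 40, offsets=[840, 846, 852, 856, 859])
print()
print(profile.to_string(index=False))
# Shifts early in the period leave mostly-anomalous data in the single
# monitorable block and are detected reliably; shifts near the end leave
# mostly-baseline data and detection collapses.
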