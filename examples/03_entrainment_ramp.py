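"""Entrainment: two approaching hyphae drift into the anti-phasic dialogue.

The inter-cell distance ramps linearly from 10 to 0 over 30 time units;
the sliding-window correlation of the two activators shows anti-synchrony
emerging as the cells meet.
"""

import numpy as np

from hyphal_dialogue import (DistanceSchedule, SimulationSettings,
                             run_approach_ramp)

sched = DistanceSchedule.linear_ramp(d_start=10.0, d_end=0.0,
                                     ramp_start=10.0, ramp_end=40.0)
settings = SimulationSettings(total_time=80.0, burn_in=200.0, seed=1)
res = run_approach_ramp(sched, settings=settings)

print("windowed Pearson(A1, A2) along the approach:")
for c, v in zip(res.window_centers[::4], res.window_correlations[::4]):
    bar = "#" * int(20 * min(1, abs(v)))
    print(f"  t = {c:5.1f}  {v:+.2f} {'-' if v < 0 else '+'}{bar}")
late = np.nanmean(res.window_correlations[res.window_centers >= 60.0])
print(f"\nmean correlation after contact (t >= 60): {late:+.3f}")
print(f"slowdown ratio (transition vs flanks): {res.slowdown_ratio:.3f}")
print("-> correlation moves from ~0 (independent monologues) to clearly")
print("   negative (dialogue) once the gap closes.")
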