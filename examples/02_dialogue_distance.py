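"""Dialogue vs monologue: how the inter-cell distance shapes coordination.

Runs the two-cell model at contact (d=0) and far apart (d=10), classifies
the phase relation of the two activators, then sweeps the distance grid to
show the anti-correlation fading with distance.
"""

from hyphal_dialogue import (SimulationSettings, run_distance_sweep,
                             run_fixed_distance)

settings = SimulationSettings(total_time=100.0, burn_in=200.0, seed=1)

for d in (0.0, 10.0):
    _, corr, phase = run_fixed_distance(d, settings=settings)
    print(f"d = {d:4.1f}: Pearson(A1, A2) = {corr:+.3f}, "
          f"phase = {phase.label} (lag {phase.lag_fraction:.2f} of a period)")

res = run_distance_sweep([0, 2, 4, 6, 8, 10], n_seeds=5, settings=settings)
print("\nmean correlation vs distance (5 seeds each):")
for d, m in zip(res.d_values, res.summary_mean):
    print(f"  d = {d:4.1f}: {m:+.3f}")
print("-> at contact the cells alternate (anti-phase, lag ~0.5); the")
print("   anti-correlation weakens as the coupling kz*exp(-d) decays.")
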