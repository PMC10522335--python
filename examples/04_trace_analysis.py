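"""Trace analysis on synthetic fluorescence data with known ground truth.

Generates a 200-pulse surrogate tip-fluorescence trace with the measured
dialogue-phase period statistics (104 +/- 28 s), adds 5% measurement noise,
and runs the peak / interval / histogram pipeline.
"""

from hyphal_dialogue import (PulseTrainSpec, detect_peaks, generate_pulse_trace,
                             interval_statistics, relative_frequency_histogram)

spec = PulseTrainSpec(period_mean=104.0, period_sd=28.0, n_pulses=200,
                      noise_sd=0.05, seed=1)
trace, truth = generate_pulse_trace(spec)
peaks = detect_peaks(trace)
stats = interval_statistics(peaks)
hist = relative_frequency_histogram(stats, bin_width=20.0)

print(f"ground-truth pulses: {len(truth)}, detected peaks: {peaks.n}")
print(f"recovered period: {stats.mean:.1f} +/- {stats.sd:.1f} s (n = {stats.n})")
print("interval histogram (20 s bins):")
for lo, f in zip(hist.bin_edges[:-1], hist.relative_frequencies):
    print(f"  [{lo:5.0f},{lo + 20:5.0f}) {'#' * int(50 * f)} {f:.2f}")
print("-> the pipeline recovers the generator's 104 +/- 28 s statistics from")
print("   a noisy sampled trace, the same way measured traces are summarized.")
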