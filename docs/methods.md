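# Methods

## Model

Two cells, five variables each: activator *A*, inhibitor *I*, free
vesicles *X*, docked vesicles *Y*, and tip-local extracellular signal *Z*.
The activator is excited by uptake of extracellular signal (+A·Z), amplifies
itself (βA²) against linear and cubic decay, and is curbed by the delayed
inhibitor (Hill production γA²/(A²+k) at time-scale separation ε). The
activator drives vesicle docking (k₁A²X); release k₂Y/(A³+1) is gated off
while the activator is high, so each cell secretes only after its own
excitation has passed — the refractory structure that prevents
self-stimulation. Released signal feeds the tip pool *Z*, which exchanges
with the bulk medium at rate k_Cext (toward C_media) and with the partner
tip at rate k_z·e^(−d). The coupling flux k_z·e^(−d)·(Z̃ − Z) is
conservative between the tips; distance enters the model only through this
one factor. All constants use the published values (see README); one
simulation time unit represents one minute, and a helper converts model
periods to seconds (×60) for comparison with measured trace statistics.

## Noise

The state equation is dU = τF(U)dt + τ√(1/Ω)·(channel noise). Each of the
19 reaction channels per cell carries an independent Wiener process;
independent Gaussian increments add in variance, so the integrator draws
one normal per variable per step with per-variable amplitude
s_v = √(Σ_j g_{v,j}) (chemical-Langevin convention: each channel has
amplitude √propensity; the default) or s_v = √(Σ_j g_{v,j}²) (each channel
amplitude equal to its raw propensity; available as
`noise_mode="as-printed"`). The chemical-Langevin convention is the default
because it is the standard system-size expansion and because the
raw-propensity reading is numerically explosive at the published
parameters: near a spike the cubic activator channel reaches A³ ≈ 60,
giving per-step kicks of order 2 at dt = 0.001 that drive the state to
overflow within ~100 time units. Under the default convention the model
reproduces the expected phenomenology (sustained noisy pulsing, anti-phase
locking at contact, entrainment during approach) at the published Ω = 1000.

Propensities are evaluated on the nonnegative-clamped state, and the state
is clamped at zero after every step (concentrations are physical;
configurable off). Per-step draws are consumed in a fixed variable order
(A₁, I₁, X₁, Y₁, Z₁, A₂, …) from a single generator seeded per run, so
trajectories are bit-reproducible from (seed, parameters, settings,
schedule) regardless of internal vectorization.

## Excitability: the deterministic limit does not oscillate

At the published parameters the noise-free system has a stable
high-activator fixed point (single cell / decoupled:
A ≈ 3.955, I ≈ 5.882, X ≈ 0.639, Y ≈ 62.85, Z ≈ 0.670; Jacobian
eigenvalues −69.7, −9.11 ± 10.9i, −13.3, −0.126 with τ included) and a
marginally stable low-activator state near A ≈ 1. Adaptive-step ODE
integration from the canonical initial state confirms relaxation to the
fixed point with no limit cycle. The model is therefore an excitable
system: system-size noise triggers large-amplitude excursions
(A ≈ 0.3 → 6) whose recurrence at Ω = 1000 produces quasi-regular pulsing
with a period of ≈ 1.3 time units. All oscillation, synchronization and
entrainment results in this package are statements about the stochastic
dynamics; deterministic mode (`noise_mode="off"`) exists for integrator
validation (against `scipy.integrate.solve_ivp` and dt-halving) and for
studying the underlying fixed-point structure.

Two documented consequences, measured rather than asserted:

- **Media depletion.** Lowering C_media to 0 reduces the stochastic firing
  rate roughly threefold (≈ 21 vs ≈ 75 activator peaks per 100 time units,
  seed-dependent) but does not abolish firing: the basal-production noise
  channel (amplitude ∝ √(a₀/Ω)) can trigger the excitable loop without
  extracellular signal. In the deterministic limit neither condition
  oscillates at all. The depletion experiment therefore appears in this
  package as a monotone rate effect, not an on/off bifurcation; a sharper
  threshold presumably requires a weaker noise regime than the published
  Ω = 1000 supports.
- **Transient slowing.** The pooled inter-peak interval is statistically
  flat in distance (≈ 1.30 ± 0.36 time units across d = 0…10, n ≈ 2250
  intervals per distance), and per-seed slowdown ratios across the
  approach ramp scatter around 1 (mean ≈ 0.99). A "critical slowing down"
  of the oscillation during entrainment, if present, is below seed-to-seed
  variability at Ω = 1000. The `slowdown_statistic` itself is validated on
  synthetic entrainment sequences with a known slowed middle segment.

## Integration and schedules

Fixed-step Euler–Maruyama at dt = 0.001 (numba-compiled inner loop; a pure
Python fallback runs when numba is unavailable). Runs start from the
canonical initial state [0.7065, 0.7145, 0, 0, 1]×2, discard a burn-in
(default 200 time units) and record every 100th step (one sample per 0.1
time unit, ~13 samples per pulse). Distance schedules are constant, linear
ramp, or piecewise-linear; the schedule clock starts at the end of burn-in
and the burn-in runs at the schedule's initial value, so ramps begin from
an already-equilibrated oscillatory state. The dt-halving check
(`deterministic_convergence_check`) reports a maximum discrepancy of 0.030
at dt = 0.001 over 20 time units (tolerance stated as 0.05); the
discrepancy is dominated by the stiff initial transient of the
largest-scale variable Y (~60), i.e. a relative error of ~5·10⁻⁴.

## Trace analysis

Peak detection finds strict local maxima of the (linearly detrended) trace
with prominence ≥ 20 % of the detrended range, greedily keeping the more
prominent peak when two candidates fall within the minimum separation
(default 30 s for experimental-scale traces, 0.5 time units for model
traces). Interval statistics use per-interval pooling and the sample (n−1)
SD; quantities that are undefined (fewer than two peaks, zero variance)
are returned as `None`, never silently 0 or NaN. Histograms use
left-closed bins of 20 s anchored at 0 by default. Phase classification
takes the dominant period from the mean inter-peak interval of the first
trace and the lag from the argmax of the circular cross-correlation within
one period: in-phase for lag fraction in [0, 0.15] ∪ [0.85, 1), anti-phase
for [0.35, 0.65], otherwise uncoordinated, with |Pearson r| ≥ 0.3 required
for either synchronized label. The slowing statistic divides the pooled
mean interval of a transition window by the average of the flanking
windows' pooled means.

Note for sparse pulse trains: the Pearson coefficient of two trains of
narrow, mostly non-overlapping pulses is biased negative (pulses that
never coincide anticorrelate by construction), so "uncoordinated" pairs of
synthetic trains sit slightly below zero; the model's activator traces are
dense enough not to show this bias. Tests of the entrainment generator use
before/after contrasts rather than absolute correlation levels for this
reason.

## Synthetic traces

Pulse trains draw inter-pulse intervals from a normal distribution
truncated below at twice the pulse width (no pulse overlap; the truncation
bias on mean/SD is negligible at the default parameters), render Gaussian
pulses of width 10 s (SD) on a 5 s sampling grid, and optionally add linear
drift (photobleaching surrogate) and white measurement noise. Defaults
follow the measured dialogue-phase period 104 ± 28 s; recovery tests also
use the monologue regime 137 ± 17 s. Anti-phasic pairs share one interval
realization with the second train offset by half of each realized cycle
(so its pulses bisect the first train's); independent pairs draw separate
realizations. Entrainment sequences concatenate independent, slowed
independent (period × factor), and anti-phasic segments with recorded
change points and ground-truth pulse centers. The generator emulates
period statistics, jitter, drift and additive noise of tip-fluorescence
recordings; it does not model imaging physics (PSF, shot noise, ROI
geometry) or exponential bleaching, so passing recovery tests demonstrate
correctness of the analysis pipeline on traces with realistic statistics,
not robustness to all imaging artifacts.

## Particle-size bound

Three-dimensional Brownian motion covers L² = 6Dt; with Stokes–Einstein
D = k_B·T/(6πηr) the largest particle that can cross a gap L within time t
has radius r = k_B·T/(πη) · t/L². At T = 298.15 K and η = 0.89 mPa·s the
prefactor is 1.47×10⁻¹⁸ m²/s (1.5×10⁻¹⁸ to two significant figures); k_B
uses the exact 2019 SI value. At the reference inputs L = 10 µm, t = 10 s
the formula yields r ≈ 1.5×10⁻⁷ m, whereas the nanometre-scale bound
usually quoted for this argument (r ≲ 1.5 nm) corresponds to L ≈ 100 µm or
t ≈ 0.1 s; the implementation returns the formula value unmodified and
flags the discrepancy in its documentation rather than reconciling it.

## Problem sizes and scope

Test and acceptance runs use the published burn-in of 200 time units with
analysis windows of 60–100 time units, 10 seeds per condition, and the
full distance grid d = 0…10; synthetic recovery uses 500-pulse trains.
The package deliberately excludes spatial/PDE extensions (distance acts
only through k_z·e^(−d)), parameter fitting to measured traces, and any
image processing upstream of extracted intensity traces.
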