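# Methods

## Single-cell model

The intracellular cAMP relay circuit is reduced to a noisy FitzHugh–Nagumo
(FHN) system: a fast activator `A` (proxy for cytosolic cAMP) with cubic
positive feedback `f(A) = A − A³/3`, and a slow repressor `R`,

    dA/dt = A − A³/3 − R + I([cAMP]ex) + η(t)
    dR/dt = ε (A − γR + c0),

with Gaussian white noise `⟨η(t)η(t′)⟩ = σ²δ(t−t′)`.  The input module is
a fold-change sensor, `I(x) = a·ln(1 + x/Kd)` (natural logarithm; the base
only rescales `a` and is fixed here).  One parameter set is used
everywhere:

| parameter | default | meaning |
|---|---|---|
| ε | 0.1 | activator/repressor timescale ratio (excitability) |
| γ | 0.5 | repressor degradation rate |
| c0 | 1.2 | repressor-nullcline offset (resting repressor level) |
| a | 0.058 | input-response magnitude |
| Kd | 1e−5 | cAMP response threshold (model concentration units) |
| σ | 0.15 | Langevin noise strength |

All quantities are dimensionless model units.  One model concentration
unit is mapped to 1 nM by the stimulus presets.  The model's time unit
`T` is *defined* as the minimum oscillation period of a deterministic
cell over a supra-threshold drive scan (`metrics.calibrate_units`); with
the defaults this is ≈ 28.9 raw integration-time units, frozen as
`stimulus.TIME_UNITS_PER_MIN` with the convention 1 T ↔ 1 experimental
minute.  The amplitude unit is the mean spike height of noisy responses
to the 1 nM step (≈ 3.4 activator units).

Analysis of the fixed structure is closed-form where possible: fixed
points are the real roots of the depressed cubic obtained by equating the
nullclines `R = A − A³/3 + I` and `R = (A + c0)/γ`, classified by the
Jacobian `[[1 − A*², −1], [ε, −εγ]]`; the supercritical Hopf drive is
`drive_c = (A*c + c0)/γ − A*c + A*c³/3` at `A*c = −√(1 − εγ)` (the
resting branch has `A* < 0`), ≈ 1.1167 at the defaults.  Useful measured
facts: the excitation threshold for a fast step from rest is drive
≈ 0.41 (≈ 0.37·drive_c) — steps between that and `drive_c` fire exactly
one accommodation spike; weaker steps relax without a spike.

## Stochastic integration

Euler–Maruyama, `state += drift·dt + σ√dt·ξ`, at `dt = 0.005`.  Noise
enters the activator equation by default; variants put it in the external
cAMP (with the field clipped at zero) or disable it.  Initial conditions
default to uniform draws in [−2, 2]²; deterministic analyses start at the
resting fixed point.  Output is decimated by `record_stride` (default 10)
and all statistics are computed on the decimated grid.  Kernels are
numba-compiled; the population integrator consumes pre-drawn normal
slabs (step-major, then cell-major) from a `numpy` Generator so a single
seed fixes the trajectory bitwise.  Accuracy: against an adaptive LSODA
oracle at tight tolerance the Euler path agrees to ≤ 1e−3 sup-norm on
smooth (non-spiking) protocols over t = 50; across a relaxation spike the
O(dt) phase error of the upstroke dominates and the deviation is ~1e−2.
Numbers that hinge on trajectory timing (widths, periods) are insensitive
to this at the scales reported.

## Stimulus protocols

Piecewise protocols tile [0, t_end] with holds, instantaneous steps,
exponential ramps and ideal rectangular pulse trains (instantaneous
edges, as in microfluidic switching); evaluation is right-continuous.
The exponential ramp is parameterized by a time constant τ (default a
quarter of the segment) with endpoint normalization, and interpolates
*geometrically* between its start and target concentrations: for the
logarithmic sensor only a ramp with constant decades-per-time has a
well-defined "slow" limit — a saturating linear-space ramp from zero
drives the input through the decades around Kd almost instantaneously
and fires the cell regardless of τ.  A zero start level is replaced by a
sensor floor of 1e−5 concentration units.

## Population model

N cells share one well-mixed extracellular pool:

    d[cAMP]ex/dt = αf + ρ·α0 + (ρS/N)·Σi Θ(Ai) − D·[cAMP]ex,  D = J + αPDE·ρ

with Θ the strict Heaviside (Θ(0) = 0); `αf` is an inflow *source rate*
(the reading consistent with the background-cAMP axis (αf + ρα0)/J), α0
basal secretion, S spike-driven release, J flow, αPDE·ρ degradation by
secreted phosphodiesterase.  Defaults: N = 100, α0 = 800, αPDE = 1e3,
S = 1e6.  At fast flow the field slaves to the quasi-steady value
`(αf + ρα0 + ρS·θ̄)/D`, so population behavior organizes on the axes
"background cAMP" B = (αf + ρα0)/J and "firing-induced cAMP" F = ρS/J.

The knee template used by the experiment suites is ρ = 2.5e−4, J = 10
(B = 0.02, F = 25 at the default S): collective oscillation there is
relay of stochastic accommodation spikes — a noise-triggered spike
releases cAMP, the fold-change kick recruits the rest of the population,
and the pool clears within 1/D.  Measured collective period at the knee
is ≈ 100 raw units (≈ 3.5 T).  Optional per-cell heterogeneity draws Kd
from a lognormal (configured median and log-sd shape; shape 1.0 ≈ one
decade of spread is used for the heterogeneity-only variant).

## Trace statistics

* **Spikes** — one spike per contiguous excursion of the signal above the
  baseline (0 for activator traces), timed at the excursion maximum;
  excursions shorter than 5 samples are discarded as noise crossings, and
  a `min_height` filter mirrors the 0.25 (single-cell) / 0.3 (population)
  FRET-unit spike filters.
* **Firing rates** — spike count / window.  Ensemble single-cell rate =
  mean of per-cell rates; population rate = rate of the population-mean
  trace.  Note that partial-recruitment events (40–90 % of cells firing
  together) can push the mean trace above zero, so the population rate
  may *exceed* the mean per-cell rate by up to ~20 % on the synchronized
  region's boundary — counting full events that individual cells
  occasionally skip.
* **Spike width** — first post-onset excursion, from the crossing of
  baseline + 5 % of the excursion peak to the return to baseline; NaN
  sentinel when no excursion or no return exists.
* **Oscillation period** — Hann-windowed periodogram, 4× zero-padding, DC
  excluded; the peak must pass a Fisher-style test (peak > (ln m + 4) ×
  mean ordinate, m = number of independent frequencies), which keeps the
  white-noise false-alarm rate near e⁻⁴ independent of trace length.
  For the irregular collective spike trains of the population model the
  mean inter-spike interval of the population-mean trace is used instead.
* **Entrainment quality** — mean Pearson correlation between the response
  in the first pulse period and each subsequent period-aligned window.
* **Bootstrap** — case resampling, percentile 95 % intervals, 2,000
  replicates.
* **Variability increase** — per condition, the cell-mean within-window
  standard deviation of single-cell traces normalized to a reference
  condition, with a bootstrap CI resampling cells.

## Experiment suites and regime labels

Phase diagrams map each (B, F) grid point to (αf, ρ, S, J) at fixed ρ, J:
`S = F·J/ρ`, `αf = max(B·J − ρα0, 0)`; per-point seeds derive from the
master seed and grid indices.  Desk-scale defaults: 16×16 grids (log axes
B ∈ [0.02, 2000], F ∈ [0.25, 250]), 1,200 raw time units per point with
240 discarded — roughly 25–40 collective periods.  The synchronized
"knee" is operationalized as the largest 4-connected region with
population rate ≥ 0.8× the single-cell rate and above 0.004 events per
raw unit, containing the lowest populated background row.

The external-cAMP step scenario labels each inflow level against the
αf = 0 reference using the collective inter-spike interval:
*synchronized* (population rate ≥ 0.8× cell rate, interval not
lengthened), *slowed* (collective events persist at > 1.25× the reference
interval — in this model these are partial-recruitment events, so no
pop/cell ratio is required), *silent* (population rate < 0.05× the
reference population rate and cell rate below the reference cell rate:
cells fall back to sparse stochastic firing), *asynchronous* (cell rate
at or above the reference but incoherent, population rate < 0.2× cell
rate).  The default levels αf = 0, 2, 10, 3e4 (B = 0.02, 0.22, 1.02,
3000) traverse the four regimes in order.

The density×flow scan uses log-lattice-aligned grids (ρ ∈ [2.5e−5,
2.5e−3] and J ∈ [10⁻⁰·⁵, 100], both in half-decade steps) so that ρ/J
values coincide across flow rates; the collapse score bins population
rates by log₁₀(ρ/J) and averages the across-J standard deviation within
bins.  The collapse holds at high flow and degrades at the smallest J,
where the field timescale 1/D approaches the spike width and secreted
phosphodiesterase (αPDE·ρ vs J) is no longer negligible.

## Synthetic FRET traces

The generator emits the three per-timepoint cell-averaged intensities of
a three-cube FRET measurement for a single-chain cAMP sensor that is in
a *low*-FRET state when bound: effective efficiency
`E(t) = E_high − (E_high − E_low)·fda(t)` with bound fraction `fda`.
Forward model (baselines B_D, B_A; bleedthroughs α = 0.054, β = 0.906;
relative donor/acceptor extinction γ_ext):

    F_D = B_D (1 − E) e^(−k_D t)
    F_A = B_A e^(−k_A t)
    F_F = (B_A E / γ_ext + β·B_D(1 − E) + α·B_A) e^(−(k_D + k_A) t / 2)

plus per-channel additive Gaussian noise clipped at zero.  The readout

    E·f_DA/γ_ext = (F_F − β F_D − α F_A) / F_A

is the exact algebraic inverse of the forward model in the noiseless,
unbleached limit (correctness is a round-trip identity), is homogeneous
of degree zero in the channels, and is exactly invariant under equal-rate
photobleaching; unequal rates distort it (the method's documented
limitation).  `−E·f_DA/γ_ext`, baseline-subtracted over a pre-stimulus
window, is the FRET signal in which cAMP spikes are positive; sensor
defaults (E_high = 0.5, E_low = 0.05, γ_ext = 0.5) put a full
accommodation spike at ~0.7–0.9 signal units so the 0.25/0.3-unit spike
filters operate on a realistic scale.

What the generator does *not* emulate: image formation, segmentation and
tracking, shot-noise scaling with intensity, per-fluorophore stochastic
bleaching within the sensor pair, movement artifacts.  Passing tests
therefore certify the correction algebra and the analysis chain, not
image-level robustness.  With intracellular noise on, the model produces
sub-spike humps whose FRET heights (~0.2–0.3 units) straddle the 0.25
filter; exact-count pipeline checks use deterministic multi-pulse traces
whose events sit far from the threshold.

## Numerical and design notes

* Heaviside uses strict inequality (Θ(0) = 0); the external field is
  clipped at zero every step.
* `np.roots` supplies cubic roots; roots with |Im| < 1e−9 are accepted as
  real.  The cubic is strictly monotone at the defaults, so the fixed
  point is unique at every drive.
* Slow passage through the Hopf point shows the expected bifurcation
  delay; oscillation amplitudes quoted "at a drive" on a ramp are
  peak-to-peak within a narrow drive window around that value.
* Up/down drive ladders (2 % steps, 300 raw units per rung) classify
  quiescent vs oscillating identically in both directions: no hysteresis.
* Desk-scale problem sizes (grids, horizons, seed counts) are stated
  inline above and in `scripts/acceptance.py`; doubling per-point
  durations or grid density does not change the qualitative structure
  (knee presence/absence, regime ordering, collapse).

## Known limitations

* The mean-field pool has no space: no waves, spirals or aggregation
  geometry.
* Long-timescale adaptation (gene-expression changes, damped oscillations
  under prolonged stimulation) is outside the model.
* The model does not reproduce experimental spike *shapes*, only their
  presence, width scaling and timing statistics.
* Experimental unit mappings (nM, minutes, cells/mm², µl/min) are
  conventions, not fits; only the qualitative/structural claims are
  transferable.
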