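# Methods

## Circuit model and assumptions

The NLIF neuron is a two-node RC circuit.  Node 1 (auxiliary voltage
`V1`) receives the input current and is tied to the negative bias
`V_dc1 = -V_d` through threshold switch S1; node 2 (membrane potential
`V2`) is tied to the positive bias `V_dc2 = +V_d` through S2, coupled to
node 1 by `R2` and loaded by `R_L`.  Nodal current balance gives

    C1 dV1/dt = I_in - (V1 - V_dc1)/R_S1 - (V1 - V2)/R2
    C2 dV2/dt = (V1 - V2)/R2 - (V2 - V_dc2)/R_S2 - V2/R_L

Assumptions built into the model:

* Threshold switches are ideal two-state resistors: exactly `R_on` when
  on, `R_off` when off (linear I-V in both branches), switching
  instantaneously when the magnitude of the voltage across the switch
  reaches `V_on` (off→on) or falls to `V_off` (on→off).  Comparisons are
  closed (`>=`/`<=`) for deterministic boundary behavior.
* The input is an ideal current source, so the series resistor `R1` has
  no dynamic role; it is stored for completeness and unused.
* Spike = one completed off→on→off cycle of S2, time-stamped at the
  on-switching event; *activity* = spikes per 30 ms observation window.

Reference parameter set (package defaults): `R2 = 100 kΩ`, `R_L = 1 GΩ`,
`C1 = 3 nF`, `C2 = 2 nF`, `V_d = 0.9 V`, switches `R_on = 50 kΩ`,
`R_off = 1 MΩ`, `V_on = 1.0 V`, `V_off = 0.5 V`; stimulus map
`I(s) = 1 µA · exp(-s²/(2·30°²))`.  With these values the sub-threshold
fixed point is (V2, V1) = (0.0428, -0.0429) V, the four switching lines
sit at V1 ≥ 0.1 / V1 ≤ -0.4 / V2 ≤ -0.1 / V2 ≥ 0.4 V, and the spiking
limit cycle is confined to that rectangle.

## Integration

Crank–Nicolson on the 2×2 linear system, with the switch resistances
frozen over each step and threshold checks applied to the new voltages
after the step (no sub-step event bisection).  Default `dt = 0.5 µs`,
two hundred times smaller than the smallest circuit time constant
(`R_on·C2 = 100 µs`); halving `dt` changes a 30 ms trace only at second
order (verified against an independent RK4 oracle in the test suite, and
by a Richardson convergence test with slope 2.0 ± 0.2).  Event timing is
accurate to one step; the convergence test guards the residual error.
The kernel is numba-compiled; one 30 ms trial costs about a millisecond,
which sets the problem sizes below.

Degenerate inputs: a singular step matrix (non-physical parameters)
raises; `duration < dt` raises; a trace with no events yields an empty
spike train (silent is a valid outcome, distinct from failure).

## Switching-noise protocol

Device variability is modelled as *noise, not heterogeneity*: after
every on- and every off-switching event, the parameters of the switch
that just transitioned are redrawn from Gaussians centered at the
nominal values with per-parameter relative standard deviations,
truncated by redraw (up to 1000 attempts) so that all values stay
positive, `R_off > R_on` and `V_on > V_off`.  Between events parameters
are constant, so resistance traces step-fluctuate.  Trials start at the
nominal means, which makes the pre-first-event transient exactly
noise-free; with zero deviations the noisy path is bitwise identical to
the noise-free one.  A `sample_initial` option additionally draws both
switches' parameters at trial start (a running device's parameters are
whatever its last switching cycle set them to).  This device-history
variant produces spiking well outside the noise-free active range and is
kept for population experiments that model an operating device, but it
conflates per-trial heterogeneity with operating noise — under it, the
per-parameter tolerance scans mostly measure whether the drawn starting
point can fire at all — so it is off by default.

For the combined-noise coding and population studies only `R_on` and
`R_off` fluctuate: `V_off` tolerance is far tighter than the resistance
tolerances and `V_on` variation has negligible effect on success, so
threshold-voltage noise is excluded there.

**Stuck-on failure**: the dominant noise-induced failure is S2 remaining
on (membrane potential pinned high, S1 stops switching).  A trial is
flagged stuck when S2 stays on continuously for longer than 10× the
noise-free mean inter-spike interval at the same drive, or is still on
at stimulus end for longer than 10× the noise-free spike width.  The 10×
multipliers are exposed in the run configuration; when the noise-free
circuit does not spike at that drive the limits fall back to duration/3
and duration/10.  Success in tolerance scans = at least one spike and no
stuck-on flag.  The degradation onset is reported as the smallest
deviation whose one-sided 95 % Clopper–Pearson upper bound on the
success rate falls below 0.95 (an "any failure is significant" rule
would trigger on a single failure in 100 trials).

## Variance–mean scaling

Mean activity saturates near 30 spikes/30 ms at strong drive — the
capacitor charging and discharging times bound the number of flickers a
window can hold — and at the ceiling the variance no longer follows a
power law.  `variance_mean_statistics` therefore fits
`log σ_n² = B log n̄ + log A` only over points whose mean is below 80 %
of the largest mean on the drive grid (`saturation_fraction=0.8`;
`None` fits every positive point).  A Poisson surrogate recovers
B = 1.00 ± 0.1 under the same estimator; the NLIF neuron at 10 %
resistance noise gives B ≈ 1.25–1.40 over 0.3–1.0 µA (8 drives,
100–200 trials each).

## Spike-train statistics

ISI distributions are fitted by maximum likelihood with Gamma and
exponential laws (`scipy.stats`, location fixed at zero); the recharging
of C1 imposes an effective refractory time, so the Gamma fit (shape ≈ 3)
beats the exponential.  The spike autocorrelogram (pairwise time
differences, self-pairs included, normalized to pair fractions) shows
the corresponding refractory trough and first-ISI bump at short lags;
beyond a few mean ISIs it is flat — ISIs are independent, renewal-like —
and the flatness test is asserted there (no long-lag bin above the flat
level by more than 5 SE over 30 pooled trials).

## Population decoding

A population of N identical neurons (default 20) has preferred
orientations evenly spaced over [-180°, 180°).  The likelihood
P[count | s] of each neuron is estimated by repeated noisy simulation on
a stimulus grid; a smoothing floor ε = 1/(2·repeats) is added to every
cell and columns renormalized, so an unseen count cannot zero the
decoding product (counts beyond the table range receive the column
floor).  Decoding applies flat-prior Bayes with the independence
product in log space; the posterior is summarized by a least-squares
Gaussian (amplitude, center, σ free; center initialized at the argmax
and constrained to the stimulus domain, σ ≤ 360°; moment fallback if the
fit fails).  The Poisson comparator decodes the *same* response patterns
with the closed-form independent-Poisson posterior, its rates matched to
the expected counts under the empirical likelihood (rate floor 1e-3).

Default study scale is reduced for desk runtimes: 50 grid stimuli ×
100 repeats × 20 neurons per deviation (denser grids and more repeats
are plain arguments).  (neuron, stimulus) cells that provably cannot
produce a switching event — noise-free event-free under the default
protocol, or DC-screened over ±6σ parameter draws with a 5 % margin
under the device-history variant — are filled with a point mass at zero
without simulation.

What the reduced scale can and cannot show: posterior centers at the
true stimulus and the growth of posterior width with deviation are
robust; the *difference* between the empirical decoder's width and the
Poisson comparator's is smaller than snapshot noise at this scale (and
the Gaussian-fit σ of a near-delta posterior on a 7.2° grid is
grid-limited), so the relative ordering of the two decoders' widths is
not a stable desk-scale observable in this implementation.

## Synthetic data and generalization

All spike data are generated by the simulator itself; the only
"synthetic data generator" beyond it is the Poisson count surrogate used
to anchor the scaling and decoding estimators.  The noise model captures
cycle-to-cycle switching variability with independent Gaussian draws; it
does not model drift, aging, correlated fluctuations between switches,
finite switching times, or nonlinear I-V branches, so passing tests
certify the circuit-level statistics of the idealized model, not device
physics.

## Known limitations

* The noise-free active range of the reference tuning curve extends to
  |s| ≈ 48° (firing threshold 0.273 µA under the Gaussian drive map),
  wider than the ±40° often quoted for this circuit by visual reading;
  the package reports what the model computes.
* Static operating-window requirements involve `V_off` only through the
  on-state drops (requirements iii/iv), where a *deeper* off-threshold
  is stricter; the widening of the operating window at lower
  `V_off/V_on` is a dynamic effect (a longer S1 on-phase gives S2 time
  to reach threshold) and is tested in the time domain, not in the
  static scan.
* Event handling is post-step (no bisection): event times carry an O(dt)
  bias that the dt-convergence test bounds but does not remove.
* The stimulus is treated as circular for neuron placement but linear
  for the Gaussian posterior fit near 0°; decoding stimuli near ±180°
  would need a circular fit.
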