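# Methods

`wcresonance` simulates a homogeneous patch of cortical sheet as a lattice
of loosely coupled Wilson–Cowan (WC) oscillators and measures how the
steady-state resonance frequency of an activated sub-network depends on its
size, node degree and transmission delays.  This note documents the model,
the numerical conventions the package commits to, and what the synthetic
protocols do and do not establish.

## The model

Each lattice unit represents a ~50 µm cortical minicolumn and contains an
excitatory (E) and an inhibitory (I) population:

    τ_E dE_i/dt = −E_i + σ( W_EE E_i + W_IE I_i + E_0
                            + Σ_j CE_ij E_j(t − d_ij) + f(t) + z ξ_m(i)(t) )
    τ_I dI_i/dt = −I_i + σ( W_EI E_i + W_II I_i + I_0
                            + Σ_j CI_ij E_j(t − d_ij) )

with the logistic response function σ(x) = 1 / (1 + e^{−m(x−n)}).  The
fixed operating point is W_EE = 23, W_II = 0, W_EI = 35, W_IE = −15,
E₀ = 0.5, I₀ = −5, m = 1, n = 4, τ_E = 14 ms, τ_I = 13 ms.  Inter-unit
excitation (CE = 0.15 per edge) targets E populations; inter-unit
"inhibition" (CI = 0.10 per edge) is excitatory activity targeting the
*inhibitory* population of the receiving unit.  ξ is Gaussian white noise
shared by all units of a 10×10 macrocolumn, drawn independently per
macrocolumn per step and scaled by z.  f(t) is the repetitive pulse-train
drive built from the gamma-like kernel q (t/w)^s e^{−t/w} (q = 0.5, s = 3,
w = 3.7 ms), restarted at each cycle of the driving frequency and applied
only to the E populations of the activated (masked) units.

**Units of the time constants.** τ values of 0.013–0.018 interpreted in
milliseconds would put the unit's dynamics three orders of magnitude above
the 1 ms integration grid; interpreted in seconds (13–18 ms), an isolated
unit oscillates in the alpha band, which is the regime all protocols probe.
The package therefore treats all τ values as seconds.

### Fixed points and the oscillatory branch

At the default weights the isolated unit has three equilibria: a
low-activity state (E* ≈ 0.214) that is an unstable spiral — the source of
the oscillation — a saddle near E ≈ 0.90, and a stable saturated state
(E* ≈ 0.984).  `uncoupled_fixed_point` returns the **lowest-E** root,
found by reducing the E nullcline to a one-dimensional bracketed root
problem (damped Picard iteration cannot reach this root: the fixed-point
map has spectral radius ≈ 3.6 there and converges only to the saturated
state).  All simulations start on the oscillatory branch; the saturated
state acts as an absorbing trap for strongly excited networks, which is
the practical stability limit of the model (see Limitations).

## Integration

Euler–Maruyama with dt = 1 ms.  Two conventions are part of the numerical
contract:

* **Sequential (Gauss–Seidel) population update.** Within a step, E is
  updated first and the *updated* E enters the intra-unit term of the I
  equation.  This choice is empirically forced: it is the only Euler
  variant at dt = 1 ms that reproduces the isolated unit's published
  spectral-peak sequence (7.8 → 12.6 Hz as τ_I falls from 17 ms to 13 ms
  at τ_E = 18 ms) and it stabilizes the oscillatory branch against capture
  by the saturated state.  The simultaneous-update variant misses those
  peaks by ~2 grid positions and loses the rhythm entirely at
  τ_I = 17 ms.
* **Delay history.** Delayed inter-unit inputs read E values `delay`
  steps in the past from a circular buffer whose length is the maximum
  delay + 1; pre-history values equal the initial state, and a delay of 0
  reads the pre-update value of the current step.  The buffered kernel is
  certified against a naive full-history reference implementation to
  1 × 10⁻¹² on small delayed networks (the two share the exact
  floating-point association order, since the oscillation's local
  instability amplifies even last-bit differences).

The noise term is drawn per macrocolumn per step as z·N(0, 1) and added
inside the sigmoid argument, exactly where the model equation places it;
no √dt rescaling is applied.  This convention is pinned by the
single-unit spectra: with a √dt-scaled term the published peak sequence is
missed by 5–7 Hz.

Because the sigmoid argument is clamped at ±500, state blow-up is only
possible for pathological parameters (dt ≫ τ); the integrator checks
finiteness each step and reports the failing step index.

### Burn-in

Each trial integrates 500 extra steps (0.5 s) before the analyzed samples
and discards them.  The onset transient — ringing at the network's
spontaneous rhythm while the drive's steady state develops — otherwise
contaminates the low-frequency response bins and biases the resonance
curves' argmax downward by 1–1.5 Hz.  Discarding 500 ms after stimulus
onset is also the convention the corresponding EEG steady-state analyses
use.  `SimulationConfig.burn_in_steps` defaults to 0 (the integrator is
neutral); the protocol configurations set 500.

### Step-size sensitivity (known limitation)

The operating regime is *not* robust to changing dt.  At dt = 0.5 ms the
30×30 network's noise-driven trajectories escape to the saturated state
and the rhythm collapses; at dt = 2 ms the spontaneous peak shifts up by
~1.5 Hz.  This is a direct consequence of the bistability described above
together with the dt-dependence of the sequential sweep's stabilizing
effect.  The step-halving property test documents this honestly and fails.

## Connectivity generation

* **Local edges.** Every unit receives exactly `k_exc` excitatory and
  `k_inh` inhibitory out-edges (defaults 5/5).  Targets are drawn by
  sampling 2-D Gaussian offsets (SD 250 µm = 5 lattice steps), rounding to
  the nearest site, and rejecting self-targets, duplicates, and offsets
  beyond the 700 µm (14-step) cutoff.  Redraw-to-exact-degree is the
  simplest construction honouring both the stated Gaussian fall-off and
  the stated mean degree of 5.
* **Long-range edges.** `round(0.25 × local excitatory edge count)`
  additional excitatory edges drawn uniformly over ordered unit pairs,
  rejecting self-edges, duplicates, and targets within the local cutoff of
  the source (so "long-range" is well defined).  The degree-scan
  protocols freeze this count at its degree-5 value while the local degree
  varies.
* **Delays.** Every edge's delay is `round(rate × torus distance)`
  integration steps (round-half-away-from-zero), with the default rate of
  10 steps per unit lattice distance; distances use per-axis wrap-around
  (periodic boundaries).  Inhibitory edges carry delays under the same
  rule.  Rate 0 gives instantaneous transmission.
* **Lateral inhibition.** For a driven mask, existing excitatory edges
  from inside to outside are zeroed and existing inhibitory edges in the
  same orientation are set to weight 1 (the maximal CI entry).  No new
  edges are created: the construction rescales the already-generated
  connectivity matrix entries rather than densifying the surround.
* Edge sets are generated independently (connectivity is not reciprocal);
  a fixed seed reproduces a network bit-for-bit, and the plain-text
  edge-list serialization round-trips exactly.

## Spectral statistics

Spectra are |FFT|² of the mean-removed mask-averaged series at positive
frequencies, normalized to unit area with the DC bin excluded — the
statistics of interest are oscillatory, and including DC would let the
standing offset of E dominate every spectrum.  No tapering is applied:
trial lengths are integer multiples of the drive periods on the protocol
grids, so rectangular-window leakage is minimal.

Response power at the drive is the normalized power in the bin nearest the
driving frequency; the three-nearest-bin maximum (`ssep_response_power`)
is provided for externally recorded epochs whose stimulation frequency may
fall between bins.  Bootstrap statistics resample trials with replacement
(default 1000 resamples), average the resampled spectra, and evaluate
either the response at the drive bin (resonance curves) or the drive
frequency of maximal response across a scanned grid (scan protocols);
frequency ties break toward the lower frequency.  The bootstrap RNG is
seeded independently of the simulation RNG.  Trend lines are ordinary
least squares with R² and the two-sided slope p-value from the t
distribution.

## Protocols and problem sizes

Each protocol derives all of its randomness from one seed through named
sub-streams (connectivity, trials, bootstrap), uses one connectivity
realization per condition shared across that condition's trials, and
exposes `scale`, which multiplies only the trial and bootstrap counts
(floored at 5 trials / 100 resamples) — never model parameters, grids or
trial lengths.  The shipped defaults are the published operating points
(50×50 size protocol at 100 trials × 2000 samples; 30×30 scans at 5000
samples; degree scans at z = 0.07 with delay 0; drive grids 10–15 Hz in
0.5 Hz steps, 12–14 Hz and 12–17 Hz in 0.2 Hz steps; 6–13 Hz for the
single unit).  The acceptance script runs the size protocol at 20
trials/frequency, the delay scan at 5 trials/condition, the degree scans
at 5 trials/condition and the single-unit scan at 30 trials — sizes chosen
so a complete from-scratch reproduction runs on one desktop core in under
twenty minutes while keeping the bootstrap statistics meaningful.

## What the synthetic protocols do and do not show

The generator *is* the study system — there is no external data — so
passing protocols demonstrate properties of the model, not of cortex:
that an isolated unit's resonance is set by τ_I/τ_E; that a driven patch
entrains over a band whose edges move with coupling structure; that the
activated patch, not the whole lattice, determines the measured response.
Real EEG adds volume conduction, heterogeneous conduction velocities,
non-stationary background rhythms and measurement noise, none of which are
modelled.

Two published network-level findings do **not** reproduce under this
re-implementation with the printed parameters, and the package reports
them as computed rather than adjusting the model: (1) the negative
dependence of resonance on transmission delay — at 10 steps per unit
distance the typical local delay (50–70 ms) already exceeds half an
oscillation period, outside the linear delay-slowing regime of
delay-coupled oscillator theory, and no delay mapping we tested restores a
clean negative trend; (2) the negative dependence on excitatory degree —
here added excitation widens the entrainment band upward until the network
is captured by the saturated state.  The inhibitory-degree trend
reproduces in direction (resonance rises from ~13.1 to ~14.8 Hz as the
inhibitory degree grows from 0 to 5) before a grid-edge artifact takes
over, and the headline size effect reproduces at the one-bin level (both
patches peak near 13.0 Hz, within one 0.5 Hz bin of the published 13.5 and
12.5 Hz).  The single-unit results reproduce exactly.

## Numerical details worth knowing

* Sigmoid exponent argument clamped to ±500; inert in the operating range.
* Drive cycle onsets are placed at multiples of 1/f rounded to the grid;
  the kernel restarts at each onset rather than summing overlapping tails
  (at ≥8 Hz the kernel has decayed below 2 % of its peak by cycle end, so
  the constructions nearly coincide; restart is exactly periodic and
  deterministic).
* The connectivity sampler refuses configurations it cannot satisfy
  (local degree exceeding the sites within the cutoff; long-range edges on
  a lattice whose diameter does not exceed the cutoff).
* A constant series has no normalizable spectrum and is rejected; the
  z = 0 control in the noise scan reports NaN for that condition instead
  of failing.
* Degenerate sub-networks (a single unit) report mean degree 0 and NaN
  mean delay.
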