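# Methods

## Model

The analog represents a dosed subject as five equally sized 2-D grids —
dissolution, GI/tissue spaces A, B and C, and plasma — plus a scalar
eliminated pool and an integer clock. Site amounts are continuous
non-negative reals: the published transfer rules act on *fractions* of a
site's amount, which is ill-defined for indivisible objects, so the "number
of drug objects" is treated as an amount scale. The dose is spread uniformly
over the dissolution grid at initialization.

Six transfer channels connect the spaces: dissolution→GI (split between A
and B by `diff_g_ratio`), A→C and B→C (one shared delay/fraction/probability
triple applied independently to each), A→plasma, B→plasma, C→plasma, and
plasma→eliminated. Each channel carries three parameters: an initial delay
(time steps), the fraction of a site's amount moved per firing, and the
Bernoulli probability of firing, drawn independently per site per cycle. The
delay is gated on the *global* clock (no per-site clocks): a channel fires in
the cycle executing at clock `t` iff `t >= delay`. All five grids share the
same dimensions and "corresponding sites" means identical coordinates.

### Event schedule

One cycle executes, in order: (1) elimination from plasma; (2) transfer from
A, B and C to plasma (sub-order fixed A, B, C — the class ordering alone is
prescribed, so the sub-order is pinned down here so the deterministic-limit
oracle is well defined); (3) dissolution→GI with the A/B split. The
remaining events — A→C, B→C, and dispersion on each of the five grids — run
in a fresh pseudorandom permutation drawn each cycle from the simulation
RNG. The clock then increments. Measurements are taken at the end of every
cycle and stamped with the post-cycle clock (1..n), which together with the
one-step mapping offset places the first reportable sample at t_r = 0.

A consequence of the ordered classes is that drug entering the GI spaces in
cycle `k` cannot reach plasma before cycle `k+1`, and drug entering plasma
cannot be eliminated in the same cycle it arrives. This gives the exact lag
relation `t_lag = d_to_g_delay · x_scale` for profiles sampled on the cycle
grid — the property that reproduces the fasting/fed panel lag means.

### Dispersion kernel

Intra-grid mixing uses a synchronous discrete kernel: per iteration each
site sends `disperse_rate/4` of its amount to each von-Neumann neighbor,
computed from a snapshot; shares directed out of bounds remain at the source
(no-flux boundary); afterwards every site is multiplied by `1 − evap_rate`.
The kernel conserves mass when `evap_rate = 0`, leaves uniform fields fixed,
and runs `disperse_count` iterations per cycle. The original kernel is
specified only by its rate/loss/iteration-count semantics, so this concrete
kernel was chosen as the simplest one with the stated conservation
properties; on aggregate (grid-total) outcomes its exact form is immaterial
because transfers are spatially homogeneous.

### Randomness and determinism

All stochasticity flows from one `numpy` PCG64 generator seeded per run:
one uniform per site per *active* channel per cycle (delay-gated channels
consume nothing), then one 7-event permutation. Identical (parameters,
seed, cycles) therefore give bit-identical trajectories. In the
deterministic limit — 1×1 grids, all probabilities 1 — the engine reduces to
a scalar difference-equation system; the test suite codes that system
independently and checks bitwise agreement over 100 cycles, including
nonzero evaporation (where the per-cycle permutation affects the arithmetic
order, which the oracle re-derives from the seed alone).

## Parameters

Defaults produce the stock single-peak profile: 100×100 grids, dose 10000,
dissolution→GI and GI→plasma and elimination all at fraction 0.1 /
probability 0.8, `diff_g_ratio` 1 (everything through space A), space C
disconnected, dispersion rate 0.1 × 2 iterations, no evaporation,
`x_scale` 1, `y_scale` 120. Under these defaults the plasma total still
rises at cycle 20; its single maximum sits at the end of the sampled window,
so "one peak" is counted with boundary maxima included (a two-peak profile
counts 2 under the same rule).

The twelve shipped subject files set only the parameters that vary by
subject and condition (`x_scale` is globally 0.45 h/cycle; `y_scale` and the
channel triples are per subject/condition); unlisted fields take the
defaults, which apply automatically at initialization. Multi-peak fed
profiles arise from small `diff_g_ratio` (most drug routed to the slow B
path) combined with large B→plasma and C→plasma delays.

The default run length is 20 cycles, covering the sub-8-hour sampling window
at 0.45 h/cycle (samples at 0, 0.45, …, 8.55 h).

## Unit mapping and NCA

`t_r = (t_s − offset)·x_scale` with `offset = 1`; mapped times below zero
are discarded rather than clamped, so profiles start at t_r = 0.
`C = A_plasma·d/y_scale`; the referent dose `d` is a required scalar with
default 1 — its clinical value is not published, so absolute concentrations
are reproducible only up to `d`, while all time-domain quantities are
unaffected.

NCA conventions follow standard noncompartmental practice: `c_max` is the
maximum sampled concentration, `t_max` the earliest time attaining it
(ties break early), `t_lag` the time of the last zero sample before the
first measurable one (0 if the first sample is measurable, NaN if the
profile never leaves zero), and `auc_all` the linear trapezoid over all
samples. No terminal-phase parameters are estimated — the observation
window is too short for reliable λz fits.

## Similarity criteria

Validation compares profiles on the referent's time grid; the simulated
curve is linearly interpolated, never extrapolated (uncovered
referent-nonzero points fail the check rather than being dropped). Checked
points are those with nonzero referent value; band membership is closed,
`|sim − ref| ≤ b·ref`. The stock criteria are outer band 0.30, inner band
0.10, minimum inner count 4, with the inner band counted as a subset of the
outer. Zero referent values are excluded because a relative band is
undefined there; a simulated zero at a nonzero referent point counts as 100%
deviation. Loosening any of the three knobs is monotone: a pass stays a
pass.

## Experimentation

Panels run the six subjects of one condition with a shared seed list,
average NCA metrics across seeds per subject, then report across-subject
mean ± SD (n−1). Seeds are replicated (default ≥10) because the engine is
stochastic even though single runs suffice at the 100×100 grid size — the
across-seed dispersion of the panel means is reported alongside so the
Monte-Carlo noise floor is visible. Sweeps rerun one parameter from a shared
base with the same seed list per value. Every batch result carries a
manifest (seed list, parameter hash, cycle count, package version) so any
reported number is re-derivable.

The refinement loop exposes a pluggable proposal rule rather than a built-in
optimizer, since published parameter adjustment was manual and heuristic.
Iteration `i` asks the rule for a parameterization (passing the previous
similarity report), simulates with seed `seed + i − 1`, and validates;
the loop stops at the first pass or reports "falsified" when the budget
(default 100 iterations) is exhausted — an outcome, not an error. A simple
random-search rule is included; it leaves the first iteration's parameters
untouched so a known-good start validates immediately.

## Synthetic referents

Real observed plasma profiles are external data, so validator tests use a
synthetic generator: a sum of Gaussian peaks sampled at fixed times with
multiplicative truncated-normal noise of a chosen CV. This reproduces the
features the validator cares about — single versus multiple peaks, lag
segments of zeros, noise around a smooth curve — but not the physiology of
real profiles (asymmetric absorption/elimination shapes, correlated assay
error), so passing the validator tests demonstrates correctness of the
banded comparison, not clinical fidelity of any particular profile.

## Numerical choices and limitations

Float64 throughout; mass balance holds to ~1e-12 relative over 20 cycles
(tested at 1e-9). Non-negativity is structural: transfers remove at most
`fract ≤ 1` of a site and dispersion redistributes at most `rate ≤ 1`.
The panel tests use 20 cycles × 20 seeds × 100×100 grids, which runs in a
few seconds; grid-size insensitivity of aggregate outcomes is checked
against 200×200.

Known limitations: space C's two inflows share one parameter triple, so A→C
and B→C cannot be tuned independently; two parameters named in the source
material's delayed-effect list (`MaxCencentration`, `DispersionOn`) have no
published housing and are not implemented; absolute concentration outputs
depend on the unpublished referent dose; and the refinement loop makes no
claim to reproduce any particular manual search path.
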