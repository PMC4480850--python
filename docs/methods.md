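# Methods

## Model and assumptions

The cable is a single effective polymer of `l ≥ 0` subunits; the 2–4
bundled filaments of a real cable are not resolved.  Its state is `(l, s)`
with `s ∈ {ON, OFF}` the chemical state of the formin at the growing end.
Transitions and rates:

| event          | rate       | condition |
|----------------|------------|-----------|
| polymerize     | `r`        | ON        |
| polymerize     | `r_off`    | OFF (0 by default) |
| depolymerize   | `d`        | `l > 0`, either state |
| inhibitor bind | `w·l`      | ON        |
| inhibitor unbind | `k_off`  | OFF       |

The linear binding rate is the antenna effect: motors land uniformly along
the cable and walk to the formin without detaching, so the inhibitor
delivery rate is proportional to cable length.  Growth while inhibited is
taken as zero; the qualitative behavior needs only `r_off < r`, and
`r_off` is exposed as a parameter (default 0) so that assumption can be
relaxed.  All rates are per second; lengths are integer subunit counts,
converted to microns at the fixed integer convention 370 subunits/μm
(not 1/0.0027 μm = 370.37 — the integer convention is used for parity with
how these quantities are conventionally quoted).

**Boundary at l = 0.** Depolymerization is disabled at zero length
(reflecting boundary).  A cable that shrinks to zero while inhibited waits
for unbinding; with `r = d = 0` the origin becomes absorbing and the
simulator flags the trajectory.  The master-equation generator and the
stochastic simulator share one transition-rule function
(`antenna.gillespie.transition_rates`), so the boundary convention cannot
drift between them.  For in-vivo-like parameters the stationary mass near
`l = 0` is negligible and the convention is immaterial.

## Analytic layer

Averaging over switching at fixed length gives
`r̄(l) = (r·k_off + r_off·w·l)/(k_off + w·l)`.  Setting `r̄(⟨l⟩) = d` yields
`⟨l⟩ = (k_off/w)(r/d − 1)` and its two inversions `solve_for_d` and
`solve_for_w` (used to pair `(k_off, w)` values sharing one mean).

In the fast-switching limit the length process is an effective birth–death
chain with birth rate `r̄(l)` and death rate `d`, whose stationary law obeys
detailed balance `P(l+1)/P(l) = r̄(l)/d`.  `stationary_distribution_recursive`
accumulates the log-ratios and normalizes once (log-sum-exp), which is exact
to floating point at means of thousands of subunits.  Support extension: the
support grows in blocks until the probability over the last 50 states falls
1e-14 below the running maximum *and* a geometric bound on the remaining
tail is below 1e-10, with a hard cap of 5×10⁶ states (explicit error beyond
it).  For `r_off = 0` the detailed-balance product telescopes to the
Gamma-function form `P(l) ∝ (r/d)^l (k_off/w)^l Γ(k_off/w)/Γ(k_off/w + l)`,
implemented via log-Gamma as `stationary_distribution_closed_form` — a
cross-check of the recursion, never the normative result.

Two exact facts worth noting because tests rely on them:

- The detailed-balance law depends on `(k_off, w)` only through `w/k_off`,
  so it is *identical* across fixed-mean parameter pairs; the variance
  reduction at fast switching is invisible to it by construction.
- Its mean matches the exact (master-equation) mean essentially perfectly in
  every regime probed (the exact mean sits one subunit above the
  rate-balance formula), while its variance can be an order of magnitude
  too small when switching is slow: switching noise, not birth–death shot
  noise, dominates the width in the slow regime.

## Stochastic simulation

`simulate` is a textbook Gillespie loop (numba-compiled): exponential
waiting times in the total propensity, event choice proportional to rates.
Steady-state sampling defaults to one length per independent trajectory at
`t_end` (no autocorrelation); thinned within-trajectory sampling is opt-in,
and all standard errors are bootstrapped across whole trajectories (400
resamples) so correlated samples never shrink the error bars.  Each
trajectory runs on its own substream: 31-bit kernel seeds are drawn from a
`numpy.random.SeedSequence` of the user seed, deduplicated, and assigned per
trajectory, so results are reproducible and independent of scheduling.

**Switching-aggregated exact sampler.**  In stiff-switching regimes almost
all events are bind/unbind.  At the fast-switching reference parameters
(`r = 0.2, d = 0.001, w = 10, k_off = 40`) the stationary point is
`l* ≈ 800`, switching produces ~80 events/s, and the length
autocorrelation time is `τ ≈ σ²/(r̄+d) ≈ 8×10⁵ s` — so one effectively
independent stationary sample costs ~10⁸ direct events, and an
equilibrated 3000-trajectory ensemble is out of reach by direct stepping.
Between length events, however, the length is constant and the formin is a
two-state Markov chain with fixed rates, so the number of complete ON→OFF→ON
cycles before the next length event is geometric
(success probability `1 − (w·l/a_on)(k_off/a_off)`, with
`a_on = r + d + w·l`, `a_off = k_off + d`) and the waiting time is a sum of
Erlang variables in the two sojourn rates.  Sampling (cycle count, Erlang
times, terminal event) costs O(1) per *length* event and reproduces the
direct sampler's law exactly — event types and sojourn durations of
competing exponentials are independent, so no approximation enters (this is
not tau-leaping or a hybrid scheme).  A test validates the two samplers
against each other and against the master equation on parameters where both
are affordable; the fast-regime agreement suite then uses the aggregated
sampler with a 1.2×10⁷ s horizon.

## Master-equation oracle

The truncated generator over states `(l, s)`, `l ≤ l_max`, is assembled
sparsely (columns sum to zero; `dP/dt = Q·P`) with upward transitions out of
`l_max` removed.  The stationary vector is obtained by replacing the
(redundant) balance row of a reference state near the analytic mean with
`p[ref] = 1` and solving the banded sparse system, then normalizing; pinning
near the mode keeps every entry ≤ O(1) so distant tails underflow harmlessly.
(A dense normalization row `Σp = 1` was tried first and rejected: it
destroys bandedness and the LU fill-in is quadratic in the state count.)
The truncation starts at `2×⟨l⟩ + 200` states and grows by 1.5× until the
stationary mass within 50 lengths of the boundary is below 1e-10.
Transients integrate `dP/dt = Q·P` with BDF and the exact sparse Jacobian
(`rtol 1e-8`, `atol 1e-12`); a raw mass defect above 1e-8 at any output time
is an error, and outputs are renormalized.

## Distribution comparisons

Agreement between distributions is measured in total variation,
`TV = ½·Σ|p − q|`.  Analytic-vs-analytic comparisons use single-subunit
resolution.  Comparisons involving an *empirical* distribution first
aggregate both sides into bins of about half the reference standard
deviation: on supports thousands of subunits wide, single-subunit TV
between an n = 1000 sample and a smooth reference has a finite-sample floor
of ~0.5–0.7 regardless of agreement, while σ/2 bins put the floor near
0.03 at the sample sizes used, well below the 0.05 thresholds in the
agreement tests.  The bin width used is recorded in every report.

## Experiments and problem sizes

The canonical sweep grids are `k_off = 0.5–5.5` step 0.0625 (fixed
`w = 0.004`), `w = 0.0008–0.01` step 0.000125 (fixed `k_off = 1`), and the
fixed-mean pairing `k_off = 0.5–20` step 0.125 with `w` from the mean
inversion at 5 μm; `smoke()` keeps every 8th point.  Figure-quality runs
default to 1000 trajectories per condition with a 500 s burn-in (the
relaxation time under in-vivo rates is tens of seconds and the distribution
is stationary well before 500 s); both are configurable and recorded in
every output row and manifest.  The test suite runs the sweeps at smoke
scale with 300–400 trajectories, uses the deterministic master-equation
solution for strict monotonicity claims (variance and CV² trends), and
reserves the stochastic runs for mean agreement and endpoint contrasts —
statistical assertions are sized so that their false-failure probability is
small (aggregate z-score bounds rather than per-point 3σ gates across
20-point grids).

Sweep tables report the sample mean, variance and CV² with bootstrap
standard errors, next to the rate-balance mean.  The sample mean of the
right-skewed length distribution is itself mildly heavy-tailed at a few
hundred trajectories; occasional ~4σ excursions of a single grid point are
expected and are why sweep functions record rather than assert agreement.

## What the model does and does not emulate

Simulated lengths emulate the steady-state and transient statistics of
single cables under constant cytoplasmic conditions: no finite monomer
pool (the `estimates` module bounds that effect separately), no severing,
no bundle substructure, no cell-scale geometry (a cable may exceed the
cell diameter), and no motor traffic jams (delivery stays linear in
length).  Passing tests therefore validate the mathematics of the antenna
feedback, not the completeness of the in-vivo picture; the Discussion-style
estimates quantify exactly where the single-mechanism picture fails
(pool-limited 18 μm and severing-limited 45 μm cables versus ~5 μm
observed).

## Parameter conventions

- `d` from the mean-length inversion is 44.05 subunits/s (0.12 μm/s to two
  decimals).  Simulations conventionally use the rounded `d = 45`; both are
  presets (`YEAST`, `YEAST_EXACT_D`).  The provenance table reports the
  full-precision value with nearest-integer rounding (44) — 45 is a
  quoting convention, kept for comparability, not a recomputation.
- Rounding is explicit per quantity: `w` to one significant figure,
  `d` in μm/s to two decimals, micron lengths to the nearest micron.
- The actin pool from concentration × volume is 3.9×10⁵ molecules; the
  conventionally quoted 3×10⁵ agrees only to order of magnitude, and the
  finite-pool estimate uses the quoted 3×10⁵ as its input.  Both numbers
  are reported side by side.

## Known limitations

- The aggregated sampler requires `r_off = 0` (the telescoping of ON/OFF
  cycles assumes no growth while inhibited); use the direct sampler
  otherwise.
- The detailed-balance recursion silently loses accuracy (variance only)
  as switching slows; use the oracle or the simulator when
  `k_off + w·⟨l⟩` is not ≫ `max(r, d)`.
- The transient solver's cost grows with the truncation size; for means
  beyond ~10⁴ subunits prefer the simulator for time-resolved questions.
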