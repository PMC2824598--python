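# Methods

## Model

The network is a list of 39 elementary reactions over 16 species
(free, phosphorylated and complexed forms of p53, Mdm2 and MdmX, p53
oligomers, the target promoter and its complexes, and Mdm2 mRNA), all
treated as deterministic mass action; homodimerisation flux follows the
standard convention k·x². Two variants are compiled from the same
list: the *simple* model (x₁–x₁₄, rows 1–33) in which promoter-bound
p53 tetramers produce Mdm2 directly, and the *full* model (x₁–x₁₆,
rows 1–32 and 34–39) in which transcription produces mRNA that
produces Mdm2, plus a basal transcription route through a
p53-monomer:promoter complex. One printed symbol, k33, is
variant-scoped: it is the direct Mdm2-production rate in the simple
model and the mRNA-production rate in the full model; each built-in
parameter column stores the value appropriate to its own variant.

Structural facts used throughout: the promoter moiety
(x₁₃ + x₁₄ [+ x₁₆]) is conserved by every reaction, and the pure
binding/dissociation rows conserve the subunit-weighted totals of all
three proteins (dimers count twice, tetramers four times).

### Rate-constant sets

Six columns are built in. `col4` (simple; exploratory early-response
set), `col5` (simple; oscillatory set used for the k₁ bifurcation
diagrams, where the damage level is k₃ = 0.0086851), `col6` (simple;
delayed-feedback set, 50-time-unit delay on Mdm2 production), `col7`
(simple; heterodimer-knockout control), `col8` and `col9` (full;
fitted sets from the two oscillatory regions of parameter space —
`col8` is the MdmX-sensitive one). Cells published as scan ranges are
stored as scan-axis metadata with the log-midpoint (middle element for
discrete lists) as default; every reproduction routine sets them
explicitly. The full-model basal p53 production k₁ is state-dependent
(0.003 resting, 0.01 under damage, reflecting enhanced p53 translation
after damage); protocols switch it automatically.

The total promoter concentration is not published; the default is 1.0
concentration unit and is configurable (`ParameterSet.promoter_total`).
This is the one unconstrained scale in the model; see *Known
limitations*.

## Protocols

**DNA damage** is a constant kinase input: k₃ = k₈ = k₁₇ switch from 0
to a common positive value at t = 0 and stay there (ATM activity
saturates fast and persists). Early-response studies **pre-equilibrate**
the damage-free system first; late-response (oscillation) studies start
from the documented default state (everything zero, free promoter at
its total) because the limit cycle does not depend on the transient.
Early activity is read as x₁₄ at t = 55 AU (simple model) or the
maximum of mRNA x₁₅ over 0–180 min (full model); the late window is
10020–10980 min.

**Nutlin** blocks only p53–Mdm2 association: pre-equilibrate with
k₁₁ > 0, then set k₁₁ = 0 with every other rate at its resting value,
and report subunit-weighted total p53/Mdm2/MdmX as fold change over the
pre-treatment totals.

**MdmX pulse** (memory effect): piecewise-constant multiplier on k₁₅
(default 1× / 100× / 1× for 2000 min each) with the state carried
continuously across phases.

**Delayed feedback**: in the simple model the Mdm2-production flux may
lag the promoter occupancy, flux(t) = k₃₃·x₁₄(t−τ) with τ = 50. Solved
by the method of steps with constant pre-damage history and internal
step bounded by τ/20; τ = 0 reproduces the ODE path exactly, and the
machinery is validated against a piecewise closed form on a degenerate
network.

## Steady states and pre-equilibration

At any steady state of this network the phospho-oligomerisation
cascade is in detailed balance (dimers, tetramers and the
promoter complex have no sink other than dissociation), the
heterodimer reservoirs are flux-balanced, and Mdm2, mRNA and the
promoter complexes are explicit functions of free p53 — so the whole
system reduces to one scalar monotone balance for free p53, solved by
bracketed root finding (`steady_state_reduction`). A corollary that the
package exposes and tests: steady levels of all

non-MdmX species are independent of the MdmX production rate k₁₅.

Pre-equilibration uses this reduction directly (with the damage rates
zero the reduction is unconditionally valid) and verifies
‖f‖∞ < 1e−9·(1+‖x‖∞). This matters practically: at high Mdm2
production the resting Mdm2:MdmX reservoir is ~10⁴ concentration units
and fills on a ~10⁹-time-unit scale, so integration alone cannot reach
it; the reservoir state at damage onset is exactly what drives the
switch behaviour, so getting the true equilibrium is not optional.
A general damped, state-rescaled Newton (`solve_steady_state`) backs
the reduction for verification and for arbitrary guesses.

## Bifurcation analysis

The conserved promoter makes the full-state Jacobian structurally
singular, so all Newton solves and eigenvalue analysis run in reduced
coordinates with the free promoter eliminated. Branches over a control
parameter (k₁ or k₁₅) are traced with the scalar reduction (Newton
continuation with step-halving as fallback); stability comes from the
analytic mass-action Jacobian; Hopf points are bracketed by sign
changes of the leading complex pair and bisected to 1e−6 relative.

**Sub/supercritical classification.** The original plan — fitting the
square-root amplitude law just past onset — fails in practice on the
oscillatory simple-model set: cycle periods near onset are 13,000–19,000
AU and linear growth rates ~1e−5, so any affordable amplitude
measurement is transient-contaminated. The implemented classifier uses
the defining hysteresis property instead: seed a trajectory on the
oscillatory attractor (10% into the unstable side), move the control
2% past onset onto the stable side, integrate ~50 cycles, and measure
the per-cycle amplitude envelope. A subcritical point sustains the
large cycle (envelope ratio ≈ 1); a supercritical point lets it decay
to the focus (ratio → 0); the threshold is a factor 2. On the col5 set
this separates the three cases by wide margins (ratios 0.002 / 1.000 /
0.340 for k₁₅ = 0 / 0.2 / 0.6 → super / sub / super). The amplitude
law itself lives on in `classify_amplitude_scaling`, validated on the
Hopf normal form.

Periodic orbits (stable or unstable) can be computed directly by
single-period shooting in reduced coordinates — unknowns are the
initial state and the period, the phase pinned by orthogonality to the
flow at the guess — with Floquet multipliers from a finite-difference
monodromy matrix.

## Parameter-space search

Stage 1 searches 15 rate constants (p53/Mdm2 core and transcription)
for oscillatory damage responses, with the remaining constants tied
(k₇ = k₅ = k₂, k₁₄ = 0.2·k₁₃, k₈ = k₃, k₉ = k₄ = 0.02·k₃); candidates
that keep maximal p53 activity above 1e−4 pass the oscillation floor.
Stage 2 refines 11 constants (k₂, k₃, k₆, k₇, k₁₅, k₁₆, k₂₃, k₂₅,
k₃₄, k₃₆, k₃₈; the ties k₁₀ = k₁₇ = k₃, k₄ = k₉ = k₁₈ = 0.02·k₃)
against a composite score. The search itself is a radius-growing
random neighbour walk in log₁₀ space: uniform candidates within R
decades of the centre, centre moves on any improvement, R doubles
after 200 stagnant evaluations up to 2 decades; fully deterministic
given the seed.

Fitness: the oscillation score is the lag-maximised normalised
cross-correlation (per-overlap mean subtraction, so an exact
subsequence scores 1; zero-variance input scores 0 with a flag)
between simulated total p53 and the target pattern. The composite
stage-2 score is the equal-weight mean of three [0,1] terms: the
cross-correlation mapped (s+1)/2, exp(−RMSE) of the Nutlin total
p53/Mdm2 fold-change curves, and exp(−mean |log ratio error|) of the
resting Mdm2/p53 and MdmX/Mdm2 totals. The 0.25 success threshold is
meaningful under this monotone mapping; the `col9` set scores ≈ 0.38
against the default synthetic targets.

## Synthetic calibration targets

The original calibration data are figure-derived and not numerically
published, so `p53mdmx.targets` generates stand-ins carrying the
field's headline features: a pulsatile oscillation series (raised-cosine
pulses every 360 min — the ~6 h peak-to-peak interval of damage-induced
p53 pulses — with configurable count, width, damping and smoothed
Gaussian noise), Nutlin fold-change curves 1 + (plateau−1)(1−e^(−rt))
with default plateaus 3.0 / 3.0 / 1.5 for p53 / Mdm2 / MdmX and
r = 1/240 min⁻¹ (a few-fold accumulation over several hours), and
resting ratio targets Mdm2/p53 = 2, MdmX/Mdm2 = 1 (order-of-magnitude
plausible for an Mdm2-amplified cell line). These emulate, not
reproduce, the real measurements: a search that fits them demonstrates
that the machinery works, not that the recovered constants are the
physiological ones. All generators are seed-deterministic.

## Sensitivity analysis

Normalised local sensitivity of mRNA, LS_j(t) = (∂x₁₅/∂k_j)·k_j/x₁₅,
over the early response (pre-equilibration included in the
perturbation), by central differences with relative step 1e−3
(validated by step-halving to 1%), a 1e−12 floor on x₁₅ in the
normalisation, trapezoidal integration over 0–180 min, and ranking by
|LS_j|. The two fitted sets reproduce the expected contrast: the
MdmX-insensitive set (`col9`) is dominated by p53 oligomerisation
constants, the MdmX-sensitive set (`col8`) by p53/Mdm2
production–degradation constants.

## Numerical choices

* Integration: LSODA with the analytic Jacobian; rtol 1e−8, atol 1e−12
  (mRNA concentrations are O(1e−4); the atol must sit far below).
  Outputs are sampled on a fixed 1-time-unit grid (coarser for very
  long runs) independent of internal steps. Tightening tolerances 10×
  moves the tested readouts by <0.1%.
* Peak detection: local maxima with prominence ≥ 5% of the
  post-transient range, first 20% of the window discarded; the period
  is the median peak-to-peak interval and is undefined (flagged, not
  silently NaN) with fewer than 3 peaks.
* Percentage effects of MdmX are always relative to the k₁₅ = 0 arm.
* Classification grids (low/high Mdm2) span two decades below and
  above the set's baseline k₆; the >5%/>30% criteria are evaluated as
  "exists on the scan grid".
* Problem sizes: acceptance-style scans use 20-point k₆ grids; late
  windows are simulated to 11,000 min at 2-min sampling; the
  oscillation period uses a 10,000-min run discarding the first
  2000 min. These complete in about a minute on one core.

## Known limitations and discrepancies

* **Promoter total.** The early-response percentage effects depend
  strongly on the unpublished promoter total (at 100× MdmX, low-k₆
  branch: +409% at P = 0.5, +26% at P = 1.0, −65% at P = 2.0). With
  the documented default P = 1.0 the low-Mdm2 amplification reaches
  ~26%, short of the ~30% headline; the high-Mdm2 suppression (>50%),
  late dampening (>30%) and the dependency criteria are robustly
  reproduced.
* **Oscillation period.** The `col8` set oscillates at 283 min
  (4.7 h) under the stated late-response protocol — robust to the
  promoter total, the damage level and stoichiometric conventions —
  versus the ~6 h experimental peak-to-peak interval that the original
  fit matched only approximately.
* Even with both heterodimer association constants zero,
  phosphorylated MdmX still couples to Mdm2 through the Mdm2:MdmXP
  complex, so the "no heterodimers" control shifts the late maximum by
  ~2% (no dampening) rather than exactly 0.
* The scalar steady-state reduction assumes the p53 balance is
  monotone over the bracket; at a fold of the steady-state branch the
  general Newton solver must be used instead.
* The two-stage search here runs at workstation budgets (10²–10³
  evaluations); published cluster-scale success counts are out of
  scope, and only the qualitative asymmetry between the two oscillatory
  regions is asserted.
* Stochastic (SSA) simulation, ternary complexes, explicit
  ubiquitination intermediates and DDE bifurcation analysis are out of
  scope; the delay variant is handled by simulation only.
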