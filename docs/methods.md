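# Methods

## Model

Bacteria are discrete agents; free phages are per-deme, per-strain
integer counters (individual virions carry no state beyond their strain,
so counters are exact).  Each cell holds two clocks: a growth clock that
advances while the cell is healthy and triggers division when it
completes (cycle lengths drawn from 𝒩(τ̄_D, Δτ_D), redrawn for mother
and daughter), and a lysis countdown drawn from the infecting strain's
lysis-time distribution at the moment of infection, when the growth
clock freezes.  Division is blocked while a deme is at carrying
capacity; a completed growth clock is held and retried, not discarded.

Each timestep Δt applies six substeps in a fixed order — adsorption,
infection, growth, lysis, decay, diffusion — followed by the protocol
event (treadmill shift or dilution transfer).  At Δt = 0.01 min the
substep ordering matters only at O(Δt); the order is configurable
(`SimConfig.substep_order`) for anyone who wants to check.

**Adsorption.**  Events per (deme, strain) are Poisson with mean
α(B+I)VΔt/Vol, capped at the available free virions.  Each event
targets a uniformly random cell (healthy or infected) and fails with
probability n_adsorbed/Amax, successes within a step raising later
failure odds on the same cell.  This sequential rule is implemented
exactly but without an event loop: failing with probability
n_adsorbed/Amax is equivalent to each event drawing one of the cell's
Amax receptor slots uniformly and succeeding iff the slot is free, so a
step resolves as one first-come-first-served pass over randomly ordered
(cell, slot) draws.  A successful event removes the virion from the
free pool whether the target was healthy (productive) or already
infected (super-adsorption — the virion is wasted); a failed event
leaves it free.  Setting Amax = 1 makes every event on an infected cell
fail, i.e. disables super-adsorption exactly.

**Infection.**  A healthy cell with adsorbed virions of both strains
becomes infected by one of them with probability proportional to its
per-strain adsorbed counts; the first infection permanently fixes the
cell's fate.  Lysis times are drawn at infection; negative draws from
wide distributions are clamped to zero (the cell lyses immediately,
producing whatever β(0) is — nothing, under the linear and eclipse
models).

**Lysis.**  A cell whose countdown completes is removed and adds
`sample_burst(model, τ_realized)` virions of its strain to the local
free pool.  Burst counts are rounded to the nearest integer (ties up);
negative draws of the `normal` model are clamped to zero before
rounding.

**Decay and diffusion.**  Free pools lose Poisson(δVΔt) virions; on
the lattice, each deme sends Poisson(DVΔt/2Δx²) virions per neighbour
direction (D converted from μm²/s to μm²/min internally), clamped
proportionally so emigration never exceeds the pool.  Boundaries
reflect; lattice totals are exactly conserved, which a per-step ledger
test asserts.

**Treadmill (plaque).**  While the deme with the most free virions lies
more than 30 demes from the left edge, the leftmost deme is dropped and
a fresh deme of healthy cells at carrying capacity is appended at the
right; absolute positions add `cumulative_shift · Δx`.

**Transfer (serial passage).**  When total bacteria fall below 1% of
B₀, every bacterium (with its clocks and infection state) and every
free virion survives independently with probability 10⁻³ and B₀ fresh
healthy cells are added.  A fixed-interval variant
(`transfer_interval`) fires on a schedule instead.

## Growth-rate theory

`effective_growth_rate` integrates p(τ)·ln β(τ)/τ adaptively
(`scipy.integrate.quad`, absolute tolerance 10⁻⁸, breakpoints at the
distribution's mass so narrow distributions are not missed; a
2001-point Simpson rule is the fallback when the adaptive routine
warns).  The integrand diverges where β(τ) → 0 or τ → 0, so the domain
is restricted to β(τ) ≥ 1 and τ ≥ 10⁻³ min, i.e. to lysis cycles that
can contribute at least one descendant; the excluded probability mass
is reported alongside k and is *not* renormalized away — unproductive
infections should depress a lineage average, not vanish from it.  Point
(delta) distributions bypass quadrature: k = ln β(τ)/τ, with a −∞
sentinel for non-viable strains.  For the `normal` model the theory
uses ln β̄ (burst noise has negligible effect on fitness, which the
competition tests confirm independently).  Optima in mean lysis time
are located by bounded scalar minimization on [ε+0.1, 60] min to 10⁻³
min; the `normal` and `linear` models are monotone in τ̄ and are
flagged as such rather than given a fake optimum.

## Fixation bookkeeping

A strain wins by extinction of its competitor (no free virions and no
infected cells) at any step.  The 70:30 pool rule is applied to
*sustained* dominance: one pool must hold ≥70% of at least 100 free
virions continuously for 10 minutes.  The sustainment window exists
because with tightly synchronized lysis the instantaneous share swings
to ~100:0 at every burst — the very first burst of any run would
otherwise decide it — while the genuine outcomes of interest
(dead-time losses under default conditions, persistent idle pools under
conservative conditions) play out over tens of minutes.  Undecided runs
get a final ratio check at t_max.  Dilution preserves the pool share in
expectation, so a dominance streak may span a transfer.

Two selection-rate estimators are provided.
`estimate_fitness_difference` is the direct definition — the OLS slope
of ln(V_mu/V_wt) on 1-minute samples, excluding samples where either
pool is empty — and is appropriate when lysis noise keeps the pools
occupied.  For near-deterministic lysis the pools are empty between
synchronized bursts and that estimator has no usable samples, so
`estimate_fitness_from_transfers` fits the same slope on the
pre-dilution pool ratios at passage boundaries (runs continued to t_max
with the verdict recorded when first reached), flooring extinct pools
at one virion so that a lost strain registers as a strongly negative
rate rather than missing data.  The resonance scans use the latter.
Note that ΔF only approaches Δk = k_mu − k_wt when the strains do not
interact; in any shared culture, resource competition screens the
difference (that screening is one of the model's findings, not an
estimator artefact).

## Synthetic data and problem sizes

There is no external data; every input is generated by the simulator
from the standard parameter sets (serial passage: Vol 10⁻⁵ ml,
B₀ 10⁴, C 10⁵, V₀ 100 per strain, Δt 0.01 min, T ≤ 600 min; plaque: 60
demes × 100 cells at capacity, Vol 10⁻⁷ ml per deme, Δx 10 μm,
T = 180 min; bacteria: doubling 20 ± 2 min, Amax 100).  The dynamics
are invariant under joint rescaling of Vol, B₀, C and V₀ (verified by a
KS test on per-capita endpoints at 10× size ratio), and the
serial-passage-heavy analyses — resonance scans, symmetric-competition
checks — run on a 0.1× system for speed.  Landscape sweeps default to
coarse grids with a few replicates per cell and deterministic per-cell
seeds (`SeedSequence(base, cell, replicate)`); paper-scale landscapes
are the same calls with denser axes and more replicates.

What the generator does *not* emulate: host physiology (burst size and
lysis time are drawn from fixed distributions rather than emerging from
cell state), nutrient gradients or biofilm structure (all cells are
metabolically active lawn cells), adsorption-rate variability,
lysis inhibition, lysogeny, and superinfection with progeny sharing.
Passing tests therefore speak to the population-dynamic consequences of
life-history noise, not to its mechanistic origin.

## Numerical choices and degenerate inputs

* Growth-cycle draws are clamped below at 1 min; lysis-time draws at 0.
* Poisson event counts are clamped at the available counters
  (bias O(Δt²)); emigration is split proportionally when clamped.
* `distribution_from_mean_std` rounds the Erlang shape to the nearest
  positive integer, preserving the mean exactly and letting the std
  deviate; std = 0 collapses any family to a delta.
* Ties in burst rounding go up; virions are integers throughout.
* A single RNG stream per simulation with fixed draw order makes runs
  bit-reproducible given (config, seed).
* Resonance-edge detection smooths the ΔF scan with a 3-point moving
  average, takes the deepest interior local minimum at least 0.02/min
  deep (shallower wiggles are replicate noise at the default replicate
  counts), and reports the grid point below the steepest fall as the
  dip's lower edge.

## Known limitations

* The β ≥ 1 integration cutoff is a regularization choice; growth rates
  for distributions with substantial mass at unproductive lysis times
  depend mildly on it (the excluded mass is reported so users can
  judge).
* The sustained-dominance window (10 min) and gate (100 virions) are
  protocol constants, not fitted quantities; outcomes are insensitive
  to them except exactly at resonance boundaries, where the competition
  itself is marginal.
* At exactly τ_mu = τ_wt/2 the realized mutant dead time is not zero
  (the wild type's penultimate burst captures the remaining hosts
  first); the favourable edge at the 1/2 ratio emerges from the
  competition outcome, not from a literal zero dead time.
* Plaque fronts are 1-D; radial geometry, and any quantity depending on
  front curvature, is out of scope.
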