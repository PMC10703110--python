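# Methods

This note documents the models implemented in `emsrank`, the
assumptions behind them, the tunable parameters, and the choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## System model and units

A system is `A ≥ 2` atoms (zones), each emitting two independent
Poisson call streams — *serious* (life-threatening, index `a` in the
case tables) and *regular* (index `b`) — so the queuing model sees
`2A` sub atoms. Fleets are homogeneous pools: basic service units
(BSU), movable between atoms, and advanced service units (ASU),
dedicated to serious calls and pinned to their base atoms by default
(`Fleet.fixed_atoms`); an unpinned dedicated fleet is enumerated like
any other.

Internally all rates are per minute and all times in minutes; the CSV
schema carries arrival rates per hour (as the case tables print them)
and the loader converts at the boundary, so `rate × service time` is
always a dimensionless offered load. Atom ids are 1-based in every
file and report, 0-based in code. The packaged fixtures transcribe
the two published SAMU case studies; each fixture README records the
transcription notes (atom-name discrepancies in the published
description, and the ASU base atoms, which it leaves open and which
we pin at atom 1, giving a single dedicated group).

The synthetic generator (`generate_synthetic_system`) reproduces this
structure: roughly symmetric positive travel times on a 6–16 minute
urban scale with intra-atom journeys on the same scale (crossing a
dense atom can take longer than hopping to a neighbour), a serious
share of 8–15% per atom mirroring the advanced/basic split of the
case tables, and total demand scaled to a target fleet utilization
(default 0.5, always < 0.9 so the chain is stable and far from
saturation). It emulates the *structure* of real systems, not their
geography: travel times are independent draws, not road distances,
and demand has no time-of-day profile — so passing tests show model
correctness, not predictive validity for any real city.

## Aggregated hypercube chain

Servers of one type co-located in one atom are indistinguishable and
are tracked only by their busy count (server aggregation). A state is
`(b_1..b_T, s, g)`: busy counts per group plus the number of waiting
serious and regular calls. Validity rules encode the dispatch
physics: a non-empty queue requires every BSU group to be full
(regular calls may not use ASUs, so they can wait while an ASU idles
— the dedicated-server-induced queue states), and waiting *serious*
calls additionally require every ASU to be busy (a free dedicated
unit would take them immediately). With one dedicated group of `n_ds`
servers the queue states number exactly
`n_ds·Q_l + C(2+Q_l, Q_l) − 1`; the implementation generalizes to
several dedicated groups (the first term becomes the count of
not-all-busy dedicated patterns). A property test verifies these
counts over random group shapes.

Transitions: an arrival goes to the first group in its preference
list with a free server; with none it waits (if the queue variant is
active and `s + g < Q_l`) or is lost. Preference lists: serious calls
— nearest dedicated groups, then the BSU group of the call's atom,
then the remaining BSU groups in seeded-random backup order; regular
calls — same-atom BSU group, then the remaining BSU groups by mean
travel time with seeded-random tie-breaks. The randomized backup
order uses one seeded generator per policy and the seed is recorded
in every output row. A completion frees one server which,
non-preemptively, admits the highest-priority waiting call it may
serve: any group takes a waiting serious call, only BSU groups take
regular calls, and a dedicated server with nothing eligible simply
goes idle. Arrivals never displace service in progress.

The transition structure above is derived directly from the dispatch
rules and reproduces the closed-form state counts exactly. Its
strongest validation is lumpability: splitting
every group into individual servers (uniform choice among a group's
free servers) and solving the `2^n`-state per-server chain gives
workloads, loss and empty probabilities and dispatch frequencies
identical to the aggregated chain to 1e−8 (tests), and a
discrete-event simulation of the same rules brackets the analytic
workloads within 99% batch-means confidence intervals.

Steady state: `pQ = 0, Σp = 1` by sparse LU up to 20,000 states
(exact at the case-study sizes, a few hundred states), Gauss–Seidel
sweeps above that (tolerance 1e−10, max 10,000 sweeps). States
unreachable from the empty system (possible when a demand stream is
zero) are transient, carry zero probability, and are reported in the
structure diagnostics. A state-space cap (default 2×10⁵) fails fast
on oversized models.

### Performance measures

* workload `ρ_t = Σ_r b_tr P_r / n_t`, identical for servers within a
  group;
* dispatch frequency of group `t` for sub atom `m`: the probability
  mass of states where `t` is the first free eligible group, plus the
  queued share attributed to eligible groups in proportion to their
  completion rates `n_t μ_t` — the multiset queue encoding forgets a
  waiting call's origin, and `n_t μ_t / Σ n_u μ_u` is the exact
  first-to-free probability for the head of the queue by
  memorylessness, so this attribution is exact for the head and an
  approximation deeper in the queue (the lumpability test therefore
  compares immediate-dispatch frequencies, which are exact);
* mean response time of a sub atom: dispatch-weighted mean of (travel
  time from the serving group's atom + the type's on-scene
  component). Lost calls are excluded and reported as a loss
  probability; queueing *delay* is likewise not folded into this
  measure (it is a dispatch-mix response time, matching the
  definition of the case tables' mean times). A flag
  (`include_on_scene=False`) switches to travel-only times;
* per-server mean response time: call-flow-weighted over the sub
  atoms the group serves; loss probability per sub atom and overall;
  empty-system probability.

### Service-time calibration

The case tables print each unit's *total* mean response time
(travel + on-scene) measured with servers spread over the atoms. The
pure on-scene component is recovered as the type's total minus the
demand-weighted intra-atom journey time (floored at 1 minute), since
in the baseline layout most dispatches are same-atom. For each
configuration a fixed point is then iterated: solve the chain,
recompute every group's mean travel from its dispatch frequencies,
set `μ⁻¹_t = on-scene + travel_t`, repeat until the largest change is
below `tol` (default 1e−6 minutes, max 100 iterations; a constant
travel matrix converges in one pass). Non-convergence is a warning
and a flag on the result, not an error. Calibration schemes of this
kind vary across the literature; this concrete fixed point is the
package's choice.

## DEA / benefit-of-the-doubt stage

Inputs are the `n` BSU per-server workloads (undesirable), outputs
the reciprocals of the `2A` sub-atom response times and the `n` BSU
per-server response times (desirable; reciprocals are valid because
all times are strictly positive, and they penalize long times more
than a sign flip would). ASU columns are excluded: pinned units carry
no information about the configuration. Per-server columns are laid
out in atom order, group values repeated by group size — servers are
indistinguishable, so any deterministic convention works and this one
is stable across runs.

The multiplier LP (output-oriented BCC, one solve per DMU per
frontier) is stated in the README. Implementation choices:

* three group-contribution constraints (regular-atom, serious-atom
  and per-server blocks each ≥ `0.01 P` of the unit's normalized
  output value) keep any one block from being weighted away;
  `P = 0` disables them. Default `P = 20` (so the three floors claim
  60% of the efficiency at most); there is no canonical value for
  `P` — multicriteria methods can set it — so it is a first-class
  flag;
* the strict assurance-region inequality is realized as
  `α_h^S − α_h ≥ ε`, and the bare printed lower bounds as `≥ ε`, with
  default `ε = 1e−6` on the normalized column scale; on an infeasible
  solve `ε` is relaxed once by 10× with a warning before the DMU is
  reported failed (batch solves continue past per-DMU failures);
* columns are mean-normalized before solving for conditioning;
  efficiencies are invariant to positive column rescaling (tested),
  so this is purely numerical;
* the inverted frontier swaps the input/output roles and mirrors the
  assurance-region and group constraints onto the swapped side (the
  mirrored convention is a documented choice);
* the composite index is `(standard + (1 − inverted)) / 2` normalized
  by its maximum (max-normalization is the package's reading of a
  "normalized mean" and is recorded in the output metadata). Ranks descend by composite; exact ties
  share the best rank, and an all-tie vector triggers a warning.

LPs are solved with `scipy.optimize.linprog` (HiGHS). Correctness is
pinned by an envelopment-form dual implemented independently in the
tests (agreement to 1e−6 on random instances with `P = 0, ε = 0`),
plus self-dominance, dominance, duplication-symmetry and
units-invariance properties.

## Ranking analysis

Spearman correlations (average ranks for ties, large-sample two-sided
p-values via `scipy.stats.spearmanr`) between rank vectors and (a)
per-atom server counts, (b) the standard deviation of each allocation
vector; significance stars at 0.05 / 0.01 / 0.001. A constant vector
has no defined rank correlation and is reported as NaN. The
concentration summary groups configurations by number of occupied
atoms (fully spread first, single-atom last) and reports rank
statistics per group. The cross-scenario agreement matrix is the
pairwise Spearman correlation of rank vectors.

## Pipeline and determinism

`run_all` evaluates the scenario grid (default
`P0pq, P0nq, P25pq, P25nq, P50pq, P50nq`: current/+25%/+50% demand ×
queue/no-queue), writing one performance, ranking and weights table
per scenario plus the analysis tables and a manifest materializing
every parameter. All randomness (backup dispatch order) flows from
the single run seed, outputs are merged in configuration-id order,
and a re-run with the same RunConfig is byte-identical (tested). A
scenario aborts only if more than 1% of its configurations fail;
individual failures are logged and listed in the manifest.

## Problem sizes and defaults

Queue capacity `Q_l` defaults to 5, a modeling default: real
dispatch centers rarely exhibit a hard queue bound, and 5 keeps the
blocking probability negligible at the case-study loads. The six-atom case (792 configurations,
calibration plus two DEA frontiers) runs in well under a minute on
one CPU; the oracle cross-checks in the test suite use 2–3 atom toys
with up to 4 servers (where the `2^n` exact chain and long
discrete-event runs are cheap) — the exact expansion is a test
oracle only, not a supported execution path for large fleets.

## Known limitations

* Queue-served calls are attributed to servers by completion rates
  (exact only for the queue head), and queueing delay is not part of
  the reported response times.
* Travel times are fixed means; no time-varying demand, no
  inter-jurisdiction mutual aid, no preemption.
* Rankings for the case studies published elsewhere depend on
  parameters those descriptions leave open (`P`, `ε`, `Q_l`, the
  random dispatch matrices and calibration details), so this package
  reproduces qualitative patterns (concentration effects,
  dispersion-row correlations) but makes no claim of row-level
  agreement; the end-to-end test prints the comparison rather than
  asserting it.
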