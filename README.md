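# emsrank

Ranking server-location configurations for urban emergency medical
services (EMS), for operations-research analysts and EMS planners who
must decide **where to base ambulances**.

An EMS region is split into *atoms* (zones). Every way of distributing
the `n` basic ambulances (BSUs) over the `A` atoms is a candidate
configuration; dedicated advanced units (ASUs) answer only
life-threatening calls and stay at their bases. `emsrank` scores every
configuration and ranks them with a composite index, in three stages:

1. **Enumeration.** All allocations of `n` indistinguishable servers to
   `A` atoms, via integer partitions and their permutations:
   `C_k = A! / ∏_j R_j!` per zero-filled partition and `C = Σ_k C_k`
   in total (equal to the weak-composition count `C(n+A−1, A−1)`).
   Server types are enumerated separately and combined as a product.

2. **Hypercube queuing model.** Each configuration is a spatial Markov
   chain: Poisson calls per sub atom (each atom × {serious, regular}),
   exponential service, dispatch preference lists (same-atom unit
   first, ASUs only for serious calls), non-preemptive priority queue
   of capacity `Q_l` or loss. Co-located identical servers are
   aggregated into groups tracked by busy count, so the busy states
   number `∏_t (n_t+1)` instead of `2^n`, plus
   `|Q| = n_ds·Q_l + C(2+Q_l, Q_l) − 1` queue states when a dedicated
   group of `n_ds` servers is present. Steady-state probabilities give
   per-server workloads `ρ_it = Σ_r n_tr·P_r / n_t`, dispatch
   frequencies, loss/empty probabilities and mean response times,
   with service times calibrated to each configuration's actual travel.

3. **DEA / benefit-of-the-doubt composite index.** Each configuration
   is a DMU with inputs `ρ_ik` (BSU workloads) and outputs
   `y_hk, y_hk^S, z_ik` (reciprocal response times per atom-priority
   and per BSU; `O = 2A + n`). An output-oriented BCC multiplier LP
   with non-Archimedean bounds `ε`, an assurance region
   `α_h^S ≥ α_h + ε` (serious calls weigh at least as much as regular
   ones) and minimum group contributions (`≥ P%` each) yields the
   standard efficiency; re-running with inputs and outputs swapped
   yields the inverted (worst-practice) efficiency; the composite
   index is the max-normalized mean of `standard` and
   `1 − inverted`, and configurations are ranked by it.

A discrete-event simulator of the same system, a Spearman
correlation/concentration analysis of the resulting rankings, and the
two published Brazilian SAMU case studies (six-atom and five-atom
systems, shipped as CSV fixtures) round out the package.

## Worked example

Rank every allocation of the seven basic units of the six-atom case
under current demand with a queue (the `P0pq` scenario):

```
$ emsrank run-all --system bauru --scenario P0pq --seed 1 --out out/
scenario P0pq: 792 configurations, demand x1.00, queue
P0pq: best config 791 (composite 1.0000)
```

This takes well under a minute on one CPU and writes
`configurations.csv`, `performance_P0pq.csv` (the queueing measures —
the contract between the two stages), `ranking_P0pq.csv`,
`weights_P0pq.csv`, `correlations.csv`, `groups.csv`, `agreement.csv`
and a `manifest.json` recording every parameter. The best
configuration (id 791, allocation `0,0,0,0,1,6`) concentrates six
basic units in atom 6 and one in atom 5: its composite index is 1 —
it is fully efficient on the standard frontier (`standard_eff = 1`)
and has the lowest worst-practice score of the efficient units.

The correlation table summarizes what drives the ranking
(`rank 1` = best, so a *negative* coefficient means more ambulances in
that atom improve the ranking):

```
$ cat out/correlations.csv
,P0pq
A1,-0.27***
A2,0.07
A3,0.19***
A4,0.24***
A5,-0.05
A6,-0.5***
std_dev,0.35***
```

Placing servers in atom 6 strongly improves a configuration's rank
(−0.50, p < 0.001), while spreading the fleet thin across all atoms
(the `std_dev` row: +0.35 for *concentration*) is associated with
worse ranks in this scenario — the trade-off the composite index is
designed to expose. `groups.csv` reports mean rank by the number of
occupied atoms (fully spread → single atom).

The same pipeline is available as library calls
(`emsrank.calibrate`, `emsrank.build_dea_dataset`,
`emsrank.efficiency_all`, `emsrank.composite_index`, …); see
`docs/methods.md` for the model details and every tunable parameter.

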