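"""Aggregated hypercube queuing model with two call priorities.

The classic hypercube model tracks each server's busy/free status, so a
system with ``n`` servers has ``2^n`` states.  Here co-located servers
of the same type are *aggregated*: a group of ``n_t`` indistinguishable
servers in one atom is tracked only by its busy count, so the busy part
of the state space has ``prod_t (n_t + 1)`` states.  Two extensions are
layered on top:

* **two priorities** — each atom generates a serious and a regular call
  stream (sub atoms); dedicated advanced units (ASUs) answer only
  serious calls, so regular calls may queue while an ASU sits free;
* **a finite priority queue** — up to ``Q_l`` calls wait when no
  eligible server is free (or are lost when the queue is full or the
  no-queue variant is used).  Queued calls are served non-preemptively,
  highest priority first, by the next eligible server to free up.

A state is ``(b_1..b_T, s, g)``: busy counts per group plus the number
of serious and regular calls waiting.  Queue states split into the
dedicated-server-induced ones (some ASU free, all basic units busy,
only regular calls waiting) and the saturated ones (everything busy,
any mix of priorities waiting); with one dedicated group of ``n_ds``
servers their counts are ``n_ds * Q_l`` and ``C(2 + Q_l, Q_l) - 1``.

Steady-state probabilities come from the balance equations of the
continuous-time Markov chain (sparse direct solve, Gauss-Seidel above a
size threshold); workloads, dispatch frequencies, response times and
loss/empty probabilities follow, and a fixed-point calibration step
makes each group's mean service time consistent with the travel it
actually performs under the configuration being evaluated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from emsrank.enumeration import Configuration
from emsrank.system_model import PRIORITIES, REGULAR, SERIOUS, SystemDescription


class StateSpaceSizeError(RuntimeError):
    """State count exceeds the configured cap."""


@dataclass(frozen=True)
class ServerGroup:
    """A set of homogeneous, indistinguishable servers in one atom."""

    index: int
    atom: int
    type: str
    size: int
    dedicated: bool


@dataclass(frozen=True)
class DispatchPolicy:
    """Ordered server-group preference list per sub atom.

    Serious calls prefer the dedicated (ASU) groups (nearest first),
    then the basic unit of the call's atom, then the remaining basic
    units in seeded-random backup order.  Regular calls prefer the
    basic unit of the call's atom, then the remaining basic units by
    mean travel time with seeded-random tie-breaks; dedicated units
    never appear in regular-call lists.
    """

    groups: tuple[ServerGroup, ...]
    preference: Mapping[tuple[int, str], tuple[int, ...]]
    seed: int


@dataclass
class StateSpace:
    """All states of the aggregated chain plus both-way index maps."""

    groups: tuple[ServerGroup, ...]
    Q_l: int
    policy: str  # "queue" | "no_queue"
    states: list[tuple[tuple[int, ...], int, int]]
    index: dict[tuple[tuple[int, ...], int, int], int]
    n_ds: int

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_queue_states(self) -> int:
        return sum(1 for (_, s, g) in self.states if s + g > 0)


@dataclass
class SteadyStateSolution:
    """Steady-state probabilities with solver diagnostics."""

    p: np.ndarray
    residual: float
    iterations: int
    method: str
    unreachable: int = 0


@dataclass
class PerformanceMeasures:
    """Per-configuration queueing outputs feeding the DEA stage.

    ``dispatch_freq[t, m]`` is the probability that a call from sub
    atom ``m`` is served by group ``t`` (queue-served calls included);
    for each sub atom the column sums to one minus its loss share.
    Response times are in minutes and include the on-scene component by
    default, matching the definition of the case tables' mean times.
    """

    groups: tuple[ServerGroup, ...]
    sub_atoms: list[tuple[int, str]]
    workload: np.ndarray                 # per group, = per server in group
    dispatch_freq: np.ndarray            # (T, n_sub)
    response_time_sub: np.ndarray        # (n_sub,)
    response_time_group: np.ndarray      # (T,)
    travel_component_group: np.ndarray   # (T,)
    loss_prob_sub: np.ndarray            # (n_sub,)
    loss_prob: float
    empty_prob: float
    converged: bool = True
    iterations: int = 0
    seed: int = 0

    def workload_per_server(self, type: str | None = None) -> np.ndarray:
        """Per-server workloads, group values repeated by group size."""
        vals = []
        for t, grp in enumerate(self.groups):
            if type is None or grp.type == type:
                vals.extend([self.workload[t]] * grp.size)
        return np.array(vals)

    def response_time_per_server(self, type: str | None = None) -> np.ndarray:
        vals = []
        for t, grp in enumerate(self.groups):
            if type is None or grp.type == type:
                vals.extend([self.response_time_group[t]] * grp.size)
        return np.array(vals)


@dataclass
class CalibrationResult:
    """Outcome of the service-time fixed-point calibration."""

    service_times: np.ndarray  # mean total service time per group, minutes
    measures: PerformanceMeasures
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_server_groups(
    config: Configuration, sys: SystemDescription
) -> list[ServerGroup]:
    """One group per (type, atom) cell with a positive server count.

    Dedicated fleets absent from the configuration fall back to their
    pinned ``fixed_atoms`` allocation.  Ordering is deterministic:
    fleets in system order, atoms ascending.
    """
    groups: list[ServerGroup] = []
    for fleet in sys.fleets:
        if fleet.type in config.allocation:
            vec = config.allocation[fleet.type]
        elif fleet.fixed_atoms is not None:
            vec = fleet.fixed_atoms
        else:
            raise ValueError(
                f"configuration {config.id} has no allocation for fleet "
                f"{fleet.type!r} and the fleet is not pinned"
            )
        if sum(vec) != fleet.count:
            raise ValueError(
                f"allocation {vec} does not sum to fleet count {fleet.count}"
            )
        for atom, count in enumerate(vec):
            if count > 0:
                groups.append(
                    ServerGroup(len(groups), atom, fleet.type, count, fleet.dedicated)
                )
    if not groups:
        raise ValueError("empty configuration: no servers allocated")
    return groups


def build_state_space(
    groups: Sequence[ServerGroup],
    Q_l: int,
    policy: str = "queue",
    state_cap: int = 200_000,
) -> StateSpace:
    """Enumerate all states ``(busy counts, s queued serious, g queued regular)``.

    Validity rules: ``s + g <= Q_l``; a non-empty queue requires every
    non-dedicated group to be full (regular calls cannot use dedicated
    units); waiting serious calls additionally require every dedicated
    group to be full (a free dedicated unit would take them).
    """
    if not groups:
        raise ValueError("need at least one server group")
    if policy not in ("queue", "no_queue"):
        raise ValueError(f"unknown queue policy {policy!r}")
    if Q_l < 0:
        raise ValueError("Q_l must be >= 0")
    if policy == "no_queue":
        Q_l = 0

    sizes = [g.size for g in groups]
    ded = [g.dedicated for g in groups]
    n_ds = sum(g.size for g in groups if g.dedicated)

    est = math.prod(s + 1 for s in sizes) * (Q_l + 1) ** 2
    if est > 4 * state_cap:
        raise StateSpaceSizeError(
            f"candidate state space ({est}) exceeds cap {state_cap}"
        )

    states: list[tuple[tuple[int, ...], int, int]] = []
    for busy in product(*(range(s + 1) for s in sizes)):
        basics_full = all(b == s for b, s, d in zip(busy, sizes, ded) if not d)
        all_full = all(b == s for b, s in zip(busy, sizes))
        for s in range(Q_l + 1):
            for g in range(Q_l + 1 - s):
                if s + g > 0 and not basics_full:
                    continue
                if s > 0 and not all_full:
                    continue
                states.append((busy, s, g))
    if len(states) > state_cap:
        raise StateSpaceSizeError(
            f"state space has {len(states)} states, cap is {state_cap}"
        )
    index = {st: i for i, st in enumerate(states)}
    return StateSpace(tuple(groups), Q_l, policy, states, index, n_ds)


def make_dispatch_policy(
    config: Configuration,
    sys: SystemDescription,
    seed: int = 0,
    groups: Sequence[ServerGroup] | None = None,
) -> DispatchPolicy:
    """Build the seeded dispatch preference lists for every sub atom."""
    if groups is None:
        groups = build_server_groups(config, sys)
    groups = tuple(groups)
    rng = np.random.default_rng(seed)
    tt = sys.travel_time
    basics = [g for g in groups if not g.dedicated]
    dedicated = [g for g in groups if g.dedicated]

    pref: dict[tuple[int, str], tuple[int, ...]] = {}
    for j in range(sys.n_atoms):
        same = [g for g in basics if g.atom == j]
        others = [g for g in basics if g.atom != j]

        # serious: nearest dedicated units, same-atom basic, random backups
        ded_sorted = sorted(dedicated, key=lambda g: (tt[g.atom, j], g.atom))
        backup = [others[i] for i in rng.permutation(len(others))]
        serious_list = ded_sorted + same + backup
        if not serious_list:
            raise ValueError(f"sub atom ({j + 1}, serious) has no eligible group")

        # regular: same-atom basic, then basics by travel time (random ties)
        tie = rng.random(len(others))
        reg_backup = [
            g for _, _, g in sorted(
                zip((tt[g.atom, j] for g in others), tie, others),
                key=lambda x: (x[0], x[1]),
            )
        ]
        regular_list = same + reg_backup
        if not regular_list:
            raise ValueError(f"sub atom ({j + 1}, regular) has no eligible group")

        pref[(j, SERIOUS)] = tuple(g.index for g in serious_list)
        pref[(j, REGULAR)] = tuple(g.index for g in regular_list)

    return DispatchPolicy(groups, pref, seed)


# ---------------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------------

_NO_FREE = -1  # outcome code: every eligible group busy (queue or lose)


@dataclass
class TransitionStructure:
    """Sparse state-to-state rate structure of the chain.

    Arrival entries are fixed; completion entries carry the busy count
    and group index so that the rate matrix can be re-assembled cheaply
    for new service rates during calibration.
    """

    space: StateSpace
    sub_atoms: list[tuple[int, str]]
    rates: np.ndarray            # lambda per sub atom (per minute)
    outcome: np.ndarray          # (n_sub, n_states) int codes
    arr_rows: np.ndarray
    arr_cols: np.ndarray
    arr_vals: np.ndarray
    comp_rows: np.ndarray
    comp_cols: np.ndarray
    comp_group: np.ndarray
    comp_count: np.ndarray
    unreachable: int = 0

    def rate_matrix(self, service_times: np.ndarray) -> sp.csr_matrix:
        """Assemble the generator for per-group mean service times (minutes)."""
        service_times = np.asarray(service_times, float)
        if np.any(service_times <= 0):
            raise ValueError("service times must be > 0")
        mu = 1.0 / service_times
        comp_vals = self.comp_count * mu[self.comp_group]
        rows = np.concatenate([self.arr_rows, self.comp_rows])
        cols = np.concatenate([self.arr_cols, self.comp_cols])
        vals = np.concatenate([self.arr_vals, comp_vals])
        if np.any(vals < 0):
            raise RuntimeError("negative transition rate")
        n = self.space.n_states
        out = np.zeros(n)
        np.add.at(out, rows, vals)
        rows = np.concatenate([rows, np.arange(n)])
        cols = np.concatenate([cols, np.arange(n)])
        vals = np.concatenate([vals, -out])
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def build_generator(
    space: StateSpace,
    policy: DispatchPolicy,
    sys: SystemDescription,
    service_times: np.ndarray | None = None,
) -> TransitionStructure:
    """Derive every state-to-state transition of the aggregated chain.

    Arrivals send a call to the first free group of its preference
    list; with no free eligible group the call waits (if the queue
    variant is active and there is room) or is lost.  Completions free
    a server which, non-preemptively, admits the highest-priority
    waiting call it is allowed to serve: any group takes a waiting
    serious call, only non-dedicated groups take regular calls, and a
    dedicated server that can serve nothing waiting simply goes idle.
    """
    groups = space.groups
    sizes = np.array([g.size for g in groups])
    T = len(groups)
    sub_atoms = sys.sub_atoms
    rates = np.array([sys.rate(j, p) for j, p in sub_atoms])
    Q_l = space.Q_l
    queueing = space.policy == "queue"

    n = space.n_states
    busy = np.array([st[0] for st in space.states])      # (n, T)
    qs = np.array([st[1] for st in space.states])
    qg = np.array([st[2] for st in space.states])

    # dispatch outcome per sub atom per state, vectorized over states
    outcome = np.full((len(sub_atoms), n), _NO_FREE, dtype=np.int64)
    free = busy < sizes[None, :]
    for m, (j, p) in enumerate(sub_atoms):
        for t in reversed(policy.preference[(j, p)]):
            outcome[m][free[:, t]] = t

    idx = space.index
    arr_r: list[int] = []
    arr_c: list[int] = []
    arr_v: list[float] = []
    for m, (j, p) in enumerate(sub_atoms):
        lam = rates[m]
        if lam <= 0:
            continue
        out_m = outcome[m]
        for r, st in enumerate(space.states):
            b, s, g = st
            t = out_m[r]
            if t >= 0:
                b2 = list(b)
                b2[t] += 1
                target = (tuple(b2), s, g)
            elif queueing and s + g < Q_l:
                target = (b, s + 1, g) if p == SERIOUS else (b, s, g + 1)
            else:
                continue  # lost call: no state change
            arr_r.append(r)
            arr_c.append(idx[target])
            arr_v.append(lam)

    comp_r: list[int] = []
    comp_c: list[int] = []
    comp_g: list[int] = []
    comp_n: list[int] = []
    for r, (b, s, g) in enumerate(space.states):
        for t, bt in enumerate(b):
            if bt == 0:
                continue
            if s > 0:
                # all groups full; the freed server takes the serious head
                target = (b, s - 1, g)
            elif g > 0 and not groups[t].dedicated:
                target = (b, s, g - 1)
            else:
                b2 = list(b)
                b2[t] -= 1
                target = (tuple(b2), s, g)
            comp_r.append(r)
            comp_c.append(idx[target])
            comp_g.append(t)
            comp_n.append(bt)

    struct = TransitionStructure(
        space=space,
        sub_atoms=sub_atoms,
        rates=rates,
        outcome=outcome,
        arr_rows=np.array(arr_r, dtype=np.int64),
        arr_cols=np.array(arr_c, dtype=np.int64),
        arr_vals=np.array(arr_v),
        comp_rows=np.array(comp_r, dtype=np.int64),
        comp_cols=np.array(comp_c, dtype=np.int64),
        comp_group=np.array(comp_g, dtype=np.int64),
        comp_count=np.array(comp_n, dtype=float),
    )
    struct.unreachable = _count_unreachable(struct)
    if struct.unreachable:
        warnings.warn(
            f"{struct.unreachable} states unreachable from the empty system "
            "(zero steady-state probability)",
            RuntimeWarning,
            stacklevel=2,
        )
    return struct


def _count_unreachable(struct: TransitionStructure) -> int:
    n = struct.space.n_states
    rows = np.concatenate([struct.arr_rows, struct.comp_rows])
    cols = np.concatenate([struct.arr_cols, struct.comp_cols])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    start = struct.space.index[(tuple([0] * len(struct.space.groups)), 0, 0)]
    reached = sp.csgraph.breadth_first_order(
        adj, start, directed=True, return_predecessors=False
    )
    return n - len(reached)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def solve_steady_state(
    generator: sp.spmatrix,
    tol: float = 1e-10,
    direct_limit: int = 20_000,
    max_sweeps: int = 10_000,
) -> SteadyStateSolution:
    """Solve ``p Q = 0`` with ``sum(p) = 1``.

    Direct sparse LU for chains up to ``direct_limit`` states; a
    Gauss-Seidel sweep iteration above that, failing loudly if the
    residual does not reach ``tol``.
    """
    Q = sp.csr_matrix(generator)
    n = Q.shape[0]
    if n <= direct_limit:
        A = Q.T.tolil()
        A[n - 1, :] = 1.0
        b = np.zeros(n)
        b[n - 1] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", spla.MatrixRankWarning)
            p = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(p)):  # singular (transient states): least squares
            p = spla.lsqr(A.tocsc(), b, atol=1e-14, btol=1e-14)[0]
        method, iters = "sparse_lu", 1
    else:
        p, iters = _gauss_seidel(Q, tol, max_sweeps)
        method = "gauss_seidel"
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    residual = float(np.max(np.abs(p @ Q)))
    if residual > max(tol, 1e-8):
        raise RuntimeError(
            f"steady-state solve did not converge: residual {residual:.3e}"
        )
    return SteadyStateSolution(p, residual, iters, method)


def _gauss_seidel(Q: sp.csr_matrix, tol: float, max_sweeps: int):
    n = Q.shape[0]
    A = Q.T.tocsr()  # solve A p = 0 with normalization
    diag = A.diagonal()
    p = np.full(n, 1.0 / n)
    for sweep in range(1, max_sweeps + 1):
        for i in range(n):
            row = A.indices[A.indptr[i]:A.indptr[i + 1]]
            vals = A.data[A.indptr[i]:A.indptr[i + 1]]
            acc = vals @ p[row] - diag[i] * p[i]
            p[i] = -acc / diag[i] if diag[i] != 0 else 0.0
        p /= p.sum()
        res = np.max(np.abs(p @ Q))
        if res < tol:
            return p, sweep
    return p, max_sweeps


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

def compute_workloads(
    solution: SteadyStateSolution, space: StateSpace
) -> np.ndarray:
    """Per-group (= per-server) workloads: ``rho_t = sum_r n_tr P_r / n_t``."""
    busy = np.array([st[0] for st in space.states], dtype=float)
    sizes = np.array([g.size for g in space.groups], dtype=float)
    return (solution.p @ busy) / sizes


def on_scene_times(sys: SystemDescription) -> dict[str, float]:
    """Recover the pure on-scene component of each type's mean service time.

    Fixture service times are total mean response times (travel +
    on-scene) measured with servers spread over the atoms, so the
    travel part is approximated by the demand-weighted intra-atom
    journey time; the remainder is the on-scene component (floored at
    one minute).
    """
    lam = np.array(
        [sum(sys.rate(j, p) for p in PRIORITIES) for j in range(sys.n_atoms)]
    )
    base_travel = float(lam @ np.diag(sys.travel_time) / lam.sum())
    return {
        typ: max(st - base_travel, 1.0) for typ, st in sys.service_time.items()
    }


def compute_response_times(
    solution: SteadyStateSolution,
    space: StateSpace,
    policy: DispatchPolicy,
    sys: SystemDescription,
    structure: TransitionStructure | None = None,
    service_times: np.ndarray | None = None,
    on_scene: Mapping[str, float] | None = None,
    include_on_scene: bool = True,
) -> PerformanceMeasures:
    """Dispatch frequencies, response times and loss/empty probabilities.

    The mean response time of a sub atom is the dispatch-probability
    weighted mean of (journey time from the serving group's atom +
    on-scene component); lost calls are excluded from the mean and
    recorded as a loss probability.  Calls served from the queue are
    attributed to eligible groups in proportion to their completion
    rates ``n_t mu_t`` (the probability of freeing up first).
    """
    if structure is None:
        structure = build_generator(space, policy, sys)
    groups = space.groups
    T = len(groups)
    if service_times is None:
        service_times = np.array([sys.service_time[g.type] for g in groups])
    mu = 1.0 / np.asarray(service_times, float)
    sizes = np.array([g.size for g in groups], dtype=float)
    if on_scene is None:
        on_scene = on_scene_times(sys)
    onsc = np.array([on_scene[g.type] for g in groups]) if include_on_scene \
        else np.zeros(T)

    sub_atoms = structure.sub_atoms
    n_sub = len(sub_atoms)
    p = solution.p
    qs = np.array([st[1] for st in space.states])
    qg = np.array([st[2] for st in space.states])
    room = (qs + qg < space.Q_l) & (space.policy == "queue")

    freq = np.zeros((T, n_sub))
    loss = np.zeros(n_sub)
    comp_rate = sizes * mu  # first-to-free weights
    for m, (j, pr) in enumerate(sub_atoms):
        out_m = structure.outcome[m]
        for t in range(T):
            freq[t, m] = p[out_m == t].sum()
        blocked = out_m == _NO_FREE
        queued = float(p[blocked & room].sum())
        loss[m] = float(p[blocked & ~room].sum())
        if queued > 0:
            eligible = np.array(
                [pr == SERIOUS or not g.dedicated for g in groups]
            )
            w = comp_rate * eligible
            freq[:, m] += queued * w / w.sum()

    tt = sys.travel_time
    travel = np.array(
        [[tt[g.atom, j] for (j, _) in sub_atoms] for g in groups]
    )  # (T, n_sub)
    resp = travel + onsc[:, None]

    served = freq.sum(axis=0)
    if np.any(served <= 0):
        bad = [sub_atoms[m] for m in np.nonzero(served <= 0)[0]]
        raise ValueError(f"sub atoms with zero dispatch probability mass: {bad}")
    resp_sub = (freq * resp).sum(axis=0) / served

    lam = structure.rates
    flow = freq * lam[None, :]  # call flow group x sub atom
    group_flow = flow.sum(axis=1)
    resp_group = np.where(
        group_flow > 0, (flow * resp).sum(axis=1) / np.maximum(group_flow, 1e-300),
        service_times,
    )
    travel_group = np.where(
        group_flow > 0, (flow * travel).sum(axis=1) / np.maximum(group_flow, 1e-300),
        np.diag(tt)[[g.atom for g in groups]],
    )

    total_lam = lam.sum()
    loss_prob = float((lam * loss).sum() / total_lam) if total_lam > 0 else 0.0
    empty = space.index.get((tuple([0] * T), 0, 0))
    empty_prob = float(p[empty]) if empty is not None else 0.0

    return PerformanceMeasures(
        groups=groups,
        sub_atoms=list(sub_atoms),
        workload=compute_workloads(solution, space),
        dispatch_freq=freq,
        response_time_sub=resp_sub,
        response_time_group=resp_group,
        travel_component_group=travel_group,
        loss_prob_sub=loss,
        loss_prob=loss_prob,
        empty_prob=empty_prob,
        seed=policy.seed,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    config: Configuration,
    sys: SystemDescription,
    policy: DispatchPolicy | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    queue_policy: str = "queue",
    Q_l: int | None = None,
    seed: int = 0,
    state_cap: int = 200_000,
    include_on_scene: bool = True,
) -> CalibrationResult:
    """Fixed-point calibration of group service times for one configuration.

    Mean service time of a group = on-scene component of its type +
    mean journey time over the dispatches it actually performs, which
    itself depends on the model solution.  Starting from the fixture
    (type-level) service times, the model is re-solved until the
    largest change falls below ``tol`` minutes.  Non-convergence is a
    warning, not an error; the last iterate is flagged and returned.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    groups = build_server_groups(config, sys)
    if policy is None:
        policy = make_dispatch_policy(config, sys, seed, groups=groups)
    if Q_l is None:
        Q_l = sys.queue_capacity
    space = build_state_space(groups, Q_l, queue_policy, state_cap)
    structure = build_generator(space, policy, sys)
    onsc = on_scene_times(sys)
    onsc_vec = np.array([onsc[g.type] for g in groups])
    mu_inv = np.array([sys.service_time[g.type] for g in groups], dtype=float)

    converged = False
    iterations = 0
    measures: PerformanceMeasures | None = None
    for iterations in range(1, max_iter + 1):
        Q = structure.rate_matrix(mu_inv)
        sol = solve_steady_state(Q)
        measures = compute_response_times(
            sol, space, policy, sys,
            structure=structure, service_times=mu_inv, on_scene=onsc,
            include_on_scene=include_on_scene,
        )
        new = onsc_vec + measures.travel_component_group
        delta = float(np.max(np.abs(new - mu_inv)))
        mu_inv = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"calibration did not converge within {max_iter} iterations "
            f"for configuration {config.id}",
            RuntimeWarning,
            stacklevel=2,
        )
    assert measures is not None
    measures.converged = converged
    measures.iterations = iterations
    measures.seed = policy.seed
    return CalibrationResult(mu_inv, measures, converged, iterations)
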