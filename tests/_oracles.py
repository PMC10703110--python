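"""Independent brute-force oracles used only by the tests.

* an exact per-server hypercube chain (2^n busy states plus queue
  states) built directly from the dispatch narrative, against which the
  aggregated chain must agree exactly (lumpability of indistinguishable
  co-located servers under uniform within-group selection);
* an envelopment-form output-oriented VRS DEA solve, the LP dual of the
  multiplier form implemented in the package.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import linprog

from emsrank.hypercube import DispatchPolicy, StateSpace
from emsrank.system_model import SERIOUS, SystemDescription


def exact_hypercube_measures(
    space: StateSpace, policy: DispatchPolicy, sys: SystemDescription,
    service_times: np.ndarray,
):
    """Solve the exact per-server chain and aggregate to group level.

    Returns (workload per group, immediate dispatch frequency matrix
    group x sub atom, loss probability per sub atom, empty probability).
    Arrivals to a group are split uniformly over its free servers.
    """
    groups = space.groups
    servers: list[int] = []  # server -> group index
    for t, g in enumerate(groups):
        servers.extend([t] * g.size)
    n = len(servers)
    mu = 1.0 / np.asarray(service_times, float)
    Q_l = space.Q_l
    queueing = space.policy == "queue"
    sub_atoms = sys.sub_atoms
    lam = np.array([sys.rate(j, p) for j, p in sub_atoms])
    dedicated = np.array([groups[t].dedicated for t in servers])

    states = []
    for busy in product((0, 1), repeat=n):
        basics_full = all(b for b, d in zip(busy, dedicated) if not d)
        all_full = all(busy)
        for s in range(Q_l + 1):
            for g in range(Q_l + 1 - s):
                if s + g > 0 and not basics_full:
                    continue
                if s > 0 and not all_full:
                    continue
                states.append((busy, s, g))
    idx = {st: i for i, st in enumerate(states)}
    N = len(states)
    Q = np.zeros((N, N))

    for r, (busy, s, g) in enumerate(states):
        # arrivals
        for m, (j, p) in enumerate(sub_atoms):
            if lam[m] <= 0:
                continue
            target_group = None
            for t in policy.preference[(j, p)]:
                free = [k for k in range(n) if servers[k] == t and not busy[k]]
                if free:
                    target_group = (t, free)
                    break
            if target_group is not None:
                t, free = target_group
                for k in free:  # uniform choice among free members
                    b2 = list(busy)
                    b2[k] = 1
                    Q[r, idx[(tuple(b2), s, g)]] += lam[m] / len(free)
            elif queueing and s + g < Q_l:
                tgt = (busy, s + 1, g) if p == SERIOUS else (busy, s, g + 1)
                Q[r, idx[tgt]] += lam[m]
        # completions
        for k in range(n):
            if not busy[k]:
                continue
            if s > 0:
                tgt = (busy, s - 1, g)
            elif g > 0 and not dedicated[k]:
                tgt = (busy, s, g - 1)
            else:
                b2 = list(busy)
                b2[k] = 0
                tgt = (tuple(b2), s, g)
            Q[r, idx[tgt]] += mu[servers[k]]

    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    p_ss, *_ = np.linalg.lstsq(A, b, rcond=None)
    p_ss = np.clip(p_ss, 0, None)
    p_ss /= p_ss.sum()

    T = len(groups)
    sizes = np.array([g.size for g in groups], dtype=float)
    busy_mat = np.array([st[0] for st in states], dtype=float)
    per_server_busy = p_ss @ busy_mat
    workload = np.array(
        [per_server_busy[[k for k in range(n) if servers[k] == t]].mean()
         for t in range(T)]
    )

    freq = np.zeros((T, len(sub_atoms)))
    loss = np.zeros(len(sub_atoms))
    room = np.array([(st[1] + st[2] < Q_l) and queueing for st in states])
    for m, (j, p) in enumerate(sub_atoms):
        for r, (busy, s, g) in enumerate(states):
            tgt = None
            for t in policy.preference[(j, p)]:
                if any(servers[k] == t and not busy[k] for k in range(n)):
                    tgt = t
                    break
            if tgt is not None:
                freq[tgt, m] += p_ss[r]
            elif not room[r]:
                loss[m] += p_ss[r]
    empty_idx = idx[(tuple([0] * n), 0, 0)]
    return workload, freq, loss, float(p_ss[empty_idx])


def envelopment_output_vrs(X: np.ndarray, Y: np.ndarray, k0: int) -> float:
    """Output-oriented VRS expansion factor phi via the envelopment LP:
    max phi s.t. Y'lam >= phi*y0, X'lam <= x0, sum lam = 1, lam >= 0."""
    C, I = X.shape
    O = Y.shape[1]
    nv = C + 1
    c = np.zeros(nv)
    c[-1] = -1.0  # maximize phi
    A_ub = []
    b_ub = []
    for o in range(O):
        row = np.zeros(nv)
        row[:C] = -Y[:, o]
        row[-1] = Y[k0, o]
        A_ub.append(row)
        b_ub.append(0.0)
    for i in range(I):
        row = np.zeros(nv)
        row[:C] = X[:, i]
        A_ub.append(row)
        b_ub.append(X[k0, i])
    A_eq = np.zeros((1, nv))
    A_eq[0, :C] = 1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0, None)] * C + [(None, None)], method="highs")
    assert res.success, res.message
    return float(res.x[-1])
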