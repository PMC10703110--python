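"""Discrete-event simulation of the same emergency system.

An independent validation oracle for the analytic chain: Poisson
arrivals per sub atom, exponential service per group, the same dispatch
preference lists, the same non-preemptive priority queue (or loss)
behaviour.  Statistics are collected after a warmup period; confidence
intervals use batch means.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from emsrank.enumeration import Configuration
from emsrank.hypercube import (
    DispatchPolicy,
    build_server_groups,
    make_dispatch_policy,
    on_scene_times,
)
from emsrank.system_model import REGULAR, SERIOUS, SystemDescription


@dataclass
class SimulationResult:
    """Long-run estimates with batch-means confidence half-widths."""

    busy_fraction: np.ndarray          # per group
    busy_fraction_hw: np.ndarray
    response_time_sub: np.ndarray      # per sub atom (nan if never served)
    response_time_sub_hw: np.ndarray
    loss_fraction: float
    events: int
    seed: int


def simulate(
    config: Configuration,
    sys: SystemDescription,
    policy: DispatchPolicy | None = None,
    horizon: float = 50_000.0,
    warmup: float | None = None,
    seed: int = 0,
    Q_l: int | None = None,
    queue_policy: str = "queue",
    service_times: np.ndarray | None = None,
    n_batches: int = 10,
) -> SimulationResult:
    """Simulate one configuration and return long-run statistics.

    Time is in minutes.  The event queue is keyed by (time, sequence)
    for deterministic tie-breaking; the warmup defaults to 10% of the
    horizon.  Response times are recorded at dispatch as the mean
    journey time of the serving group's atom plus the on-scene
    component, matching the analytic definition (queueing delay is
    tracked by the chain's state, not added to this measure).
    """
    if warmup is None:
        warmup = 0.1 * horizon
    if not horizon > warmup >= 0:
        raise ValueError("need horizon > warmup >= 0")
    groups = build_server_groups(config, sys)
    if policy is None:
        policy = make_dispatch_policy(config, sys, seed, groups=groups)
    if Q_l is None:
        Q_l = sys.queue_capacity
    if queue_policy == "no_queue":
        Q_l = 0
    rng = np.random.default_rng(seed)

    T = len(groups)
    sizes = np.array([g.size for g in groups])
    if service_times is None:
        service_times = np.array([sys.service_time[g.type] for g in groups])
    mu = 1.0 / np.asarray(service_times, float)
    onsc = on_scene_times(sys)
    resp_of = {
        (t, m): sys.travel_time[groups[t].atom, j] + onsc[groups[t].type]
        for t in range(T)
        for m, (j, _) in enumerate(sys.sub_atoms)
    }

    sub_atoms = sys.sub_atoms
    lam = np.array([sys.rate(j, p) for j, p in sub_atoms])
    active = np.nonzero(lam > 0)[0]

    busy = np.zeros(T, dtype=int)
    queue_s: list[int] = []  # sub-atom indices of waiting serious calls (FIFO)
    queue_g: list[int] = []

    batch_len = (horizon - warmup) / n_batches
    busy_time = np.zeros((n_batches, T))
    resp_sum = np.zeros((n_batches, len(sub_atoms)))
    resp_cnt = np.zeros((n_batches, len(sub_atoms)))
    lost = 0
    arrived = 0
    last_t = warmup
    events = 0

    def batch_of(t: float) -> int:
        return min(int((t - warmup) / batch_len), n_batches - 1)

    heap: list[tuple[float, int, int, int]] = []  # (time, seq, kind, payload)
    seq = 0
    ARRIVAL, COMPLETION = 0, 1
    for m in active:
        t0 = rng.exponential(1.0 / lam[m])
        heapq.heappush(heap, (t0, seq, ARRIVAL, m))
        seq += 1

    def record(t: float, m: int, grp: int) -> None:
        if t >= warmup:
            b = batch_of(t)
            resp_sum[b, m] += resp_of[(grp, m)]
            resp_cnt[b, m] += 1

    def start_service(t: float, m: int, grp: int) -> None:
        nonlocal seq
        busy[grp] += 1
        record(t, m, grp)
        done = t + rng.exponential(1.0 / mu[grp])
        heapq.heappush(heap, (done, seq, COMPLETION, grp))
        seq += 1

    while heap:
        t, _, kind, payload = heapq.heappop(heap)
        if t > horizon:
            break
        # accumulate busy time since last event (within collection window)
        if t > warmup:
            lo = max(last_t, warmup)
            a, b = batch_of(lo), batch_of(t)
            if a == b:
                busy_time[a] += (t - lo) * busy
            else:
                edge = warmup + (a + 1) * batch_len
                busy_time[a] += (edge - lo) * busy
                for k in range(a + 1, b):
                    busy_time[k] += batch_len * busy
                busy_time[b] += (t - (warmup + b * batch_len)) * busy
        last_t = max(last_t, t)
        events += 1

        if kind == ARRIVAL:
            m = payload
            j, p = sub_atoms[m]
            if t >= warmup:
                arrived += 1
            served = False
            for grp in policy.preference[(j, p)]:
                if busy[grp] < sizes[grp]:
                    start_service(t, m, grp)
                    served = True
                    break
            if not served:
                if len(queue_s) + len(queue_g) < Q_l:
                    (queue_s if p == SERIOUS else queue_g).append(m)
                elif t >= warmup:
                    lost += 1
            nxt = t + rng.exponential(1.0 / lam[m])
            heapq.heappush(heap, (nxt, seq, ARRIVAL, m))
            seq += 1
        else:
            grp = payload
            busy[grp] -= 1
            if queue_s:
                start_service(t, queue_s.pop(0), grp)
            elif queue_g and not policy.groups[grp].dedicated:
                start_service(t, queue_g.pop(0), grp)

    busy_frac = busy_time / (batch_len * sizes[None, :])
    resp_batch = np.divide(
        resp_sum, resp_cnt, out=np.full_like(resp_sum, np.nan), where=resp_cnt > 0
    )

    def batch_ci(x: np.ndarray):
        from scipy import stats

        mean = np.nanmean(x, axis=0)
        k = np.sum(~np.isnan(x), axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
        tq = stats.t.ppf(0.995, np.maximum(k - 1, 1))  # 99% two-sided
        hw = tq * sd / np.sqrt(np.maximum(k, 1))
        return mean, hw

    bf_mean, bf_hw = batch_ci(busy_frac)
    rt_mean, rt_hw = batch_ci(resp_batch)
    loss_fraction = lost / arrived if arrived else 0.0

    return SimulationResult(
        busy_fraction=bf_mean,
        busy_fraction_hw=np.maximum(bf_hw, 1e-12),
        response_time_sub=rt_mean,
        response_time_sub_hw=np.maximum(rt_hw, 1e-12),
        loss_fraction=loss_fraction,
        events=events,
        seed=seed,
    )
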