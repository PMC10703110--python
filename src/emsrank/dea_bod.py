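"""Constrained output-oriented BCC / benefit-of-the-doubt DEA.

Each server configuration is a decision-making unit (DMU).  Inputs are
the per-server workloads of the basic units (undesirable); outputs are
reciprocals of mean response times — per atom for regular calls
(``y_h``), per atom for serious calls (``y_h^S``) and per basic server
(``z_i``) — so a DMU with ``n`` basic servers over ``A`` atoms has
``I = n`` inputs and ``O = 2A + n`` outputs.

The multiplier LP solved for DMU 0 is

    min   sum_i gamma_i rho_i0  -  w
    s.t.  sum_h alpha_h y_h0 + sum_h alpha_h^S y_h0^S
              + sum_i beta_i z_i0  =  1
          (outputs_k . weights) - (inputs_k . gamma) + w <= 0   for all k
          sum_h alpha_h y_h0      >= 0.01 P     (group contributions,
          sum_h alpha_h^S y_h0^S  >= 0.01 P      omitted when P = 0)
          sum_i beta_i z_i0       >= 0.01 P
          alpha_h^S - alpha_h >= eps            (assurance region, per atom)
          all weights >= eps,  w free

with efficiency ``1 / phi`` for optimum ``phi >= 1``.  The inverted
frontier swaps input and output roles (scoring each DMU by its worst
practices); the composite index is the normalized mean of the standard
efficiency and one minus the inverted efficiency.

Columns are mean-normalized before solving for numerical conditioning;
efficiencies are invariant to positive column rescaling (``eps`` and
the group bounds act on the normalized scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from emsrank.hypercube import PerformanceMeasures
from emsrank.system_model import REGULAR, SERIOUS


@dataclass
class DEAProblem:
    """Input/output matrices for all DMUs plus model parameters."""

    dmu_ids: list[int]
    rho: np.ndarray   # (C, I)  workloads
    y: np.ndarray     # (C, A)  1 / regular response time per atom
    ys: np.ndarray    # (C, A)  1 / serious response time per atom
    z: np.ndarray     # (C, n)  1 / per-server response time
    P: float = 20.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("rho", "y", "ys", "z"):
            m = np.asarray(getattr(self, name), float)
            setattr(self, name, m)
            if m.ndim != 2 or m.shape[0] != len(self.dmu_ids):
                raise ValueError(f"{name}: bad shape {m.shape}")
            if m.size and not np.all(m > 0):
                k = int(np.argwhere(m <= 0)[0][0])
                raise ValueError(
                    f"{name} has a non-positive entry for DMU {self.dmu_ids[k]}"
                )
        if self.y.shape != self.ys.shape:
            raise ValueError("y and ys must have identical shapes")
        if self.P < 0 or 3 * 0.01 * self.P > 1:
            raise ValueError(f"P={self.P} infeasible: need 0 <= 0.03 P <= 1")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_atoms(self) -> int:
        return self.y.shape[1]

    @property
    def n_servers(self) -> int:
        return self.z.shape[1]


@dataclass
class DEASolution:
    """One multiplier-LP solve: objective, weights, efficiency, status."""

    phi: float
    efficiency: float
    gamma: np.ndarray
    alpha: np.ndarray
    alpha_s: np.ndarray
    beta: np.ndarray
    w: float
    status: str  # "optimal" | "infeasible" | "failed"


@dataclass
class CompositeRanking:
    """Standard/inverted efficiencies, composite index and ranks."""

    dmu_ids: list[int]
    standard: np.ndarray
    inverted: np.ndarray
    composite: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "config_id": self.dmu_ids,
                "standard_eff": self.standard,
                "inverted_eff": self.inverted,
                "composite_index": self.composite,
                "rank": self.rank,
            }
        )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dea_dataset(
    measures: Sequence[PerformanceMeasures],
    dmu_ids: Sequence[int] | None = None,
    P: float = 20.0,
    eps: float = 1e-6,
    server_type: str = "BSU",
) -> DEAProblem:
    """Assemble the DEA matrices from solved queueing measures.

    Only the movable basic fleet enters: dedicated advanced units keep
    a fixed base, so their workloads and times carry no information
    about the configuration.  Per-server columns are laid out in atom
    order (group values repeated by group size), which is deterministic
    because servers within a group are indistinguishable.
    """
    if not measures:
        raise ValueError("no measures supplied")
    if dmu_ids is None:
        dmu_ids = list(range(1, len(measures) + 1))
    rho_rows, y_rows, ys_rows, z_rows = [], [], [], []
    for did, m in zip(dmu_ids, measures):
        rho_rows.append(m.workload_per_server(server_type))
        resp = {sub: t for sub, t in zip(m.sub_atoms, m.response_time_sub)}
        atoms = sorted({j for j, _ in m.sub_atoms})
        try:
            y_rows.append([1.0 / resp[(j, REGULAR)] for j in atoms])
            ys_rows.append([1.0 / resp[(j, SERIOUS)] for j in atoms])
            z_rows.append(1.0 / m.response_time_per_server(server_type))
        except ZeroDivisionError:
            raise ValueError(f"zero response time in DMU {did}") from None
    shape0 = (len(rho_rows[0]), len(y_rows[0]), len(z_rows[0]))
    for did, r, yy, zz in zip(dmu_ids, rho_rows, y_rows, z_rows):
        if (len(r), len(yy), len(zz)) != shape0:
            raise ValueError(f"DMU {did} has inconsistent dimensions")
    return DEAProblem(
        dmu_ids=list(dmu_ids),
        rho=np.array(rho_rows),
        y=np.array(y_rows),
        ys=np.array(ys_rows),
        z=np.array(z_rows),
        P=P,
        eps=eps,
    )


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

def _bcc_output_multiplier(
    X: np.ndarray,
    Y: np.ndarray,
    k0: int,
    eps: float,
    out_groups: Sequence[np.ndarray] = (),
    in_groups: Sequence[np.ndarray] = (),
    out_assurance: Sequence[tuple[int, int]] = (),
    in_assurance: Sequence[tuple[int, int]] = (),
    P: float = 0.0,
) -> tuple[float, np.ndarray] | None:
    """Generic output-oriented VRS multiplier LP with weight restrictions.

    Variables are ``[v (input weights), u (output weights), w]``.
    Assurance pairs ``(low, high)`` require ``weight_high - weight_low
    >= eps`` on the given side.  Group constraints require the named
    columns' weighted DMU-0 value to reach ``0.01 P``.  Returns
    ``(phi, x)`` with the raw variable vector, or None if the LP is
    infeasible/failed.
    """
    C, I = X.shape
    O = Y.shape[1]
    nv = I + O + 1
    c = np.zeros(nv)
    c[:I] = X[k0]
    c[-1] = -1.0

    A_eq = np.zeros((1, nv))
    A_eq[0, I:I + O] = Y[k0]
    b_eq = np.array([1.0])

    rows = []
    rhs = []
    for k in range(C):
        r = np.zeros(nv)
        r[:I] = -X[k]
        r[I:I + O] = Y[k]
        r[-1] = 1.0
        rows.append(r)
        rhs.append(0.0)
    if P > 0:
        for cols in out_groups:
            r = np.zeros(nv)
            r[I + np.asarray(cols)] = -Y[k0][np.asarray(cols)]
            rows.append(r)
            rhs.append(-0.01 * P)
        for cols in in_groups:
            r = np.zeros(nv)
            r[np.asarray(cols)] = -X[k0][np.asarray(cols)]
            rows.append(r)
            rhs.append(-0.01 * P)
    for lo, hi in out_assurance:
        r = np.zeros(nv)
        r[I + lo] = 1.0
        r[I + hi] = -1.0
        rows.append(r)
        rhs.append(-eps)
    for lo, hi in in_assurance:
        r = np.zeros(nv)
        r[lo] = 1.0
        r[hi] = -1.0
        rows.append(r)
        rhs.append(-eps)

    bounds = [(eps, None)] * (I + O) + [(None, None)]
    res = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return None
    return float(res.fun), res.x


def _normalized(problem: DEAProblem):
    X = problem.rho / problem.rho.mean(axis=0)
    blocks = [b for b in (problem.y, problem.ys, problem.z) if b.size]
    Y = np.hstack([b / b.mean(axis=0) for b in blocks]) if blocks else \
        np.zeros((problem.n_dmus, 0))
    return X, Y


def _structure(problem: DEAProblem):
    A = problem.n_atoms
    nz = problem.n_servers
    out_groups = []
    if A:
        out_groups = [np.arange(A), np.arange(A, 2 * A)]
    if nz:
        out_groups.append(np.arange(2 * A, 2 * A + nz))
    assurance = [(h, A + h) for h in range(A)]  # alpha_h^S >= alpha_h + eps
    return out_groups, assurance


def _solve_one(problem: DEAProblem, k: int, inverted: bool) -> DEASolution:
    X, Y = _normalized(problem)
    out_groups, assurance = _structure(problem)
    in_groups: list = []
    in_assurance: list = []
    if inverted:
        X, Y = Y, X
        in_groups, out_groups = out_groups, []
        in_assurance, assurance = assurance, []

    A = problem.n_atoms
    nz = problem.n_servers
    res = None
    for attempt, eps in enumerate((problem.eps, problem.eps / 10.0)):
        res = _bcc_output_multiplier(
            X, Y, k, eps,
            out_groups=out_groups, in_groups=in_groups,
            out_assurance=assurance, in_assurance=in_assurance,
            P=problem.P,
        )
        if res is not None:
            if attempt:
                warnings.warn(
                    f"DMU {problem.dmu_ids[k]}: eps relaxed 10x to obtain a "
                    "feasible weight set",
                    RuntimeWarning,
                    stacklevel=3,
                )
            break
    if res is None:
        nan = np.nan
        return DEASolution(
            phi=nan, efficiency=nan,
            gamma=np.full(problem.rho.shape[1], nan),
            alpha=np.full(A, nan), alpha_s=np.full(A, nan),
            beta=np.full(nz, nan), w=nan, status="infeasible",
        )
    phi, x = res
    I = X.shape[1]
    if inverted:
        # inputs are the (y, ys, z) blocks, outputs the workloads
        gamma = x[I:I + problem.rho.shape[1]]
        alpha = x[:A]
        alpha_s = x[A:2 * A]
        beta = x[2 * A:2 * A + nz]
    else:
        gamma = x[:I]
        alpha = x[I:I + A]
        alpha_s = x[I + A:I + 2 * A]
        beta = x[I + 2 * A:I + 2 * A + nz]
    return DEASolution(
        phi=phi, efficiency=1.0 / phi,
        gamma=gamma, alpha=alpha, alpha_s=alpha_s, beta=beta,
        w=float(x[-1]), status="optimal",
    )


def solve_bcc_output(dmu0: int, problem: DEAProblem) -> DEASolution:
    """Solve the constrained multiplier LP for one DMU (0-based index).

    On infeasibility (weight restrictions too tight for this DMU's
    data) ``eps`` is relaxed once by a factor of 10 with a warning
    before reporting failure.  Weights are on the mean-normalized
    column scale.
    """
    return _solve_one(problem, dmu0, inverted=False)


def efficiency_all(problem: DEAProblem) -> tuple[np.ndarray, pd.DataFrame]:
    """Standard-frontier efficiencies for every DMU plus a weight report.

    Per-DMU failures are recorded in the report (efficiency NaN)
    without aborting the batch.
    """
    return _solve_all(problem, inverted=False)


def inverted_efficiency_all(problem: DEAProblem) -> np.ndarray:
    """Inverted-frontier efficiencies (inputs and outputs role-swapped)."""
    eff, _ = _solve_all(problem, inverted=True)
    return eff


def _solve_all(problem: DEAProblem, inverted: bool):
    eff = np.full(problem.n_dmus, np.nan)
    report_rows = []
    for k in range(problem.n_dmus):
        sol = _solve_one(problem, k, inverted)
        row: dict = {"config_id": problem.dmu_ids[k], "status": sol.status}
        if sol.status == "optimal":
            eff[k] = sol.efficiency
            row["phi"] = sol.phi
            row["w"] = sol.w
            row.update({f"gamma_{i + 1}": v for i, v in enumerate(sol.gamma)})
            row.update({f"alpha_{h + 1}": v for h, v in enumerate(sol.alpha)})
            row.update({f"alphaS_{h + 1}": v for h, v in enumerate(sol.alpha_s)})
            row.update({f"beta_{i + 1}": v for i, v in enumerate(sol.beta)})
        report_rows.append(row)
    return eff, pd.DataFrame(report_rows)


def composite_index(
    standard: np.ndarray,
    inverted: np.ndarray,
    dmu_ids: Sequence[int] | None = None,
) -> CompositeRanking:
    """Normalized mean of standard efficiency and inverted inefficiency.

    ``raw_k = (standard_k + (1 - inverted_k)) / 2`` normalized by its
    maximum; ranks descend by composite with exact ties sharing the
    best (minimum) rank.
    """
    standard = np.asarray(standard, float)
    inverted = np.asarray(inverted, float)
    if standard.shape != inverted.shape:
        raise ValueError("standard and inverted must have equal lengths")
    if dmu_ids is None:
        dmu_ids = list(range(1, len(standard) + 1))
    raw = (standard + (1.0 - inverted)) / 2.0
    mx = raw.max()
    if mx <= 0:
        raise ValueError("composite index undefined: all raw scores <= 0")
    comp = raw / mx
    if np.allclose(comp, comp[0]):
        warnings.warn("all composite scores tie", RuntimeWarning, stacklevel=2)
    # competition ranking, descending; ties share the minimum rank
    order = np.lexsort((np.asarray(dmu_ids), -comp))
    rank = np.empty(len(comp), dtype=int)
    prev_val, prev_rank = None, 0
    for pos, k in enumerate(order, start=1):
        if prev_val is not None and comp[k] == prev_val:
            rank[k] = prev_rank
        else:
            rank[k] = pos
            prev_val, prev_rank = comp[k], pos
    return CompositeRanking(list(dmu_ids), standard, inverted, comp, rank)
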