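"""Canonical data model for a spatially distributed emergency-care system.

An urban service region is partitioned into *atoms* (geographic zones).
Each atom generates two independent Poisson call streams — *serious*
(life-threatening, answered preferentially by dedicated advanced units)
and *regular* — so the queuing model sees ``2 A`` sub atoms.  Servers are
ambulances of two types: basic service units (BSU), free to be placed in
any atom, and advanced service units (ASU), dedicated to serious calls
and usually pinned to their base atoms.

Internally all rates are **per minute** and all times are **minutes**;
fixture files carry arrival rates per hour (the loader converts), so
``rate x service_time`` is a dimensionless offered load in erlangs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SERIOUS = "serious"
REGULAR = "regular"
PRIORITIES = (SERIOUS, REGULAR)

#: sub-atom suffix convention used by the case tables: "a" = advanced
#: (serious) calls, "b" = basic (regular) calls.
_PRIORITY_SUFFIX = {SERIOUS: "a", REGULAR: "b"}


class SystemValidationError(ValueError):
    """Raised when a system description violates its invariants."""


@dataclass(frozen=True)
class Fleet:
    """A homogeneous pool of servers of one type.

    Parameters
    ----------
    type:
        Server-type tag, e.g. ``"BSU"`` or ``"ASU"``.
    count:
        Number of allocatable servers of this type (>= 1).
    dedicated:
        True for fleets that answer only serious calls (ASUs).
    fixed_atoms:
        Length-A allocation vector used when the fleet does not move
        between configurations (dedicated fleets by default).  Must sum
        to ``count`` when present.
    """

    type: str
    count: int
    dedicated: bool = False
    fixed_atoms: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise SystemValidationError(
                f"fleet {self.type!r}: count must be >= 1, got {self.count}"
            )
        if self.fixed_atoms is not None and sum(self.fixed_atoms) != self.count:
            raise SystemValidationError(
                f"fleet {self.type!r}: fixed_atoms {self.fixed_atoms} "
                f"must sum to count {self.count}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """A demand/queue scenario, e.g. ``P25pq`` = +25% demand, queue allowed."""

    demand_multiplier: float = 1.0
    queue_policy: str = "queue"  # "queue" | "no_queue"
    label: str = "P0pq"

    def __post_init__(self) -> None:
        if self.demand_multiplier <= 0:
            raise SystemValidationError("demand multiplier must be > 0")
        if self.queue_policy not in ("queue", "no_queue"):
            raise SystemValidationError(
                f"unknown queue policy {self.queue_policy!r}"
            )

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        """Parse labels of the form ``P<percent><pq|nq>``."""
        body = label.strip()
        if not body.startswith("P") or body[-2:] not in ("pq", "nq"):
            raise SystemValidationError(f"cannot parse scenario label {label!r}")
        pct = float(body[1:-2])
        policy = "queue" if body.endswith("pq") else "no_queue"
        return cls(1.0 + pct / 100.0, policy, body)


@dataclass(frozen=True)
class SystemDescription:
    """A validated emergency system: atoms, demand, travel times, fleets."""

    atoms: tuple[str, ...]
    #: (atom_index, priority) -> calls per MINUTE
    arrival_rate: Mapping[tuple[int, str], float]
    #: A x A mean journey times in minutes (row = server atom, col = call atom)
    travel_time: np.ndarray
    #: server type -> mean total response time mu^-1 (travel + on-scene), minutes
    service_time: Mapping[str, float]
    fleets: tuple[Fleet, ...]
    queue_capacity: int = 5
    time_unit: str = "min"
    name: str = "system"

    def __post_init__(self) -> None:
        object.__setattr__(self, "travel_time", np.asarray(self.travel_time, float))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        A = len(self.atoms)
        if A < 2:
            raise SystemValidationError(f"need at least 2 atoms, got {A}")
        t = self.travel_time
        if t.shape != (A, A):
            raise SystemValidationError(
                f"travel matrix shape {t.shape} does not match {A} atoms"
            )
        if not np.all(t > 0):
            raise SystemValidationError("travel times must be strictly positive")
        total = 0.0
        for (j, p), lam in self.arrival_rate.items():
            if not (0 <= j < A) or p not in PRIORITIES:
                raise SystemValidationError(f"bad sub atom key ({j}, {p!r})")
            if lam < 0:
                raise SystemValidationError(
                    f"negative arrival rate for atom {j + 1} priority {p}"
                )
            total += lam
        if total <= 0:
            raise SystemValidationError("at least one arrival rate must be > 0")
        for typ, st in self.service_time.items():
            if st <= 0:
                raise SystemValidationError(
                    f"service time for {typ!r} must be > 0, got {st}"
                )
        if not self.fleets:
            raise SystemValidationError("at least one fleet is required")
        for f in self.fleets:
            if f.type not in self.service_time:
                raise SystemValidationError(
                    f"fleet {f.type!r} has no service time entry"
                )
            if f.fixed_atoms is not None and len(f.fixed_atoms) != A:
                raise SystemValidationError(
                    f"fleet {f.type!r}: fixed_atoms length != number of atoms"
                )
        if self.queue_capacity < 0:
            raise SystemValidationError("queue capacity must be >= 0")

    # -- convenience ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def sub_atoms(self) -> list[tuple[int, str]]:
        """All (atom, priority) demand points, serious first within an atom."""
        return [(j, p) for j in range(self.n_atoms) for p in PRIORITIES]

    def rate(self, atom: int, priority: str) -> float:
        return float(self.arrival_rate.get((atom, priority), 0.0))

    def total_rate(self, per: str = "min") -> float:
        total = sum(self.arrival_rate.values())
        return total * 60.0 if per == "hour" else total

    def fleet(self, type: str) -> Fleet:
        for f in self.fleets:
            if f.type == type:
                return f
        raise KeyError(type)

    def offered_load(self) -> float:
        """Total offered load in erlangs, lambda x mean service time."""
        lam_by_type = self.total_rate()  # all calls
        # weight service times by fleet share of capacity
        counts = {f.type: f.count for f in self.fleets}
        n = sum(counts.values())
        mean_st = sum(self.service_time[t] * c for t, c in counts.items()) / n
        return lam_by_type * mean_st


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

_FILES = ("atoms.csv", "arrival_rates.csv", "travel_times.csv", "servers.csv")


def load_system(path: str | Path, queue_capacity: int = 5) -> SystemDescription:
    """Load a system from a directory of CSV files.

    Expected schema (header rows, atom ids 1-based):

    * ``atoms.csv``: atom_id,name
    * ``arrival_rates.csv``: atom_id,priority{serious|regular},rate_per_hour
    * ``travel_times.csv``: from_atom,to_atom,minutes
    * ``servers.csv``: server_type,count,dedicated{0|1},base_atom,
      mean_service_time_min

    Arrival rates are converted from per-hour to per-minute at this
    boundary; atom order is the file order.
    """
    path = Path(path)
    for fname in _FILES:
        if not (path / fname).exists():
            raise SystemValidationError(f"missing file {fname} in {path}")

    atoms_df = pd.read_csv(path / "atoms.csv")
    atoms = tuple(str(n) for n in atoms_df["name"])
    index_of = {int(a): i for i, a in enumerate(atoms_df["atom_id"])}
    A = len(atoms)

    rates: dict[tuple[int, str], float] = {}
    for rec in pd.read_csv(path / "arrival_rates.csv").itertuples():
        if rec.priority not in PRIORITIES:
            raise SystemValidationError(
                f"unknown priority tag {rec.priority!r} for atom {rec.atom_id}"
            )
        if rec.rate_per_hour < 0:
            raise SystemValidationError(
                f"negative rate for atom {rec.atom_id} priority {rec.priority}"
            )
        rates[(index_of[int(rec.atom_id)], rec.priority)] = rec.rate_per_hour / 60.0

    tt = np.full((A, A), np.nan)
    for rec in pd.read_csv(path / "travel_times.csv").itertuples():
        tt[index_of[int(rec.from_atom)], index_of[int(rec.to_atom)]] = rec.minutes
    if np.isnan(tt).any():
        raise SystemValidationError("travel_times.csv does not cover all atom pairs")

    service: dict[str, float] = {}
    fleet_rows: dict[str, list] = {}
    for rec in pd.read_csv(path / "servers.csv").itertuples():
        fleet_rows.setdefault(str(rec.server_type), []).append(rec)
    fleets = []
    for typ, rows in fleet_rows.items():
        count = int(sum(r.count for r in rows))
        dedicated = bool(rows[0].dedicated)
        service[typ] = float(rows[0].mean_service_time_min)
        fixed = None
        if dedicated:
            vec = [0] * A
            for r in rows:
                if pd.isna(r.base_atom):
                    raise SystemValidationError(
                        f"dedicated fleet {typ!r} row without base_atom"
                    )
                vec[index_of[int(r.base_atom)]] += int(r.count)
            fixed = tuple(vec)
        fleets.append(Fleet(typ, count, dedicated, fixed))

    return SystemDescription(
        atoms=atoms,
        arrival_rate=rates,
        travel_time=tt,
        service_time=service,
        fleets=tuple(fleets),
        queue_capacity=queue_capacity,
        name=path.name,
    )


def write_system(sys: SystemDescription, path: str | Path) -> None:
    """Write a system back to the documented CSV schema (round-trippable)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    A = sys.n_atoms
    pd.DataFrame(
        {"atom_id": range(1, A + 1), "name": list(sys.atoms)}
    ).to_csv(path / "atoms.csv", index=False)
    rows = [
        {"atom_id": j + 1, "priority": p, "rate_per_hour": sys.rate(j, p) * 60.0}
        for j, p in sys.sub_atoms
    ]
    pd.DataFrame(rows).to_csv(path / "arrival_rates.csv", index=False)
    rows = [
        {"from_atom": i + 1, "to_atom": j + 1, "minutes": sys.travel_time[i, j]}
        for i in range(A)
        for j in range(A)
    ]
    pd.DataFrame(rows).to_csv(path / "travel_times.csv", index=False)
    srows = []
    for f in sys.fleets:
        if f.dedicated and f.fixed_atoms is not None:
            for j, c in enumerate(f.fixed_atoms):
                if c > 0:
                    srows.append(
                        {
                            "server_type": f.type,
                            "count": c,
                            "dedicated": 1,
                            "base_atom": j + 1,
                            "mean_service_time_min": sys.service_time[f.type],
                        }
                    )
        else:
            srows.append(
                {
                    "server_type": f.type,
                    "count": f.count,
                    "dedicated": int(f.dedicated),
                    "base_atom": "",
                    "mean_service_time_min": sys.service_time[f.type],
                }
            )
    pd.DataFrame(srows).to_csv(path / "servers.csv", index=False)


def load_fixture(name: str, queue_capacity: int = 5) -> SystemDescription:
    """Load one of the packaged case studies: ``"bauru"`` or ``"ribeirao_preto"``."""
    root = importlib.resources.files("emsrank") / "data" / name
    with importlib.resources.as_file(root) as p:
        return load_system(p, queue_capacity=queue_capacity)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def scale_demand(sys: SystemDescription, factor: float) -> SystemDescription:
    """Return a copy with every sub-atom arrival rate multiplied by ``factor``."""
    if factor <= 0:
        raise SystemValidationError(f"demand factor must be > 0, got {factor}")
    rates = {k: v * factor for k, v in sys.arrival_rate.items()}
    return replace(sys, arrival_rate=rates)


def generate_synthetic_system(
    A: int,
    n_bsu: int,
    n_asu: int = 0,
    seed: int = 0,
    target_utilization: float = 0.5,
    queue_capacity: int = 5,
) -> SystemDescription:
    """Generate a random system with the structure of the case studies.

    Travel times are positive and roughly symmetric, with intra-atom
    journeys drawn on the same scale as inter-atom ones (in dense urban
    areas crossing an atom can take longer than hopping to a neighbour).
    Each atom carries a serious and a regular call stream; serious calls
    are a ~10-15% share, mirroring the advanced/basic split of the case
    tables.  Total demand is scaled so that the offered load stays below
    ``target_utilization`` x fleet capacity (must be < 0.9).
    """
    if A < 2:
        raise SystemValidationError("A must be >= 2")
    if n_bsu < 1:
        raise SystemValidationError("n_bsu must be >= 1")
    if n_asu < 0:
        raise SystemValidationError("n_asu must be >= 0")
    if not 0 < target_utilization < 0.9:
        raise SystemValidationError("target_utilization must be in (0, 0.9)")
    rng = np.random.default_rng(seed)

    base = rng.uniform(6.0, 16.0, size=(A, A))
    tt = (base + base.T) / 2.0
    tt[np.diag_indices(A)] = rng.uniform(6.0, 12.0, size=A)

    service = {"BSU": float(rng.uniform(30.0, 50.0))}
    fleets = [Fleet("BSU", n_bsu, dedicated=False)]
    if n_asu > 0:
        service["ASU"] = float(rng.uniform(40.0, 60.0))
        vec = [0] * A
        for _ in range(n_asu):
            vec[int(rng.integers(A))] += 1
        fleets.append(Fleet("ASU", n_asu, dedicated=True, fixed_atoms=tuple(vec)))

    n = n_bsu + n_asu
    mean_st = sum(service[f.type] * f.count for f in fleets) / n
    lam_total = target_utilization * n / mean_st  # per minute
    weights = rng.dirichlet(np.ones(A) * 2.0)
    serious_share = rng.uniform(0.08, 0.15, size=A)
    rates: dict[tuple[int, str], float] = {}
    for j in range(A):
        rates[(j, SERIOUS)] = float(lam_total * weights[j] * serious_share[j])
        rates[(j, REGULAR)] = float(lam_total * weights[j] * (1 - serious_share[j]))

    return SystemDescription(
        atoms=tuple(f"Z{j + 1}" for j in range(A)),
        arrival_rate=rates,
        travel_time=tt,
        service_time=service,
        fleets=tuple(fleets),
        queue_capacity=queue_capacity,
        name=f"synthetic-A{A}-b{n_bsu}-a{n_asu}-s{seed}",
    )
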