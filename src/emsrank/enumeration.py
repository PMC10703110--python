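"""Exhaustive enumeration of server-to-atom allocations.

Every way of distributing ``n`` indistinguishable servers over ``A``
atoms is one candidate configuration (one DMU for the DEA stage).  The
count is obtained by listing the integer partitions of ``n`` into at
most ``A`` parts, zero-filling each to length ``A``, and counting the
distinct permutations of each filled partition:

    C_k = A! / prod_j R_j!        C = sum_k C_k

where ``R_j`` is the number of repetitions of term ``j`` (zeros
included) in the filled partition.  ``C`` equals the weak-composition
count ``C(n + A - 1, A - 1)``, which serves as an independent oracle.

Different server types are enumerated separately and combined as a
Cartesian product.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping, Sequence


@dataclass(frozen=True)
class Partition:
    """An integer partition: non-increasing positive terms."""

    terms: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.terms or any(t <= 0 for t in self.terms):
            raise ValueError(f"partition terms must be positive: {self.terms}")
        if any(a < b for a, b in zip(self.terms, self.terms[1:])):
            raise ValueError(f"partition terms must be non-increasing: {self.terms}")

    @property
    def n(self) -> int:
        return sum(self.terms)

    def repetition_counts(self, A: int) -> Mapping[int, int]:
        """Multiplicity of each term value after zero-filling to length A."""
        if len(self.terms) > A:
            raise ValueError(
                f"partition {self.terms} has more than {A} parts"
            )
        counts = Counter(self.terms)
        zeros = A - len(self.terms)
        if zeros:
            counts[0] = zeros
        return dict(counts)


@dataclass(frozen=True)
class Configuration:
    """One complete allocation of all server types to atoms (a DMU)."""

    id: int
    allocation: Mapping[str, tuple[int, ...]]

    def vector(self, type: str) -> tuple[int, ...]:
        return tuple(self.allocation[type])


def integer_partitions(n: int, max_parts: int) -> list[Partition]:
    """All partitions of ``n`` into at most ``max_parts`` positive parts.

    Returned in reverse-lexicographic order ("4", "3+1", "2+2", ...).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if max_parts < 1:
        raise ValueError(f"max_parts must be >= 1, got {max_parts}")

    out: list[Partition] = []

    def rec(remaining: int, cap: int, prefix: list[int]) -> None:
        if remaining == 0:
            out.append(Partition(tuple(prefix)))
            return
        if len(prefix) == max_parts:
            return
        for part in range(min(cap, remaining), 0, -1):
            prefix.append(part)
            rec(remaining - part, part, prefix)
            prefix.pop()

    rec(n, n, [])
    return out


def count_permutations(partition: Partition, A: int) -> int:
    """Number of distinct length-A arrangements of a zero-filled partition,
    ``A! / prod_j R_j!`` as an exact integer."""
    reps = partition.repetition_counts(A)
    denom = math.prod(math.factorial(r) for r in reps.values())
    return math.factorial(A) // denom


def enumerate_allocations(n: int, A: int) -> list[tuple[int, ...]]:
    """All distinct non-negative length-A vectors summing to ``n``.

    Deterministic reverse-lexicographic order, so configuration ids are
    stable across runs.  ``n = 0`` yields the single all-zero vector.
    """
    if A < 1:
        raise ValueError(f"A must be >= 1, got {A}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")

    out: list[tuple[int, ...]] = []

    def rec(remaining: int, slots: int, prefix: list[int]) -> None:
        if slots == 1:
            out.append(tuple(prefix + [remaining]))
            return
        for first in range(remaining, -1, -1):
            prefix.append(first)
            rec(remaining - first, slots - 1, prefix)
            prefix.pop()

    rec(n, A, [])
    return out


def total_configurations(n: int, A: int) -> int:
    """Total allocation count via the partition-permutation formula."""
    if n == 0:
        return 1
    return sum(count_permutations(p, A) for p in integer_partitions(n, A))


def combine_server_types(
    per_type_lists: Mapping[str, Sequence[tuple[int, ...]]],
) -> list[Configuration]:
    """Cartesian product of per-type allocation lists, with sequential ids.

    The resulting count is the product of the per-type counts; ids start
    at 1 and follow the product order (last type varying fastest).
    """
    for typ, lst in per_type_lists.items():
        if not lst:
            raise ValueError(f"empty allocation list for server type {typ!r}")
    types = list(per_type_lists)
    configs = []
    for i, combo in enumerate(product(*(per_type_lists[t] for t in types)), start=1):
        configs.append(Configuration(i, dict(zip(types, combo))))
    return configs
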