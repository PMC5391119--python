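"""Breadth-first assembly of the skeleton graph ``G(P) = (V, E)``.

Starting from one known extreme point, each popped vertex has the cone of its
active set sliced to extreme rays, is pivoted along every ray to its
neighbours, and the unseen neighbours join a FIFO queue; the traversal stops
when the queue drains.  Skeletons of polytopes are connected, so this visits
every vertex.  Admission to the queue is checked against scanned *and*
queued vertices, so a vertex is expanded exactly once, and undirected edges
found from both endpoints collapse to a single sorted key pair.
"""

from __future__ import annotations

import math
import time
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Callable, Iterable, Literal, Sequence

from .hrep import HRepresentation, HRepError
from .linalg import (Ray, VertexRecord, is_extreme, make_vertex, nullspace,
                     rank_of_rows, slack_vector)
from .pivoting import UnboundedError, neighbors
from .slicing import Counters, slice_cone

__all__ = [
    "SkeletonGraph",
    "GuardError",
    "choose_basis",
    "tighten_to_vertex",
    "skeleton_graph",
    "enumerate_bases",
]

Key = tuple[Fraction, ...]


class GuardError(HRepError):
    """A combinatorial guard (enumeration cap) was exceeded."""


@dataclass
class VertexMeta:
    """Provenance of one scanned vertex: which cone description was used."""

    basis: tuple[int, ...]
    order: tuple[int, ...]
    n_rays: int


@dataclass
class SkeletonGraph:
    """The skeleton graph: exact vertices, undirected edges, provenance."""

    H: HRepresentation
    vertices: dict[Key, VertexRecord] = field(default_factory=dict)
    edges: set[tuple[Key, Key]] = field(default_factory=set)
    meta: dict[Key, VertexMeta] = field(default_factory=dict)
    counters: Counters = field(default_factory=Counters)
    timings: dict[str, float] = field(default_factory=dict)
    test_used: str = "algebraic"
    partial: bool = False

    def degree(self, key: Key) -> int:
        return sum(1 for e in self.edges if key in e)

    def degrees(self) -> dict[Key, int]:
        deg = {k: 0 for k in self.vertices}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def check_handshake(self) -> None:
        assert sum(self.degrees().values()) == 2 * len(self.edges)


def choose_basis(H: HRepresentation, Z: Iterable[int]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Deterministic basis of an active set: first ``n`` indices (ascending)
    that greedily increase the rank; the complement, ascending, is the
    insertion order.  Raises when ``rank(Z) < n`` (not a vertex)."""
    Zs = sorted(Z)
    n = H.n
    chosen: list[int] = []
    reduced: list[list[Fraction]] = []  # row-echelon accumulator
    pivot_cols: list[int] = []
    for i in Zs:
        if len(chosen) == n:
            break
        row = [Fraction(x) for x in H.row_int(i)]
        for r, pc in zip(reduced, pivot_cols):
            if row[pc]:
                f = row[pc] / r[pc]
                row = [x - f * y for x, y in zip(row, r)]
        pc = next((c for c, x in enumerate(row) if x), None)
        if pc is None:
            continue  # dependent on rows already chosen
        reduced.append(row)
        pivot_cols.append(pc)
        chosen.append(i)
    if len(chosen) < n:
        raise HRepError(f"active set {Zs} has rank {len(chosen)} < n = {n}: not a vertex")
    B = tuple(chosen)
    Bp = tuple(i for i in Zs if i not in set(chosen))
    return B, Bp


def tighten_to_vertex(H: HRepresentation, x0: Sequence[Fraction | int]) -> VertexRecord:
    """Walk a feasible point to an extreme point in at most ``n`` moves.

    While the active rows do not span the space, move along a null-space
    direction of the active rows (flipped if necessary so some constraint
    blocks it) until the nearest blocking hyperplane is hit; each move adds
    an independent active row.
    """
    x = [Fraction(v) for v in x0]
    s = slack_vector(H, x)
    if any(v < 0 for v in s):
        raise HRepError(f"start point {tuple(x)} is infeasible")
    for _ in range(H.n + 1):
        Z = [i for i, v in enumerate(slack_vector(H, x)) if v == 0]
        if rank_of_rows(H, Z) == H.n:
            return make_vertex(H, x)
        d = nullspace([H.row(i) for i in Z], H.n)[0]
        blocking = _blocking(H, Z, d)
        if not blocking:
            d = tuple(-v for v in d)
            blocking = _blocking(H, Z, d)
            if not blocking:
                raise UnboundedError(
                    "feasible line with no blocking constraint in either "
                    "orientation: the polytope is unbounded")
        lam = min((H.b[t] - sum(a * v for a, v in zip(H.A[t], x))) /
                  sum(a * v for a, v in zip(H.A[t], d))
                  for t in blocking)
        x = [xv + lam * dv for xv, dv in zip(x, d)]
    raise HRepError("tighten_to_vertex failed to converge (should be impossible)")


def _blocking(H: HRepresentation, Z: Iterable[int], d: Sequence[Fraction]) -> list[int]:
    Zs = set(Z)
    out = []
    for t in H.indices:
        if t in Zs:
            continue
        if sum(a * v for a, v in zip(H.A[t], d)) > 0:
            out.append(t)
    return out


BasisChooser = Callable[[HRepresentation, tuple[int, ...]],
                        tuple[tuple[int, ...], tuple[int, ...]]]


def _acquire_start(H: HRepresentation, start, interior_point) -> VertexRecord:
    if start is not None and start != "auto":
        feasible, extreme, _ = is_extreme(H, start)
        if not feasible:
            raise HRepError(f"start point {tuple(start)} is infeasible")
        if extreme:
            return make_vertex(H, start)
        return tighten_to_vertex(H, start)
    origin = [0] * H.n
    feasible, extreme, _ = is_extreme(H, origin)
    if extreme:
        return make_vertex(H, origin)
    if feasible:
        return tighten_to_vertex(H, origin)
    if interior_point is not None:
        return tighten_to_vertex(H, interior_point)
    raise HRepError(
        "no start vertex: the origin is infeasible and no start/interior "
        "point was supplied — pass start=<feasible point>")


def skeleton_graph(H: HRepresentation, start=None, *,
                   interior_point: Sequence[Fraction | int] | None = None,
                   test: Literal["algebraic", "combinatorial", "auto"] = "auto",
                   use_record: bool = True,
                   basis_chooser: BasisChooser | None = None,
                   order_fn: Callable[[tuple[int, ...]], Sequence[int]] | None = None,
                   allow_unbounded: bool = False) -> SkeletonGraph:
    """Convert ``Ax <= b`` into the complete skeleton graph of its polytope.

    ``test`` selects the colaminarity test; ``"auto"`` times both on the
    first vertex's cone and keeps the faster.  ``basis_chooser`` and
    ``order_fn`` override the deterministic basis choice and insertion order
    (the output graph does not depend on either).  Unbounded inputs raise
    :class:`UnboundedError` unless ``allow_unbounded`` marks the graph
    partial and skips receding rays.
    """
    t0 = time.perf_counter()
    v0 = _acquire_start(H, start, interior_point)
    chooser = basis_chooser or choose_basis
    G = SkeletonGraph(H=H)
    slicing_time = 0.0

    queue: deque[VertexRecord] = deque([v0])
    seen: set[Key] = {v0.key}
    chosen_test: str | None = None if test == "auto" else test

    while queue:
        v = queue.popleft()
        B, Bp = chooser(H, v.active)
        order = tuple(order_fn(Bp)) if order_fn is not None else Bp
        ts = time.perf_counter()
        if chosen_test is None:
            ta = time.perf_counter()
            st_a = slice_cone(H, B, order, test="algebraic", use_record=use_record)
            ta = time.perf_counter() - ta
            tc = time.perf_counter()
            st_c = slice_cone(H, B, order, test="combinatorial", use_record=use_record)
            tc = time.perf_counter() - tc
            assert st_a.ray_set() == st_c.ray_set()
            chosen_test = "algebraic" if ta <= tc else "combinatorial"
            state = st_a if chosen_test == "algebraic" else st_c
        else:
            state = slice_cone(H, B, order, test=chosen_test, use_record=use_record)
        slicing_time += time.perf_counter() - ts

        piv = neighbors(H, v, state.rays.values(), allow_unbounded=allow_unbounded)
        if piv.skipped_unbounded:
            G.partial = True
        G.vertices[v.key] = v
        G.meta[v.key] = VertexMeta(basis=B, order=order, n_rays=len(state.rays))
        G.edges |= piv.edges
        c = state.counters
        G.counters.tests += c.tests
        G.counters.record_hits += c.record_hits
        G.counters.rejections += c.rejections
        G.counters.duplicates_merged += c.duplicates_merged
        G.counters.ray_counts.extend(c.ray_counts)
        for q in piv.neighbors.values():
            if q.key not in seen:
                seen.add(q.key)
                queue.append(q)

    total = time.perf_counter() - t0
    G.timings = {"slicing": slicing_time, "traversal": total - slicing_time,
                 "total": total}
    G.test_used = chosen_test or "algebraic"
    G.check_handshake()
    return G


def enumerate_bases(H: HRepresentation, Z: Iterable[int], *,
                    cap: int = 10 ** 6, collect: bool = False):
    """Count (and optionally list) the rank-``n`` subsets of an active set.

    Exhaustive exact rank checks over all ``C(|Z|, n)`` subsets; refuses with
    :class:`GuardError` when that count exceeds ``cap``.
    """
    Zs = sorted(Z)
    n = H.n
    if rank_of_rows(H, Zs) != n:
        raise HRepError(f"active set {Zs} has rank < n: not a vertex")
    total = math.comb(len(Zs), n)
    if total > cap:
        raise GuardError(
            f"C({len(Zs)}, {n}) = {total} exceeds the enumeration cap {cap}")
    count = 0
    found: list[tuple[int, ...]] | None = [] if collect else None
    for subset in combinations(Zs, n):
        if rank_of_rows(H, subset) == n:
            count += 1
            if found is not None:
                found.append(subset)
    return count, found
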