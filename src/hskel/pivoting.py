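"""Min-ratio pivoting: from a vertex along its cone's extreme rays to the
neighbouring vertices.

For a compact feasible region every extreme ray ``rho`` of the cone at ``p``
eventually hits one of the hyperplanes not active at ``p``; the blocking set
is ``N_p(rho) = {t in I \\ Z(p) : a_t . rho > 0}`` and the hyperplane reached
first — at step length ``lambda_t = (b_t - a_t . p) / (a_t . rho)`` — yields
the neighbour ``q = p + lambda rho`` with ``lambda = min_t lambda_t``.  Ties
among the minimizing ``t`` simply mean the neighbour is itself degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .hrep import HRepresentation, HRepError
from .linalg import Ray, VertexRecord, make_vertex

__all__ = ["PivotResult", "UnboundedError", "step_length", "neighbors"]


class UnboundedError(HRepError):
    """A ray of the vertex cone recedes to infinity: the polytope is unbounded."""


@dataclass
class PivotResult:
    """Neighbours of one vertex and the edges reaching them."""

    vertex: VertexRecord
    neighbors: dict[tuple[Fraction, ...], VertexRecord]
    edges: set[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]]
    steps: list[tuple[Ray, Fraction]] = field(default_factory=list)
    skipped_unbounded: list[Ray] = field(default_factory=list)


def step_length(H: HRepresentation, p: Sequence[Fraction | int], rho: Ray | Sequence[int],
                t: int) -> Fraction:
    """Exact step ``lambda_t = (b_t - a_t . p) / (a_t . rho)`` to hyperplane ``t``.

    Requires ``a_t . rho > 0`` (i.e. ``t`` blocks the ray); homogeneous of
    degree -1 in the scale of ``rho``, so the reached point is scale-free.
    """
    d = rho.direction if isinstance(rho, Ray) else tuple(rho)
    at = H.row(t)
    denom = sum(a * Fraction(x) for a, x in zip(at, d))
    if denom <= 0:
        raise HRepError(
            f"constraint {t} does not block the ray (a_t . rho = {denom} <= 0)")
    num = H.b[t] - sum(a * Fraction(x) for a, x in zip(at, p))
    lam = num / denom
    if lam <= 0:
        raise HRepError(f"non-positive step to constraint {t}: is p feasible?")
    return lam


def neighbors(H: HRepresentation, vertex: VertexRecord, rays: Iterable[Ray], *,
              allow_unbounded: bool = False) -> PivotResult:
    """All neighbouring vertices of ``vertex`` along the given extreme rays.

    ``rays`` must be the extreme rays of the cone at the vertex (the output
    of cone slicing).  Each ray is followed to the nearest blocking
    hyperplane; a ray with no blocking hyperplane means the polytope is
    unbounded along it, which raises :class:`UnboundedError` unless
    ``allow_unbounded`` marks the result partial instead.
    """
    p = vertex.point
    Z = set(vertex.active)
    outside = [t for t in H.indices if t not in Z]
    res = PivotResult(vertex=vertex, neighbors={}, edges=set())
    for rho in rays:
        blocking = []
        for t in outside:
            d = sum(a * x for a, x in zip(H.row_int(t), rho.direction) if a)
            if d > 0:
                blocking.append(t)
        if not blocking:
            if allow_unbounded:
                res.skipped_unbounded.append(rho)
                continue
            raise UnboundedError(
                f"ray {rho.direction} at vertex {p} never hits a constraint: "
                "the feasible region is unbounded")
        lam = min(step_length(H, p, rho, t) for t in blocking)
        q = tuple(x + lam * f for x, f in zip(p, rho.direction))
        if q in res.neighbors:
            raise HRepError(
                f"two distinct extreme rays reached the same neighbour {q}; "
                "input cone rays were not extreme")
        res.neighbors[q] = make_vertex(H, q)
        a, b = sorted((p, q))
        res.edges.add((a, b))
        res.steps.append((rho, lam))
    return res
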