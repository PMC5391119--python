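"""Exact rational linear algebra for vertex and ray certificates.

Everything sign-critical (slacks, active sets, ranks, ray membership) runs in
exact rational arithmetic; degeneracy detection is a zero-test and tolerances
would silently merge or split faces.  Rank is computed fraction-free: rows are
rescaled to integers, then reduced modulo the Mersenne prime ``2^61 - 1``
whenever a Hadamard bound certifies that no minor can wrap (this covers every
small-coefficient system, where rank is called hundreds of thousands of
times), with an exact rational elimination as the general fallback.

Key objects:

``VertexRecord``
    an extreme point ``p`` with its slack vector ``s(p) = b - Ap``, active set
    ``Z(p) = {i : a_i . p = b_i}`` and degeneracy ``sigma = |Z(p)| - n``.
``Ray``
    a primitive integer direction ``rho`` of a cone together with the subset
    ``J|rho`` of the cone's constraints tight on it.  A ray is extreme in the
    cone ``{x : a_i . x <= 0, i in J}`` iff ``rank(J|rho) = n - 1``.

The base cone at a vertex is spanned by the negated biorthogonal companion of
a basis ``B`` of its active set: the ``n`` rays ``rho_j`` with
``a_i . rho_j = -delta_ij`` for ``i, j in B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .hrep import HRepresentation, HRepError

__all__ = [
    "Ray",
    "VertexRecord",
    "primitive",
    "matrix_rank",
    "slack_vector",
    "active_set",
    "is_extreme",
    "make_vertex",
    "biorthogonal_rays",
    "multiplicity",
]

_P = (1 << 61) - 1  # Mersenne prime for the certified modular rank path
_P2 = _P * _P


# ---------------------------------------------------------------------------
# normalization

def primitive(vec: Sequence[Fraction | int]) -> tuple[int, ...]:
    """Rescale a nonzero rational vector by a positive rational to a primitive
    integer vector (content 1, orientation preserved)."""
    fr = [Fraction(x) for x in vec]
    if all(x == 0 for x in fr):
        raise ValueError("zero vector has no primitive form")
    lcm = math.lcm(*(x.denominator for x in fr))
    ints = [int(x * lcm) for x in fr]
    g = math.gcd(*ints)
    return tuple(x // g for x in ints)


# ---------------------------------------------------------------------------
# rank

def _rank_mod(rows: list[Sequence[int]], ncols: int) -> int:
    M = [[x % _P for x in r] for r in rows]
    pr = 0
    for c in range(ncols):
        piv = None
        for i in range(pr, len(M)):
            if M[i][c]:
                piv = i
                break
        if piv is None:
            continue
        M[pr], M[piv] = M[piv], M[pr]
        prow = M[pr]
        inv = pow(prow[c], _P - 2, _P)
        for i in range(pr + 1, len(M)):
            row = M[i]
            if row[c]:
                f = (row[c] * inv) % _P
                for j in range(c, ncols):
                    row[j] = (row[j] - f * prow[j]) % _P
        pr += 1
        if pr == len(M):
            break
    return pr


def _rank_exact(rows: list[Sequence[Fraction]], ncols: int) -> int:
    M = [[Fraction(x) for x in r] for r in rows]
    pr = 0
    for c in range(ncols):
        piv = None
        for i in range(pr, len(M)):
            if M[i][c]:
                piv = i
                break
        if piv is None:
            continue
        M[pr], M[piv] = M[piv], M[pr]
        prow = M[pr]
        for i in range(pr + 1, len(M)):
            row = M[i]
            if row[c]:
                f = row[c] / prow[c]
                for j in range(c, ncols):
                    row[j] -= f * prow[j]
        pr += 1
        if pr == len(M):
            break
    return pr


def _rank_int_rows(rows: list[tuple[int, ...]], ncols: int) -> int:
    # Hadamard: every minor^2 <= prod of row norms^2; if that stays below P^2
    # no nonzero minor can vanish mod P and the modular rank is exact.
    bound = 1
    for r in rows:
        s = sum(x * x for x in r)
        bound *= s
        if bound >= _P2:
            return _rank_exact(rows, ncols)
    return _rank_mod(rows, ncols)


def matrix_rank(rows: Iterable[Sequence[Fraction | int]], n: int | None = None) -> int:
    """Exact rank over the rationals of a collection of row vectors.

    Invariant under row permutation and scaling by nonzero rationals; an empty
    collection has rank 0.  ``n`` (the row length) is only needed when
    ``rows`` may be empty.
    """
    rows = list(rows)
    int_rows = []
    for r in rows:
        fr = [Fraction(x) for x in r]
        if all(x == 0 for x in fr):
            continue
        lcm = math.lcm(*(x.denominator for x in fr))
        int_rows.append(tuple(int(x * lcm) for x in fr))
    if not int_rows:
        return 0
    ncols = len(int_rows[0])
    return _rank_int_rows(int_rows, ncols)


def rank_of_rows(H: HRepresentation, indices: Iterable[int]) -> int:
    """Rank of the constraint rows ``{a_i : i in indices}`` (integer-scaled)."""
    rows = [H.row_int(i) for i in indices]
    if not rows:
        return 0
    return _rank_int_rows(rows, H.n)


# ---------------------------------------------------------------------------
# square solves (small systems only: base-cone construction, oracles)

def invert_square(rows: Sequence[Sequence[Fraction]]) -> list[list[Fraction]]:
    """Inverse of a square rational matrix by Gauss-Jordan elimination."""
    n = len(rows)
    M = [[Fraction(x) for x in r] + [Fraction(int(i == j)) for j in range(n)]
         for i, r in enumerate(rows)]
    for c in range(n):
        piv = None
        for i in range(c, n):
            if M[i][c]:
                piv = i
                break
        if piv is None:
            raise HRepError("singular matrix")
        M[c], M[piv] = M[piv], M[c]
        pv = M[c][c]
        M[c] = [x / pv for x in M[c]]
        for i in range(n):
            if i != c and M[i][c]:
                f = M[i][c]
                M[i] = [x - f * y for x, y in zip(M[i], M[c])]
    return [row[n:] for row in M]


def nullspace(rows: Sequence[Sequence[Fraction | int]], n: int) -> list[tuple[Fraction, ...]]:
    """Basis of the exact rational null space of the given rows (length ``n``).

    Deterministic: free columns are taken in ascending order, so repeated
    calls pick the same directions.
    """
    M = [[Fraction(x) for x in r] for r in rows]
    pivots: list[int] = []
    pr = 0
    for c in range(n):
        piv = None
        for i in range(pr, len(M)):
            if M[i][c]:
                piv = i
                break
        if piv is None:
            continue
        M[pr], M[piv] = M[piv], M[pr]
        pv = M[pr][c]
        M[pr] = [x / pv for x in M[pr]]
        for i in range(len(M)):
            if i != pr and M[i][c]:
                f = M[i][c]
                M[i] = [x - f * y for x, y in zip(M[i], M[pr])]
        pivots.append(c)
        pr += 1
    basis = []
    free = [c for c in range(n) if c not in pivots]
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -M[r][fc]
        basis.append(tuple(v))
    return basis


# ---------------------------------------------------------------------------
# vertex and ray records

@dataclass(frozen=True)
class Ray:
    """Primitive integer direction with its active subset in the owning cone."""

    direction: tuple[int, ...]
    active: frozenset[int]

    def __hash__(self) -> int:  # identity is the canonical direction
        return hash(self.direction)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Ray) and self.direction == other.direction


@dataclass(frozen=True)
class VertexRecord:
    """An extreme point with its slack vector, active set and degeneracy."""

    point: tuple[Fraction, ...]
    slack: tuple[Fraction, ...]
    active: tuple[int, ...]
    sigma: int

    @property
    def key(self) -> tuple[Fraction, ...]:
        """Canonical hashable key (the exact coordinates)."""
        return self.point

    def __hash__(self) -> int:
        return hash(self.point)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VertexRecord) and self.point == other.point


def slack_vector(H: HRepresentation, p: Sequence[Fraction | int]) -> tuple[Fraction, ...]:
    """Exact slack vector ``s(p) = b - Ap``."""
    pt = [Fraction(x) for x in p]
    if len(pt) != H.n:
        raise HRepError(f"point has dimension {len(pt)}, expected {H.n}")
    return tuple(
        H.b[i] - sum(a * x for a, x in zip(H.A[i], pt) if a)
        for i in range(H.m)
    )


def active_set(H: HRepresentation, p: Sequence[Fraction | int]) -> tuple[int, ...]:
    """Indices of constraints tight at ``p`` (ascending)."""
    s = slack_vector(H, p)
    return tuple(i for i, v in enumerate(s) if v == 0)


def is_extreme(H: HRepresentation, p: Sequence[Fraction | int]):
    """Classify a point: ``(feasible, extreme, sigma)``.

    ``p`` is feasible iff its slack vector is non-negative, and extreme iff in
    addition its active rows have full rank ``n``; then ``sigma = |Z(p)| - n``
    is its degeneracy (``sigma`` is ``None`` for non-extreme points).
    """
    s = slack_vector(H, p)
    feasible = all(v >= 0 for v in s)
    if not feasible:
        return False, False, None
    Z = [i for i, v in enumerate(s) if v == 0]
    extreme = rank_of_rows(H, Z) == H.n
    sigma = len(Z) - H.n if extreme else None
    return True, extreme, sigma


def make_vertex(H: HRepresentation, p: Sequence[Fraction | int]) -> VertexRecord:
    """Build the :class:`VertexRecord` of an extreme point; raises otherwise."""
    pt = tuple(Fraction(x) for x in p)
    s = slack_vector(H, pt)
    if any(v < 0 for v in s):
        raise HRepError(f"point {pt} is infeasible")
    Z = tuple(i for i, v in enumerate(s) if v == 0)
    if rank_of_rows(H, Z) != H.n:
        raise HRepError(f"point {pt} is feasible but not extreme (rank(Z) < n)")
    return VertexRecord(point=pt, slack=s, active=Z, sigma=len(Z) - H.n)


def biorthogonal_rays(H: HRepresentation, basis: Iterable[int]) -> list[Ray]:
    """Extreme rays of the regular cone of a basis ``B``.

    Solves ``a_i . rho_j = -delta_ij`` for ``i, j in B`` (the rays are the
    negated columns of the inverse of the basis matrix), normalizes each ray
    to primitive integer form, and attaches the active subset ``B \\ {j}``.
    Raises for ``|B| != n`` or a singular basis.
    """
    B = sorted(basis)
    if len(B) != H.n or len(set(B)) != H.n:
        raise HRepError(f"basis must contain n = {H.n} distinct indices, got {B}")
    try:
        inv = invert_square([H.A[i] for i in B])
    except HRepError:
        raise HRepError(f"rows of {B} are singular: not a basis") from None
    rays = []
    for j, bj in enumerate(B):
        col = [-inv[i][j] for i in range(H.n)]
        rays.append(Ray(direction=primitive(col),
                        active=frozenset(B) - {bj}))
    return rays


def multiplicity(n: int, m: int, sigma: int) -> int:
    """Simplex search multiplicity at a ``sigma``-degenerate vertex.

    ``mu = n * (m - n - sigma) * C(n + sigma, n)``: the number of candidate
    (tableau, row, column) inspections an exhaustive simplex neighbour search
    faces at such a vertex.
    """
    if n < 0 or sigma < 0 or m - n - sigma < 0:
        raise ValueError(f"invalid arguments (n={n}, m={m}, sigma={sigma})")
    return n * (m - n - sigma) * math.comb(n + sigma, n)
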